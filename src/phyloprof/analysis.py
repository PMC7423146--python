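"""Network reconstruction and benchmarking over signature collections.

Covers the downstream analyses a profiling study runs once signatures
exist: all-vs-all Jaccard kernels, UPGMA (average-linkage) clustering with a
flat height cutoff, the classical baseline profile distances (binary
Pearson, occurrence Euclidean/Pearson), ROC/AUC evaluation on labelled
family pairs, and top-k network augmentation through the LSH Forest.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_auc_score, roc_curve

from .lshforest import ForestIndex
from .minhash import Signature, _check_comparable, _mix64

__all__ = [
    "Kernel",
    "ClusterAssignment",
    "BenchmarkPair",
    "build_kernel",
    "upgma_clusters",
    "binary_pearson",
    "occurrence_metrics",
    "roc_auc",
    "bootstrap_auc_ci",
    "augment_network",
]


@dataclass
class Kernel:
    """Square symmetric pairwise similarity matrix with row/column ids."""

    family_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.family_ids):
            raise ValueError("kernel matrix must be square and match the id list")
        self.matrix = m

    def to_tsv(self) -> str:
        df = pd.DataFrame(self.matrix, index=self.family_ids, columns=self.family_ids)
        buf = io.StringIO()
        df.to_csv(buf, sep="\t")
        return buf.getvalue()


@dataclass
class ClusterAssignment:
    """Flat clustering of families at a given merge-height cutoff."""

    labels: dict[str, int]
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def to_tsv(self) -> str:
        lines = ["family_id\tcluster"]
        lines += [f"{fam}\t{self.labels[fam]}" for fam in sorted(self.labels)]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class BenchmarkPair:
    """A labelled family pair: interacting (True) or not (False)."""

    family_a: str
    family_b: str
    label: bool

    def __post_init__(self):
        if self.family_a == self.family_b:
            raise ValueError("benchmark pair must join two distinct families")


# ---------------------------------------------------------------------------
# kernels and clustering
# ---------------------------------------------------------------------------


def build_kernel(sigs: list[Signature]) -> Kernel:
    """All-vs-all Jaccard-estimate matrix (diagonal 1, symmetric)."""
    if len(sigs) < 2:
        raise ValueError("a kernel needs at least 2 signatures")
    first = sigs[0]
    for s in sigs[1:]:
        _check_comparable(first, s)
    combined = np.stack([s.combined() for s in sigs])  # (m, n) uint64
    m = len(sigs)
    out = np.eye(m)
    for i in range(m - 1):
        sims = np.mean(combined[i + 1 :] == combined[i], axis=1)
        out[i, i + 1 :] = sims
        out[i + 1 :, i] = sims
    return Kernel([s.family_id for s in sigs], out)


def upgma_clusters(kern: Kernel, cutoff: float) -> ClusterAssignment:
    """Average-linkage clustering of ``1 - similarity``, cut at ``cutoff``.

    Heights are ultrametric node ages (half the cophenetic distance), so two
    identical families merge at height 0 and co-clustered families never
    merge above ``cutoff``. Rows are canonically reordered by family id
    before linkage, which makes the flat partition invariant under
    row/column permutations of the input kernel, ties included.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    m = kern.matrix
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("kernel matrix is not symmetric")
    order = np.argsort(np.asarray(kern.family_ids, dtype=object), kind="stable")
    ids = [kern.family_ids[i] for i in order]
    dist = 1.0 - m[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    flat = fcluster(z, t=2.0 * cutoff, criterion="distance")
    return ClusterAssignment({fam: int(c) for fam, c in zip(ids, flat)}, cutoff)


# ---------------------------------------------------------------------------
# baseline profile distances
# ---------------------------------------------------------------------------


def binary_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of binarised profiles (any weight > 0 counts 1).

    A constant vector has no defined correlation and raises; benchmark
    callers drop (and count) such pairs.
    """
    a = (np.asarray(a) > 0).astype(float)
    b = (np.asarray(b) > 0).astype(float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson correlation undefined for constant vectors")
    return float(np.corrcoef(a, b)[0, 1])


def occurrence_metrics(a: np.ndarray, b: np.ndarray) -> tuple[float, float | None]:
    """(Euclidean distance, Pearson r) on copy-number occurrence profiles.

    Pearson is ``None`` when either vector is constant; the Euclidean
    distance is always returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    euclidean = float(np.sqrt(np.sum((a - b) ** 2)))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return euclidean, None
    return euclidean, float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# ROC / AUC benchmarking
# ---------------------------------------------------------------------------


def _pair_key(p: BenchmarkPair) -> tuple[str, str]:
    return (p.family_a, p.family_b)


def roc_auc(
    pairs: list[BenchmarkPair], scores: dict[tuple[str, str], float]
) -> tuple[np.ndarray, float]:
    """ROC curve points (fpr, tpr) and AUC for scored labelled pairs.

    Higher scores must mean "more likely interacting" (negate distances
    first). Ties follow the Mann-Whitney midpoint convention.
    """
    y = np.array([p.label for p in pairs], dtype=int)
    try:
        s = np.array([scores[_pair_key(p)] for p in pairs], dtype=float)
    except KeyError as exc:
        raise KeyError(f"missing score for pair {exc}") from exc
    if len(set(y)) < 2:
        raise ValueError("ROC needs both interacting and non-interacting pairs")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return np.column_stack([fpr, tpr]), auc


def bootstrap_auc_ci(
    pairs: list[BenchmarkPair],
    scores: dict[tuple[str, str], float],
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC (resampling pairs)."""
    y = np.array([p.label for p in pairs], dtype=int)
    s = np.array([scores[_pair_key(p)] for p in pairs], dtype=float)
    rng = np.random.default_rng(seed)
    stats = []
    while len(stats) < n_boot:
        idx = rng.integers(0, len(y), size=len(y))
        if len(set(y[idx])) < 2:
            continue
        stats.append(roc_auc_score(y[idx], s[idx]))
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# network augmentation
# ---------------------------------------------------------------------------


def augment_network(
    idx: ForestIndex, query_ids: list[str], k: int
) -> Kernel:
    """Kernel over the queries plus their deduplicated top-k neighbours.

    This is the module-discovery loop: seed families retrieve their closest
    co-evolving partners from the forest, and the joint all-vs-all kernel is
    ready for UPGMA clustering.
    """
    unknown = [q for q in query_ids if q not in idx]
    if unknown:
        raise KeyError(f"query ids not indexed: {', '.join(unknown)}")
    union: list[str] = []
    seen: set[str] = set()
    for q in query_ids:
        if q not in seen:
            seen.add(q)
            union.append(q)
    for q in query_ids:
        for fam, _sim in idx.query(idx.signature(q), k + 1):
            if fam not in seen:
                seen.add(fam)
                union.append(fam)
    return build_kernel([idx.signature(fam) for fam in union])
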