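"""LSH Forest: sub-linear top-k retrieval of similar MinHash signatures.

The forest splits each length-n signature into ``l`` disjoint slices of
r = n/l samples. Each slice is rendered as a byte string (8 hashed bytes per
sample) and stored, sorted, in one prefix tree realised as a sorted key
array with binary search — the classic B-tree/sorted-array embodiment of an
LSH Forest. A query descends from the deepest prefix (r samples) towards
the root, harvesting every indexed signature that shares its leading
samples in any tree; because a prefix of length d matches with probability
J^d, high-similarity families surface at deep levels first. Candidates are
then re-ranked with the full-signature Jaccard estimate, so the forest is a
candidate generator only and the returned ranking is exact with respect to
the estimator.

Insertion is incremental (sorted insert into each tree), and a forest is
rebuilt from its HDF5 signature store on load — signatures, not the tree
structure, are the persisted artefact.
"""

from __future__ import annotations

from bisect import bisect_left, insort

from .minhash import Signature, estimate_jaccard, _check_comparable
from .store import load_signatures

__all__ = ["ForestIndex", "build_index", "load_index", "DEFAULT_N_TREES"]

DEFAULT_N_TREES = 8


class ForestIndex:
    """Prefix-tree ensemble over permuted signature sample slices."""

    def __init__(self, n: int, l: int, scheme_seed: int | None):
        if n % l != 0:
            raise ValueError(f"n ({n}) must be divisible by the tree count l ({l})")
        self.n = n
        self.l = l
        self.r = n // l
        self.scheme_seed = scheme_seed
        self.family_ids: list[str] = []  # internal id -> family id
        self._id_of: dict[str, int] = {}
        self._signatures: list[Signature] = []
        # per tree: parallel sorted (keys, internal ids)
        self._keys: list[list[bytes]] = [[] for _ in range(l)]
        self._ids: list[list[int]] = [[] for _ in range(l)]
        self.last_inspected = 0  # entries scanned by the most recent query

    def __len__(self) -> int:
        return len(self.family_ids)

    def __contains__(self, family_id: str) -> bool:
        return family_id in self._id_of

    def signature(self, family_id: str) -> Signature:
        return self._signatures[self._id_of[family_id]]

    # -- construction ------------------------------------------------------

    def _slice_keys(self, s: Signature) -> list[bytes]:
        data = s.combined().astype(">u8").tobytes()
        step = 8 * self.r
        return [data[t * step : (t + 1) * step] for t in range(self.l)]

    def _check(self, s: Signature) -> None:
        if self.scheme_seed is None and not self.family_ids:
            # empty index built without signatures adopts the first scheme seen
            if s.n % self.l != 0:
                raise ValueError(
                    f"signature n ({s.n}) not divisible by the tree count ({self.l})"
                )
            self.n = s.n
            self.r = s.n // self.l
            self.scheme_seed = s.scheme_seed
        if s.n != self.n:
            raise ValueError(f"signature n ({s.n}) does not match index n ({self.n})")
        if s.scheme_seed != self.scheme_seed:
            raise ValueError(
                f"signature scheme_seed ({s.scheme_seed}) does not match "
                f"index scheme_seed ({self.scheme_seed})"
            )

    def insert(self, s: Signature) -> "ForestIndex":
        """Add one signature; it becomes retrievable immediately."""
        self._check(s)
        if s.family_id in self._id_of:
            raise ValueError(f"family {s.family_id!r} already indexed")
        internal = len(self.family_ids)
        self.family_ids.append(s.family_id)
        self._id_of[s.family_id] = internal
        self._signatures.append(s)
        for t, key in enumerate(self._slice_keys(s)):
            pos = bisect_left(self._keys[t], key)
            # ids with equal keys stay ordered by insertion for determinism
            while pos < len(self._keys[t]) and self._keys[t][pos] == key:
                pos += 1
            self._keys[t].insert(pos, key)
            self._ids[t].insert(pos, internal)
        return self

    # -- retrieval ---------------------------------------------------------

    def query(
        self,
        q: Signature,
        k: int,
        min_candidates: int | None = None,
    ) -> list[tuple[str, float]]:
        """Top-k most similar indexed families, ranked by Jaccard estimate.

        ``min_candidates`` floors the size of the candidate pool gathered
        before re-ranking (default ``max(16*k, 100)``); larger pools trade
        query time for recall.
        """
        self._check(q)
        if k < 1:
            raise ValueError("k must be >= 1")
        if not self.family_ids:
            return []
        if min_candidates is None:
            min_candidates = max(16 * k, 100)
        needed = min(max(k, min_candidates), len(self.family_ids))

        qkeys = self._slice_keys(q)
        candidates: set[int] = set()
        inspected = 0
        # depth 0 matches everything; only fall through to it when fewer
        # than k candidates exist at every positive prefix depth
        floor_depth = 1 if len(self.family_ids) > k else 0
        for depth in range(self.r, floor_depth - 1, -1):
            for t in range(self.l):
                prefix = qkeys[t][: 8 * depth]
                keys = self._keys[t]
                i = bisect_left(keys, prefix)
                while i < len(keys) and keys[i].startswith(prefix):
                    inspected += 1
                    candidates.add(self._ids[t][i])
                    i += 1
            if len(candidates) >= needed:
                break
        if len(candidates) < min(k, len(self.family_ids)):
            inspected += len(self.family_ids)
            candidates.update(range(len(self.family_ids)))
        self.last_inspected = inspected

        scored = sorted(
            ((estimate_jaccard(q, self._signatures[c]), c) for c in candidates),
            key=lambda sc: (-sc[0], sc[1]),
        )
        return [(self.family_ids[c], est) for est, c in scored[:k]]


def build_index(
    signatures: list[Signature], l: int = DEFAULT_N_TREES
) -> ForestIndex:
    """Batch-build a forest; equivalent to inserting one by one."""
    if signatures:
        first = signatures[0]
        for s in signatures[1:]:
            _check_comparable(first, s)
        idx = ForestIndex(first.n, l, first.scheme_seed)
    else:
        idx = ForestIndex(DEFAULT_N_HASHES_FALLBACK, l, None)
    for s in signatures:
        idx.insert(s)
    return idx


DEFAULT_N_HASHES_FALLBACK = 256


def load_index(store_path, l: int = DEFAULT_N_TREES) -> ForestIndex:
    """Rebuild a forest from an HDF5 signature store."""
    signatures, meta = load_signatures(store_path)
    if not signatures:
        return ForestIndex(DEFAULT_N_HASHES_FALLBACK, l, None)
    return build_index(signatures, l=l)
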