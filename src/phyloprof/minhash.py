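"""Weighted MinHash signatures and Jaccard estimation.

Profiles are sketched with consistent weighted sampling (Ioffe 2010): for
each of ``n`` independent hash functions the scheme samples one coordinate
(and a discretised weight level) such that two profiles draw the *same*
sample with probability equal to their weighted Jaccard similarity

    J(a, b) = sum_i min(a_i, b_i) / sum_i max(a_i, b_i).

The fraction of matching positions between two signatures is therefore an
unbiased estimator of J with standard error sqrt(J(1-J)/n); comparing two
signatures costs O(n) regardless of profile dimensionality.

Hash parameters depend only on (scheme seed, coordinate, sample position),
so signatures are deterministic and comparable across sessions as long as
seed and n match — both are recorded on every signature and refuse to mix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import WeightedProfile

__all__ = [
    "Signature",
    "sign",
    "estimate_jaccard",
    "exact_weighted_jaccard",
    "DEFAULT_N_HASHES",
    "DEFAULT_SCHEME_SEED",
]

DEFAULT_N_HASHES = 256
DEFAULT_SCHEME_SEED = 1


@dataclass
class Signature:
    """Fixed-length weighted-MinHash sketch of one profile.

    ``samples`` has shape (n, 2): column 0 is the sampled coordinate id,
    column 1 the discretised weight level.
    """

    family_id: str
    samples: np.ndarray
    n: int
    scheme_seed: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.int64)
        if self.samples.shape != (self.n, 2):
            raise ValueError("samples must have shape (n, 2)")

    def combined(self) -> np.ndarray:
        """64-bit mix of each (coordinate, level) pair; used for fast
        equality tests and as LSH key material."""
        return _mix64(self.samples[:, 0], self.samples[:, 1])


def _check_comparable(a: Signature, b: Signature) -> None:
    if a.n != b.n:
        raise ValueError(f"signatures not comparable: n differs ({a.n} vs {b.n})")
    if a.scheme_seed != b.scheme_seed:
        raise ValueError(
            "signatures not comparable: scheme_seed differs "
            f"({a.scheme_seed} vs {b.scheme_seed})"
        )


def _mix64(k: np.ndarray, t: np.ndarray) -> np.ndarray:
    # splitmix64-style finaliser over the packed (coordinate, level) pair
    x = (k.astype(np.uint64) << np.uint64(32)) ^ (
        t.astype(np.int64).astype(np.uint64) * np.uint64(0x9E3779B97F4A7C15)
    )
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


class _CwsParams:
    """Per-(seed, n) cache of Ioffe hash parameters, one row per coordinate.

    Parameters are drawn lazily per coordinate from a seed sequence keyed by
    (scheme_seed, coordinate), so the same coordinate always re-derives the
    same r ~ Gamma(2,1), ln c with c ~ Gamma(2,1) and beta ~ U(0,1) rows, and
    the cache is shared by every profile signed under that scheme.
    """

    def __init__(self, scheme_seed: int, n: int):
        self.seed = scheme_seed
        self.n = n
        self._rows: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def rows(self, coords: np.ndarray):
        for k in coords:
            k = int(k)
            if k not in self._rows:
                rng = np.random.default_rng(np.random.SeedSequence([self.seed, k]))
                r = rng.gamma(2.0, 1.0, size=self.n)
                lnc = np.log(rng.gamma(2.0, 1.0, size=self.n))
                beta = rng.uniform(0.0, 1.0, size=self.n)
                self._rows[k] = (r, lnc, beta)
        r = np.stack([self._rows[int(k)][0] for k in coords])
        lnc = np.stack([self._rows[int(k)][1] for k in coords])
        beta = np.stack([self._rows[int(k)][2] for k in coords])
        return r, lnc, beta


_PARAM_CACHE: dict[tuple[int, int], _CwsParams] = {}


def _params(scheme_seed: int, n: int) -> _CwsParams:
    key = (scheme_seed, n)
    if key not in _PARAM_CACHE:
        if len(_PARAM_CACHE) >= 4:
            _PARAM_CACHE.pop(next(iter(_PARAM_CACHE)))
        _PARAM_CACHE[key] = _CwsParams(scheme_seed, n)
    return _PARAM_CACHE[key]


def sign(
    p: WeightedProfile,
    n: int = DEFAULT_N_HASHES,
    scheme_seed: int = DEFAULT_SCHEME_SEED,
) -> Signature:
    """Sketch a non-empty weighted profile with ``n`` hash functions."""
    if len(p.entries) == 0:
        raise ValueError("cannot MinHash an empty profile")
    if n < 1:
        raise ValueError("n must be >= 1")
    if scheme_seed < 0:
        raise ValueError("scheme_seed must be a non-negative integer")

    coords = np.array(sorted(p.entries), dtype=np.int64)
    weights = np.array([p.entries[int(c)] for c in coords], dtype=float)
    lnw = np.log(weights)[:, None]

    r, lnc, beta = _params(scheme_seed, n).rows(coords)
    t = np.floor(lnw / r + beta)  # discretised weight level
    ln_y = r * (t - beta)
    ln_a = lnc - ln_y - r
    best = np.argmin(ln_a, axis=0)
    pos = np.arange(n)
    samples = np.stack(
        [coords[best], t[best, pos].astype(np.int64)], axis=1
    )
    return Signature(p.family_id, samples, n, scheme_seed)


def estimate_jaccard(a: Signature, b: Signature) -> float:
    """Fraction of agreeing signature positions — the Jaccard estimate.

    Symmetric, in [0, 1], a multiple of 1/n, and exactly 1 iff the
    signatures are identical.
    """
    _check_comparable(a, b)
    return float(np.mean(np.all(a.samples == b.samples, axis=1)))


def exact_weighted_jaccard(a: WeightedProfile, b: WeightedProfile) -> float:
    """Brute-force weighted Jaccard sum(min)/sum(max) over sparse profiles."""
    if a.dim != b.dim:
        raise ValueError("profiles live in different coordinate spaces")
    if not a.entries and not b.entries:
        raise ValueError("weighted Jaccard of two empty profiles is undefined")
    num = 0.0
    den = 0.0
    for coord in set(a.entries) | set(b.entries):
        wa = a.entries.get(coord, 0.0)
        wb = b.entries.get(coord, 0.0)
        num += min(wa, wb)
        den += max(wa, wb)
    return num / den
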