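"""HDF5 persistence for signature collections.

The store is the source of truth for an index: the LSH Forest is rebuilt
from it on load. Layout: one integer matrix of shape (families, 2n) whose
rows interleave (coordinate, level) sample pairs, a parallel family-id
string dataset, and metadata attributes (n, scheme seed, coordinate packing
version, taxonomy checksum) that guard against mixing incompatible stores.
"""

from __future__ import annotations

import h5py
import numpy as np

from .minhash import Signature
from .profiles import PACKING_VERSION

__all__ = ["save_signatures", "load_signatures"]


def save_signatures(
    path,
    signatures: list[Signature],
    taxonomy_checksum: str = "",
) -> None:
    """Write signatures to an HDF5 store (overwrites ``path``)."""
    if signatures:
        n = signatures[0].n
        seed = signatures[0].scheme_seed
        for s in signatures:
            if s.n != n or s.scheme_seed != seed:
                raise ValueError("cannot store signatures with mixed (n, scheme_seed)")
        ids = [s.family_id for s in signatures]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate family ids in signature store")
        matrix = np.stack([s.samples.reshape(-1) for s in signatures])
    else:
        n, seed = 0, 0
        ids = []
        matrix = np.zeros((0, 0), dtype=np.int64)

    with h5py.File(path, "w") as fh:
        # fixed fill/track times keep rebuilds byte-reproducible
        fh.create_dataset("signatures", data=matrix, dtype=np.int64)
        fh.create_dataset(
            "family_ids",
            data=np.array(ids, dtype=h5py.string_dtype(encoding="utf-8")),
        )
        fh.attrs["n"] = n
        fh.attrs["scheme_seed"] = seed
        fh.attrs["packing_version"] = PACKING_VERSION
        fh.attrs["taxonomy_checksum"] = taxonomy_checksum


def load_signatures(path) -> tuple[list[Signature], dict]:
    """Read a store back into signatures plus its metadata dict."""
    with h5py.File(path, "r") as fh:
        matrix = fh["signatures"][...]
        ids = [
            s.decode() if isinstance(s, bytes) else str(s) for s in fh["family_ids"][...]
        ]
        meta = {
            "n": int(fh.attrs["n"]),
            "scheme_seed": int(fh.attrs["scheme_seed"]),
            "packing_version": int(fh.attrs["packing_version"]),
            "taxonomy_checksum": str(fh.attrs["taxonomy_checksum"]),
        }
    if meta["packing_version"] != PACKING_VERSION:
        raise ValueError(
            f"store uses coordinate packing v{meta['packing_version']}, "
            f"this build expects v{PACKING_VERSION}"
        )
    n = meta["n"]
    sigs = [
        Signature(fam, matrix[i].reshape(n, 2), n, meta["scheme_seed"])
        for i, fam in enumerate(ids)
    ]
    return sigs, meta
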