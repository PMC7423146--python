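"""Flatten event trees into the weighted multiset vectors MinHash consumes.

The profile coordinate space has one coordinate per (taxonomy node, event
category) pair, packed as ``3 * node_index + category`` with categories
0 = presence, 1 = loss, 2 = duplication. A taxonomy with N nodes therefore
spans a dense vector of length 3N. Events are encoded as the node's weight
(binary occurrence scaled by taxon weight), not by copy number: the weighted
Jaccard framing needs only multiset weights, and copy numbers stay available
on the event tree for the occurrence-profile baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hog_events import EventTree
from .taxonomy import Taxonomy

__all__ = [
    "CATEGORIES",
    "WeightedProfile",
    "build_profile",
    "profile_to_dense",
    "profile_to_tsv",
]

CATEGORIES = ("presence", "loss", "duplication")
PACKING_VERSION = 1  # coordinate id = 3 * node_index + category


@dataclass
class WeightedProfile:
    """Sparse weighted multiset over (node x event-category) coordinates."""

    family_id: str
    dim: int  # dense length = 3 * node_count
    entries: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        for coord, w in self.entries.items():
            if not (0 <= coord < self.dim):
                raise ValueError(
                    f"coordinate {coord} out of range for dense length {self.dim}"
                )
            if not w > 0:
                raise ValueError("profile weights must be strictly positive")

    def __len__(self) -> int:
        return len(self.entries)


def build_profile(ev: EventTree, tax: Taxonomy) -> WeightedProfile:
    """Encode an event tree as a weighted profile over ``tax``.

    Nodes with weight 0 contribute no coordinates (clade filtering); an event
    tree with no presence anywhere is refused as degenerate.
    """
    if ev.tax.node_count != tax.node_count or any(
        a.name != b.name for a, b in zip(ev.tax.nodes, tax.nodes)
    ):
        raise ValueError("event tree and taxonomy node sets do not match")
    entries: dict[int, float] = {}
    for node in tax.nodes:
        w = node.weight
        if w <= 0:
            continue
        i = node.index
        if ev.present[i]:
            entries[3 * i] = w
        if ev.lost[i]:
            entries[3 * i + 1] = w
        if ev.duplicated[i]:
            entries[3 * i + 2] = w
    if not any(ev.present):
        raise ValueError(f"family {ev.family_id!r} yields an empty profile")
    return WeightedProfile(ev.family_id, 3 * tax.node_count, entries)


def profile_to_dense(p: WeightedProfile, tax: Taxonomy) -> np.ndarray:
    """Dense weight vector of length ``3 * node_count`` (zeros elsewhere)."""
    dim = 3 * tax.node_count
    if p.dim != dim:
        raise ValueError(
            f"profile dense length {p.dim} does not match taxonomy ({dim})"
        )
    out = np.zeros(dim, dtype=float)
    for coord, w in p.entries.items():
        if not 0 <= coord < dim:
            raise ValueError(f"coordinate {coord} out of range")
        out[coord] = w
    return out


def profile_to_tsv(p: WeightedProfile, tax: Taxonomy) -> str:
    """Human-readable TSV export: family, coordinate, node, category, weight."""
    lines = ["family_id\tcoordinate\tnode_name\tcategory\tweight"]
    for coord in sorted(p.entries):
        node = tax.nodes[coord // 3]
        lines.append(
            f"{p.family_id}\t{coord}\t{node.name}\t"
            f"{CATEGORIES[coord % 3]}\t{p.entries[coord]:g}"
        )
    return "\n".join(lines) + "\n"
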