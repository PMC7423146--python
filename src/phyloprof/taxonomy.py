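"""Reference species taxonomy: the coordinate system of all profiles.

Every profile, signature and index in this package is defined over a single
rooted species tree whose nodes — leaves *and* internal taxonomic levels —
are uniquely named. Nodes are numbered in preorder (parent before children,
children in the order written in the newick source), and that numbering is
the master coordinate order: it is persisted alongside every signature store
so that signatures built in different sessions remain comparable.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field

import dendropy

__all__ = ["TaxNode", "Taxonomy", "load_taxonomy", "prune_to_leaves", "set_weights"]


@dataclass
class TaxNode:
    """A single taxon (leaf species or named internal taxonomic level)."""

    name: str
    index: int
    parent: int | None
    children: list[int] = field(default_factory=list)
    weight: float = 1.0

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Taxonomy:
    """Indexed rooted species tree with deterministic preorder node order.

    Attributes
    ----------
    nodes : list of TaxNode
        All nodes in preorder; ``nodes[i].index == i``.
    name_index : dict
        Unique node name -> preorder index.
    """

    def __init__(self, nodes: list[TaxNode]):
        self.nodes = nodes
        self.name_index: dict[str, int] = {n.name: n.index for n in nodes}
        if len(self.name_index) != len(nodes):
            raise ValueError("duplicate node names in taxonomy")
        # subtree_end[i]: one past the last preorder index inside i's subtree.
        # Preorder makes every subtree a contiguous index interval.
        self._subtree_end = [0] * len(nodes)
        for i in range(len(nodes) - 1, -1, -1):
            node = nodes[i]
            self._subtree_end[i] = (
                self._subtree_end[node.children[-1]] if node.children else i + 1
            )

    # -- basic structure ---------------------------------------------------

    @property
    def root(self) -> TaxNode:
        return self.nodes[0]

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    def index_of(self, name: str) -> int:
        try:
            return self.name_index[name]
        except KeyError:
            raise KeyError(f"unknown taxonomy node: {name!r}") from None

    def leaf_indices(self) -> list[int]:
        return [n.index for n in self.nodes if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.nodes if n.is_leaf]

    def subtree_interval(self, index: int) -> tuple[int, int]:
        """Half-open preorder interval [lo, hi) spanned by ``index``'s subtree."""
        return index, self._subtree_end[index]

    def is_descendant(self, index: int, ancestor: int) -> bool:
        """True if ``index`` lies in ``ancestor``'s subtree (descendant-or-self)."""
        return ancestor <= index < self._subtree_end[ancestor]

    def subtree_indices(self, index: int) -> range:
        lo, hi = self.subtree_interval(index)
        return range(lo, hi)

    # -- serialisation -----------------------------------------------------

    def to_newick(self) -> str:
        def render(i: int) -> str:
            node = self.nodes[i]
            if node.is_leaf:
                return node.name
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){node.name}"

        return render(0) + ";"

    def order_table(self) -> str:
        """TSV sidecar (index, name, weight) pinning the coordinate order."""
        buf = io.StringIO()
        buf.write("index\tname\tweight\n")
        for n in self.nodes:
            buf.write(f"{n.index}\t{n.name}\t{n.weight:g}\n")
        return buf.getvalue()

    def write_order(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.order_table())

    def checksum(self) -> str:
        """SHA-256 of the order table; stored with every signature store."""
        return hashlib.sha256(self.order_table().encode()).hexdigest()

    def copy(self) -> "Taxonomy":
        return Taxonomy(
            [
                TaxNode(n.name, n.index, n.parent, list(n.children), n.weight)
                for n in self.nodes
            ]
        )


def load_taxonomy(newick_text: str) -> Taxonomy:
    """Parse a rooted newick tree into an indexed :class:`Taxonomy`.

    All nodes, internal ones included, must carry unique non-empty labels:
    internal levels are first-class coordinates of the profile space, so an
    anonymous node would be an unaddressable coordinate.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise ValueError(f"malformed newick: {exc}") from exc
    if tree.seed_node is None:
        raise ValueError("malformed newick: empty tree")

    nodes: list[TaxNode] = []
    seen: set[str] = set()

    def visit(dnode, parent_index: int | None) -> int:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if label is None or label == "":
            raise ValueError("unnamed node in newick tree; all nodes need labels")
        if label in seen:
            raise ValueError(f"duplicate node label in newick tree: {label!r}")
        seen.add(label)
        index = len(nodes)
        node = TaxNode(name=label, index=index, parent=parent_index)
        nodes.append(node)
        for child in dnode.child_nodes():
            node.children.append(visit(child, index))
        return index

    visit(tree.seed_node, None)
    return Taxonomy(nodes)


def prune_to_leaves(tax: Taxonomy, keep: set[str]) -> Taxonomy:
    """Restrict ``tax`` to ``keep`` leaves and all of their ancestors.

    Internal nodes left with a single child are retained, not collapsed:
    taxonomic levels keep their identity (and their coordinates) even when
    only one lineage below them survives the pruning.
    """
    if not keep:
        raise ValueError("keep must be a non-empty set of leaf names")
    leaf_set = set(tax.leaf_names())
    unknown = sorted(set(keep) - leaf_set)
    if unknown:
        raise KeyError(f"unknown leaf names: {', '.join(unknown)}")

    kept: set[int] = set()
    for name in keep:
        i: int | None = tax.name_index[name]
        while i is not None and i not in kept:
            kept.add(i)
            i = tax.nodes[i].parent

    old_order = sorted(kept)  # preorder of the induced subtree
    remap = {old: new for new, old in enumerate(old_order)}
    nodes: list[TaxNode] = []
    for old in old_order:
        src = tax.nodes[old]
        parent = remap[src.parent] if src.parent is not None else None
        node = TaxNode(src.name, remap[old], parent, weight=src.weight)
        nodes.append(node)
        if parent is not None:
            nodes[parent].children.append(remap[old])
    return Taxonomy(nodes)


def set_weights(tax: Taxonomy, weights: dict[str, float]) -> Taxonomy:
    """Return a copy of ``tax`` with per-node weights overridden.

    Unnamed nodes keep their current weight (default 1.0). A weight of 0
    removes that node's coordinates from every profile built afterwards.
    """
    out = tax.copy()
    for name, w in weights.items():
        if name not in out.name_index:
            raise KeyError(f"unknown taxonomy node: {name!r}")
        if not (isinstance(w, (int, float)) and math.isfinite(w)) or w < 0:
            raise ValueError(f"weight for {name!r} must be finite and >= 0, got {w!r}")
        out.nodes[out.name_index[name]].weight = float(w)
    return out
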