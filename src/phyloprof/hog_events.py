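"""OrthoXML parsing and gain/loss/duplication inference for gene families.

A hierarchical orthologous group (HOG) is the set of genes descending from a
single ancestral gene at some taxonomic level. In OrthoXML a HOG is a nested
structure of ``orthologGroup`` elements (speciation nodes, annotated with a
``TaxRange`` property naming the taxonomic level), ``paralogGroup`` elements
(duplication nodes) and ``geneRef`` leaves. This module turns each family
into an *event tree*: a copy of the reference taxonomy annotated per node
with presence, loss, duplication and copy number — the same information a
labelled gene/species-tree reconciliation provides.

Conventions
-----------
* presence: a node is present iff it lies in the family's root-level subtree
  and has at least one extant member at or below it;
* loss: recorded only at the topmost node of each maximal extinct subtree
  whose parent is present — one event per loss;
* copy number: gene count at leaves; number of distinct gene lineages at a
  level for internal nodes (nested duplications compound multiplicatively);
* duplication: flagged exactly where copy number exceeds the parent's
  (the root level's parent copy number is defined as 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .taxonomy import Taxonomy

__all__ = [
    "GeneLeaf",
    "OrthologGroup",
    "ParalogGroup",
    "HogFamily",
    "EventTree",
    "parse_orthoxml",
    "infer_event_tree",
]

ORTHOXML_NS = "http://orthoXML.org/2011/"


@dataclass
class GeneLeaf:
    species: str
    gene_id: str


@dataclass
class OrthologGroup:
    level: str
    children: list = field(default_factory=list)


@dataclass
class ParalogGroup:
    level: str  # explicit TaxRange, or inherited from enclosing orthologGroup
    children: list = field(default_factory=list)


@dataclass
class HogFamily:
    """One parsed hierarchical orthologous group."""

    family_id: str
    root_level: str
    root: OrthologGroup

    def genes(self) -> list[GeneLeaf]:
        out: list[GeneLeaf] = []

        def walk(el):
            if isinstance(el, GeneLeaf):
                out.append(el)
            else:
                for c in el.children:
                    walk(c)

        walk(self.root)
        return out


class EventTree:
    """Per-family annotation of the taxonomy with evolutionary events.

    Arrays are indexed by taxonomy preorder index.
    """

    def __init__(
        self,
        family_id: str,
        tax: Taxonomy,
        present: np.ndarray,
        lost: np.ndarray,
        duplicated: np.ndarray,
        copy_number: np.ndarray,
    ):
        n = tax.node_count
        for arr in (present, lost, duplicated, copy_number):
            if arr.shape != (n,):
                raise ValueError("event arrays must match the taxonomy node count")
        self.family_id = family_id
        self.tax = tax
        self.present = present.astype(bool)
        self.lost = lost.astype(bool)
        self.duplicated = duplicated.astype(bool)
        self.copy_number = copy_number.astype(np.int64)

    def _names(self, mask: np.ndarray) -> set[str]:
        return {self.tax.nodes[i].name for i in np.flatnonzero(mask)}

    def present_names(self) -> set[str]:
        return self._names(self.present)

    def loss_names(self) -> set[str]:
        return self._names(self.lost)

    def duplication_names(self) -> set[str]:
        return self._names(self.duplicated)

    @property
    def gain_node(self) -> str:
        """Name of the topmost present node (where the ancestral gene appeared)."""
        idx = np.flatnonzero(self.present)
        if idx.size == 0:
            raise ValueError("empty event tree has no gain node")
        return self.tax.nodes[int(idx[0])].name


# ---------------------------------------------------------------------------
# OrthoXML parsing
# ---------------------------------------------------------------------------


def _local(el) -> str:
    return etree.QName(el).localname


def _tax_range(el) -> str | None:
    for child in el:
        if isinstance(child.tag, str) and _local(child) == "property":
            if child.get("name") == "TaxRange":
                return child.get("value")
    return None


def parse_orthoxml(xml_text: str, tax: Taxonomy) -> list[HogFamily]:
    """Parse an OrthoXML document into :class:`HogFamily` objects.

    One family is produced per top-level ``orthologGroup``. Species names in
    the header must resolve to taxonomy leaves, and every group level must
    resolve to a taxonomy node; nesting must respect taxonomy ancestry.
    """
    try:
        root = etree.fromstring(
            xml_text.encode() if isinstance(xml_text, str) else xml_text
        )
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed OrthoXML: {exc}") from exc

    leaf_names = set(tax.leaf_names())

    # species header: internal numeric id -> (species, external gene id)
    gene_table: dict[str, tuple[str, str]] = {}
    for sp in root.iter():
        if not isinstance(sp.tag, str) or _local(sp) != "species":
            continue
        sp_name = sp.get("name")
        if sp_name not in leaf_names:
            raise KeyError(f"species {sp_name!r} is not a leaf of the taxonomy")
        for gene in sp.iter():
            if isinstance(gene.tag, str) and _local(gene) == "gene":
                gid = gene.get("id")
                ext = gene.get("geneId") or gene.get("protId") or gid
                if gid in gene_table:
                    raise ValueError(f"duplicate gene id in document: {gid!r}")
                gene_table[gid] = (sp_name, ext)

    groups_el = None
    for el in root:
        if isinstance(el.tag, str) and _local(el) == "groups":
            groups_el = el
    if groups_el is None:
        return []

    def build(el, enclosing_level: str | None):
        kind = _local(el)
        if kind == "geneRef":
            ref = el.get("id")
            if ref not in gene_table:
                raise KeyError(f"geneRef {ref!r} not declared in species header")
            species, ext = gene_table[ref]
            return GeneLeaf(species=species, gene_id=ext)
        if kind in ("orthologGroup", "paralogGroup"):
            level = _tax_range(el)
            if kind == "paralogGroup" and level is None:
                level = enclosing_level  # inherit from nearest ortholog group
            if level is None:
                raise ValueError(f"{kind} without a TaxRange level annotation")
            if level not in tax.name_index:
                raise KeyError(f"group level {level!r} not in the taxonomy")
            if enclosing_level is not None and not tax.is_descendant(
                tax.index_of(level), tax.index_of(enclosing_level)
            ):
                raise ValueError(
                    f"group level {level!r} is not a descendant of its "
                    f"parent level {enclosing_level!r}"
                )
            grp = OrthologGroup(level) if kind == "orthologGroup" else ParalogGroup(level)
            next_level = level if kind == "orthologGroup" else enclosing_level
            for child in el:
                if not isinstance(child.tag, str):
                    continue
                if _local(child) in ("orthologGroup", "paralogGroup", "geneRef"):
                    grp.children.append(
                        build(child, level if kind == "orthologGroup" else next_level)
                    )
            return grp
        raise ValueError(f"unexpected element inside groups: {kind!r}")

    families: list[HogFamily] = []
    for el in groups_el:
        if not isinstance(el.tag, str) or _local(el) != "orthologGroup":
            continue
        fam_id = el.get("id") or f"fam{len(families)}"
        grp = build(el, None)
        families.append(HogFamily(family_id=fam_id, root_level=grp.level, root=grp))
    return families


# ---------------------------------------------------------------------------
# Event inference
# ---------------------------------------------------------------------------


def _collect_genes(fam: HogFamily):
    """Flatten the group tree to (species, gene_id, paralog-path) triples.

    The paralog path of a gene is the sequence of ``(paralog-group instance,
    child slot, level)`` it sits under; two genes descend from the same
    ancestral copy at node x iff their paths agree on every entry whose level
    is an ancestor-or-self of x.
    """
    genes: list[tuple[str, str, tuple]] = []
    counter = [0]

    def walk(el, path: tuple):
        if isinstance(el, GeneLeaf):
            genes.append((el.species, el.gene_id, path))
        elif isinstance(el, ParalogGroup):
            pg_id = counter[0]
            counter[0] += 1
            for slot, child in enumerate(el.children):
                walk(child, path + ((pg_id, slot, el.level),))
        else:
            for child in el.children:
                walk(child, path)

    walk(fam.root, ())
    return genes


def infer_event_tree(fam: HogFamily, tax: Taxonomy) -> EventTree:
    """Infer the per-node event annotation of one family.

    Raises if the family's root level or any gene species is missing from
    the taxonomy, if a gene falls outside the root-level subtree, or if the
    family carries no extant genes at all.
    """
    if fam.root_level not in tax.name_index:
        raise KeyError(f"root level {fam.root_level!r} not in the taxonomy")
    g = tax.index_of(fam.root_level)
    genes = _collect_genes(fam)
    if not genes:
        raise ValueError(f"family {fam.family_id!r} has no extant genes")

    n = tax.node_count
    present = np.zeros(n, dtype=bool)
    copy_number = np.zeros(n, dtype=np.int64)

    gene_leaf_idx = []
    for species, gid, _path in genes:
        s = tax.index_of(species)
        if not tax.nodes[s].is_leaf:
            raise ValueError(f"gene species {species!r} is not a taxonomy leaf")
        if not tax.is_descendant(s, g):
            raise ValueError(
                f"gene {gid!r} of species {species!r} lies outside the "
                f"family root level {fam.root_level!r}"
            )
        gene_leaf_idx.append(s)
        copy_number[s] += 1

    # presence: ancestors-or-self of extant leaves, capped at the root level
    for s in set(gene_leaf_idx):
        i: int | None = s
        while i is not None and not present[i]:
            present[i] = True
            if i == g:
                break
            i = tax.nodes[i].parent

    # copy number at internal present nodes: count distinct lineages, i.e.
    # equivalence classes of genes under the paralog paths restricted to
    # levels at-or-above the node
    order = np.argsort(gene_leaf_idx, kind="stable")
    sorted_leaf = np.asarray(gene_leaf_idx)[order]
    sorted_paths = [genes[i][2] for i in order]
    for x in np.flatnonzero(present):
        if tax.nodes[x].is_leaf:
            continue
        lo, hi = tax.subtree_interval(int(x))
        a = np.searchsorted(sorted_leaf, lo, side="left")
        b = np.searchsorted(sorted_leaf, hi, side="left")
        classes = {
            tuple(
                (pg, slot)
                for pg, slot, level in sorted_paths[i]
                if tax.is_descendant(int(x), tax.index_of(level))
            )
            for i in range(a, b)
        }
        copy_number[x] = len(classes)

    # losses: topmost absent node under a present parent, within the subtree
    lost = np.zeros(n, dtype=bool)
    for x in tax.subtree_indices(g):
        if x == g or present[x]:
            continue
        p = tax.nodes[x].parent
        if p is not None and present[p]:
            lost[x] = True

    # duplications: copy number strictly above the parent level's
    duplicated = np.zeros(n, dtype=bool)
    for x in np.flatnonzero(present):
        parent_cn = 1 if x == g else copy_number[tax.nodes[int(x)].parent]
        duplicated[x] = copy_number[x] > parent_cn

    return EventTree(fam.family_id, tax, present, lost, duplicated, copy_number)
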