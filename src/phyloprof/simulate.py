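"""Synthetic gene-family evolution with logged ground truth.

Families evolve on a species tree under a discrete branch-wise process: a
family appears (gain) at one taxonomy node, and on every branch below it
the lineage is independently lost with probability ``loss_rate`` (pruning
the whole subtree) or duplicated with probability ``dup_rate`` (doubling
every lineage below, so copy numbers are powers of two). The per-node event
bookkeeping this produces is exactly what the event-inference stage claims
to recover, which makes the simulator the ground-truth oracle for the whole
pipeline: families are exported to standard OrthoXML and must round-trip
through parsing and inference with every logged event reproduced.

Co-evolving pairs model correlated gene loss: the partner shares the gain
node and copies each loss (and duplication) of the first family with
probability ``coevolution_rho``, alongside private events at rate
``rate * (1 - rho)`` — at rho=1 the event trees are identical, at rho=0
independent with unchanged marginal rates.

Ground-truth loss sets are stored in canonical form (topmost node of each
maximal extinct subtree), matching the one-event-per-loss convention of the
inference stage; raw per-branch loss coin counts are kept separately so the
branch-wise rates remain directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .analysis import BenchmarkPair
from .hog_events import ORTHOXML_NS, EventTree
from .taxonomy import Taxonomy, load_taxonomy

__all__ = [
    "SimConfig",
    "SimFamily",
    "simulate_taxonomy",
    "simulate_family",
    "simulate_coevolving_pair",
    "write_orthoxml",
    "make_benchmark",
]

_MAX_REJECTIONS = 10_000


@dataclass
class SimConfig:
    """Parameters of the branch-wise gain/loss/duplication process.

    gain_node_sampler: "root" gains every family at the tree root (ancient
    families, the regime of correlated-loss benchmarks), "uniform" draws the
    gain uniformly over all nodes (a database of families of mixed ages),
    "internal" restricts to internal nodes.
    """

    n_leaves: int = 64
    loss_rate: float = 0.1
    dup_rate: float = 0.05
    gain_node_sampler: str = "root"
    coevolution_rho: float = 0.8
    n_families: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        for name in ("loss_rate", "dup_rate", "coevolution_rho"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.gain_node_sampler not in ("root", "uniform", "internal"):
            raise ValueError(
                "gain_node_sampler must be 'root', 'uniform' or 'internal'"
            )


@dataclass
class SimFamily:
    """One simulated family plus its logged ground truth."""

    family_id: str
    gain: str
    losses: set[str]  # canonical: topmost node of each extinct subtree
    duplications: set[str]  # duplication events on surviving branches
    genes: dict[str, list[str]]  # species -> gene ids (len = copy number)
    n_rejections: int = 0
    raw_loss_events: int = 0  # loss coins that came up positive
    raw_branches: int = 0  # branches on which a loss coin was drawn
    shared_losses: set[str] = field(default_factory=set)
    shared_duplications: set[str] = field(default_factory=set)

    def gene_count(self) -> int:
        return sum(len(g) for g in self.genes.values())

    def to_event_tree(self, tax: Taxonomy) -> EventTree:
        """Ground-truth event tree, bypassing OrthoXML entirely."""
        n = tax.node_count
        g = tax.index_of(self.gain)
        present = np.zeros(n, dtype=bool)
        lost = np.zeros(n, dtype=bool)
        duplicated = np.zeros(n, dtype=bool)
        copy_number = np.zeros(n, dtype=np.int64)
        for species in self.genes:
            i: int | None = tax.index_of(species)
            while i is not None and not present[i]:
                present[i] = True
                if i == g:
                    break
                i = tax.nodes[i].parent
        for name in self.losses:
            lost[tax.index_of(name)] = True
        dup_idx = {tax.index_of(name) for name in self.duplications}
        for x in tax.subtree_indices(g):
            if not present[x]:
                continue
            if x == g:
                copy_number[x] = 1
            else:
                copy_number[x] = copy_number[tax.nodes[x].parent] * (
                    2 if x in dup_idx else 1
                )
            duplicated[x] = x in dup_idx
        return EventTree(self.family_id, tax, present, lost, duplicated, copy_number)


def simulate_taxonomy(n_leaves: int, seed: int) -> Taxonomy:
    """Random rooted binary species tree by uniform coalescent-style joins."""
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = np.random.default_rng(seed)
    subtrees = [f"S{i + 1}" for i in range(n_leaves)]
    for j in range(n_leaves - 1):
        a, b = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(int(b))
        left = subtrees.pop(int(a))
        subtrees.append(f"({left},{right})N{j + 1}")
    return load_taxonomy(subtrees[0] + ";")


def _draw_gain(tax: Taxonomy, cfg: SimConfig, rng: np.random.Generator) -> int:
    if cfg.gain_node_sampler == "root":
        return 0
    if cfg.gain_node_sampler == "uniform":
        return int(rng.integers(0, tax.node_count))
    internal = [n.index for n in tax.nodes if not n.is_leaf]
    return int(internal[rng.integers(0, len(internal))])


def _descend(
    tax: Taxonomy,
    gain: int,
    rng: np.random.Generator,
    loss_prob,
    dup_prob,
):
    """One pass of the branch process below ``gain``.

    ``loss_prob``/``dup_prob`` map a node index to that branch's event
    probability (constants for a free family, event-copying mixtures for a
    co-evolving partner). Returns (alive mask over all nodes, raw loss coin
    hits, branches considered, duplication event node set).
    """
    alive = np.zeros(tax.node_count, dtype=bool)
    alive[gain] = True
    raw_losses = 0
    branches = 0
    dups: set[int] = set()
    for x in tax.subtree_indices(gain):
        if x == gain:
            continue
        parent = tax.nodes[x].parent
        if parent is None or not alive[parent]:
            continue
        branches += 1
        if rng.random() < loss_prob(x):
            raw_losses += 1
            continue
        alive[x] = True
        if rng.random() < dup_prob(x):
            dups.add(x)
    return alive, raw_losses, branches, dups


def _assemble_family(
    tax: Taxonomy,
    family_id: str,
    gain: int,
    alive: np.ndarray,
    dups: set[int],
) -> SimFamily | None:
    """Canonicalise one descent into a SimFamily; None if extinct."""
    extant = [x for x in tax.subtree_indices(gain) if alive[x] and tax.nodes[x].is_leaf]
    if not extant:
        return None
    present = np.zeros(tax.node_count, dtype=bool)
    for s in extant:
        i: int | None = s
        while i is not None and not present[i]:
            present[i] = True
            if i == gain:
                break
            i = tax.nodes[i].parent
    losses = {
        tax.nodes[x].name
        for x in tax.subtree_indices(gain)
        if x != gain
        and not present[x]
        and tax.nodes[x].parent is not None
        and present[tax.nodes[x].parent]
    }
    eff_dups = {tax.nodes[x].name for x in dups if present[x]}
    # copy number at a leaf: one doubling per duplication on the gain->leaf path
    genes: dict[str, list[str]] = {}
    cn = np.zeros(tax.node_count, dtype=np.int64)
    for x in tax.subtree_indices(gain):
        if not present[x]:
            continue
        if x == gain:
            cn[x] = 1
        else:
            cn[x] = cn[tax.nodes[x].parent] * (2 if x in dups else 1)
        node = tax.nodes[x]
        if node.is_leaf:
            genes[node.name] = [
                f"{family_id}_{node.name}_{i + 1}" for i in range(cn[x])
            ]
    return SimFamily(
        family_id=family_id,
        gain=tax.nodes[gain].name,
        losses=losses,
        duplications=eff_dups,
        genes=genes,
    )


def simulate_family(
    tax: Taxonomy,
    cfg: SimConfig,
    rng: np.random.Generator,
    family_id: str = "fam",
    gain_index: int | None = None,
) -> SimFamily:
    """Simulate one family; extinct draws are rejected and resampled."""
    if cfg.loss_rate >= 1:
        raise ValueError("loss_rate = 1 leaves no family able to survive")
    gain = _draw_gain(tax, cfg, rng) if gain_index is None else gain_index
    rejections = 0
    while True:
        alive, raw, branches, dups = _descend(
            tax, gain, rng, lambda x: cfg.loss_rate, lambda x: cfg.dup_rate
        )
        fam = _assemble_family(tax, family_id, gain, alive, dups)
        if fam is not None:
            fam.n_rejections = rejections
            fam.raw_loss_events = raw
            fam.raw_branches = branches
            return fam
        rejections += 1
        if rejections > _MAX_REJECTIONS:
            raise RuntimeError(
                f"family extinct in {_MAX_REJECTIONS} consecutive draws; "
                "loss_rate is too close to 1 for this tree"
            )


def simulate_coevolving_pair(
    tax: Taxonomy,
    cfg: SimConfig,
    rng: np.random.Generator,
    id_a: str = "famA",
    id_b: str = "famB",
) -> tuple[SimFamily, SimFamily]:
    """A free family plus a partner with correlated events.

    The partner shares A's gain node, copies each canonical loss of A with
    probability rho and each duplication of A with probability rho, and adds
    private losses/duplications at ``rate * (1 - rho)`` on every branch. The
    ground truth records which of B's events are shared with A.
    """
    rho = cfg.coevolution_rho
    fam_a = simulate_family(tax, cfg, rng, family_id=id_a)
    gain = tax.index_of(fam_a.gain)
    a_losses = {tax.index_of(n) for n in fam_a.losses}
    a_dups = {tax.index_of(n) for n in fam_a.duplications}

    # pre-draw the copy decisions so rejection resampling of B's private
    # coins cannot re-roll which of A's events are inherited
    copied_losses = {x for x in a_losses if rng.random() < rho}
    copied_dups = {x for x in a_dups if rng.random() < rho}

    def loss_prob(x: int) -> float:
        return 1.0 if x in copied_losses else cfg.loss_rate * (1 - rho)

    def dup_prob(x: int) -> float:
        if x in copied_dups:
            return 1.0
        return cfg.dup_rate * (1 - rho)

    rejections = 0
    while True:
        alive, raw, branches, dups = _descend(tax, gain, rng, loss_prob, dup_prob)
        fam_b = _assemble_family(tax, id_b, gain, alive, dups)
        if fam_b is not None:
            break
        rejections += 1
        if rejections > _MAX_REJECTIONS:
            raise RuntimeError("co-evolving partner extinct in too many draws")
    fam_b.n_rejections = rejections
    fam_b.raw_loss_events = raw
    fam_b.raw_branches = branches
    fam_b.shared_losses = fam_b.losses & fam_a.losses
    fam_b.shared_duplications = fam_b.duplications & fam_a.duplications
    return fam_a, fam_b


# ---------------------------------------------------------------------------
# OrthoXML export
# ---------------------------------------------------------------------------


def write_orthoxml(families: list[SimFamily], tax: Taxonomy) -> str:
    """Serialise simulated families as a standard OrthoXML document.

    The inverse of parsing + event inference: duplications become
    ``paralogGroup`` elements carrying an explicit TaxRange at the event
    node, each copy written as a separate subtree with its own gene ids.
    """
    for fam in families:
        if fam.gene_count() == 0:
            raise ValueError(f"family {fam.family_id!r} has no genes")

    nsmap = {None: ORTHOXML_NS}
    root = etree.Element(
        f"{{{ORTHOXML_NS}}}orthoXML",
        nsmap=nsmap,
        origin="phyloprof-simulator",
        originVersion="1",
        version="0.3",
    )

    # species header: stable order (taxonomy preorder, then family order)
    numeric_of: dict[str, str] = {}
    counter = 0
    species_order = [n.name for n in tax.nodes if n.is_leaf]
    per_species: dict[str, list[str]] = {s: [] for s in species_order}
    for fam in families:
        for s in species_order:
            per_species[s].extend(fam.genes.get(s, []))
    for s in species_order:
        if not per_species[s]:
            continue
        sp_el = etree.SubElement(
            root, f"{{{ORTHOXML_NS}}}species", name=s, NCBITaxId="0"
        )
        db_el = etree.SubElement(
            sp_el, f"{{{ORTHOXML_NS}}}database", name="synthetic", version="1"
        )
        genes_el = etree.SubElement(db_el, f"{{{ORTHOXML_NS}}}genes")
        for gid in per_species[s]:
            counter += 1
            numeric_of[gid] = str(counter)
            etree.SubElement(
                genes_el, f"{{{ORTHOXML_NS}}}gene", id=str(counter), geneId=gid
            )

    groups = etree.SubElement(root, f"{{{ORTHOXML_NS}}}groups")
    for fam in families:
        groups.append(_family_element(fam, tax, numeric_of))
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def _family_element(fam: SimFamily, tax: Taxonomy, numeric_of: dict[str, str]):
    gain = tax.index_of(fam.gain)
    dup_idx = {tax.index_of(n) for n in fam.duplications}
    present = np.zeros(tax.node_count, dtype=bool)
    for species in fam.genes:
        i: int | None = tax.index_of(species)
        while i is not None and not present[i]:
            present[i] = True
            if i == gain:
                break
            i = tax.nodes[i].parent
    queues = {s: iter(ids) for s, ids in fam.genes.items()}

    def tag(name: str) -> str:
        return f"{{{ORTHOXML_NS}}}{name}"

    def add_level(el, index: int) -> None:
        etree.SubElement(
            el, tag("property"), name="TaxRange", value=tax.nodes[index].name
        )

    def gene_ref(species: str):
        gid = next(queues[species])
        return etree.Element(tag("geneRef"), id=numeric_of[gid])

    def body(x: int):
        node = tax.nodes[x]
        if node.is_leaf:
            return gene_ref(node.name)
        el = etree.Element(tag("orthologGroup"))
        add_level(el, x)
        for c in node.children:
            if present[c]:
                el.append(enc_child(c))
        return el

    def enc_child(c: int):
        if c in dup_idx:
            pg = etree.Element(tag("paralogGroup"))
            add_level(pg, c)
            pg.append(body(c))
            pg.append(body(c))
            return pg
        return body(c)

    if tax.nodes[gain].is_leaf:
        top = etree.Element(tag("orthologGroup"), id=fam.family_id)
        add_level(top, gain)
        top.append(gene_ref(fam.gain))
    else:
        top = body(gain)
        top.set("id", fam.family_id)
    return top


# ---------------------------------------------------------------------------
# labelled benchmark pairs
# ---------------------------------------------------------------------------


def make_benchmark(
    tax: Taxonomy, cfg: SimConfig, n_pairs: int
) -> tuple[list[BenchmarkPair], dict[str, SimFamily]]:
    """Balanced labelled pairs: co-evolving positives, independent negatives.

    Negatives are two independently simulated families sharing one randomly
    drawn gain node, so the only signal separating the classes is event
    correlation, not family age.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if n_pairs % 2 != 0:
        raise ValueError("n_pairs must be even to keep the benchmark balanced")
    rng = np.random.default_rng(cfg.seed)
    pairs: list[BenchmarkPair] = []
    families: dict[str, SimFamily] = {}
    for i in range(n_pairs // 2):
        a, b = simulate_coevolving_pair(
            tax, cfg, rng, id_a=f"P{i:04d}a", id_b=f"P{i:04d}b"
        )
        families[a.family_id] = a
        families[b.family_id] = b
        pairs.append(BenchmarkPair(a.family_id, b.family_id, True))
    for i in range(n_pairs // 2):
        gain = _draw_gain(tax, cfg, rng)
        a = simulate_family(tax, cfg, rng, f"N{i:04d}a", gain_index=gain)
        b = simulate_family(tax, cfg, rng, f"N{i:04d}b", gain_index=gain)
        families[a.family_id] = a
        families[b.family_id] = b
        pairs.append(BenchmarkPair(a.family_id, b.family_id, False))
    return pairs, families
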