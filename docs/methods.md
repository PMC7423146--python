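# Methods

This note records the models, conventions and parameter choices behind
`phyloprof`, and what the synthetic-data experiments do and do not show.

## Coordinate system

All profiles live over one indexed species tree whose nodes — leaves and
internal taxonomic levels alike — carry unique names. Nodes are numbered in
preorder (parent before children, children in written order); the numbering
is arbitrary but must be persisted, because signatures built under
different orderings are incomparable. Every signature store therefore
carries a taxonomy checksum and is written next to an order sidecar
(index, name, weight). Pruning a taxonomy to a genome subset keeps every
ancestor of a kept leaf, including levels left with a single child:
taxonomic levels are identities in the profile space, not mere topology.

A taxonomy with N nodes spans 3N profile coordinates, packed as
`3*node_index + category` with categories presence = 0, loss = 1,
duplication = 2. Coordinate packing is versioned in the store metadata.

## Event inference

For a family rooted at level g (the top ortholog-group's taxonomic range):

* **presence** — every node in g's subtree with at least one extant member
  at or below it; presence is connected by construction.
* **loss** — the topmost node of each maximal extinct subtree whose parent
  is present: one event per loss. Recording a loss at every node beneath
  would count a single evolutionary event many times and make profile
  similarity depend on clade size below the loss.
* **copy number** — at a leaf, the species' gene count; at an internal
  present node, the number of distinct gene lineages at that level. Two
  genes belong to the same lineage at node x iff no paralog group at a
  level ancestral-or-equal to x separates them; nested paralog groups
  mapping to the same level therefore compound multiplicatively. Paralog
  groups without an explicit level annotation inherit the nearest enclosing
  ortholog group's level.
* **duplication** — flagged exactly where copy number exceeds the parent
  level's (the root level's parent copy number is defined as 1).

Profiles encode the three event categories as the node's weight, not the
copy number: the weighted-Jaccard machinery needs only multiset weights,
and magnitudes would let a single high-copy family dominate every
comparison. Copy numbers remain on the event tree for the occurrence-
profile baselines. Per-node weights default to 1.0 for all three
categories; weight 0 removes a node from the profile space entirely
(equivalent to deleting its coordinates), which is how clade filters are
expressed.

## Weighted MinHash

Signatures use consistent weighted sampling (Ioffe-style): per coordinate k
and hash position i, parameters r ~ Gamma(2,1), c ~ Gamma(2,1) and
β ~ U(0,1) are derived deterministically from (scheme seed, k), and
position i samples the coordinate minimising ln c − r·(⌊ln w_k/r + β⌋ − β)
− r, recording (coordinate, discretised level). Two profiles collide at a
position with probability equal to their weighted Jaccard similarity; the
match fraction across n positions estimates J without bias and with
standard error √(J(1−J)/n).

* **n = 256** hash functions by default: estimator standard error ≤ 0.031,
  and similarity estimates are multiples of 1/256.
* **scheme seed = 1** by default; recorded on every signature and store.
  Signatures from different seeds or lengths refuse to compare, which turns
  silent incomparability into an error.
* Similarity is the match fraction; distance for clustering is defined as
  1 − similarity.
* Per-coordinate hash parameters are cached and shared across profiles, so
  signing a collection costs one Gamma draw batch per distinct coordinate,
  not per profile.

The conformance contract for the sampler is behavioural, tested against the
brute-force Σmin/Σmax oracle: mean absolute error within the Monte-Carlo
bound, ≥99% of pairs within 3 standard errors, and a mean signed error
indistinguishable from zero over independent pairs signed with fresh
schemes. (Pairs drawn from a common profile pool share hash functions and
coordinates, so their errors are correlated; the unbiasedness statistic is
only valid with independent pairs.)

## LSH Forest

Each signature's n samples are split into l = 8 contiguous slices of
r = n/l = 32 samples; slice t, hashed to 8 bytes per sample, is the key of
tree t, and each tree is a sorted key array searched by binary prefix
search. Queries descend from depth r towards depth 1, harvesting every
indexed signature sharing the leading d samples in any tree (a prefix of
length d matches with probability J^d, so close families surface first),
stop once the candidate pool reaches `min_candidates` (default
max(16·k, 100)), and re-rank candidates by the full-signature estimate,
breaking ties by insertion order. Depth 0 matches everything and is only
entered when fewer than k candidates exist above it. The forest is a
candidate generator; the returned ranking is exact with respect to the
estimator over the candidate set.

The candidate floor is a recall/speed dial: on 5000 indexed signatures of
simulated mixed-age families the default floor reproduces the brute-force
top-1 neighbour inside the top 10 for ≥95% of queries (measured 100%)
while inspecting a bounded number of entries (asserted
≤ 64·k·l·log₂(size), the documented constant). When every indexed family
is highly similar to every other (e.g. thousands of families all gained at
the root), exact nearest-neighbour identity among hundreds of near-ties is
not meaningful and recall of the single brute-force top hit degrades to
~95% — re-ranked similarity values remain correct.

Batch build and incremental insertion produce identical query results; the
HDF5 signature store is the persistence format, and forests are rebuilt
from it on load rather than serialised.

## Clustering and benchmarking

UPGMA (average linkage, via scipy) runs on 1 − similarity. Merge heights
are ultrametric node ages — half the cophenetic distance — so two families
at distance 2d merge at height d; the flat cutoff bounds the merge height
of any two co-clustered families. Kernel rows are canonically reordered by
family id before linkage, making the partition invariant under input
permutation even with tied merges. Cutoffs are free parameters chosen per
analysis (module-size targets), not constants of the method.

ROC analysis scores labelled pairs with higher = more likely interacting
(distances are negated first), handles score ties by the Mann–Whitney
midpoint convention, and reports a percentile-bootstrap confidence interval
over pairs. Binary Pearson on a constant vector is an error, not a silent
zero; benchmark code drops and counts such pairs.

## The simulator

Families evolve on a random binary species tree (uniform joins) by a
branch-wise Bernoulli process below a gain node: each branch loses the
family with probability `loss_rate` (pruning its subtree) or duplicates it
with probability `dup_rate` (doubling every lineage below; copy numbers are
powers of two). Extinct draws are rejected and counted — silent resampling
would bias rate checks. Logged loss sets are canonicalised to the topmost
node of each extinct subtree, the same convention inference uses, so
recovery can be asserted exactly; raw per-branch coin counts are kept so
the branch-wise rate itself stays testable. A discrete process (rather than
continuous-time rates) is sufficient because profiles only record per-node
events, and it keeps ground truth unambiguous.

Co-evolving partners share the gain node and copy each canonical loss —
and each duplication — of the first family with probability ρ, plus
private events at `rate·(1−ρ)`. Copying duplications as well as losses is
deliberate: co-evolution of interacting families shows in all event types,
and it makes ρ = 1 produce identical event trees (profile Jaccard exactly
1) rather than trees differing by private duplications. Benchmark negatives
are two independently simulated families *sharing one randomly drawn gain
node per pair*: without the matched gain, positives would be separable by
family age alone and a ρ = 0 benchmark would not sit at AUC 0.5.

Defaults: 64 leaves, loss_rate 0.1, dup_rate 0.05, ρ 0.8, gain at the root
for co-evolution benchmarks (ancient families, the regime where correlated
loss is informative) and uniform over nodes when emulating a database of
mixed-age families (as in the retrieval experiments).

### What the simulator does not emulate

Real data differ in ways that matter for interpreting green tests:
orthology inference errors (mis-assigned genes, split/merged HOGs), biased
taxon sampling, rate heterogeneity across lineages and time, horizontal
transfer, and losses that do not prune whole subtrees independently.
Because simulated losses are branch-wise and fully visible in the presence
pattern, presence-only baselines (binary Pearson over node presence) are
nearly as informative as event-aware profiles here — measurably more so on
loss-driven benchmarks, since Pearson's centering removes the shared
presence backbone that dilutes Jaccard. The advantage of event-aware
profiles on this generator appears where it is structural: co-duplication
signal is invisible to presence-only profiles (with no losses their vectors
are constant and unscoreable), while the event-aware score separates such
pairs perfectly. Synthetic AUCs therefore validate the machinery and its
calibration, not the field performance reported on curated interaction
data.

## Numerical and degenerate-input conventions

* Empty profiles (no presence anywhere) are refused at build and at
  signing — the empty multiset has no MinHash.
* The weighted Jaccard of two empty profiles is an error; one empty side
  yields 0 (handled before signing can occur).
* Signatures, stores and indexes refuse mixed (n, scheme seed) rather than
  degrade.
* All randomness flows through explicit seeds: taxonomy and family
  simulation from caller-supplied generators, hash schemes from the scheme
  seed. Same seeds ⇒ byte-identical OrthoXML, signature matrices and
  cluster assignments.
* Problem sizes in the test and acceptance workloads (64-leaf trees, 500
  round-trip families, 5000 indexed signatures, 200 benchmark pairs per ρ)
  are chosen to estimate each statistic well inside its asserted margin on
  a single CPU in minutes.

## Known limitations

* Copy-number inference counts lineage classes per node in O(genes × nodes)
  per family; fine for families of tens to hundreds of genes, not tuned for
  families with tens of thousands.
* The forest holds signatures in memory; stores are the unit of
  persistence and sharding across stores is the intended scale-out path.
* Taxon weighting is exposed (per-node weights, weight-0 filtering) but no
  weighting scheme is recommended; uniform weights are the tested default.
* OrthoXML support covers standard-conformant ortholog/paralog-group
  nesting with TaxRange annotations; vendor extensions are ignored.
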