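"""Kernels, UPGMA clustering, baseline metrics, ROC/AUC and augmentation."""

import numpy as np
import pytest

import phyloprof as pp
from phyloprof.analysis import BenchmarkPair, Kernel
from tests.conftest import make_profiles


@pytest.fixture(scope="module")
def module_sigs():
    tax = pp.simulate_taxonomy(32, 23)
    cfg = pp.SimConfig(n_leaves=32, seed=23, gain_node_sampler="root")
    gen = np.random.default_rng(23)
    sigs = []
    for i in range(40):
        fam = pp.simulate_family(tax, cfg, gen, family_id=f"F{i:03d}")
        sigs.append(pp.sign(pp.build_profile(fam.to_event_tree(tax), tax)))
    return sigs


# -- kernels ----------------------------------------------------------------


def test_kernel_of_identical_signatures(module_sigs):
    s = module_sigs[0]
    twin = pp.Signature("twin", s.samples.copy(), s.n, s.scheme_seed)
    kern = pp.build_kernel([s, twin])
    assert np.array_equal(kern.matrix, np.ones((2, 2)))


def test_kernel_matches_pairwise_estimates(module_sigs):
    kern = pp.build_kernel(module_sigs)
    gen = np.random.default_rng(1)
    for _ in range(100):
        i, j = gen.integers(0, len(module_sigs), 2)
        assert kern.matrix[i, j] == pytest.approx(
            pp.estimate_jaccard(module_sigs[i], module_sigs[j])
        )
    assert np.allclose(kern.matrix, kern.matrix.T)
    assert np.allclose(np.diag(kern.matrix), 1.0)


def test_kernel_disjoint_profiles_near_zero():
    from phyloprof.profiles import WeightedProfile

    a = pp.sign(WeightedProfile("a", 900, {i: 1.0 for i in range(100)}))
    b = pp.sign(WeightedProfile("b", 900, {i: 1.0 for i in range(300, 400)}))
    kern = pp.build_kernel([a, b])
    assert kern.matrix[0, 1] <= 3 / np.sqrt(256)


def test_kernel_needs_two_signatures(module_sigs):
    with pytest.raises(ValueError):
        pp.build_kernel(module_sigs[:1])


# -- UPGMA ------------------------------------------------------------------


def hand_kernel():
    # similarities chosen so distances are d(A,B)=2, d(A,C)=d(B,C)=8
    sim = 1.0 - np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
    return Kernel(["A", "B", "C"], sim)


def test_upgma_hand_example():
    """A,B merge at height 1; C joins at height 4 (average distance 8)."""
    kern = hand_kernel()
    three = pp.upgma_clusters(kern, cutoff=3.0)
    assert three.labels["A"] == three.labels["B"] != three.labels["C"]
    assert three.n_clusters == 2
    one = pp.upgma_clusters(kern, cutoff=5.0)
    assert one.n_clusters == 1


def test_upgma_cutoff_extremes(module_sigs):
    kern = pp.build_kernel(module_sigs[:12])
    singletons = pp.upgma_clusters(kern, cutoff=0.0)
    assert singletons.n_clusters == len(set(kern.family_ids))
    everything = pp.upgma_clusters(kern, cutoff=1.0)
    assert everything.n_clusters == 1


def test_upgma_permutation_invariance(module_sigs):
    kern = pp.build_kernel(module_sigs[:20])
    gen = np.random.default_rng(5)
    perm = gen.permutation(20)
    shuffled = Kernel(
        [kern.family_ids[i] for i in perm], kern.matrix[np.ix_(perm, perm)]
    )
    a = pp.upgma_clusters(kern, cutoff=0.2)
    b = pp.upgma_clusters(shuffled, cutoff=0.2)
    # same partition: identical co-membership for every pair
    ids = kern.family_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            assert (a.labels[ids[i]] == a.labels[ids[j]]) == (
                b.labels[ids[i]] == b.labels[ids[j]]
            )


def test_upgma_rejects_asymmetry():
    bad = Kernel(["A", "B"], np.array([[1.0, 0.2], [0.4, 1.0]]))
    with pytest.raises(ValueError, match="symmetric"):
        pp.upgma_clusters(bad, 0.5)


# -- baseline metrics -------------------------------------------------------


def test_binary_pearson_examples():
    v = np.array([1, 0, 1, 0])
    assert pp.binary_pearson(v, v) == pytest.approx(1.0)
    assert pp.binary_pearson(v, 1 - v) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        pp.binary_pearson(np.ones(4), v)


def test_occurrence_metrics_examples():
    e, r = pp.occurrence_metrics(np.array([2.0, 0.0]), np.array([0.0, 2.0]))
    assert e == pytest.approx(np.sqrt(8))
    e, r = pp.occurrence_metrics(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
    assert e == pytest.approx(np.sqrt(2))
    assert r is None
    e, r = pp.occurrence_metrics(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
    assert e == 0.0 and r == pytest.approx(1.0)


# -- ROC / AUC --------------------------------------------------------------


def pairs_with_scores(scored):
    pairs = [
        BenchmarkPair(f"a{i}", f"b{i}", label) for i, (label, _s) in enumerate(scored)
    ]
    scores = {
        (p.family_a, p.family_b): s for p, (_l, s) in zip(pairs, scored)
    }
    return pairs, scores


def test_roc_auc_perfect_separation():
    pairs, scores = pairs_with_scores(
        [(True, 0.9), (True, 0.8), (False, 0.2), (False, 0.1)]
    )
    curve, auc = pp.roc_auc(pairs, scores)
    assert auc == 1.0
    assert curve[:, 0].max() == 1.0 and curve[:, 1].max() == 1.0


def test_roc_auc_hand_count():
    # positives {0.9, 0.4}, negatives {0.6, 0.1}: 3 of 4 comparisons won
    pairs, scores = pairs_with_scores(
        [(True, 0.9), (True, 0.4), (False, 0.6), (False, 0.1)]
    )
    _curve, auc = pp.roc_auc(pairs, scores)
    assert auc == pytest.approx(0.75)


def test_roc_auc_random_scores_near_half():
    gen = np.random.default_rng(0)
    scored = [(bool(i % 2), float(gen.random())) for i in range(2000)]
    _c, auc = pp.roc_auc(*pairs_with_scores(scored))
    assert abs(auc - 0.5) < 0.05


def test_roc_auc_single_class_rejected():
    pairs, scores = pairs_with_scores([(True, 0.5), (True, 0.6)])
    with pytest.raises(ValueError):
        pp.roc_auc(pairs, scores)


def test_benchmark_pair_rejects_self_pair():
    with pytest.raises(ValueError):
        BenchmarkPair("a", "a", True)


# -- augmentation -----------------------------------------------------------


def test_augment_single_query(module_sigs):
    idx = pp.build_index(module_sigs)
    kern = pp.augment_network(idx, [module_sigs[0].family_id], k=1)
    assert module_sigs[0].family_id in kern.family_ids
    assert len(kern.family_ids) == 2


def test_augment_deduplicates_overlapping_hits(module_sigs):
    idx = pp.build_index(module_sigs)
    queries = [s.family_id for s in module_sigs[:6]]
    kern = pp.augment_network(idx, queries, k=5)
    assert len(kern.family_ids) == len(set(kern.family_ids))
    assert len(kern.family_ids) < 6 * 6  # overlap collapses the union
    assert set(queries) <= set(kern.family_ids)


def test_augment_unknown_query(module_sigs):
    idx = pp.build_index(module_sigs)
    with pytest.raises(KeyError, match="nope"):
        pp.augment_network(idx, ["nope"], k=2)


def test_augment_finds_designed_partner():
    """Co-evolving partners surface in each other's top-20 at rho=0.8.

    Scenario: 25 correlated-loss module pairs indexed inside a database of
    350 unrelated mixed-age families, aggregated over five replicates. The
    forest's candidate generation matches a brute-force scan here; the
    residual misses are pairs whose shared-event signal genuinely ranks
    below 20 coincidentally similar ancient families.
    """
    found = total = 0
    for seed in (31, 32, 33, 34, 35):
        tax = pp.simulate_taxonomy(64, seed)
        cfg = pp.SimConfig(n_leaves=64, seed=seed, coevolution_rho=0.8)
        bg_cfg = pp.SimConfig(n_leaves=64, seed=seed, gain_node_sampler="uniform")
        gen = np.random.default_rng(seed)
        sigs, partners = [], {}
        for i in range(25):
            a, b = pp.simulate_coevolving_pair(
                tax, cfg, gen, id_a=f"A{i:03d}", id_b=f"B{i:03d}"
            )
            for fam in (a, b):
                sigs.append(pp.sign(pp.build_profile(fam.to_event_tree(tax), tax)))
            partners[a.family_id] = b.family_id
        for i in range(350):
            fam = pp.simulate_family(tax, bg_cfg, gen, family_id=f"BG{i:04d}")
            sigs.append(pp.sign(pp.build_profile(fam.to_event_tree(tax), tax)))
        idx = pp.build_index(sigs)
        for query, partner in partners.items():
            hits = [f for f, _s in idx.query(idx.signature(query), 21)]
            found += partner in hits
            total += 1
    assert found / total >= 0.90
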