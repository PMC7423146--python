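"""The synthetic evolution process: rates, determinism, co-evolution."""

import numpy as np
import pytest
from scipy import stats

import phyloprof as pp


def test_two_leaf_taxonomy():
    tax = pp.simulate_taxonomy(2, 0)
    assert tax.node_count == 3


@pytest.mark.parametrize("n_leaves", [10, 100])
def test_binary_tree_node_count(n_leaves):
    assert pp.simulate_taxonomy(n_leaves, 1).node_count == 2 * n_leaves - 1


def test_taxonomy_deterministic_per_seed():
    assert pp.simulate_taxonomy(25, 4).to_newick() == pp.simulate_taxonomy(25, 4).to_newick()
    assert pp.simulate_taxonomy(25, 4).to_newick() != pp.simulate_taxonomy(25, 5).to_newick()


def test_taxonomy_too_small():
    with pytest.raises(ValueError):
        pp.simulate_taxonomy(1, 0)


def test_eventless_family_covers_whole_tree(sim_tax):
    cfg = pp.SimConfig(n_leaves=32, loss_rate=0.0, dup_rate=0.0)
    fam = pp.simulate_family(sim_tax, cfg, np.random.default_rng(0), "f")
    assert fam.gain == sim_tax.root.name
    assert not fam.losses and not fam.duplications
    assert all(len(g) == 1 for g in fam.genes.values())
    assert set(fam.genes) == set(sim_tax.leaf_names())


def test_total_loss_rate_rejected(sim_tax):
    cfg = pp.SimConfig(n_leaves=32, loss_rate=1.0)
    with pytest.raises(ValueError, match="survive"):
        pp.simulate_family(sim_tax, cfg, np.random.default_rng(0), "f")


def test_high_loss_rate_rejects_draws():
    tax = pp.simulate_taxonomy(100, 2)
    cfg = pp.SimConfig(n_leaves=100, loss_rate=0.9)
    gen = np.random.default_rng(2)
    fams = [pp.simulate_family(tax, cfg, gen, f"f{i}") for i in range(20)]
    assert sum(f.n_rejections for f in fams) > 0


def test_branchwise_loss_rate_is_calibrated():
    """Raw loss coins hit at the configured per-branch probability."""
    tax = pp.simulate_taxonomy(64, 3)
    cfg = pp.SimConfig(n_leaves=64, loss_rate=0.1, dup_rate=0.0)
    gen = np.random.default_rng(3)
    events = branches = 0
    for i in range(1000):
        fam = pp.simulate_family(tax, cfg, gen, f"f{i}")
        events += fam.raw_loss_events
        branches += fam.raw_branches
    rate = events / branches
    se = np.sqrt(0.1 * 0.9 / branches)
    assert abs(rate - 0.1) < 3 * se


def test_rho_one_gives_identical_profiles(sim_tax):
    cfg = pp.SimConfig(n_leaves=32, coevolution_rho=1.0, seed=5)
    gen = np.random.default_rng(5)
    for i in range(20):
        a, b = pp.simulate_coevolving_pair(sim_tax, cfg, gen, f"a{i}", f"b{i}")
        assert a.losses == b.losses and a.duplications == b.duplications
        pa = pp.build_profile(a.to_event_tree(sim_tax), sim_tax)
        pb = pp.build_profile(b.to_event_tree(sim_tax), sim_tax)
        assert pp.exact_weighted_jaccard(pa, pb) == 1.0


def test_rho_zero_losses_independent():
    """Shared-loss counts match the product of marginals (chi-square)."""
    tax = pp.simulate_taxonomy(64, 7)
    cfg = pp.SimConfig(n_leaves=64, coevolution_rho=0.0, seed=7, dup_rate=0.0)
    gen = np.random.default_rng(7)
    table = np.zeros((2, 2))
    for i in range(400):
        a, b = pp.simulate_coevolving_pair(tax, cfg, gen, f"a{i}", f"b{i}")
        for x in tax.subtree_indices(tax.index_of(a.gain)):
            name = tax.nodes[x].name
            table[int(name in a.losses), int(name in b.losses)] += 1
    _chi2, p, _dof, _exp = stats.chi2_contingency(table)
    assert p > 0.01


def test_rho_raises_pair_similarity_above_background():
    """Co-evolving pairs are more similar than unrelated families."""
    tax = pp.simulate_taxonomy(64, 9)
    cfg = pp.SimConfig(n_leaves=64, coevolution_rho=0.8, seed=9)
    gen = np.random.default_rng(9)
    paired, background = [], []
    fams = []
    for i in range(200):
        a, b = pp.simulate_coevolving_pair(tax, cfg, gen, f"a{i}", f"b{i}")
        pa = pp.build_profile(a.to_event_tree(tax), tax)
        pb = pp.build_profile(b.to_event_tree(tax), tax)
        paired.append(pp.exact_weighted_jaccard(pa, pb))
        fams.append(pa)
    for i in range(0, 198, 2):
        background.append(pp.exact_weighted_jaccard(fams[i], fams[i + 1]))
    assert np.mean(paired) > np.mean(background)
    assert stats.mannwhitneyu(paired, background, alternative="greater").pvalue < 0.01


def test_orthoxml_deterministic_per_seed(sim_tax):
    def run():
        cfg = pp.SimConfig(n_leaves=32, seed=13, gain_node_sampler="uniform")
        gen = np.random.default_rng(13)
        fams = [pp.simulate_family(sim_tax, cfg, gen, f"F{i}") for i in range(25)]
        return pp.write_orthoxml(fams, sim_tax)

    assert run() == run()


def test_orthoxml_contains_paralog_group_per_duplication(sim_tax):
    cfg = pp.SimConfig(n_leaves=32, seed=15, dup_rate=0.3, loss_rate=0.0)
    gen = np.random.default_rng(15)
    fam = pp.simulate_family(sim_tax, cfg, gen, "F0")
    assert fam.duplications  # dup_rate 0.3 on 61 branches
    xml = pp.write_orthoxml([fam], sim_tax)
    # a duplication nested below d earlier duplications is written once per
    # surviving copy, i.e. 2**d times
    dup_idx = {sim_tax.index_of(n) for n in fam.duplications}
    expected = 0
    for d in dup_idx:
        above = 0
        i = sim_tax.nodes[d].parent
        while i is not None:
            above += i in dup_idx
            i = sim_tax.nodes[i].parent
        expected += 2**above
    assert xml.count("<paralogGroup>") == expected


def test_write_orthoxml_rejects_empty_family(sim_tax):
    empty = pp.SimFamily("f", sim_tax.root.name, set(), set(), {})
    with pytest.raises(ValueError, match="no genes"):
        pp.write_orthoxml([empty], sim_tax)


def test_benchmark_is_balanced(sim_tax):
    cfg = pp.SimConfig(n_leaves=32, seed=17)
    pairs, families = pp.make_benchmark(sim_tax, cfg, 10)
    assert sum(p.label for p in pairs) == 5
    assert sum(not p.label for p in pairs) == 5
    assert len(families) == 20
    with pytest.raises(ValueError, match="even"):
        pp.make_benchmark(sim_tax, cfg, 9)


def test_benchmark_rho_extremes(sim_tax):
    """rho=1 separates perfectly; rho=0 carries no label signal."""

    def auc_at(rho, seed):
        cfg = pp.SimConfig(n_leaves=32, seed=seed, coevolution_rho=rho)
        pairs, fams = pp.make_benchmark(sim_tax, cfg, 200)
        profs = {
            fid: pp.build_profile(f.to_event_tree(sim_tax), sim_tax)
            for fid, f in fams.items()
        }
        scores = {
            (p.family_a, p.family_b): pp.exact_weighted_jaccard(
                profs[p.family_a], profs[p.family_b]
            )
            for p in pairs
        }
        return pp.roc_auc(pairs, scores)[1]

    assert auc_at(1.0, 19) == 1.0
    assert abs(auc_at(0.0, 19) - 0.5) < 0.12
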