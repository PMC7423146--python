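import numpy as np
import pytest

import phyloprof as pp


@pytest.fixture
def small_tax():
    """5-node tree ((A,B)AB,C)Root with preorder [Root, AB, A, B, C]."""
    return pp.load_taxonomy("((A,B)AB,C)Root;")


@pytest.fixture
def sim_tax():
    """32-leaf (63-node) random species tree, fixed seed."""
    return pp.simulate_taxonomy(32, 7)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def make_profiles(tax, n, seed, sampler="uniform", **cfg_kwargs):
    """n simulated families as (SimFamily, WeightedProfile) pairs."""
    cfg = pp.SimConfig(
        n_leaves=len(tax.leaf_names()), seed=seed, gain_node_sampler=sampler, **cfg_kwargs
    )
    gen = np.random.default_rng(seed)
    out = []
    for i in range(n):
        fam = pp.simulate_family(tax, cfg, gen, family_id=f"F{i:05d}")
        out.append((fam, pp.build_profile(fam.to_event_tree(tax), tax)))
    return out
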