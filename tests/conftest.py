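import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ggdrift.io import BranchParams, TraitTable, parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_trees():
    """Fixture trees with <= 5 tips for oracle comparisons."""
    return [
        parse_newick("(A:1,B:3);"),
        parse_newick("((A:1,B:1):1,C:2);"),
        parse_newick("((A:0.5,B:2.5):1.5,(C:1,D:3):0.7);"),
        parse_newick("(((A:1,B:2):0.5,C:3):1,(D:0.8,E:1.2):2);"),
    ]


@pytest.fixture
def simple_params():
    return BranchParams(
        node_id="n", Ne_mean=10000, Ne_lower=5000, Ne_upper=20000,
        divergence_time=250000, generation_length=25,
    )


def make_trait_table(rng, taxa=("A", "B", "C"), n_per_taxon=10, p=3, sex_effect=0.0):
    ids, tx, sx, blocks = [], [], [], []
    for t in taxa:
        Z = rng.normal(size=(n_per_taxon, p)) + rng.normal(scale=2.0, size=p)
        half = n_per_taxon // 2
        sex = ["F"] * half + ["M"] * (n_per_taxon - half)
        Z[np.array(sex) == "M"] += sex_effect
        ids += [f"{t}{i}" for i in range(n_per_taxon)]
        tx += [t] * n_per_taxon
        sx += sex
        blocks.append(Z)
    return TraitTable(
        specimen_id=ids, taxon=tx, sex=sx, z=np.vstack(blocks),
        trait_names=[f"tr{k}" for k in range(p)],
    )


@pytest.fixture
def trait_table(rng):
    return make_trait_table(rng)


def brute_force_ancestral(tree, tip_values):
    """Independent oracle: numerically maximize the BM likelihood over
    internal-node values (equivalently minimize the branch-length-weighted
    sum of squared changes).  ``tip_values`` maps tip label -> value.
    Returns node id -> estimate for internal nodes."""
    internal = tree.internal_nodes
    pos = {n: i for i, n in enumerate(internal)}

    def objective(x):
        total = 0.0
        grad = np.zeros_like(x)
        for child, anc in tree.parent.items():
            v = tree.branch_length[child]
            child_val = (
                tip_values[tree.tip_label[child]] if child in tree.tip_label else x[pos[child]]
            )
            diff = x[pos[anc]] - child_val
            total += diff**2 / v
            grad[pos[anc]] += 2.0 * diff / v
            if child not in tree.tip_label:
                grad[pos[child]] -= 2.0 * diff / v
        return total, grad

    x0 = np.full(len(internal), np.mean(list(tip_values.values())))
    res = optimize.minimize(objective, x0, method="BFGS", jac=True, options={"gtol": 1e-12})
    assert np.linalg.norm(res.jac) < 1e-9
    return {n: res.x[pos[n]] for n in internal}


@pytest.fixture
def oracle():
    return brute_force_ancestral
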