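import numpy as np
import pytest

from dendromut.model import ModelParams
from dendromut.simulate import SimulationConfig, default_physical_tree, simulate
from dendromut.tree import PhysicalTree


@pytest.fixture(scope="session")
def physical_tree():
    return default_physical_tree()


@pytest.fixture()
def params():
    return ModelParams(theta=0.01, kappa=2.0, epsilon=0.01, lam=1e-3)


@pytest.fixture(scope="session")
def small_sim():
    """50 kb, 30x-per-tip dataset with ~20 expected somatic mutations."""
    cfg = SimulationConfig(genome_length=50_000, mean_depth=10.0, epsilon=0.005,
                           lam=20 / (2 * 90.1 * 50_000), repeat_fraction=0.2,
                           seed=123)
    return simulate(cfg)


@pytest.fixture()
def four_leaf_tree():
    nwk = "((1:2.0,2:3.0)X:1.5,(3:1.0,4:2.5)Y:2.0)R;"
    return PhysicalTree.from_newick(
        nwk, replicate_map={lf: [f"{lf}a", f"{lf}b"] for lf in "1234"})


def exhaustive_site_oracle(tree, params, leaf_counts, ref_idx):
    """Independent total-likelihood/DNP oracle: explicit sum over genotype
    assignments to every internal node, leaf genotypes marginalised by a
    direct dot product (no tree recursion)."""
    from itertools import product

    from dendromut.model import N_GENOTYPES, TreeModel

    tm = TreeModel(tree, params)
    ll = tm.leaf_logliks(leaf_counts[None])[0]          # (L, 10)
    shift = ll.max(axis=1)
    lik = np.exp(ll - shift[:, None])
    internals = [n for n in tree.postorder() if tree.children.get(n)]
    prior = tm.prior[ref_idx]
    li = tm.leaf_index
    # leaf marginal given parent genotype: (10,) per leaf
    leaf_marg = {lf: tm.T[lf] @ lik[li[lf]] for lf in tree.leaves}
    leaf_parent = {lf: tree.parent[lf] for lf in tree.leaves}
    total = 0.0
    for assign in product(range(N_GENOTYPES), repeat=len(internals)):
        a = dict(zip(internals, assign))
        w = prior[a[tree.root]]
        for node in internals:
            p = tree.parent[node]
            if p is not None:
                w *= tm.T[node][a[p], a[node]]
        for lf in tree.leaves:
            w *= leaf_marg[lf][a[leaf_parent[lf]]]
        total += w
    logtot = np.log(total) + shift.sum()
    svec = ll.sum(axis=0)
    lognum = np.log((prior * np.exp(svec - svec.max())).sum()) + svec.max()
    dnp = 1.0 - np.exp(lognum - logtot)
    return logtot, float(np.clip(dnp, 0.0, 1.0))
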