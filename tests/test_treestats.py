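import itertools

import numpy as np
import pytest

from dendromut import treestats as ts
from dendromut.simulate import default_physical_tree


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n", [3, 4, 5, 6])
def test_topology_count_double_factorial(n):
    tops = ts.enumerate_topologies(n)
    assert len(tops) == ts.double_factorial(2 * n - 5)


def test_topologies_distinct_under_isomorphism():
    tops = ts.enumerate_topologies(5)
    assert len({t.splits() for t in tops}) == 15


def test_enumeration_range_guard():
    with pytest.raises(ts.TreeStatsError):
        ts.enumerate_topologies(2)
    with pytest.raises(ts.TreeStatsError):
        ts.enumerate_topologies(11)


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def _brute_force_parsimony(topology, alignment):
    """Minimise state changes over all internal labelings, per site."""
    states_per_site = list(zip(*[alignment[lbl] for lbl in topology.labels]))
    adj = topology.adjacency()
    internal = list(range(topology.n_leaves, topology.n_nodes))
    total = 0
    for site in states_per_site:
        alphabet = sorted(set(site))
        best = None
        for labels in itertools.product(alphabet, repeat=len(internal)):
            assign = dict(zip(internal, labels))
            for li, st in enumerate(site):
                assign[li] = st
            changes = sum(assign[a] != assign[b] for a, b in topology.edges)
            best = changes if best is None else min(best, changes)
        total += best
    return total


def test_fitch_invariant_alignment_scores_zero():
    top = ts.enumerate_topologies(5)[0]
    assert ts.fitch_score(top, {lbl: "AAAA" for lbl in top.labels}) == 0


def test_fitch_four_taxon_split_example():
    al = {"1": "A", "2": "A", "3": "B", "4": "B"}
    t12 = ts.Topology(4, ((0, 4), (1, 4), (4, 5), (2, 5), (3, 5)),
                      ("1", "2", "3", "4"))
    t13 = ts.Topology(4, ((0, 4), (2, 4), (4, 5), (1, 5), (3, 5)),
                      ("1", "2", "3", "4"))
    assert ts.fitch_score(t12, al) == 1
    assert ts.fitch_score(t13, al) == 2


def test_fitch_matches_brute_force_on_random_alignments():
    rng = np.random.default_rng(1)
    for n in (4, 5, 6):
        tops = ts.enumerate_topologies(n)
        for _ in range(4):
            top = tops[rng.integers(len(tops))]
            al = {lbl: "".join(rng.choice(list("ACGT"), size=6))
                  for lbl in top.labels}
            assert ts.fitch_score(top, al) == _brute_force_parsimony(top, al)


def test_fitch_site_permutation_invariance():
    rng = np.random.default_rng(2)
    top = ts.enumerate_topologies(5)[7]
    al = {lbl: "".join(rng.choice(list("AG"), size=8)) for lbl in top.labels}
    perm = rng.permutation(8)
    al_perm = {lbl: "".join(seq[i] for i in perm) for lbl, seq in al.items()}
    assert ts.fitch_score(top, al) == ts.fitch_score(top, al_perm)


def test_fitch_label_mismatch_rejected():
    top = ts.enumerate_topologies(4)[0]
    with pytest.raises(ts.TreeStatsError):
        ts.fitch_score(top, {"x": "A", "y": "A", "z": "B", "w": "B"})


# ---------------------------------------------------------------------------
# path difference
# ---------------------------------------------------------------------------

def _pd_networkx_oracle(a, b):
    import networkx as nx
    vecs = []
    for t in (a, b):
        g = nx.Graph(list(t.edges))
        d = dict(nx.all_pairs_shortest_path_length(g))
        vec = [d[i][j] for i in range(t.n_leaves)
               for j in range(i + 1, t.n_leaves)]
        vecs.append(np.array(vec, dtype=float))
    return float(np.linalg.norm(vecs[0] - vecs[1]))


def test_pd_identity_and_symmetry():
    tops = ts.enumerate_topologies(5)
    assert ts.path_difference(tops[0], tops[0]) == 0.0
    assert ts.path_difference(tops[0], tops[3]) == \
        ts.path_difference(tops[3], tops[0])


def test_pd_matches_bfs_oracle():
    rng = np.random.default_rng(3)
    for n in (5, 6):
        tops = ts.enumerate_topologies(n)
        for _ in range(5):
            a = tops[rng.integers(len(tops))]
            b = tops[rng.integers(len(tops))]
            assert ts.path_difference(a, b) == \
                pytest.approx(_pd_networkx_oracle(a, b))


def test_pd_null_trivial_cases():
    tops = ts.enumerate_topologies(6)
    ref = tops[11]
    p_min, obs, null = ts.pd_null_test(ref, ref, tops)
    assert obs == 0.0
    assert p_min == pytest.approx((null == 0).mean())
    worst = tops[int(np.argmax([ts.path_difference(ref, t) for t in tops]))]
    p_max, _, _ = ts.pd_null_test(worst, ref, tops)
    assert p_max == 1.0


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def test_rf_identity_and_symmetry():
    tops = ts.enumerate_topologies(6)
    assert ts.rf_distance(tops[0], tops[0]) == 0
    assert ts.rf_distance(tops[0], tops[50]) == ts.rf_distance(tops[50], tops[0])


def test_rf_matches_dendropy_oracle():
    import dendropy
    rng = np.random.default_rng(4)
    tops = ts.enumerate_topologies(6)
    tns = dendropy.TaxonNamespace()
    for _ in range(6):
        a = tops[rng.integers(len(tops))]
        b = tops[rng.integers(len(tops))]
        da = dendropy.Tree.get(data=a.newick(), schema="newick",
                               taxon_namespace=tns)
        db = dendropy.Tree.get(data=b.newick(), schema="newick",
                               taxon_namespace=tns)
        expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
        assert ts.rf_distance(a, b) == expected


# ---------------------------------------------------------------------------
# likelihood scan
# ---------------------------------------------------------------------------

def test_ml_scan_recovers_generating_topology():
    rng = np.random.default_rng(5)
    tops = ts.enumerate_topologies(5)
    truth = tops[9]
    # simulate binary states down the unrooted tree from an arbitrary root
    adj = truth.adjacency()
    n_sites = 300
    states = np.zeros((truth.n_nodes, n_sites), dtype=np.int64)
    root = truth.n_leaves
    states[root] = rng.integers(0, 2, n_sites)
    order = [(root, -1)]
    seen = {root}
    queue = [root]
    while queue:
        v = queue.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                flip = rng.random(n_sites) < 0.12
                states[w] = np.where(flip, 1 - states[v], states[v])
                queue.append(w)
    res = ts.ml_tree_scan(states[:truth.n_leaves], tops, n_bootstrap=0)
    assert res["best"].splits() == truth.splits()


def test_ml_scan_single_site_reports_ties():
    tops = ts.enumerate_topologies(5)
    al = np.array([[0], [0], [1], [1], [0]])
    res = ts.ml_tree_scan(al, tops, n_bootstrap=0)
    assert len(res["ties"]) > 1


def test_ml_scan_bootstrap_supports_bounded():
    rng = np.random.default_rng(6)
    tops = ts.enumerate_topologies(4)
    al = rng.integers(0, 2, size=(4, 40))
    res = ts.ml_tree_scan(al, tops, n_bootstrap=10, seed=1)
    assert all(0.0 <= v <= 100.0 for v in res["support"].values())


def test_ml_scan_invariant_alignment_rejected():
    tops = ts.enumerate_topologies(4)
    with pytest.raises(ts.TreeStatsError):
        ts.ml_tree_scan(np.zeros((4, 5), dtype=int), tops)


# ---------------------------------------------------------------------------
# branch-length regression
# ---------------------------------------------------------------------------

def test_regression_exact_proportionality():
    metres = np.array([1.0, 2.0, 5.0, 8.0])
    slope, r2, p = ts.branch_length_regression(metres, 3.0 * metres)
    assert slope == pytest.approx(3.0)
    assert r2 == pytest.approx(1.0)


def test_regression_poisson_counts_on_physical_tree():
    tree = default_physical_tree()
    metres = np.array([tree.length[c] for _, c in tree.edges])
    rng = np.random.default_rng(7)
    rho = 3.3
    counts = rng.poisson(rho * metres)
    slope, r2, p = ts.branch_length_regression(metres, counts.astype(float))
    assert r2 > 0.7
    assert p < 0.001
    se = abs(slope - rho) / max(np.sqrt(rho / metres.sum()), 1e-9)
    assert se < 4.0  # slope within ~4 standard errors of the generating rate


def test_regression_all_zero_counts_rejected():
    with pytest.raises(ts.TreeStatsError):
        ts.branch_length_regression(np.array([1.0, 2.0]), np.array([0.0, 0.0]))


def test_physical_topology_conversion():
    tree = default_physical_tree()
    topo = ts.topology_from_physical(tree)
    assert topo.n_leaves == 8
    assert len(topo.splits()) == 5  # unrooted binary: n-3 internal splits
    # clade {1,2,3} is a split of the physical tree
    ids = {lbl: i for i, lbl in enumerate(topo.labels)}
    assert frozenset({ids["1"], ids["2"], ids["3"]}) in topo.splits() or \
        frozenset(set(ids.values()) - {ids["1"], ids["2"], ids["3"]}) in topo.splits()
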