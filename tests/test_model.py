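import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendromut.model import (BASES, GENOTYPES, GENOTYPE_PAIRS, ModelParams,
                             ModelError, N_GENOTYPES, Thresholds, TreeModel,
                             allele_kernel, branch_transition_matrix,
                             call_mutations, fit_params, genotype_prior,
                             peel_batch, replicate_likelihood, site_peel)
from dendromut.simulate import SimulationConfig, simulate
from dendromut.tree import PhysicalTree

from conftest import exhaustive_site_oracle


# ---------------------------------------------------------------------------
# genotype prior
# ---------------------------------------------------------------------------

def test_prior_hand_computed_values():
    p = ModelParams(theta=0.01, kappa=2.0)
    pr = genotype_prior("A", p)
    assert pr[GENOTYPES.index("AA")] == pytest.approx(0.985)
    assert pr[GENOTYPES.index("AG")] == pytest.approx(0.005)     # transition het
    assert pr[GENOTYPES.index("AC")] == pytest.approx(0.0025)    # transversion het
    assert pr[GENOTYPES.index("GG")] == pytest.approx(0.0025)    # transition hom
    assert pr[GENOTYPES.index("CT")] == 0.0                      # no ref allele


def test_prior_theta_limit_is_point_mass():
    pr = genotype_prior("C", ModelParams(theta=1e-12))
    assert pr[GENOTYPES.index("CC")] == pytest.approx(1.0)


@given(theta=st.floats(1e-6, 0.5), kappa=st.floats(0.1, 10.0),
       ref=st.sampled_from("ACGT"))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_prior_normalised(theta, kappa, ref):
    pr = genotype_prior(ref, ModelParams(theta=theta, kappa=kappa))
    assert pr.sum() == pytest.approx(1.0, abs=1e-9)
    assert (pr >= 0).all()


def test_prior_invalid_allele():
    with pytest.raises(ModelError):
        genotype_prior("N", ModelParams())


# ---------------------------------------------------------------------------
# branch transition matrix
# ---------------------------------------------------------------------------

def test_transition_zero_length_identity(params):
    assert np.allclose(branch_transition_matrix(0.0, params), np.eye(10))


def test_transition_rows_normalised(params):
    for L in (0.1, 1.0, 50.0):
        T = branch_transition_matrix(L, params)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-9)


def test_transition_saturation_limit():
    """As lam*L grows the per-allele no-mutation probability vanishes, so
    genotypes retaining either starting allele lose all mass."""
    p = ModelParams(lam=1e6, kappa=2.0)
    T = branch_transition_matrix(100.0, p)
    aa = GENOTYPES.index("AA")
    assert T[aa, aa] == pytest.approx(0.0, abs=1e-12)
    for g in ("AC", "AG", "AT"):
        assert T[aa, GENOTYPES.index(g)] == pytest.approx(0.0, abs=1e-12)
    # both alleles jump independently with the kappa-weighted kernel
    assert T[aa, GENOTYPES.index("GG")] == pytest.approx((2 / 4) ** 2)
    assert T[aa, GENOTYPES.index("CT")] == pytest.approx(2 * (1 / 4) ** 2)


def test_transition_matches_ordered_pair_oracle(params):
    """Collapse of the ordered two-allele product onto unordered genotypes."""
    K = allele_kernel(10.0, params)
    T = branch_transition_matrix(10.0, params)
    for gi, (a1, a2) in enumerate(GENOTYPE_PAIRS):
        brute = np.zeros(N_GENOTYPES)
        for b1 in range(4):
            for b2 in range(4):
                hi = GENOTYPE_PAIRS.index((min(b1, b2), max(b1, b2)))
                brute[hi] += K[a1, b1] * K[a2, b2]
        assert np.allclose(T[gi], brute, atol=1e-12)


def test_transition_negative_length_rejected(params):
    with pytest.raises(ModelError):
        branch_transition_matrix(-1.0, params)


# ---------------------------------------------------------------------------
# replicate read likelihood
# ---------------------------------------------------------------------------

def test_replicate_likelihood_closed_forms():
    p = ModelParams(epsilon=0.01)
    assert replicate_likelihood({"A": 10}, "AA", p) == pytest.approx(0.99 ** 10)
    half = 0.5 * 0.99 + 0.5 * (0.01 / 3)
    assert replicate_likelihood({"A": 5, "C": 5}, "AC", p) == \
        pytest.approx(half ** 10)
    assert replicate_likelihood({}, "GT", p) == pytest.approx(1.0)


def test_replicate_likelihood_rejects_negative():
    with pytest.raises(ModelError):
        replicate_likelihood([1, -2, 0, 0], "AA", ModelParams())


# ---------------------------------------------------------------------------
# site peel
# ---------------------------------------------------------------------------

def _uniform_pileup(tree, vec_for_leaf):
    return {lf: {r: vec_for_leaf(lf) for r in tree.replicate_map[lf]}
            for lf in tree.leaves}


def test_peel_no_variant_signal(physical_tree, params):
    pile = _uniform_pileup(physical_tree, lambda lf: [10, 0, 0, 0])
    score = site_peel(physical_tree, pile, "A", params)
    assert score.dnp < 1e-6
    assert score.map_root_genotype == "AA"


def test_peel_clade_variant_assigned_to_subtending_edge(physical_tree, params):
    """Leaves 1-3 heterozygous A/G, others hom-ref: the mutation belongs on
    the edge into their common ancestor C, with near-certain DNP."""
    pile = _uniform_pileup(
        physical_tree,
        lambda lf: [8, 0, 7, 0] if lf in ("1", "2", "3") else [15, 0, 0, 0])
    score = site_peel(physical_tree, pile, "A", params)
    assert score.dnp > 0.99999
    assert score.branch == "C"
    assert score.map_node_genotypes["1"] == "AG"
    assert score.map_node_genotypes["8"] == "AA"


def test_peel_dnp_orders_variant_above_no_variant(physical_tree, params):
    clean = _uniform_pileup(physical_tree, lambda lf: [12, 0, 0, 0])
    variant = _uniform_pileup(
        physical_tree, lambda lf: [6, 6, 0, 0] if lf in ("7", "8") else [12, 0, 0, 0])
    s_clean = site_peel(physical_tree, clean, "A", params)
    s_var = site_peel(physical_tree, variant, "A", params)
    assert s_clean.dnp < s_var.dnp


def test_peel_missing_replicate_rejected(four_leaf_tree, params):
    pile = {lf: {f"{lf}a": [5, 0, 0, 0]} for lf in "1234"}  # b replicates absent
    with pytest.raises(ModelError):
        site_peel(four_leaf_tree, pile, "A", params)


def test_peel_matches_exhaustive_oracle(four_leaf_tree, params):
    rng = np.random.default_rng(7)
    tm = TreeModel(four_leaf_tree, params)
    for _ in range(10):
        gt = rng.integers(0, N_GENOTYPES, size=4)
        counts = np.zeros((8, 4))
        emission = np.exp(tm.log_emission)
        for ri in range(8):
            counts[ri] = rng.multinomial(8, emission[gt[ri // 2]])
        lc = np.zeros((1, 4, 4))
        for ri in range(8):
            lc[0, ri // 2] += counts[ri]
        ref = np.array([int(rng.integers(0, 4))])
        res = peel_batch(tm, lc, ref)
        lo, dnp_o = exhaustive_site_oracle(four_leaf_tree, params, lc[0], ref[0])
        assert res["loglik"][0] == pytest.approx(lo, abs=1e-8)
        assert res["dnp"][0] == pytest.approx(dnp_o, abs=1e-8)


def test_peel_rerooting_invariance():
    """The genotype chain is reversible with respect to the ordered-pair
    multiplicity distribution (heterozygotes carry twice the mass of
    homozygotes); with that root prior the total likelihood is independent
    of root placement on the unrooted tree."""
    params = ModelParams(theta=0.01, epsilon=0.01, lam=1e-3)
    # same unrooted shape and edge lengths, rooted at either internal node
    # (the single-jump kernel is not a semigroup, so the root must sit on an
    # existing node rather than subdivide an edge)
    t_a = PhysicalTree.from_newick(
        "(1:1.0,2:2.0,(3:0.5,4:1.0)Y:4.0)X;",
        replicate_map={lf: [lf + "r"] for lf in "1234"})
    t_b = PhysicalTree.from_newick(
        "((1:1.0,2:2.0)X:4.0,3:0.5,4:1.0)Y;",
        replicate_map={lf: [lf + "r"] for lf in "1234"})
    rng = np.random.default_rng(0)
    by_leaf = {lf: rng.poisson(4.0, size=4).astype(float) for lf in "1234"}
    ref = np.array([0])
    mult = np.array([1.0 if a == b else 2.0 for a, b in GENOTYPE_PAIRS])
    stationary = mult / mult.sum()
    lls = []
    for t in (t_a, t_b):
        tm = TreeModel(t, params)
        tm.prior = np.tile(stationary, (4, 1))
        lc = np.stack([by_leaf[lf] for lf in t.leaves])[None, ...]
        lls.append(peel_batch(tm, lc, ref)["loglik"][0])
    assert lls[0] == pytest.approx(lls[1], abs=1e-6)


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------

def test_fit_params_invariant_sites_push_theta_down(four_leaf_tree):
    lc = np.zeros((300, 4, 4))
    lc[:, :, 0] = 12.0  # every leaf hom-ref A
    ref = np.zeros(300, dtype=np.int8)
    fitted, ll, _ = fit_params(four_leaf_tree, lc, ref, maxiter=200)
    assert fitted.theta < 1e-3
    assert np.isfinite(ll)


def test_fit_params_likelihood_not_below_truth():
    cfg = SimulationConfig(genome_length=800, theta=0.02, epsilon=0.01,
                           lam=1e-3, mean_depth=10.0, repeat_fraction=0.0,
                           seed=5)
    sim = simulate(cfg)
    lc = sim.pileups.leaf_counts(sim.tree)
    fitted, ll_opt, _ = fit_params(sim.tree, lc, sim.pileups.ref_idx)
    tm = TreeModel(sim.tree, sim.params)
    ll_true = float(peel_batch(tm, lc, sim.pileups.ref_idx)["loglik"].sum())
    assert ll_opt >= ll_true - 1e-3


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def test_call_mutations_empty_input(physical_tree, params):
    from dendromut.io import PileupTable
    empty = PileupTable(np.array([], dtype=object), np.array([], dtype=np.int64),
                        np.array([], dtype=np.int8),
                        np.zeros((0, 24, 4), dtype=np.int32),
                        list(physical_tree.replicates))
    calls, hets = call_mutations(physical_tree, empty, params)
    assert calls == [] and hets == []


def test_call_mutations_zero_threshold_marks_every_site(physical_tree, params, small_sim):
    sub = small_sim.pileups.subset(np.arange(30))
    sub = sub.with_replicate_order(physical_tree.replicates)
    calls, _ = call_mutations(physical_tree, sub, params,
                              Thresholds(dnp=0.0), min_alt_reads=0)
    assert len(calls) == 30


def test_call_mutations_recovers_planted_candidates(small_sim):
    """On 30x-per-tip synthetic data nearly every planted non-repeat mutation
    should surface as a candidate with the right branch before filtering."""
    calls, _ = call_mutations(small_sim.tree, small_sim.pileups, small_sim.params)
    by_pos = {c.pos: c.branch for c in calls}
    planted = small_sim.truth.somatic
    hits = sum(1 for m in planted if by_pos.get(m.pos) == m.branch)
    assert len(planted) > 0
    assert hits / len(planted) >= 0.9
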