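"""Diploid genotype-likelihood machinery on the physical tree.

The model treats each site independently.  A diploid genotype (one of the 10
unordered pairs over A,C,G,T) evolves down the physical tree under a
per-allele mutation kernel: along an edge of length L metres each allele
mutates with probability mu = 1 - exp(-lam * L), and a mutating allele moves
to its transition partner with weight kappa and to each transversion with
weight 1.  Reads from a replicate are modelled as independent draws of one of
the two alleles (probability 1/2 each) followed by a sequencing error with
probability epsilon (uniform over the three other bases).  All replicates of
a leaf share the leaf genotype, so replicate counts multiply into a single
leaf likelihood.

Felsenstein pruning over the tree gives the total likelihood of a site; the
de novo probability (DNP) of a site is the posterior probability that at
least one somatic mutation occurred anywhere on the tree, computed as the
complement of the all-nodes-share-the-root-genotype configuration.  Branch
attribution considers configurations in which exactly one edge carries the
mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from .tree import PhysicalTree

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: unordered diploid genotypes, lexicographic over allele indices
GENOTYPE_PAIRS: list[tuple[int, int]] = [
    (i, j) for i in range(4) for j in range(i, 4)
]
GENOTYPES = ["".join(BASES[k] for k in g) for g in GENOTYPE_PAIRS]
N_GENOTYPES = len(GENOTYPE_PAIRS)  # 10


def transition_partner(base: int) -> int:
    """A<->G, C<->T (purine/pyrimidine partners)."""
    return base ^ 2


class ModelError(ValueError):
    pass


@dataclass
class ModelParams:
    """Site-model parameters.

    theta   expected heterozygosity per site
    kappa   transition/transversion ratio (fixed at 2 by default)
    epsilon per-base sequencing error probability
    lam     somatic mutation intensity per allele per metre of branch
    mean_depth  per-replicate sequencing depth (simulation only)
    """

    theta: float = 0.01
    kappa: float = 2.0
    epsilon: float = 0.005
    lam: float = 1e-7
    mean_depth: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ModelError(f"theta must be in (0,1), got {self.theta}")
        if self.kappa <= 0:
            raise ModelError("kappa must be positive")
        if not 0 <= self.epsilon < 0.75:
            raise ModelError("epsilon must be in [0, 0.75)")
        if self.lam < 0:
            raise ModelError("lam must be non-negative")


@dataclass
class Thresholds:
    """Calling and filtering cutoffs (defaults follow the study pipeline)."""

    dnp: float = 0.99999
    lld: float = -5.0
    min_block_size: int = 500
    proximity_nt: int = 1000
    max_total_depth: int = 500
    max_excess_het: float = 40.0


@dataclass
class SiteScore:
    """Per-site output of the pruning computation."""

    loglik: float                      # natural-log likelihood of the site
    dnp: float                         # P(>=1 somatic mutation | data)
    lld: float                         # log10 likelihood / max(1, n reads)
    branch_posteriors: dict[str, float]  # edge (child node) -> posterior
    map_root_genotype: str
    map_node_genotypes: dict[str, str] = field(default_factory=dict)

    @property
    def branch(self) -> str:
        return max(self.branch_posteriors, key=self.branch_posteriors.get)


@dataclass
class MutationCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    branch: str          # child node of the mutated edge
    dnp: float
    lld: float
    root_genotype: str
    mutant_genotype: str
    filters: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------

def genotype_prior(ref_allele: str, params: ModelParams) -> np.ndarray:
    """Germline prior over the 10 genotypes at a site with the given reference.

    Mass 1 - 3*theta/2 on hom-ref; theta over the three ref/alt heterozygotes
    and theta/2 over the three alt homozygotes, both split with weight kappa
    on the transition alt and 1 on each transversion alt.
    """
    if ref_allele not in BASE_INDEX:
        raise ModelError(f"invalid reference allele {ref_allele!r}")
    return _prior_matrix(params)[BASE_INDEX[ref_allele]]


def _prior_matrix(params: ModelParams) -> np.ndarray:
    """(4, 10) prior rows indexed by reference base."""
    th, kap = params.theta, params.kappa
    norm = kap + 2.0
    out = np.zeros((4, N_GENOTYPES))
    for r in range(4):
        for gi, (a, b) in enumerate(GENOTYPE_PAIRS):
            if a == r and b == r:
                out[r, gi] = 1.0 - 1.5 * th
            elif a == r or b == r:  # ref/alt het
                alt = b if a == r else a
                w = kap if alt == transition_partner(r) else 1.0
                out[r, gi] = th * w / norm
            elif a == b:            # alt homozygote
                w = kap if a == transition_partner(r) else 1.0
                out[r, gi] = 0.5 * th * w / norm
    return out


def allele_kernel(length_m: float, params: ModelParams) -> np.ndarray:
    """4x4 per-allele mutation matrix along an edge of the given length."""
    if length_m < 0:
        raise ModelError("branch length must be non-negative")
    mu = -np.expm1(-params.lam * length_m)
    norm = params.kappa + 2.0
    K = np.full((4, 4), mu / norm)
    for a in range(4):
        K[a, a] = 1.0 - mu
        K[a, transition_partner(a)] = mu * params.kappa / norm
    return K


def branch_transition_matrix(length_m: float, params: ModelParams) -> np.ndarray:
    """10x10 genotype transition matrix: product of independent allele kernels
    collapsed onto unordered genotypes.  Rows sum to 1."""
    K = allele_kernel(length_m, params)
    T = np.zeros((N_GENOTYPES, N_GENOTYPES))
    for gi, (a1, a2) in enumerate(GENOTYPE_PAIRS):
        for hi, (b1, b2) in enumerate(GENOTYPE_PAIRS):
            p = K[a1, b1] * K[a2, b2]
            if b1 != b2:
                p += K[a1, b2] * K[a2, b1]
            T[gi, hi] = p
    return T


def _log_emission(params: ModelParams) -> np.ndarray:
    """(10, 4) log P(read base | genotype): half/half allele sampling then
    uniform error to the three other bases."""
    eps = params.epsilon
    e = np.full((4, 4), eps / 3.0)
    np.fill_diagonal(e, 1.0 - eps)
    E = np.zeros((N_GENOTYPES, 4))
    for gi, (a1, a2) in enumerate(GENOTYPE_PAIRS):
        E[gi] = 0.5 * e[a1] + 0.5 * e[a2]
    return np.log(E)


def replicate_loglik(counts, genotype: str, params: ModelParams) -> float:
    """Natural-log likelihood of one replicate's base counts given a genotype.

    ``counts`` is a mapping base->count or a length-4 array in ACGT order.
    Zero reads give log-likelihood 0 (an empty product).
    """
    if isinstance(counts, dict):
        vec = np.zeros(4)
        for b, c in counts.items():
            vec[BASE_INDEX[b]] = c
    else:
        vec = np.asarray(counts, dtype=float)
    if np.any(vec < 0):
        raise ModelError("negative base count")
    gi = GENOTYPES.index(genotype if genotype in GENOTYPES else genotype[::-1])
    return float(vec @ _log_emission(params)[gi])


def replicate_likelihood(counts, genotype: str, params: ModelParams) -> float:
    return float(np.exp(replicate_loglik(counts, genotype, params)))


# ---------------------------------------------------------------------------
# vectorised pruning over batches of sites
# ---------------------------------------------------------------------------

class TreeModel:
    """Precomputed per-edge transition matrices and index maps for one
    (tree, params) pair, shared across sites."""

    def __init__(self, tree: PhysicalTree, params: ModelParams):
        self.tree = tree
        self.params = params
        self.leaves = tree.leaves
        self.leaf_index = {lf: i for i, lf in enumerate(self.leaves)}
        self.postorder = tree.postorder()
        self.T = {c: branch_transition_matrix(tree.length[c], params)
                  for _, c in tree.edges}
        self.prior = _prior_matrix(params)
        self.log_emission = _log_emission(params)
        # per edge: boolean mask over leaves below it, and edges inside/outside
        self.edge_children = [c for _, c in tree.edges]
        self.below = {}
        for c in self.edge_children:
            mask = np.zeros(len(self.leaves), dtype=bool)
            for lf in tree.descendant_leaves(c):
                mask[self.leaf_index[lf]] = True
            self.below[c] = mask
        self.inside_edges = {
            c: [c2 for c2 in self.edge_children
                if c2 != c and set(tree.descendant_leaves(c2)) <= set(tree.descendant_leaves(c))]
            for c in self.edge_children
        }
        self.log_diag = {c: np.log(np.diag(self.T[c])) for c in self.edge_children}

    def leaf_logliks(self, leaf_counts: np.ndarray) -> np.ndarray:
        """(S, L, 10) log P(all replicates' reads at leaf | leaf genotype).

        ``leaf_counts`` is (S, L, 4): base counts summed over the leaf's
        replicates (replicates share the genotype, so their read products
        merge into summed exponents).
        """
        return leaf_counts @ self.log_emission.T


def peel_batch(tm: TreeModel, leaf_counts: np.ndarray, ref_idx: np.ndarray,
               want_branches: bool = False):
    """Vectorised pruning over S sites.

    Returns dict with loglik (S,), dnp (S,), lld (S,), log_root_post (S,10)
    and, if requested, branch posterior arrays (S, n_edges) plus the
    maximising (root, mutant) genotype pair per edge.
    """
    tree = tm.tree
    S = leaf_counts.shape[0]
    ll = tm.leaf_logliks(leaf_counts)          # (S, L, 10)
    scale = ll.max(axis=2)                     # (S, L)
    partial_leaf = np.exp(ll - scale[..., None])
    logscale = scale.sum(axis=1)               # (S,)

    partials: dict[str, np.ndarray] = {}
    for node in tm.postorder:
        kids = tree.children.get(node, [])
        if not kids:
            partials[node] = partial_leaf[:, tm.leaf_index[node], :]
            continue
        acc = np.ones((S, N_GENOTYPES))
        for c in kids:
            acc = acc * (partials[c] @ tm.T[c].T)
            del partials[c]
        m = acc.max(axis=1)
        m[m == 0] = 1.0
        acc = acc / m[:, None]
        logscale = logscale + np.log(m)
        partials[node] = acc

    prior = tm.prior[ref_idx]                  # (S, 10)
    root_part = partials[tree.root]
    total_scaled = (prior * root_part).sum(axis=1)
    loglik = np.log(total_scaled) + logscale

    # no-mutation (all nodes share root genotype) configuration
    shared_ll = ll.sum(axis=1)                 # (S, 10)
    with np.errstate(divide="ignore"):
        log_num = logsumexp(np.log(prior) + shared_ll, axis=1)
    dnp = -np.expm1(np.clip(log_num - loglik, None, 0.0))
    dnp = np.clip(dnp, 0.0, 1.0)

    nreads = leaf_counts.sum(axis=(1, 2))
    lld = (loglik / np.log(10.0)) / np.maximum(1.0, nreads)

    with np.errstate(divide="ignore"):
        log_root_post = np.log(prior) + np.log(np.where(root_part > 0, root_part, np.nan))
    log_root_post = np.nan_to_num(log_root_post, nan=-np.inf)

    out = {"loglik": loglik, "dnp": dnp, "lld": lld,
           "log_root_post": log_root_post}
    if want_branches:
        out.update(_branch_posteriors(tm, ll, prior))
    return out


def _branch_posteriors(tm: TreeModel, ll: np.ndarray, prior: np.ndarray):
    """Posterior over {no mutation, single mutation on edge e} configurations.

    A configuration places genotype g (drawn from the prior) above edge e and
    h != g on every node below it; its weight multiplies the prior, the
    per-edge transition factors (diagonal off the mutated edge) and the leaf
    likelihoods.
    """
    S = ll.shape[0]
    edges = tm.edge_children
    log_prior = np.where(prior > 0, np.log(np.maximum(prior, 1e-300)), -np.inf)
    shared_ll = ll.sum(axis=1)
    all_diag = sum(tm.log_diag[c] for c in edges)  # (10,)

    with np.errstate(divide="ignore"):
        logw0 = logsumexp(log_prior + shared_ll + all_diag[None, :], axis=1)

    logw = np.empty((S, len(edges)))
    best_pair = np.empty((S, len(edges), 2), dtype=np.int8)
    for ei, c in enumerate(edges):
        below = tm.below[c]
        A = ll[:, ~below, :].sum(axis=1)           # (S,10) above-edge leaves
        B = ll[:, below, :].sum(axis=1)            # (S,10) below-edge leaves
        inside = tm.inside_edges[c]
        d_in = sum((tm.log_diag[c2] for c2 in inside), np.zeros(N_GENOTYPES))
        outside = [c2 for c2 in edges if c2 != c and c2 not in inside]
        d_out = sum((tm.log_diag[c2] for c2 in outside), np.zeros(N_GENOTYPES))
        with np.errstate(divide="ignore"):
            logT = np.log(tm.T[c])
        # (S, g, h) joint log-weight, diagonal (no mutation on e) excluded
        joint = (log_prior + A + d_out)[:, :, None] + logT[None, :, :] \
            + (B + d_in)[:, None, :]
        ii = np.arange(N_GENOTYPES)
        joint[:, ii, ii] = -np.inf
        flat = joint.reshape(S, -1)
        with np.errstate(divide="ignore"):
            logw[:, ei] = logsumexp(flat, axis=1)
        am = flat.argmax(axis=1)
        best_pair[:, ei, 0] = am // N_GENOTYPES
        best_pair[:, ei, 1] = am % N_GENOTYPES
    allw = np.column_stack([logw0, logw])
    allw = allw - logsumexp(allw, axis=1, keepdims=True)
    post = np.exp(allw[:, 1:])
    return {"branch_post": post, "branch_edges": edges, "branch_pairs": best_pair}


# ---------------------------------------------------------------------------
# single-site convenience API
# ---------------------------------------------------------------------------

def site_peel(tree: PhysicalTree, site_pileup: dict[str, dict[str, np.ndarray]] | np.ndarray,
              ref_allele: str, params: ModelParams) -> SiteScore:
    """Score one site.

    ``site_pileup`` maps leaf -> replicate id -> length-4 ACGT count vector
    (or is a (n_replicates, 4) array in ``tree.replicates`` order).  Every
    replicate of every leaf must be present; zero counts are allowed.
    """
    tm = TreeModel(tree, params)
    counts = _site_counts(tree, site_pileup)
    leaf_counts = _sum_by_leaf(tree, counts)[None, ...]
    ref_idx = np.array([BASE_INDEX[ref_allele]])
    res = peel_batch(tm, leaf_counts, ref_idx, want_branches=True)
    post = dict(zip(res["branch_edges"], res["branch_post"][0]))
    root_post = res["log_root_post"][0]
    map_nodes = _map_genotypes_updown(tm, leaf_counts[0], tm.prior[ref_idx[0]])
    return SiteScore(
        loglik=float(res["loglik"][0]),
        dnp=float(res["dnp"][0]),
        lld=float(res["lld"][0]),
        branch_posteriors=post,
        map_root_genotype=map_nodes[tree.root],
        map_node_genotypes=map_nodes,
    )


def _site_counts(tree: PhysicalTree, site_pileup) -> np.ndarray:
    if isinstance(site_pileup, np.ndarray):
        counts = np.asarray(site_pileup, dtype=float)
        if counts.shape != (len(tree.replicates), 4):
            raise ModelError("pileup array shape does not match tree replicates")
        return counts
    counts = np.zeros((len(tree.replicates), 4))
    order = {r: i for i, r in enumerate(tree.replicates)}
    seen = set()
    for lf, reps in site_pileup.items():
        if lf not in tree.replicate_map:
            raise ModelError(f"unknown leaf {lf!r} in pileup")
        for r, vec in reps.items():
            if r not in order:
                raise ModelError(f"unknown replicate {r!r}")
            counts[order[r]] = np.asarray(vec, dtype=float)
            seen.add(r)
    missing = set(tree.replicates) - seen
    if missing:
        raise ModelError(f"pileup missing replicates: {sorted(missing)}")
    return counts


def _sum_by_leaf(tree: PhysicalTree, counts: np.ndarray) -> np.ndarray:
    leaf_of = tree.leaf_of_replicate()
    leaves = tree.leaves
    li = {lf: i for i, lf in enumerate(leaves)}
    out = np.zeros((len(leaves), 4))
    for i, r in enumerate(tree.replicates):
        out[li[leaf_of[r]]] += counts[i]
    return out


def _map_genotypes_updown(tm: TreeModel, leaf_counts: np.ndarray, prior: np.ndarray) -> dict[str, str]:
    """Marginal MAP genotype per node via inside-outside; ties broken toward
    reference-containing genotypes (lower genotype index, since the prior
    already prefers the reference)."""
    tree = tm.tree
    ll = tm.leaf_logliks(leaf_counts[None, ...])[0]  # (L, 10)
    inside: dict[str, np.ndarray] = {}
    for node in tm.postorder:
        kids = tree.children.get(node, [])
        if not kids:
            v = np.exp(ll[tm.leaf_index[node]] - ll[tm.leaf_index[node]].max())
        else:
            v = np.ones(N_GENOTYPES)
            for c in kids:
                v = v * (inside[c] @ tm.T[c].T)
            v = v / max(v.max(), 1e-300)
        inside[node] = v
    outside: dict[str, np.ndarray] = {tree.root: prior.copy()}
    for node in reversed(tm.postorder):  # preorder
        kids = tree.children.get(node, [])
        for c in kids:
            sib = np.ones(N_GENOTYPES)
            for c2 in kids:
                if c2 != c:
                    sib = sib * (inside[c2] @ tm.T[c2].T)
            outside[c] = (outside[node] * sib) @ tm.T[c]
            outside[c] = outside[c] / max(outside[c].max(), 1e-300)
    out = {}
    for node in tm.postorder:
        post = inside[node] * outside[node]
        out[node] = GENOTYPES[int(np.argmax(post))]
    return out


def map_replicate_genotypes(counts: np.ndarray, ref_idx: np.ndarray,
                            params: ModelParams) -> np.ndarray:
    """Tree-free per-replicate MAP genotypes, (S, R) genotype indices.

    Scores prior(ref) x replicate read likelihood per sample, as a
    best-practices joint caller would per sample.  ``counts`` is (S, R, 4).
    """
    prior = _prior_matrix(params)
    with np.errstate(divide="ignore"):
        lp = np.log(np.maximum(prior, 1e-300))
    score = counts @ _log_emission(params).T + lp[ref_idx][:, None, :]
    return score.argmax(axis=2).astype(np.int8)


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------

def fit_params(tree: PhysicalTree, leaf_counts: np.ndarray, ref_idx: np.ndarray,
               start: ModelParams | None = None, kappa: float = 2.0,
               fit_kappa: bool = False, maxiter: int = 400):
    """Maximum-likelihood (theta, epsilon, lam) by Nelder-Mead simplex.

    Intended for putatively neutral sites (e.g. 3-fold degenerate positions).
    ``leaf_counts`` is (S, L, 4) with leaves in ``tree.leaves`` order.
    Returns (ModelParams, total log-likelihood, converged flag).
    """
    if leaf_counts.shape[0] < 1:
        raise ModelError("no sites to fit")
    start = start or ModelParams(kappa=kappa)

    def pack(p: ModelParams) -> np.ndarray:
        x = [logit(p.theta), logit(p.epsilon / 0.75), np.log(max(p.lam, 1e-12))]
        if fit_kappa:
            x.append(np.log(p.kappa))
        return np.array(x)

    def unpack(x: np.ndarray) -> ModelParams:
        kap = float(np.exp(x[3])) if fit_kappa else kappa
        return ModelParams(theta=float(np.clip(expit(x[0]), 1e-8, 1 - 1e-8)),
                           epsilon=float(0.75 * np.clip(expit(x[1]), 1e-9, 1 - 1e-9)),
                           lam=float(np.exp(x[2])), kappa=kap)

    def nll(x: np.ndarray) -> float:
        p = unpack(x)
        tm = TreeModel(tree, p)
        res = peel_batch(tm, leaf_counts, ref_idx)
        return -float(res["loglik"].sum())

    opt = minimize(nll, pack(start), method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-3})
    fitted = unpack(opt.x)
    return fitted, -float(opt.fun), bool(opt.success)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_mutations(tree: PhysicalTree, pileups, params: ModelParams,
                   thresholds: Thresholds | None = None,
                   chunk: int = 200_000, min_alt_reads: int = 2):
    """Scan a pileup table and emit candidate somatic mutations.

    ``pileups`` is a PileupTable (see dendromut.io).  Sites with DNP >= the
    threshold become candidate MutationCalls with the maximum-posterior branch
    assignment; sites whose MAP root genotype is heterozygous (and that are
    not candidates) are returned separately for phasing.

    ``min_alt_reads`` is a cheap prescreen: a site where no replicate shows
    the same non-reference base at least that many times cannot reach a high
    DNP, so branch posteriors are only computed for sites passing it.  Set to
    0 to disable.  The DNP/LLD scan itself runs on every site.
    """
    thresholds = thresholds or Thresholds()
    tm = TreeModel(tree, params)
    calls: list[MutationCall] = []
    het_sites: list[tuple[str, int, str]] = []  # chrom, pos, genotype

    for block in pileups.iter_blocks(chunk):
        counts = block.counts.astype(float)          # (S, R, 4)
        leaf_counts = block.leaf_counts(tree)        # (S, L, 4)
        res = peel_batch(tm, leaf_counts, block.ref_idx)
        cand = res["dnp"] >= thresholds.dnp if thresholds.dnp > 0 \
            else np.ones(len(block.pos), dtype=bool)
        if min_alt_reads > 0:
            alt = counts.copy()
            alt[np.arange(len(block.pos)), :, block.ref_idx] = 0
            cand &= (alt.max(axis=(1, 2)) >= min_alt_reads)
        if cand.any():
            idx = np.flatnonzero(cand)
            br = _branch_posteriors(tm, tm.leaf_logliks(leaf_counts[idx]),
                                    tm.prior[block.ref_idx[idx]])
            for k, s in enumerate(idx):
                ei = int(br["branch_post"][k].argmax())
                gi, hi = br["branch_pairs"][k, ei]
                g, h = GENOTYPE_PAIRS[gi], GENOTYPE_PAIRS[hi]
                alt_alleles = set(h) - set(g)
                alt_base = BASES[min(alt_alleles)] if alt_alleles else GENOTYPES[hi][0]
                calls.append(MutationCall(
                    chrom=block.chrom[s], pos=int(block.pos[s]),
                    ref=BASES[block.ref_idx[s]], alt=alt_base,
                    branch=br["branch_edges"][ei],
                    dnp=float(res["dnp"][s]), lld=float(res["lld"][s]),
                    root_genotype=GENOTYPES[gi], mutant_genotype=GENOTYPES[hi]))
        # heterozygous germline sites (for haplotype blocks)
        root_map = res["log_root_post"].argmax(axis=1)
        is_het = np.array([GENOTYPE_PAIRS[g][0] != GENOTYPE_PAIRS[g][1]
                           for g in root_map])
        for s in np.flatnonzero(is_het & ~cand):
            het_sites.append((block.chrom[s], int(block.pos[s]),
                              GENOTYPES[root_map[s]]))
    return calls, het_sites
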