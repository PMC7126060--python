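"""Empirical error-rate estimation for the calling pipeline.

False-negative rate: plant in-silico mutations into the observed pileups
(editing read counts exactly as read-level spiking would), re-run the full
pipeline and measure the recovery rate.  False-discovery rate: destroy the
phylogenetic structure by permuting replicate labels until the replicate-level
tree shares no splits with the truth, re-run the pipeline ignoring previously
called sites, and count the calls that survive - all of which must be false.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PileupTable
from .model import (BASES, BASE_INDEX, GENOTYPE_PAIRS, ModelParams, Thresholds,
                    TreeModel, call_mutations, peel_batch, transition_partner)
from .filters import denovo_filter
from .tree import PhysicalTree
from .treestats import Topology


class ValidationError(ValueError):
    pass


@dataclass
class SpikeEntry:
    chrom: str
    pos: int
    branch: str            # child node of the target edge
    root_genotype: str
    mut_from: str          # allele being overwritten (the reference allele)
    mut_to: str
    attempted: bool = True  # zero-coverage spikes stay in the denominator


@dataclass
class SpikePlan:
    entries: list[SpikeEntry]
    n_per_branch: int

    def __post_init__(self) -> None:
        keys = [(e.chrom, e.pos) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValidationError("spike sites must be unique")


@dataclass
class ValidationReport:
    n_spiked: int = 0
    n_recovered: int = 0
    per_branch: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_permutations: int = 0
    n_false_calls: int = 0
    n_called_real: int | None = None

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_spiked if self.n_spiked else float("nan")

    @property
    def false_negative_rate(self) -> float:
        return 1.0 - self.recovery_rate

    @property
    def fp_per_experiment(self) -> float:
        return self.n_false_calls / self.n_permutations if self.n_permutations \
            else float("nan")

    @property
    def false_discovery_rate(self) -> float:
        if not self.n_called_real:
            return float("nan")
        return self.fp_per_experiment / self.n_called_real


# ---------------------------------------------------------------------------
# spike planning and application
# ---------------------------------------------------------------------------

def make_spike_plan(tree: PhysicalTree, pileups: PileupTable, params: ModelParams,
                    n_per_branch: int, seed: int,
                    eligible: np.ndarray | None = None) -> SpikePlan:
    """Choose spike sites and mutant alleles.

    Sites are drawn without replacement from the pileup table (optionally
    restricted by ``eligible``), assigned evenly to every edge of the tree.
    The root genotype at each site is estimated by the caller itself; the
    reference allele is mutated to a base drawn with transition weight kappa
    versus 1 per transversion.  Sites whose estimated root genotype lacks the
    reference allele are not eligible.
    """
    rng = np.random.default_rng(seed)
    edges = [c for _, c in tree.edges]
    need = n_per_branch * len(edges)
    idx_all = np.flatnonzero(eligible) if eligible is not None \
        else np.arange(len(pileups))
    if len(idx_all) < need:
        raise ValidationError(f"only {len(idx_all)} eligible sites for {need} spikes")
    # oversample so root genotypes lacking the reference allele can be skipped
    chosen = rng.choice(idx_all, size=min(len(idx_all), 2 * need), replace=False)

    tm = TreeModel(tree, params)
    sub = pileups.subset(np.sort(chosen))
    res = peel_batch(tm, sub.leaf_counts(tree), sub.ref_idx)
    root_map = res["log_root_post"].argmax(axis=1)

    entries: list[SpikeEntry] = []
    order = rng.permutation(len(sub))
    quota = {c: n_per_branch for c in edges}
    edge_cycle = [c for c in edges for _ in range(n_per_branch)]
    rng.shuffle(edge_cycle)
    ei = 0
    for s in order:
        if ei >= len(edge_cycle):
            break
        ref = BASES[sub.ref_idx[s]]
        g = GENOTYPE_PAIRS[root_map[s]]
        alleles = (BASES[g[0]], BASES[g[1]])
        if ref not in alleles:
            continue
        mut_to = _draw_mutant(BASE_INDEX[ref], params.kappa, rng)
        entries.append(SpikeEntry(chrom=sub.chrom[s], pos=int(sub.pos[s]),
                                  branch=edge_cycle[ei],
                                  root_genotype=alleles[0] + alleles[1],
                                  mut_from=ref, mut_to=BASES[mut_to]))
        quota[edge_cycle[ei]] -= 1
        ei += 1
    if ei < len(edge_cycle):
        raise ValidationError("not enough eligible sites after root genotyping")
    return SpikePlan(entries=entries, n_per_branch=n_per_branch)


def _draw_mutant(allele: int, kappa: float, rng) -> int:
    u = rng.random() * (kappa + 2.0)
    if u < kappa:
        return transition_partner(allele)
    tvs = [b for b in range(4) if b != allele and b != transition_partner(allele)]
    return tvs[0] if u < kappa + 1.0 else tvs[1]


def spike_pileups(pileups: PileupTable, plan: SpikePlan, tree: PhysicalTree,
                  seed: int) -> PileupTable:
    """Apply a spike plan to pileup counts.

    Only replicates of leaves descending from the target edge are touched.
    At a homozygous root site, Binomial(n_ref_reads, 0.5) of each affected
    replicate's reference reads flip to the mutant allele (an induced
    heterozygote); at a heterozygous root site every reference read flips
    (the reference allele is overwritten).
    """
    rng = np.random.default_rng(seed)
    counts = pileups.counts.copy()
    pos_index = {(c, int(p)): i for i, (c, p) in
                 enumerate(zip(pileups.chrom, pileups.pos))}
    rep_index = {r: i for i, r in enumerate(pileups.replicates)}
    for e in plan.entries:
        s = pos_index.get((e.chrom, e.pos))
        if s is None:
            e.attempted = True
            continue
        affected = [rep_index[r]
                    for lf in tree.descendant_leaves(e.branch)
                    for r in tree.replicate_map[lf]]
        a = BASE_INDEX[e.mut_from]
        m = BASE_INDEX[e.mut_to]
        hom = e.root_genotype[0] == e.root_genotype[1]
        for ri in affected:
            n_ref = int(counts[s, ri, a])
            if n_ref == 0:
                continue
            k = rng.binomial(n_ref, 0.5) if hom else n_ref
            counts[s, ri, a] -= k
            counts[s, ri, m] += k
    return PileupTable(pileups.chrom, pileups.pos, pileups.ref_idx, counts,
                       list(pileups.replicates))


# ---------------------------------------------------------------------------
# pipeline wrappers
# ---------------------------------------------------------------------------

def make_pipeline(params: ModelParams, thresholds: Thresholds | None = None,
                  skip_block_filter: bool = True, blocks=None,
                  min_alt_reads: int = 2):
    """Production pipeline closure: phylogenetic calling + de novo filters."""
    thresholds = thresholds or Thresholds()

    def run(tree: PhysicalTree, pileups: PileupTable):
        calls, _ = call_mutations(tree, pileups, params, thresholds,
                                  min_alt_reads=min_alt_reads)
        survivors, _ = denovo_filter(calls, blocks=blocks, thresholds=thresholds,
                                     skip_block_filter=skip_block_filter)
        return survivors

    return run


def estimate_fnr(pipeline, spiked: PileupTable, plan: SpikePlan,
                 tree: PhysicalTree, match_branch: bool = True) -> ValidationReport:
    """Recovery of planted spikes by the full pipeline.

    A spike counts as recovered when the pipeline calls its site (and, by
    default, assigns the correct branch).  All planned spikes stay in the
    denominator, including zero-coverage attempts.
    """
    calls = pipeline(tree, spiked)
    called = {(c.chrom, c.pos): c.branch for c in calls}
    rep = ValidationReport(n_spiked=len(plan.entries))
    per_branch: dict[str, list[int]] = {}
    for e in plan.entries:
        got = called.get((e.chrom, e.pos))
        ok = got is not None and (not match_branch or got == e.branch)
        b = per_branch.setdefault(e.branch, [0, 0])
        b[1] += 1
        if ok:
            b[0] += 1
            rep.n_recovered += 1
    rep.per_branch = {k: (v[0], v[1]) for k, v in per_branch.items()}
    return rep


# ---------------------------------------------------------------------------
# label permutation
# ---------------------------------------------------------------------------

def replicate_topology(tree: PhysicalTree) -> Topology:
    tips, edges = tree.replicate_topology()
    return Topology(len(tips), tuple(tuple(sorted(e)) for e in edges),
                    tuple(tips))


def shuffle_maximal_rf(tree: PhysicalTree, seed: int, max_tries: int = 10_000):
    """Permute replicate tip labels until the permuted replicate-level tree
    shares no non-trivial splits with the original (maximal RF for binary
    trees: 2(n-3)).

    Returns (permuted replicate_map, permutation dict old->new tip label,
    achieved RF distance).
    """
    rng = np.random.default_rng(seed)
    topo = replicate_topology(tree)
    orig_splits = topo.splits()
    n = topo.n_leaves
    for attempt in range(1, max_tries + 1):
        perm = rng.permutation(n)
        permuted = topo.relabel({i: int(perm[i]) for i in range(n)})
        shared = orig_splits & permuted.splits()
        if not shared:
            rf = len(orig_splits ^ permuted.splits())
            tips = topo.labels
            mapping = {tips[i]: tips[int(perm[i])] for i in range(n)}
            new_map = {lf: [mapping[r] for r in reps]
                       for lf, reps in tree.replicate_map.items()}
            return new_map, mapping, rf
    raise ValidationError(f"no maximal-RF permutation found in {max_tries} tries")


def estimate_fdr(pipeline, pileups: PileupTable, tree: PhysicalTree,
                 n_perm: int, known_variants: set[tuple[str, int]], seed: int,
                 n_called_real: int | None = None) -> ValidationReport:
    """False calls per label-permutation experiment.

    Each permutation rearranges which replicates form each branch tip (while
    keeping the physical topology), so surviving calls at previously unseen
    sites must be artefacts.  FDR = (false calls / permutation) / number of
    calls in the real run.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rep = ValidationReport(n_permutations=n_perm, n_called_real=n_called_real)
    for i in range(n_perm):
        new_map, _, _ = shuffle_maximal_rf(tree, seed=seed + i)
        ptree = PhysicalTree(root=tree.root, parent=dict(tree.parent),
                             children={k: list(v) for k, v in tree.children.items()},
                             length=dict(tree.length), replicate_map=new_map)
        calls = pipeline(ptree, pileups)
        rep.n_false_calls += sum((c.chrom, c.pos) not in known_variants
                                 for c in calls)
    return rep
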