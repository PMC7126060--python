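"""Synthetic study-design generator.

Emulates the sequencing design the calling machinery expects: a diploid
genome with heterozygous sites at density theta, somatic mutations planted on
the edges of a known physical tree (Poisson with intensity 2*lam*metres per
site), three replicate samples per branch tip sequenced to ~10x each with
per-base error epsilon, and a repeat mask covering a configurable fraction
(default 40%) of the genome.  Everything needed to test the pipeline end to
end is produced in memory and can be written to standard formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PileupTable
from .model import BASES, GENOTYPES, ModelParams, MutationCall, transition_partner
from .tree import PhysicalTree

CHROM = "chr1"


def default_physical_tree() -> PhysicalTree:
    """Default 8-tip physical tree.

    14 edges totalling 90.1 m, with root-to-tip path lengths spanning exactly
    8.4-20.3 m; the edge B->C subtends tips 1-3 (the mosaic clade of the
    motivating study design).  Internal nodes are lettered A-G with A at the
    ground.
    """
    newick = ("(((1:1.4,(2:12.2,3:12.1)D:1.0)C:2.0,(4:12.0,5:8.1)E:3.0)B:5.0,"
              "(6:7.0,(7:9.0,8:6.0)G:5.3)F:6.0)A;")
    return PhysicalTree.from_newick(newick)


def lam_for_expected(n_mutations: float, tree: PhysicalTree,
                     genome_length: int) -> float:
    """Per-allele per-metre intensity giving the requested expected number of
    somatic mutations over the whole tree and genome."""
    return n_mutations / (2.0 * tree.total_length() * genome_length)


@dataclass
class SimulationConfig:
    genome_length: int = 1_000_000
    theta: float = 0.01
    lam: float | None = None          # default: ~100 expected somatic mutations
    kappa: float = 2.0
    epsilon: float = 0.005
    replicates_per_leaf: int = 3
    mean_depth: float = 10.0
    repeat_fraction: float = 0.4
    mean_repeat_length: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 <= self.repeat_fraction < 1:
            raise ValueError("repeat_fraction must be in [0,1)")


@dataclass
class TruthSet:
    germline_genotypes: dict[int, str]            # pos -> non-hom-ref genotype
    somatic: list[MutationCall]                   # branch = mutated edge
    repeats: list[tuple[int, int]]                # 1-based inclusive

    @property
    def het_genotypes(self) -> dict[int, str]:
        return {p: g for p, g in self.germline_genotypes.items() if g[0] != g[1]}


@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: PhysicalTree
    reference: str
    pileups: PileupTable
    truth: TruthSet
    params: ModelParams = field(init=False)

    def __post_init__(self) -> None:
        cfg = self.config
        lam = cfg.lam if cfg.lam is not None else lam_for_expected(
            100.0, self.tree, cfg.genome_length)
        self.params = ModelParams(theta=cfg.theta, kappa=cfg.kappa,
                                  epsilon=cfg.epsilon, lam=lam,
                                  mean_depth=cfg.mean_depth)

    def write(self, outdir) -> None:
        from pathlib import Path

        from . import io as dio
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_fasta(out / "reference.fa", {CHROM: self.reference})
        dio.write_pileup_tsv(out / "pileups.tsv", self.pileups)
        dio.write_tree(out / "tree.nwk", self.tree)
        dio.write_sample_map(out / "sample_map.tsv", self.tree.replicate_map)
        dio.write_bed_mask(out / "repeats.bed", {CHROM: self.truth.repeats})
        contigs = {CHROM: len(self.reference)}
        dio.write_calls_vcf(out / "truth_somatic.vcf", self.truth.somatic, contigs)
        if self.truth.het_genotypes:
            dio.write_het_sites_vcf(
                out / "truth_het.vcf",
                [(CHROM, p, g) for p, g in sorted(self.truth.het_genotypes.items())],
                contigs)


def simulate(config: SimulationConfig, tree: PhysicalTree | None = None) -> SimulationResult:
    rng = np.random.default_rng(config.seed)
    tree = tree or default_physical_tree()
    if config.replicates_per_leaf != 3:
        tree.replicate_map = {lf: [f"{lf}.{i + 1}" for i in range(config.replicates_per_leaf)]
                              for lf in tree.leaves}
    G = config.genome_length
    lam = config.lam if config.lam is not None else lam_for_expected(100.0, tree, G)
    kappa = config.kappa

    ref = rng.integers(0, 4, size=G, dtype=np.int8)

    # germline variation mirrors the calling prior: heterozygous at rate
    # theta, homozygous-alternate (pseudo-reference disagreements) at theta/2,
    # alt alleles kappa-weighted
    u = rng.random(G)
    het_pos = np.flatnonzero(u < config.theta) + 1  # 1-based
    het_alt = _mutate_alleles(ref[het_pos - 1], kappa, rng)
    hom_pos = np.flatnonzero((u >= config.theta)
                             & (u < 1.5 * config.theta)) + 1
    hom_alt = _mutate_alleles(ref[hom_pos - 1], kappa, rng)

    # germline allele arrays
    a1 = ref.copy()
    a2 = ref.copy()
    a2[het_pos - 1] = het_alt
    a1[hom_pos - 1] = hom_alt
    a2[hom_pos - 1] = hom_alt

    # somatic mutations: Poisson per edge, uniform placement, disjoint sites
    leaves = tree.leaves
    leaf_i = {lf: i for i, lf in enumerate(leaves)}
    somatic: list[MutationCall] = []
    taken: set[int] = set()
    for _, child in tree.edges:
        n = rng.poisson(2.0 * lam * tree.length[child] * G)
        for _ in range(n):
            while True:
                pos = int(rng.integers(1, G + 1))
                if pos not in taken:
                    break
            taken.add(pos)
            r = int(ref[pos - 1])
            root_alleles = (int(a1[pos - 1]), int(a2[pos - 1]))
            which = int(rng.integers(0, 2))
            mut_from = root_alleles[which]
            mut_to = int(_mutate_alleles(np.array([mut_from]), kappa, rng)[0])
            ra, rb = sorted(root_alleles)
            ma, mb = sorted((root_alleles[1 - which], mut_to))
            somatic.append(MutationCall(
                chrom=CHROM, pos=pos, ref=BASES[r], alt=BASES[mut_to],
                branch=child, dnp=1.0, lld=0.0,
                root_genotype=BASES[ra] + BASES[rb],
                mutant_genotype=BASES[ma] + BASES[mb]))

    # per-(site, leaf) genotype allele pair; start from germline everywhere
    reps = tree.replicates
    leaf_of = tree.leaf_of_replicate()
    rep_leaf = np.array([leaf_i[leaf_of[r]] for r in reps])

    # sparse overrides: somatic sites only
    overrides: dict[int, np.ndarray] = {}  # pos -> (L, 2) alleles
    for m in somatic:
        pos = m.pos
        base = overrides.get(pos)
        if base is None:
            base = np.tile([a1[pos - 1], a2[pos - 1]], (len(leaves), 1))
        gt = m.mutant_genotype
        pair = [BASES.index(gt[0]), BASES.index(gt[1])]
        for lf in tree.descendant_leaves(m.branch):
            base[leaf_i[lf]] = pair
        overrides[pos] = base

    err = np.full((4, 4), config.epsilon / 3.0)
    np.fill_diagonal(err, 1.0 - config.epsilon)

    counts = np.zeros((G, len(reps), 4), dtype=np.int32)
    chunk = 100_000
    for start in range(0, G, chunk):
        end = min(start + chunk, G)
        s = slice(start, end)
        A1 = np.repeat(a1[s][:, None], len(leaves), axis=1)  # (S, L)
        A2 = np.repeat(a2[s][:, None], len(leaves), axis=1)
        for pos, pair in overrides.items():
            if start < pos <= end:
                A1[pos - 1 - start] = pair[:, 0]
                A2[pos - 1 - start] = pair[:, 1]
        p_leaf = 0.5 * (err[A1] + err[A2])                   # (S, L, 4)
        p_rep = p_leaf[:, rep_leaf, :]                       # (S, R, 4)
        depth = rng.poisson(config.mean_depth, size=(end - start, len(reps)))
        counts[s] = rng.multinomial(depth, p_rep)

    repeats = _draw_repeats(G, config.repeat_fraction, config.mean_repeat_length, rng)

    pile = PileupTable(chrom=np.full(G, CHROM, dtype=object),
                       pos=np.arange(1, G + 1, dtype=np.int64),
                       ref_idx=ref, counts=counts, replicates=list(reps))
    germline = {int(p): GENOTYPES[_gt_index(ref[p - 1], alt)]
                for p, alt in zip(het_pos, het_alt)}
    germline.update({int(p): GENOTYPES[_gt_index(alt, alt)]
                     for p, alt in zip(hom_pos, hom_alt)})
    truth = TruthSet(germline_genotypes=germline,
                     somatic=sorted(somatic, key=lambda m: m.pos),
                     repeats=repeats)
    refstr = "".join(BASES[i] for i in ref)
    return SimulationResult(config=config, tree=tree, reference=refstr,
                            pileups=pile, truth=truth)


def _gt_index(a: int, b: int) -> int:
    a, b = min(a, b), max(a, b)
    return [(i, j) for i in range(4) for j in range(i, 4)].index((a, b))


def _mutate_alleles(alleles: np.ndarray, kappa: float, rng) -> np.ndarray:
    """Draw a different base for each input allele: transition with weight
    kappa, each transversion with weight 1."""
    if len(alleles) == 0:
        return np.empty(0, dtype=np.int8)
    u = rng.random(len(alleles)) * (kappa + 2.0)
    out = np.empty(len(alleles), dtype=np.int8)
    ts = np.array([transition_partner(a) for a in alleles], dtype=np.int8)
    tv = np.array([[b for b in range(4) if b != a and b != transition_partner(a)]
                   for a in alleles], dtype=np.int8)
    out = np.where(u < kappa, ts, np.where(u < kappa + 1.0, tv[:, 0], tv[:, 1]))
    return out.astype(np.int8)


def _draw_repeats(G: int, fraction: float, mean_len: float, rng) -> list[tuple[int, int]]:
    """Alternating exponential gaps/blocks giving the target masked fraction."""
    if fraction <= 0:
        return []
    mean_gap = mean_len * (1.0 - fraction) / fraction
    out = []
    cursor = 1
    while cursor <= G:
        cursor += int(rng.exponential(mean_gap))
        if cursor > G:
            break
        length = max(1, int(rng.exponential(mean_len)))
        out.append((cursor, min(G, cursor + length - 1)))
        cursor += length
    return out


# ---------------------------------------------------------------------------
# optional raw-read emission
# ---------------------------------------------------------------------------

def write_fastq(result: SimulationResult, outdir, read_length: int = 100,
                insert: int = 300) -> None:
    """Emit paired 100 bp reads per replicate at the configured depth.

    Reads are drawn uniformly from the genome; each carries the replicate's
    sampled allele at every variant site it spans plus epsilon errors.  Only
    practical for small genomes; the pileup representation is the default.
    """
    from pathlib import Path
    cfg = result.config
    rng = np.random.default_rng(cfg.seed + 1)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ref = np.frombuffer(result.reference.encode(), dtype=np.uint8)
    base_map = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(BASES):
        base_map[ord(b)] = i
    refi = base_map[ref]
    G = len(refi)
    tree = result.tree
    leaf_i = {lf: i for i, lf in enumerate(tree.leaves)}

    var_sites: dict[int, np.ndarray] = {}
    for p, gt in result.truth.germline_genotypes.items():
        var_sites[p] = np.tile([BASES.index(gt[0]), BASES.index(gt[1])],
                               (len(tree.leaves), 1))
    for m in result.truth.somatic:
        pair_root = var_sites.get(
            m.pos, np.tile([BASES.index(m.root_genotype[0]),
                            BASES.index(m.root_genotype[1])], (len(tree.leaves), 1)))
        mut = [BASES.index(m.mutant_genotype[0]), BASES.index(m.mutant_genotype[1])]
        for lf in tree.descendant_leaves(m.branch):
            pair_root[leaf_i[lf]] = mut
        var_sites[m.pos] = pair_root

    leaf_of = tree.leaf_of_replicate()
    for rep in tree.replicates:
        li = leaf_i[leaf_of[rep]]
        n_pairs = int(cfg.mean_depth * G / (2 * read_length))
        with open(out / f"{rep}_R1.fastq", "w") as f1, \
                open(out / f"{rep}_R2.fastq", "w") as f2:
            for k in range(n_pairs):
                start = int(rng.integers(0, max(1, G - insert)))
                frag = refi[start:start + insert].copy()
                for p, pairs in var_sites.items():
                    if start < p <= start + insert:
                        frag[p - 1 - start] = pairs[li][int(rng.integers(0, 2))]
                errs = rng.random(len(frag)) < cfg.epsilon
                if errs.any():
                    frag[errs] = (frag[errs] + rng.integers(1, 4, errs.sum())) % 4
                r1 = "".join(BASES[i] for i in frag[:read_length])
                r2 = "".join(BASES[i] for i in frag[-read_length:][::-1])
                qual = "I" * read_length
                f1.write(f"@{rep}.{k}/1\n{r1}\n+\n{qual}\n")
                f2.write(f"@{rep}.{k}/2\n{r2}\n+\n{qual}\n")
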