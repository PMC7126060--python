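"""Site-filter cascades.

Two cascades are implemented: the positive-control filters applied to
independent per-replicate genotype calls (replicate concordance, at least one
divergent tip, biallelic, depth cap, heterozygosity excess, repeat mask), and
the de novo call filters applied to phylogenetically scored candidates
(haplotype block size, proximity to other candidates, LLD and DNP cutoffs).
Each cascade reports per-rule attrition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np

from .model import GENOTYPES, MutationCall, Thresholds


@dataclass
class SiteRecord:
    chrom: str
    pos: int
    ref: str
    genotypes: dict[str, str | None]   # replicate id -> diploid genotype
    total_depth: int
    repeat_flag: bool = False
    excess_het_phred: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.total_depth < 0:
            raise ValueError("total_depth must be >= 0")


@dataclass
class HaplotypeBlock:
    chrom: str
    start: int
    end: int
    members: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("block end < start")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class Attrition:
    """Per-rule attrition of a filter cascade.

    ``failed`` counts sites failing each rule (non-exclusive), ``exclusive``
    those failing only that rule; input = survivors + sum(exclusive) +
    multi_failed."""

    n_input: int = 0
    n_survivors: int = 0
    failed: dict[str, int] = field(default_factory=dict)
    exclusive: dict[str, int] = field(default_factory=dict)
    multi_failed: int = 0

    def record(self, fails: list[str]) -> None:
        for rule in fails:
            self.failed[rule] = self.failed.get(rule, 0) + 1
        if len(fails) == 1:
            self.exclusive[fails[0]] = self.exclusive.get(fails[0], 0) + 1
        elif len(fails) > 1:
            self.multi_failed += 1

    def check(self) -> bool:
        return self.n_input == self.n_survivors + sum(self.exclusive.values()) \
            + self.multi_failed


# ---------------------------------------------------------------------------
# excess heterozygosity (Levene exact test)
# ---------------------------------------------------------------------------

def _levene_log_pmf(n_het: int, n_samples: int, n_a: int) -> float:
    """log P(n_het heterozygotes | n_samples diploids, n_a copies of allele A)
    under the Hardy-Weinberg conditional (Levene) distribution."""
    n_b = 2 * n_samples - n_a
    n_aa = (n_a - n_het) // 2
    n_bb = (n_b - n_het) // 2
    return (lgamma(n_samples + 1) - lgamma(n_aa + 1) - lgamma(n_het + 1)
            - lgamma(n_bb + 1) + n_het * log(2.0)
            + lgamma(n_a + 1) + lgamma(n_b + 1) - lgamma(2 * n_samples + 1))


def excess_het_phred(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Phred-scaled one-sided exact-test probability of observing at least the
    seen number of heterozygotes, conditioned on the sample allele counts.

    High values mean more heterozygous samples than Hardy-Weinberg predicts,
    a signature of a uniformly heterozygous site miscalled in some samples.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped samples")
    n_a = 2 * n_hom_ref + n_het
    n_rare = min(n_a, 2 * n - n_a)
    if n_het == 0:
        return 0.0
    hs = range(n_het, n_rare + 1, 2)  # parity of n_het fixed by allele counts
    logs = [_levene_log_pmf(h, n, n_a) for h in hs]
    if not logs:
        return 0.0
    m = max(logs)
    p = min(1.0, np.exp(m) * sum(np.exp(v - m) for v in logs))
    return float(-10.0 * np.log10(max(p, 1e-300)))


# ---------------------------------------------------------------------------
# positive-control cascade
# ---------------------------------------------------------------------------

def _is_het(gt: str) -> bool:
    return gt[0] != gt[1]


def positive_control_filter(records: list[SiteRecord],
                            replicate_map: dict[str, list[str]],
                            repeat_mask=None,
                            thresholds: Thresholds | None = None):
    """Keep sites passing all positive-control rules.

    Rules: (concordant) all replicates of each leaf share a genotype;
    (divergent) at least one leaf differs from another; (biallelic) at most
    two distinct alleles including the reference; (depth) total depth <= cap;
    (excess_het) phred-scaled heterozygote excess <= cap; (repeat) outside the
    repeat mask.  Sites with any missing replicate genotype are dropped and
    counted under 'missing'.  Returns (survivors, Attrition).
    """
    thresholds = thresholds or Thresholds()
    att = Attrition(n_input=len(records))
    survivors = []
    for rec in records:
        fails: list[str] = []
        gts = {}
        missing = False
        for leaf, reps in replicate_map.items():
            vals = [rec.genotypes.get(r) for r in reps]
            if any(v is None for v in vals):
                missing = True
                break
            gts[leaf] = vals
        if missing:
            fails = ["missing"]
        else:
            if any(len(set(v)) != 1 for v in gts.values()):
                fails.append("concordant")
            leaf_gt = {lf: v[0] for lf, v in gts.items()}
            if len(set(leaf_gt.values())) < 2:
                fails.append("divergent")
            alleles = set(rec.ref)
            for g in leaf_gt.values():
                alleles.update(g)
            if len(alleles) > 2:
                fails.append("biallelic")
            if rec.total_depth > thresholds.max_total_depth:
                fails.append("depth")
            eh = rec.excess_het_phred
            if eh is None:
                counts = _genotype_class_counts(rec, replicate_map)
                eh = excess_het_phred(*counts) if counts else 0.0
                rec.excess_het_phred = eh
            if eh > thresholds.max_excess_het:
                fails.append("excess_het")
            in_repeat = rec.repeat_flag
            if repeat_mask is not None:
                from .io import in_mask
                in_repeat = in_repeat or bool(
                    in_mask(repeat_mask, np.array([rec.chrom], dtype=object),
                            np.array([rec.pos]))[0])
            if in_repeat:
                fails.append("repeat")
        att.record(fails)
        if not fails:
            survivors.append(rec)
    att.n_survivors = len(survivors)
    return survivors, att


def _genotype_class_counts(rec: SiteRecord, replicate_map):
    """(n hom-ref, n het, n hom-alt) over replicate samples; None if any
    genotype involves more than one alternate allele."""
    n_rr = n_het = n_aa = 0
    for reps in replicate_map.values():
        for r in reps:
            g = rec.genotypes.get(r)
            if g is None:
                continue
            if g[0] == g[1]:
                if g[0] == rec.ref:
                    n_rr += 1
                else:
                    n_aa += 1
            else:
                n_het += 1
    return n_rr, n_het, n_aa


def records_from_map_genotypes(pileups, gt_idx: np.ndarray,
                               repeat_flags: np.ndarray | None = None) -> list[SiteRecord]:
    """Build SiteRecords from a (S, R) array of MAP genotype indices."""
    out = []
    depth = pileups.total_depth
    for s in range(len(pileups)):
        gts = {rep: GENOTYPES[gt_idx[s, ri]]
               for ri, rep in enumerate(pileups.replicates)}
        out.append(SiteRecord(
            chrom=pileups.chrom[s], pos=int(pileups.pos[s]),
            ref="ACGT"[pileups.ref_idx[s]], genotypes=gts,
            total_depth=int(depth[s]),
            repeat_flag=bool(repeat_flags[s]) if repeat_flags is not None else False))
    return out


# ---------------------------------------------------------------------------
# haplotype blocks
# ---------------------------------------------------------------------------

def build_blocks(het_sites: list[tuple[str, int]],
                 fragments: list[list[tuple[str, int]]]) -> list[HaplotypeBlock]:
    """Union-find over het sites linked by shared sequencing fragments.

    ``fragments`` lists, per fragment, the (chrom, pos) het sites it covers.
    Sites never linked form singleton blocks of size 1.
    """
    parent = {site: site for site in het_sites}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for frag in fragments:
        covered = [s for s in frag if s in parent]
        for a, b in zip(covered, covered[1:]):
            if a[0] == b[0]:
                union(a, b)
    groups: dict[tuple, list[tuple[str, int]]] = {}
    for site in het_sites:
        groups.setdefault(find(site), []).append(site)
    blocks = []
    for members in groups.values():
        positions = sorted(p for _, p in members)
        blocks.append(HaplotypeBlock(chrom=members[0][0], start=positions[0],
                                     end=positions[-1], members=positions))
    blocks.sort(key=lambda b: (b.chrom, b.start))
    return blocks


def _block_of(call: MutationCall, blocks: list[HaplotypeBlock]) -> HaplotypeBlock | None:
    for b in blocks:
        if b.chrom == call.chrom and b.start <= call.pos <= b.end:
            return b
    return None


# ---------------------------------------------------------------------------
# de novo cascade
# ---------------------------------------------------------------------------

def denovo_filter(calls: list[MutationCall],
                  blocks: list[HaplotypeBlock] | None = None,
                  thresholds: Thresholds | None = None,
                  skip_block_filter: bool = False):
    """Apply the de novo call filters; returns (survivors, Attrition).

    Rules: (block) the call lies on a haplotype block of size >= the minimum
    (calls outside any block fail, since an unphaseable region signals a poor
    alignment); (proximity) BOTH members of any candidate pair closer than the
    proximity distance are removed, evaluated on the incoming candidate set;
    (lld) LLD >= cutoff kept; (dnp) DNP >= cutoff kept.
    """
    thresholds = thresholds or Thresholds()
    att = Attrition(n_input=len(calls))

    # proximity evaluated on the whole candidate set before other rules
    close = set()
    by_chrom: dict[str, list[MutationCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for cs in by_chrom.values():
        cs.sort(key=lambda c: c.pos)
        for a, b in zip(cs, cs[1:]):
            if b.pos - a.pos < thresholds.proximity_nt:
                close.add(id(a))
                close.add(id(b))

    survivors = []
    for c in calls:
        fails = []
        if not skip_block_filter:
            blk = _block_of(c, blocks or [])
            if blk is None or blk.size < thresholds.min_block_size:
                fails.append("block")
        if id(c) in close:
            fails.append("proximity")
        if c.lld < thresholds.lld:
            fails.append("lld")
        if c.dnp < thresholds.dnp:
            fails.append("dnp")
        att.record(fails)
        if fails:
            c.filters = fails
        else:
            survivors.append(c)
    att.n_survivors = len(survivors)
    return survivors, att
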