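"""Readers, writers and coordinate conventions.

Internal coordinates are 1-based inclusive (VCF convention).  BED input
(0-based half-open) is converted at this boundary and nowhere else.  Pileups
travel as TSV with one row per site and four ACGT count columns per replicate
sample; variant calls travel as VCF 4.2 with INFO fields DNP, LLD and BRANCH.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import BASES, BASE_INDEX, MutationCall, ModelParams, Thresholds
from .tree import PhysicalTree


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

@dataclass
class PileupTable:
    """Per-site, per-replicate base counts.

    counts: (n_sites, n_replicates, 4) in ACGT order; ``replicates`` names the
    middle axis.  ``ref_idx`` holds ACGT indices of the reference allele.
    """

    chrom: np.ndarray          # (S,) object/str
    pos: np.ndarray            # (S,) int, 1-based
    ref_idx: np.ndarray        # (S,) int8
    counts: np.ndarray         # (S, R, 4) int
    replicates: list[str]

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise FormatError("negative base counts")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def total_depth(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def leaf_counts(self, tree: PhysicalTree) -> np.ndarray:
        """(S, L, 4) counts summed over each leaf's replicates, leaves in
        ``tree.leaves`` order."""
        rep_i = {r: i for i, r in enumerate(self.replicates)}
        out = np.zeros((len(self), len(tree.leaves), 4))
        for li, lf in enumerate(tree.leaves):
            for r in tree.replicate_map[lf]:
                if r not in rep_i:
                    raise FormatError(f"pileup lacks replicate {r!r}")
                out[:, li, :] += self.counts[:, rep_i[r], :]
        return out

    def iter_blocks(self, chunk: int):
        for start in range(0, len(self), chunk):
            sl = slice(start, start + chunk)
            yield PileupTable(self.chrom[sl], self.pos[sl], self.ref_idx[sl],
                              self.counts[sl], self.replicates)

    def subset(self, mask: np.ndarray) -> "PileupTable":
        return PileupTable(self.chrom[mask], self.pos[mask], self.ref_idx[mask],
                           self.counts[mask], self.replicates)

    def with_replicate_order(self, order: list[str]) -> "PileupTable":
        """Reorder/relabel columns: used by label-permutation analyses."""
        idx = [self.replicates.index(r) for r in order]
        return PileupTable(self.chrom, self.pos, self.ref_idx,
                           self.counts[:, idx, :], list(order))


def write_pileup_tsv(path: str, table: PileupTable) -> None:
    cols = {"chrom": table.chrom, "pos": table.pos,
            "ref": [BASES[i] for i in table.ref_idx]}
    for ri, rep in enumerate(table.replicates):
        for bi, b in enumerate(BASES):
            cols[f"{rep}:{b}"] = table.counts[:, ri, bi]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str) -> PileupTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "ref"):
        if col not in df.columns:
            raise FormatError(f"pileup TSV missing column {col!r}")
    rep_cols = [c for c in df.columns if ":" in c]
    reps = list(dict.fromkeys(c.rsplit(":", 1)[0] for c in rep_cols))
    counts = np.zeros((len(df), len(reps), 4), dtype=np.int32)
    for ri, rep in enumerate(reps):
        for bi, b in enumerate(BASES):
            counts[:, ri, bi] = df[f"{rep}:{b}"].to_numpy()
    try:
        ref_idx = np.array([BASE_INDEX[r] for r in df["ref"]], dtype=np.int8)
    except KeyError as e:
        raise FormatError(f"invalid reference allele {e}") from None
    return PileupTable(df["chrom"].to_numpy(dtype=object),
                       df["pos"].to_numpy(dtype=np.int64), ref_idx, counts, reps)


def pileup_from_bam(bam_path: str, fasta_path: str, replicate: str,
                    min_base_quality: int = 0) -> PileupTable:
    """Single-sample pileup from an alignment file via standard pileup
    semantics (pysam count_coverage: per-position A/C/G/T read counts)."""
    ref = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    cov = {contig: np.zeros((len(seq), 4), dtype=np.int32)
           for contig, seq in ref.items()}
    with pysam.AlignmentFile(bam_path) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name not in cov:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            arr = cov[read.reference_name]
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                bi = BASE_INDEX.get(seq[qpos])
                if bi is not None and rpos < len(arr):
                    arr[rpos, bi] += 1
    chroms, poss, refs, cnts = [], [], [], []
    for contig, seq in ref.items():
        n = len(seq)
        chroms.extend([contig] * n)
        poss.extend(range(1, n + 1))
        refs.extend(BASE_INDEX.get(b, 0) for b in seq)
        cnts.append(cov[contig])
    counts = np.concatenate(cnts)[:, None, :] if cnts else np.zeros((0, 1, 4), int)
    return PileupTable(np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
                       np.array(refs, dtype=np.int8), counts.astype(np.int32),
                       [replicate])


def merge_pileups(tables: list[PileupTable]) -> PileupTable:
    """Column-merge single/multi-sample tables that cover identical sites."""
    first = tables[0]
    for t in tables[1:]:
        if not (np.array_equal(t.pos, first.pos) and np.array_equal(t.chrom, first.chrom)):
            raise FormatError("pileup tables cover different sites")
    counts = np.concatenate([t.counts for t in tables], axis=1)
    reps = [r for t in tables for r in t.replicates]
    return PileupTable(first.chrom, first.pos, first.ref_idx, counts, reps)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_calls_vcf(path: str, calls: list[MutationCall],
                    contigs: dict[str, int] | None = None) -> None:
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    seen = contigs or {}
    if not seen:
        seen = {}
        for c in calls:
            seen[c.chrom] = max(seen.get(c.chrom, 0), c.pos)
    for chrom, ln in seen.items():
        header.contigs.add(chrom, length=int(ln))
    header.info.add("DNP", 1, "Float", "Posterior probability of >=1 somatic mutation")
    header.info.add("LLD", 1, "Float", "Per-read-scaled log10 likelihood of site data")
    header.info.add("BRANCH", 1, "String", "Assigned mutated edge (child node)")
    header.info.add("ROOTGT", 1, "String", "MAP root genotype")
    with pysam.VariantFile(path, "w", header=header) as vf:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            rec = vf.new_record(contig=c.chrom, start=c.pos - 1, stop=c.pos,
                                alleles=(c.ref, c.alt))
            rec.info["DNP"] = float(c.dnp)
            rec.info["LLD"] = float(c.lld)
            rec.info["BRANCH"] = c.branch
            rec.info["ROOTGT"] = c.root_genotype
            vf.write(rec)


def read_calls_vcf(path: str) -> list[MutationCall]:
    out = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            out.append(MutationCall(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                branch=rec.info.get("BRANCH", "."),
                dnp=float(rec.info.get("DNP", 0.0)),
                lld=float(rec.info.get("LLD", 0.0)),
                root_genotype=rec.info.get("ROOTGT", ""),
                mutant_genotype=""))
    return out


def write_het_sites_vcf(path: str, het_sites: list[tuple[str, int, str]],
                        contigs: dict[str, int] | None = None) -> None:
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    seen = contigs or {c: max(p for cc, p, _ in het_sites if cc == c)
                       for c, _, _ in het_sites}
    for chrom, ln in seen.items():
        header.contigs.add(chrom, length=int(ln))
    header.info.add("GT10", 1, "String", "MAP diploid genotype")
    with pysam.VariantFile(path, "w", header=header) as vf:
        for chrom, pos, gt in sorted(het_sites):
            a, b = gt[0], gt[1]
            rec = vf.new_record(contig=chrom, start=pos - 1, stop=pos,
                                alleles=(a, b) if a != b else (a, "N"))
            rec.info["GT10"] = gt
            vf.write(rec)


# ---------------------------------------------------------------------------
# BED repeat masks
# ---------------------------------------------------------------------------

def read_bed_mask(path: str) -> dict[str, list[tuple[int, int]]]:
    """BED (0-based half-open) -> per-chrom 1-based inclusive intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start")
            out.setdefault(chrom, []).append((start + 1, end))
    for iv in out.values():
        iv.sort()
    return out


def write_bed_mask(path: str, mask: dict[str, list[tuple[int, int]]]) -> None:
    with open(path, "w") as fh:
        for chrom in mask:
            for s, e in mask[chrom]:
                fh.write(f"{chrom}\t{s - 1}\t{e}\n")


def in_mask(mask: dict[str, list[tuple[int, int]]], chrom: np.ndarray,
            pos: np.ndarray) -> np.ndarray:
    """Vectorised membership of 1-based positions in a (1-based) mask."""
    out = np.zeros(len(pos), dtype=bool)
    for c, ivs in mask.items():
        sel = chrom == c
        if not sel.any() or not ivs:
            continue
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        p = pos[sel]
        i = np.searchsorted(starts, p, side="right") - 1
        hit = (i >= 0) & (p <= ends[np.clip(i, 0, None)])
        out[np.flatnonzero(sel)] = hit
    return out


# ---------------------------------------------------------------------------
# FASTA / trees / sample maps / config
# ---------------------------------------------------------------------------

def write_fasta(path: str, sequences: dict[str, str]) -> None:
    SeqIO.write([SeqRecord(Seq(s), id=name, description="")
                 for name, s in sequences.items()], path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_tree(newick_path: str, sample_map_path: str | None = None) -> PhysicalTree:
    with open(newick_path) as fh:
        newick = fh.read()
    rep_map = read_sample_map(sample_map_path) if sample_map_path else None
    return PhysicalTree.from_newick(newick, replicate_map=rep_map)


def write_tree(path: str, tree: PhysicalTree) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_sample_map(path: str) -> dict[str, list[str]]:
    """TSV replicate_id<TAB>leaf -> leaf -> [replicates]."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rep, leaf = line.split("\t")
            except ValueError:
                raise FormatError(f"{path}:{lineno}: expected 2 columns") from None
            out.setdefault(leaf, []).append(rep)
    return out


def write_sample_map(path: str, replicate_map: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for leaf, reps in replicate_map.items():
            for r in reps:
                fh.write(f"{r}\t{leaf}\n")


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def params_from_config(cfg: dict) -> ModelParams:
    return ModelParams(**{k: v for k, v in cfg.get("params", {}).items()
                          if k in ("theta", "kappa", "epsilon", "lam", "mean_depth")})


def thresholds_from_config(cfg: dict) -> Thresholds:
    allowed = ("dnp", "lld", "min_block_size", "proximity_nt",
               "max_total_depth", "max_excess_het")
    return Thresholds(**{k: v for k, v in cfg.get("thresholds", {}).items()
                         if k in allowed})


def write_manifest(path: str, **fields) -> None:
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, default=str)
        fh.write("\n")
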