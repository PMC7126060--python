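"""End-to-end orchestration used by the CLI and the validation loops."""

from __future__ import annotations

import numpy as np

from . import treestats
from .filters import (Attrition, denovo_filter, positive_control_filter,
                      records_from_map_genotypes)
from .io import PileupTable, in_mask
from .model import (ModelParams, Thresholds, call_mutations,
                    map_replicate_genotypes)
from .tree import PhysicalTree


def positive_control(tree: PhysicalTree, pileups: PileupTable,
                     params: ModelParams, thresholds: Thresholds | None = None,
                     repeat_mask=None, topologies=None):
    """Replicate-concordance genotype calling, strict site filters, exhaustive
    parsimony scan and the PD null test against the physical topology.

    Returns a dict with the surviving site records, combined attrition, the
    genotype alignment, maximum-parsimony topologies and score, and the PD
    p-value of each maximum-parsimony topology.
    """
    thresholds = thresholds or Thresholds()
    # order columns by tree replicate order so leaf grouping is contiguous
    pile = pileups.with_replicate_order(tree.replicates)
    gt_idx = np.concatenate([
        map_replicate_genotypes(block.counts.astype(float), block.ref_idx, params)
        for block in pile.iter_blocks(100_000)])

    leaves = tree.leaves
    cols = []
    start = 0
    for lf in leaves:
        k = len(tree.replicate_map[lf])
        cols.append(slice(start, start + k))
        start += k
    concordant = np.ones(len(pile), dtype=bool)
    leaf_gt = np.zeros((len(pile), len(leaves)), dtype=np.int8)
    for li, sl in enumerate(cols):
        block = gt_idx[:, sl]
        concordant &= (block == block[:, :1]).all(axis=1)
        leaf_gt[:, li] = block[:, 0]
    divergent = (leaf_gt != leaf_gt[:, :1]).any(axis=1)

    att = Attrition(n_input=len(pile))
    interesting = concordant & divergent
    # vectorised attrition for the two cheap rules (anything failing either
    # is excluded before record construction; overlaps counted as multi)
    both = (~concordant) & (~divergent)
    att.failed["concordant"] = int((~concordant).sum())
    att.failed["divergent"] = int((~divergent).sum())
    att.exclusive["concordant"] = int(((~concordant) & divergent).sum())
    att.exclusive["divergent"] = int((concordant & (~divergent)).sum())
    att.multi_failed += int(both.sum())

    sub = pile.subset(interesting)
    flags = in_mask(repeat_mask, sub.chrom, sub.pos) if repeat_mask else None
    records = records_from_map_genotypes(sub, gt_idx[interesting], flags)
    survivors, att2 = positive_control_filter(records, tree.replicate_map,
                                              thresholds=thresholds)
    for k, v in att2.failed.items():
        att.failed[k] = att.failed.get(k, 0) + v
    for k, v in att2.exclusive.items():
        att.exclusive[k] = att.exclusive.get(k, 0) + v
    att.multi_failed += att2.multi_failed
    att.n_survivors = len(survivors)

    out = {"records": survivors, "attrition": att, "alignment": None,
           "mp_trees": [], "mp_score": None, "pd_pvalues": [], "scores": None}
    if not survivors:
        return out

    alignment = {lf: [] for lf in leaves}
    rep0 = {lf: tree.replicate_map[lf][0] for lf in leaves}
    for rec in survivors:
        for lf in leaves:
            alignment[lf].append(rec.genotypes[rep0[lf]])
    out["alignment"] = alignment

    physical = treestats.topology_from_physical(tree)
    if topologies is None:
        topologies = treestats.enumerate_topologies(len(leaves), physical.labels)
    mp_trees, score, scores = treestats.max_parsimony_trees(topologies, alignment)
    out.update(mp_trees=mp_trees, mp_score=score, scores=scores)
    null = np.array([treestats.path_difference(physical, t) for t in topologies])
    out["pd_null"] = null
    out["pd_pvalues"] = [float((null <= treestats.path_difference(physical, t)).mean())
                         for t in mp_trees]
    out["physical_topology"] = physical
    return out


def call_and_filter(tree: PhysicalTree, pileups: PileupTable, params: ModelParams,
                    thresholds: Thresholds | None = None, blocks=None,
                    skip_block_filter: bool = True, min_alt_reads: int = 2):
    """Phylogenetic calling followed by the de novo filter cascade."""
    thresholds = thresholds or Thresholds()
    calls, het_sites = call_mutations(tree, pileups, params, thresholds,
                                      min_alt_reads=min_alt_reads)
    survivors, att = denovo_filter(calls, blocks=blocks, thresholds=thresholds,
                                   skip_block_filter=skip_block_filter)
    return {"candidates": calls, "survivors": survivors, "attrition": att,
            "het_sites": het_sites}


def calls_per_edge(calls, tree: PhysicalTree) -> dict[str, int]:
    out: dict[str, int] = {c: 0 for _, c in tree.edges}
    for call in calls:
        out[call.branch] = out.get(call.branch, 0) + 1
    return out
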