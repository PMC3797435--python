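"""RPKM quantification, low-expression filtering, demethylation-reversible
regions, and the promoter-methylation x expression join.

The candidate-gene cascade reproduces the derivation of highly methylated
upstream regulatory regions: peaks within 2 kb upstream / 1 kb downstream of
a TSS, retained only when a CpG island or registered promoter lies within
1 kb upstream of that TSS, optionally joined against expression silencing in
the methylated lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import GeneModel, GenomicInterval
from .signatures import gene_window, overlap_equivalence


def compute_rpkm(counts: pd.DataFrame, transcript_lengths: pd.Series,
                 total_mapped: Optional[pd.Series] = None) -> pd.DataFrame:
    """RPKM = count * 1e9 / (length_bp * total mapped reads), per column.

    ``total_mapped`` defaults to each column's sum.
    """
    lengths = transcript_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:3]
        raise ValueError(f"missing transcript lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if total_mapped is None:
        total_mapped = counts.sum(axis=0)
    if (total_mapped <= 0).any():
        raise ValueError("total mapped reads must be positive")
    return counts.mul(1e9).div(lengths, axis=0).div(total_mapped, axis=1)


def filter_low_expression(rpkm: pd.DataFrame,
                          threshold: float = 1.0) -> pd.DataFrame:
    """Drop transcripts with RPKM below ``threshold`` in every sample.

    A row survives iff its maximum RPKM is >= threshold (RPKM exactly 1 is
    not "less than 1" and is kept).
    """
    if rpkm.shape[1] < 1:
        raise ValueError("need at least one sample column")
    return rpkm.loc[rpkm.max(axis=1) >= threshold]


@dataclass
class ReversibleRegion:
    interval: GenomicInterval
    methylated_in_untreated: bool
    methylated_in_treated: bool

    @property
    def reversal(self) -> bool:
        return self.methylated_in_untreated and not self.methylated_in_treated


def reversible_regions(
    untreated_peaks: Sequence[GenomicInterval],
    treated_peaks: Sequence[GenomicInterval],
    min_frac: float = 0.5,
) -> List[ReversibleRegion]:
    """Regions whose methylation is erased by demethylating-agent treatment.

    A region is reversible iff it is called in the untreated sample and has
    no reciprocal-overlap match in the treated sample.
    """
    _, unmatched, _ = overlap_equivalence(list(untreated_peaks),
                                          list(treated_peaks), min_frac)
    unmatched_set = set(unmatched)
    return [
        ReversibleRegion(
            interval=iv,
            methylated_in_untreated=True,
            methylated_in_treated=i not in unmatched_set,
        )
        for i, iv in enumerate(untreated_peaks)
    ]


@dataclass
class CandidateGeneParams:
    """Parameters of the candidate-gene filter cascade."""

    tss_upstream: int = 2000
    tss_downstream: int = 1000
    promoter_evidence_window: int = 1000   # upstream window for island/promoter
    silencing_fold: float = 2.0            # expression join threshold
    rpkm_threshold: float = 1.0


@dataclass
class CandidateGeneResult:
    genes: List[str]
    regions: pd.DataFrame       # region_id, gene_id, stage of the cascade
    stage_counts: Dict[str, int]


def candidate_gene_set(
    peaks: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    island_set: Sequence[GenomicInterval],
    promoter_db: Sequence[GenomicInterval] = (),
    expression_rpkm: Optional[pd.DataFrame] = None,
    methylated_lines: Optional[Sequence[str]] = None,
    unmethylated_lines: Optional[Sequence[str]] = None,
    params: Optional[CandidateGeneParams] = None,
) -> CandidateGeneResult:
    """Derive the candidate gene set by a monotone filter cascade.

    1. keep peaks within ``tss_upstream``/``tss_downstream`` of a TSS;
    2. keep genes with a CpG island or registered promoter within
       ``promoter_evidence_window`` bp upstream of that TSS;
    3. (optional) keep genes silenced in the methylated lines: mean RPKM in
       unmethylated lines >= ``silencing_fold`` x mean in methylated lines
       and above the low-expression threshold.
    """
    params = params or CandidateGeneParams()
    genes_by_id = {g.gene_id: g for g in gene_models}

    # stage 1: peaks near a TSS
    trees: Dict[str, IntervalTree] = {}
    for g in gene_models:
        lo, hi = gene_window(g, params.tss_upstream, params.tss_downstream,
                             anchor="tss")
        if hi > lo:
            trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)
    rows = []
    for i, pk in enumerate(peaks):
        tree = trees.get(pk.chrom)
        if tree is None:
            continue
        rid = pk.name or f"peak_{i}"
        for hit in sorted(tree.overlap(pk.start, pk.end)):
            rows.append({"region_id": rid, "gene_id": hit.data})
    stage1 = pd.DataFrame(rows, columns=["region_id", "gene_id"])
    stage1 = stage1.drop_duplicates()
    genes1 = set(stage1["gene_id"])

    # stage 2: island or promoter evidence 1 kb upstream of the TSS
    evidence: Dict[str, IntervalTree] = {}
    for iv in list(island_set) + list(promoter_db):
        evidence.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    genes2 = set()
    for gid in genes1:
        g = genes_by_id[gid]
        lo, hi = gene_window(g, params.promoter_evidence_window, 0,
                             anchor="tss")
        tree = evidence.get(g.chrom)
        if tree is not None and hi > lo and tree.overlap(lo, hi):
            genes2.add(gid)
    stage2 = stage1[stage1["gene_id"].isin(genes2)]

    # stage 3: optional expression-silencing join
    genes3 = set(genes2)
    if expression_rpkm is not None and methylated_lines and unmethylated_lines:
        expr = expression_rpkm
        present = genes3 & set(expr.index)
        sil = set()
        for gid in present:
            row = expr.loc[gid]
            m_unm = float(row[list(unmethylated_lines)].mean())
            m_met = float(row[list(methylated_lines)].mean())
            if (m_unm >= params.rpkm_threshold
                    and m_unm >= params.silencing_fold * max(m_met, 1e-12)):
                sil.add(gid)
        genes3 = sil
    stage3 = stage2[stage2["gene_id"].isin(genes3)]

    regions = stage3.copy()
    return CandidateGeneResult(
        genes=sorted(genes3),
        regions=regions.reset_index(drop=True),
        stage_counts={
            "tss_window": len(genes1),
            "promoter_evidence": len(genes2),
            "silencing": len(genes3),
        },
    )


def anova_differential_expression(rpkm: pd.DataFrame,
                                  groups: Dict[str, Sequence[str]]
                                  ) -> pd.DataFrame:
    """One-way fixed-effects ANOVA on log2(RPKM + 1) across sample groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    log = np.log2(rpkm + 1.0)
    rows = []
    for tid, row in log.iterrows():
        samples = [row[list(cols)].values for cols in groups.values()]
        if all(np.ptp(np.concatenate(samples)) == 0 for _ in [0]):
            f, p = np.nan, 1.0
        else:
            f, p = stats.f_oneway(*samples)
            if np.isnan(p):
                p = 1.0
        rows.append({"transcript_id": tid, "F": float(f), "p_value": float(p)})
    return pd.DataFrame(rows).set_index("transcript_id")
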