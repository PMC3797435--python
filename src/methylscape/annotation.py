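"""CpG-island handling and genomic feature assignment.

Peaks are assigned to one of seven categories — promoter, 5'UTR, exon,
intron, 3'UTR, downstream, or intergenic — by computing the overlap length
with every candidate (gene, category) region and keeping the largest;
overlap length breaks ties between genes and categories (a peak overlapping
300 bp of one gene's promoter and 400 bp of another's intron is intronic).
Exact-length ties fall back to a fixed regulatory-first priority order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, merge_intervals

CATEGORIES = ("promoter", "5'UTR", "exon", "intron", "3'UTR", "downstream")
# tie-break priority when overlap lengths are exactly equal (regulatory first)
_PRIORITY = {
    "promoter": 0, "5'UTR": 1, "exon": 2, "3'UTR": 3, "intron": 4,
    "downstream": 5,
}

PROMOTER_WINDOW = 3000     # bp upstream of the TSS
DOWNSTREAM_WINDOW = 3000   # bp past the TES


@dataclass
class FeatureAssignment:
    peak_id: Optional[str]
    gene_id: Optional[str]
    category: str
    overlap_length: int


def gene_category_regions(gene: GeneModel,
                          promoter_window: int = PROMOTER_WINDOW,
                          downstream_window: int = DOWNSTREAM_WINDOW,
                          ) -> Dict[str, List[Tuple[int, int]]]:
    """Candidate intervals per category for one gene, strand aware.

    The promoter extends ``promoter_window`` bp 5' of the TSS; the
    downstream region extends ``downstream_window`` bp 3' of the TES.
    For transcripts without CDS the exon category covers all exons.
    """
    if gene.strand == "+":
        promoter = [(max(0, gene.tss - promoter_window), gene.tss)]
        downstream = [(gene.tes, gene.tes + downstream_window)]
    else:
        promoter = [(gene.tss, gene.tss + promoter_window)]
        downstream = [(max(0, gene.tes - downstream_window), gene.tes)]
    utr5, utr3 = gene.utr5(), gene.utr3()
    exons = gene.cds if gene.cds else gene.exons
    return {
        "promoter": promoter,
        "5'UTR": utr5,
        "exon": list(exons),
        "intron": gene.introns,
        "3'UTR": utr3,
        "downstream": downstream,
    }


class GeneIndex:
    """Interval index over extended gene spans for fast candidate lookup."""

    def __init__(self, genes: Sequence[GeneModel],
                 promoter_window: int = PROMOTER_WINDOW,
                 downstream_window: int = DOWNSTREAM_WINDOW):
        self.genes = list(genes)
        self.promoter_window = promoter_window
        self.downstream_window = downstream_window
        self._trees: Dict[str, IntervalTree] = {}
        pad = max(promoter_window, downstream_window)
        for g in self.genes:
            t = self._trees.setdefault(g.chrom, IntervalTree())
            t.addi(max(0, g.start - pad), g.end + pad, g)

    def candidates(self, iv: GenomicInterval) -> List[GeneModel]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]


def assign_feature(peak: GenomicInterval, gene_index: GeneIndex
                   ) -> FeatureAssignment:
    """Assign one peak to the (gene, category) with the longest overlap."""
    best: Optional[Tuple[int, int, str, str]] = None
    for g in gene_index.candidates(peak):
        regions = gene_category_regions(
            g, gene_index.promoter_window, gene_index.downstream_window
        )
        for cat, ivs in regions.items():
            ov = sum(
                max(0, min(peak.end, e) - max(peak.start, s)) for s, e in ivs
            )
            if ov <= 0:
                continue
            key = (-ov, _PRIORITY[cat], g.gene_id)
            if best is None or key < (best[0], best[1], best[3]):
                best = (-ov, _PRIORITY[cat], cat, g.gene_id)
    if best is None:
        return FeatureAssignment(peak.name, None, "intergenic", 0)
    return FeatureAssignment(peak.name, best[3], best[2], -best[0])


def assign_features(peaks: Iterable[GenomicInterval],
                    genes: Sequence[GeneModel],
                    promoter_window: int = PROMOTER_WINDOW,
                    downstream_window: int = DOWNSTREAM_WINDOW,
                    ) -> pd.DataFrame:
    """Assign every peak; returns a tidy table (peak_id, gene_id, category,
    overlap_length)."""
    index = GeneIndex(genes, promoter_window, downstream_window)
    rows = []
    for pk in peaks:
        a = assign_feature(pk, index)
        rows.append({"peak_id": a.peak_id, "gene_id": a.gene_id,
                     "category": a.category,
                     "overlap_length": a.overlap_length})
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "category",
                                       "overlap_length"])


# ---------------------------------------------------------------------------
# CpG island set operations
# ---------------------------------------------------------------------------

def union_islands(set_a: Sequence[GenomicInterval],
                  set_b: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Union of two island annotations: overlapping/abutting intervals merge."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in list(set_a) + list(set_b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        for i, (s, e) in enumerate(merge_intervals(by_chrom[chrom])):
            out.append(GenomicInterval(chrom, s, e))
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"union_{i:05d}")
        for i, iv in enumerate(out)
    ]


def island_size_distribution(intervals: Sequence[GenomicInterval],
                             bin_width: int = 25,
                             max_length: int = 1000) -> pd.DataFrame:
    """Normalized length-frequency table of methylated regions.

    Bins of ``bin_width`` bp from 0 to ``max_length`` plus one overflow bin;
    frequencies sum to 1.
    """
    if not intervals:
        raise ValueError("need at least one interval")
    lengths = np.array([iv.length for iv in intervals])
    edges = np.arange(0, max_length + bin_width, bin_width)
    idx = np.minimum(lengths // bin_width, len(edges) - 1)
    counts = np.bincount(idx, minlength=len(edges))
    freq = counts / counts.sum()
    return pd.DataFrame({
        "bin_start": edges,
        "bin_end": np.append(edges[:-1] + bin_width, np.iinfo(np.int64).max),
        "count": counts,
        "frequency": freq,
    })


# ---------------------------------------------------------------------------
# Transcript coding/noncoding classification
# ---------------------------------------------------------------------------

def classify_transcript(
    transcript_length: int,
    longest_orf_nt: int,
    exons: Optional[Sequence[Tuple[str, int, int]]] = None,
    coding_exon_index: Optional[Dict[str, IntervalTree]] = None,
    noncoding_override: bool = False,
) -> str:
    """Classify a transcript as ``coding`` or ``noncoding``.

    Coding if any exon overlaps a known coding exon by >= 1 bp, or if the
    longest ORF exceeds 120 codons and spans more than one third of the
    transcript length.  ``noncoding_override`` (a curated lncRNA registry
    stand-in) forces the noncoding call regardless.
    """
    if transcript_length <= 0:
        raise ValueError("transcript_length must be positive")
    if noncoding_override:
        return "noncoding"
    if exons and coding_exon_index:
        for chrom, s, e in exons:
            tree = coding_exon_index.get(chrom)
            if tree is not None and tree.overlap(s, e):
                return "coding"
    orf_codons = longest_orf_nt // 3
    if orf_codons > 120 and longest_orf_nt > transcript_length / 3:
        return "coding"
    return "noncoding"


def build_coding_exon_index(genes: Sequence[GeneModel]
                            ) -> Dict[str, IntervalTree]:
    """Index of known coding-gene exons (CDS or UTR) for overlap queries."""
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        if not g.cds:
            continue
        t = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            t.addi(s, e)
    return trees


# ---------------------------------------------------------------------------
# Extended-boundary feature association
# ---------------------------------------------------------------------------

def associate_features(
    islands: Sequence[GenomicInterval],
    feature_sets: Dict[str, Sequence[GenomicInterval]],
    extension: int = 200,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> pd.DataFrame:
    """Associate islands with extraneous features after +/-200 bp extension.

    Island *i* associates with feature *f* iff the island extended by
    ``extension`` bp on each side (clamped to chromosome bounds) overlaps
    *f*.  One row per (island, feature type, feature id).
    """
    if extension < 0:
        raise ValueError("extension must be non-negative")
    trees: Dict[str, Dict[str, IntervalTree]] = {}
    for ftype, ivs in feature_sets.items():
        d: Dict[str, IntervalTree] = {}
        for j, iv in enumerate(ivs):
            t = d.setdefault(iv.chrom, IntervalTree())
            t.addi(iv.start, iv.end, iv.name or f"{ftype}_{j}")
        trees[ftype] = d
    rows = []
    for i, isl in enumerate(islands):
        lo = max(0, isl.start - extension)
        hi = isl.end + extension
        if chrom_lengths and isl.chrom in chrom_lengths:
            hi = min(hi, chrom_lengths[isl.chrom])
        iid = isl.name or f"island_{i}"
        for ftype, d in trees.items():
            tree = d.get(isl.chrom)
            if tree is None:
                continue
            for hit in sorted(tree.overlap(lo, hi)):
                rows.append({"island_id": iid, "feature_type": ftype,
                             "feature_id": hit.data})
    return pd.DataFrame(rows, columns=["island_id", "feature_type",
                                       "feature_id"])
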