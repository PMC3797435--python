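"""Set algebra over per-cell-line methylated-region sets.

Region identity across samples uses reciprocal overlap (default >= 50% of
each region); Venn-style membership counts, stage-specific core derivation
(regions shared by a core group and absent from an exclusion group), and
window-based region-to-gene mapping all build on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, merge_intervals

# named window presets for mapping regions to genes
GENE_SPAN_PRESET = {"upstream": 3000, "downstream": 3000, "anchor": "span"}
REGULATORY_PRESET = {"upstream": 2000, "downstream": 1000, "anchor": "tss"}


def _tree_of(intervals: Sequence[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def _reciprocal(a: GenomicInterval, b_start: int, b_end: int,
                min_frac: float) -> bool:
    ov = min(a.end, b_end) - max(a.start, b_start)
    if ov <= 0:
        return False
    return ov >= min_frac * a.length and ov >= min_frac * (b_end - b_start)


def overlap_equivalence(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_frac: float = 0.5,
) -> Tuple[List[Tuple[int, int]], List[int], List[int]]:
    """Match regions of ``a`` against ``b`` by reciprocal overlap.

    ``x in a`` matches ``b`` iff some ``y in b`` overlaps at least
    ``min_frac`` of each.  Returns ``(pairs, unmatched_a, unmatched_b)``
    as index lists into the inputs; a region may appear in several pairs.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must lie in (0, 1]")
    trees = _tree_of(b)
    pairs: List[Tuple[int, int]] = []
    matched_a: Set[int] = set()
    matched_b: Set[int] = set()
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if _reciprocal(iv, hit.begin, hit.end, min_frac):
                pairs.append((i, hit.data))
                matched_a.add(i)
                matched_b.add(hit.data)
    unmatched_a = [i for i in range(len(a)) if i not in matched_a]
    unmatched_b = [j for j in range(len(b)) if j not in matched_b]
    return pairs, unmatched_a, unmatched_b


@dataclass
class PeakSetCollection:
    """Label -> sorted, internally merged interval set (one per cell line)."""

    sets: Dict[str, List[GenomicInterval]]

    def __post_init__(self) -> None:
        clean = {}
        for label, ivs in self.sets.items():
            by_chrom: Dict[str, List[Tuple[int, int]]] = {}
            for iv in ivs:
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            merged = []
            for chrom in sorted(by_chrom):
                for s, e in merge_intervals(by_chrom[chrom],
                                            merge_abutting=False):
                    merged.append(GenomicInterval(chrom, s, e))
            clean[label] = merged
        self.sets = clean

    @property
    def labels(self) -> List[str]:
        return list(self.sets)

    def union_regions(self) -> List[GenomicInterval]:
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for ivs in self.sets.values():
            for iv in ivs:
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        out = []
        for chrom in sorted(by_chrom):
            for s, e in merge_intervals(by_chrom[chrom], merge_abutting=False):
                out.append(GenomicInterval(chrom, s, e))
        return [
            GenomicInterval(iv.chrom, iv.start, iv.end, name=f"u_{i:06d}")
            for i, iv in enumerate(out)
        ]


def venn_counts(collection: PeakSetCollection,
                labels: Optional[Sequence[str]] = None,
                min_frac: float = 0.5) -> Dict[Tuple[bool, ...], int]:
    """Counts of union regions per membership class.

    Every region of the union of all sets receives a membership bit per
    label (matched by reciprocal overlap to that label's regions); counts
    are keyed by the membership tuple and sum to the union size.
    """
    labels = list(labels) if labels is not None else collection.labels
    if not 2 <= len(labels) <= 5:
        raise ValueError("venn_counts supports 2-5 labels")
    union = collection.union_regions()
    membership = []
    for label in labels:
        _, unmatched_u, _ = overlap_equivalence(
            union, collection.sets[label], min_frac
        )
        matched = set(range(len(union))) - set(unmatched_u)
        membership.append(matched)
    counts: Dict[Tuple[bool, ...], int] = {}
    for i in range(len(union)):
        key = tuple(i in m for m in membership)
        counts[key] = counts.get(key, 0) + 1
    return counts


def venn_table(collection: PeakSetCollection,
               labels: Optional[Sequence[str]] = None,
               min_frac: float = 0.5) -> pd.DataFrame:
    """Membership matrix (region x label, 0/1) over union regions."""
    labels = list(labels) if labels is not None else collection.labels
    union = collection.union_regions()
    data = {"region_id": [iv.name for iv in union],
            "chrom": [iv.chrom for iv in union],
            "start": [iv.start for iv in union],
            "end": [iv.end for iv in union]}
    for label in labels:
        _, unmatched_u, _ = overlap_equivalence(
            union, collection.sets[label], min_frac
        )
        unmatched = set(unmatched_u)
        data[label] = [0 if i in unmatched else 1 for i in range(len(union))]
    return pd.DataFrame(data)


def derive_stage_specific(
    collection: PeakSetCollection,
    core_labels: Sequence[str],
    exclude_labels: Sequence[str],
    min_frac: float = 0.5,
) -> List[GenomicInterval]:
    """Regions matched across all core labels and absent from all excludes.

    Mirrors intersecting a shared core of methylated islands with earlier
    stages to isolate the late-stage-specific set.
    """
    if set(core_labels) & set(exclude_labels):
        raise ValueError("core and exclude label sets must be disjoint")
    if not core_labels:
        raise ValueError("need at least one core label")
    result = list(collection.sets[core_labels[0]])
    for label in core_labels[1:]:
        pairs, _, _ = overlap_equivalence(result, collection.sets[label],
                                          min_frac)
        keep = {i for i, _ in pairs}
        result = [iv for i, iv in enumerate(result) if i in keep]
    for label in exclude_labels:
        pairs, _, _ = overlap_equivalence(result, collection.sets[label],
                                          min_frac)
        drop = {i for i, _ in pairs}
        result = [iv for i, iv in enumerate(result) if i not in drop]
    return result


def gene_window(gene: GeneModel, upstream: int, downstream: int,
                anchor: str = "span") -> Tuple[int, int]:
    """Strand-aware window around a gene.

    ``span``: TSS - upstream through TES + downstream (whole gene body);
    ``tss``: upstream/downstream of the TSS only (regulatory region).
    """
    if anchor not in ("span", "tss"):
        raise ValueError("anchor must be 'span' or 'tss'")
    if anchor == "span":
        if gene.strand == "+":
            return max(0, gene.tss - upstream), gene.tes + downstream
        return max(0, gene.tes - downstream), gene.tss + upstream
    if gene.strand == "+":
        return max(0, gene.tss - upstream), gene.tss + downstream
    return max(0, gene.tss - downstream), gene.tss + upstream


def map_regions_to_genes(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    upstream: int = 3000,
    downstream: int = 3000,
    anchor: str = "span",
) -> Tuple[List[str], pd.DataFrame]:
    """Map regions to genes whose window they overlap.

    Returns the deduplicated, sorted gene list and the region -> gene table.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("windows must be non-negative")
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        lo, hi = gene_window(g, upstream, downstream, anchor)
        if hi > lo:
            trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)
    rows = []
    hit_genes: Set[str] = set()
    for i, iv in enumerate(regions):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        rid = iv.name or f"region_{i}"
        for hit in sorted(tree.overlap(iv.start, iv.end)):
            rows.append({"region_id": rid, "gene_id": hit.data})
            hit_genes.add(hit.data)
    table = pd.DataFrame(rows, columns=["region_id", "gene_id"])
    return sorted(hit_genes), table
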