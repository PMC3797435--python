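"""Effective-read normalization, fold change, clustering, repeat enrichment.

Per-region tag counts are normalized into *effective reads* by equating each
cell line's library total to the input-control total; the fold change of a
gene's regulatory region is the ratio of its effective reads to the input
count; rows are normalized to mean 0 / sd 1 and cell lines clustered
hierarchically on 1 - Pearson correlation.  Repeat-class methylation is
operationalized as the in-class tag share of the enriched track versus the
input, scored by both Fisher's exact test and a per-element t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import GenomicInterval, TagTrack


def count_tags_in_regions(track: TagTrack,
                          regions: Sequence[GenomicInterval]) -> np.ndarray:
    """Tags whose 5' start falls inside each region (binary search)."""
    out = np.zeros(len(regions), dtype=np.int64)
    for i, iv in enumerate(regions):
        pos = track.positions.get(iv.chrom)
        if pos is None:
            continue
        out[i] = np.searchsorted(pos, iv.end) - np.searchsorted(pos, iv.start)
    return out


def effective_reads(counts: np.ndarray, sample_total: int,
                    input_total: int) -> np.ndarray:
    """Rescale counts so the sample library total equals the input total."""
    if sample_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be positive")
    return np.asarray(counts, dtype=float) * (input_total / sample_total)


def region_fold_change(effective: pd.DataFrame, input_counts: pd.Series,
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """Fold change = (effective + pc) / (input + pc), per region per line.

    Regions with zero methylation signal (zero counts) in every cell line
    are excluded first.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    keep = (effective > 0).any(axis=1)
    eff = effective.loc[keep]
    inp = input_counts.loc[keep]
    return (eff + pseudocount).div(inp + pseudocount, axis=0)


def normalize_rows(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Row-wise standardization to mean 0, sd 1 (sample sd by default).

    Constant rows cannot be standardized and are dropped with a warning.
    """
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant row(s) before "
            "row normalization",
            stacklevel=2,
        )
        matrix = matrix.loc[~constant]
        mean = mean.loc[~constant]
        sd = sd.loc[~constant]
    return matrix.sub(mean, axis=0).div(sd, axis=0)


def pearson_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between columns."""
    corr = matrix.corr(method="pearson")
    return 1.0 - corr


def cluster_cell_lines(matrix: pd.DataFrame, method: str = "average"
                       ) -> Tuple[np.ndarray, List[str]]:
    """Hierarchical clustering of columns on 1 - Pearson distance.

    Returns the scipy linkage matrix and the column labels in input order.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns to cluster")
    if (matrix.std(axis=0, ddof=0) == 0).any():
        raise ValueError("every column must have nonzero variance")
    if method not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage method {method!r}")
    dist = pearson_distance_matrix(matrix)
    condensed = squareform(np.clip(dist.values, 0, None), checks=False)
    linkage = hierarchy.linkage(condensed, method=method)
    return linkage, list(matrix.columns)


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch heights."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = max(0.0, parent_height - node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def top_split(linkage: np.ndarray, labels: Sequence[str]
              ) -> Tuple[frozenset, frozenset]:
    """The two label groups separated by the root of the dendrogram."""
    tree = hierarchy.to_tree(linkage)

    def leaves(node) -> frozenset:
        return frozenset(labels[i] for i in node.pre_order())

    return leaves(tree.left), leaves(tree.right)


# ---------------------------------------------------------------------------
# Repeat-class enrichment
# ---------------------------------------------------------------------------

@dataclass
class RepeatEnrichmentResult:
    repeat_class: str
    cell_line: str
    observed_share: float      # in-class tag share in the enriched track
    expected_share: float      # in-class tag share in the input track
    direction: str             # "hyper" | "hypo" | "none"
    p_fisher: float
    p_ttest: float


def repeat_enrichment(
    enriched_tracks: Dict[str, TagTrack],
    input_track: TagTrack,
    repeats_by_class: Dict[str, List[GenomicInterval]],
) -> List[RepeatEnrichmentResult]:
    """Per (repeat class, cell line) enrichment of tags versus input.

    The 2x2 table [in-class vs out-of-class tags] x [enriched vs input]
    gives a two-sided Fisher exact p; per-element library-normalized tag
    densities give a two-sample t-test p; direction is the sign of the
    observed minus expected in-class share.
    """
    if not repeats_by_class:
        raise ValueError("need at least one repeat class")
    input_total = input_track.count()
    if input_total == 0:
        raise ValueError("input track is empty")
    results: List[RepeatEnrichmentResult] = []
    input_counts = {
        cls: count_tags_in_regions(input_track, ivs)
        for cls, ivs in repeats_by_class.items()
    }
    for line in sorted(enriched_tracks):
        track = enriched_tracks[line]
        total = track.count()
        if total == 0:
            raise ValueError(f"enriched track for {line!r} is empty")
        for cls, ivs in repeats_by_class.items():
            enr = count_tags_in_regions(track, ivs)
            inp = input_counts[cls]
            a, c = int(enr.sum()), int(inp.sum())
            b, d = total - a, input_total - c
            _, p_fisher = stats.fisher_exact([[a, b], [c, d]],
                                             alternative="two-sided")
            lens = np.array([iv.length for iv in ivs], dtype=float)
            dens_enr = enr / lens / total
            dens_inp = inp / lens / input_total
            if np.allclose(dens_enr, dens_inp):
                p_t = 1.0
            else:
                _, p_t = stats.ttest_ind(dens_enr, dens_inp, equal_var=False)
                p_t = float(np.nan_to_num(p_t, nan=1.0))
            obs, exp = a / total, c / input_total
            if obs > exp:
                direction = "hyper"
            elif obs < exp:
                direction = "hypo"
            else:
                direction = "none"
            results.append(RepeatEnrichmentResult(
                repeat_class=cls, cell_line=line,
                observed_share=obs, expected_share=exp,
                direction=direction, p_fisher=float(p_fisher),
                p_ttest=float(p_t),
            ))
    return results


def repeat_enrichment_table(results: List[RepeatEnrichmentResult]
                            ) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
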