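"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately avoid the library's interval indexes
and vectorized paths: they enumerate all pairs or all bases so that tests
compare two independent routes to the same answer.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from methylscape.annotation import gene_category_regions, _PRIORITY
from methylscape.core import GeneModel, GenomicInterval
from methylscape.synthetic import (DEFAULT_STAGE_PROFILE,
                                   SyntheticGenomeConfig,
                                   assign_methylation_states, generate_genome)


@pytest.fixture(scope="session")
def small_config() -> SyntheticGenomeConfig:
    return SyntheticGenomeConfig(
        n_chroms=2, chrom_length=500_000, n_genes=60, n_islands=300,
        n_repeats_per_class=8, seed=7,
    )


@pytest.fixture(scope="session")
def small_annotations(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_annotations):
    return assign_methylation_states(small_annotations,
                                     DEFAULT_STAGE_PROFILE, seed=7)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def overlap_bp(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(b[0], a[0]))


def brute_force_assignment(peak: GenomicInterval,
                           genes: Sequence[GeneModel],
                           promoter_window: int = 3000,
                           downstream_window: int = 3000):
    """Exhaustive (gene, category) overlap scan with the same tie rule."""
    best = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        for cat, ivs in gene_category_regions(
                g, promoter_window, downstream_window).items():
            ov = sum(overlap_bp((peak.start, peak.end), iv) for iv in ivs)
            if ov <= 0:
                continue
            key = (-ov, _PRIORITY[cat], g.gene_id)
            if best is None or key < best[0]:
                best = (key, cat, g.gene_id, ov)
    if best is None:
        return ("intergenic", None, 0)
    return (best[1], best[2], best[3])


def brute_force_associations(islands, feature_sets, extension):
    """All-pairs overlap check after island extension."""
    rows = set()
    for isl in islands:
        lo, hi = max(0, isl.start - extension), isl.end + extension
        for ftype, ivs in feature_sets.items():
            for f in ivs:
                if f.chrom == isl.chrom and f.start < hi and f.end > lo:
                    rows.add((isl.name, ftype, f.name))
    return rows


def brute_force_reciprocal_pairs(a, b, min_frac):
    pairs = set()
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom != y.chrom:
                continue
            ov = overlap_bp((x.start, x.end), (y.start, y.end))
            if ov > 0 and ov >= min_frac * x.length and ov >= min_frac * y.length:
                pairs.add((i, j))
    return pairs


def brute_force_gene_mapping(regions, genes, upstream, downstream, anchor):
    from methylscape.signatures import gene_window

    rows = set()
    for i, r in enumerate(regions):
        rid = r.name or f"region_{i}"
        for g in genes:
            if g.chrom != r.chrom:
                continue
            lo, hi = gene_window(g, upstream, downstream, anchor)
            if r.start < hi and r.end > lo:
                rows.add((rid, g.gene_id))
    return rows


def poisson_tail_series(k: int, lam: float, terms: int = 400) -> float:
    """Exact upper-tail sum P(X >= k) = 1 - sum_{i<k} e^-lam lam^i / i!.

    Accumulated in float via the complementary lower sum with recursive
    term update; independent of scipy.
    """
    if k == 0:
        return 1.0
    # lower tail
    import math

    log_term = -lam            # log of e^-lam * lam^0 / 0!
    total_low = math.exp(log_term)
    for i in range(1, k):
        log_term += math.log(lam) - math.log(i)
        total_low += math.exp(log_term)
    if total_low < 0.5:
        return 1.0 - total_low
    # small upper tails: sum forward from k
    log_t = -lam + k * math.log(lam) - math.lgamma(k + 1)
    term = math.exp(log_t)
    total = 0.0
    for i in range(k, k + terms):
        total += term
        term *= lam / (i + 1)
    return total


def random_intervals(rng: np.random.Generator, n: int, chrom: str,
                     span: int, max_len: int = 800) -> List[GenomicInterval]:
    starts = rng.integers(0, span - max_len, size=n)
    lengths = rng.integers(50, max_len, size=n)
    return [
        GenomicInterval(chrom, int(s), int(s + l), name=f"iv_{i:04d}")
        for i, (s, l) in enumerate(zip(starts, lengths))
    ]
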