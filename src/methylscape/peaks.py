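"""Windowed Poisson enrichment calling against an input control.

A simplified re-statement of Poisson-model peak calling for
methylation-enrichment (MBD2 pull-down) data: the genome is tiled into
fixed windows, the expected tag count of each window is the library-size
scaled input count (floored at the genome-wide background rate), and a
window/region is called when the upper Poisson tail probability of its
observed count falls below the cutoff (default 1e-10).

Candidate windows are seeded at a looser internal threshold (``seed_p``)
and merged across gaps of up to ``merge_gap`` bp; the final cutoff is then
applied to the merged region's summed counts against its summed expectation,
so that an island spread over several windows is scored as one region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy import stats

from .core import GenomicInterval, TagTrack
from .io import bed_score_from_pvalue


@dataclass
class CoverageTrack:
    """Per-chromosome tag counts on a fixed window grid."""

    window_size: int
    counts: Dict[str, np.ndarray]
    library_size: int

    @property
    def n_windows(self) -> int:
        return int(sum(c.size for c in self.counts.values()))

    def total(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))


@dataclass
class Peak:
    """An enriched region with its Poisson evidence."""

    interval: GenomicInterval
    tag_count: int
    expected_count: float
    p_value: float

    @property
    def fold_enrichment(self) -> float:
        return self.tag_count / self.expected_count

    @property
    def bed_score(self) -> float:
        return bed_score_from_pvalue(self.p_value)


def build_coverage(tags: TagTrack, window_size: int,
                   chrom_lengths: Optional[Dict[str, int]] = None
                   ) -> CoverageTrack:
    """Count tag 5' starts per window; the last partial window is kept."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    counts: Dict[str, np.ndarray] = {}
    chroms = set(tags.positions)
    if chrom_lengths:
        chroms |= set(chrom_lengths)
    for chrom in sorted(chroms):
        pos = tags.positions.get(chrom, np.empty(0, dtype=np.int64))
        if chrom_lengths and chrom in chrom_lengths:
            n_win = max(1, -(-chrom_lengths[chrom] // window_size))
        else:
            n_win = int(pos.max() // window_size) + 1 if pos.size else 1
        counts[chrom] = np.bincount(
            (pos // window_size).astype(np.int64), minlength=n_win
        ).astype(np.int64)
    return CoverageTrack(window_size=window_size, counts=counts,
                         library_size=tags.library_size)


def poisson_tail_pvalue(k: int, lam: float) -> float:
    """Upper-tail probability ``P(X >= k)`` for ``X ~ Poisson(lam)``.

    Computed through the survival function, which is stable for the very
    small tails the 1e-10 cutoff requires.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def _smooth_counts(counts: np.ndarray, half_width: int) -> np.ndarray:
    """Centered moving average with edge-aware normalization."""
    half_width = min(half_width, (counts.size - 1) // 2)
    if half_width <= 0 or counts.size <= 1:
        return counts.astype(float)
    kernel = np.ones(2 * half_width + 1)
    sums = np.convolve(counts, kernel, mode="same")
    norm = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    return sums / norm


def call_peaks(
    sample: CoverageTrack,
    control: CoverageTrack,
    p_cutoff: float = 1.0e-10,
    merge_gap: int = 100,
    seed_p: float = 5.0e-2,
    lambda_floor: Optional[float] = None,
    control_smoothing: int = 5000,
) -> List[Peak]:
    """Call enriched regions in ``sample`` against the ``control`` input.

    Per window, the Poisson expectation is
    ``max(local control rate * sample_lib / control_lib, lambda_floor)``.
    The local control rate is the control count averaged over a centered
    ``control_smoothing`` bp span (default 5 kb) — a single window of input
    carries too few tags to estimate the background stably — and
    ``lambda_floor`` defaults to the sample's genome-wide mean window count,
    preventing zero-expectation artifacts where the input is sparse.
    Windows significant at ``seed_p`` are merged when separated by at most
    ``merge_gap`` bp (interior gap windows are absorbed into the region),
    and a merged region is reported when the tail probability of its summed
    count against its summed expectation is below ``p_cutoff``.
    """
    if sample.window_size != control.window_size:
        raise ValueError("sample and control must share the window grid")
    if control.library_size <= 0:
        raise ValueError("control track has zero library size")
    if not (0 < p_cutoff <= 1):
        raise ValueError("p_cutoff must lie in (0, 1]")
    seed_p = max(seed_p, p_cutoff)
    w = sample.window_size
    scale = sample.library_size / control.library_size
    if lambda_floor is None:
        n_windows = sample.n_windows
        lambda_floor = sample.library_size / n_windows if n_windows else 1.0
    lambda_floor = max(lambda_floor, 1e-9)
    gap_windows = merge_gap // w
    half_width = max(0, control_smoothing // (2 * w))

    peaks: List[Peak] = []
    for chrom in sorted(sample.counts):
        k = sample.counts[chrom].astype(np.int64)
        c = control.counts.get(chrom)
        if c is None or c.size != k.size:
            cc = np.zeros_like(k, dtype=float)
            if c is not None:
                cc[: min(c.size, k.size)] = c[: min(c.size, k.size)]
        else:
            cc = c.astype(float)
        lam = np.maximum(_smooth_counts(cc, half_width) * scale, lambda_floor)
        pvals = stats.poisson.sf(k - 1, lam)
        pvals[k == 0] = 1.0
        sig = np.flatnonzero(pvals < seed_p)
        if sig.size == 0:
            continue
        # group seed windows whose gap is <= gap_windows
        breaks = np.flatnonzero(np.diff(sig) > gap_windows + 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [sig.size - 1]))
        for si, ei in zip(starts, ends):
            w0, w1 = int(sig[si]), int(sig[ei])        # inclusive window span
            total_k = int(k[w0: w1 + 1].sum())
            total_lam = float(lam[w0: w1 + 1].sum())
            p = poisson_tail_pvalue(total_k, total_lam)
            if p < p_cutoff:
                peaks.append(
                    Peak(
                        interval=GenomicInterval(
                            chrom, w0 * w, (w1 + 1) * w,
                            name=f"peak_{len(peaks):05d}",
                        ),
                        tag_count=total_k,
                        expected_count=total_lam,
                        p_value=p,
                    )
                )
    return peaks


def write_peaks_bed(peaks: List[Peak], path: str) -> None:
    """BED6 with the p-value as ``-10*log10(p)`` in the score column."""
    with open(path, "w") as fh:
        fh.write('track name="methylscape_peaks"\n')
        for pk in peaks:
            fh.write(
                f"{pk.interval.chrom}\t{pk.interval.start}\t{pk.interval.end}\t"
                f"{pk.interval.name}\t{pk.bed_score:.4g}\t.\n"
            )


def read_peaks_bed(path: str) -> List[GenomicInterval]:
    from .io import read_bed

    return read_bed(path)


def write_coverage_wiggle(coverage: CoverageTrack, path: str,
                          name: str = "coverage") -> None:
    from .io import write_wiggle

    write_wiggle(coverage.counts, coverage.window_size, path, name=name)
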