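"""Simple visual summaries (per-chromosome peak density, island sizes)."""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .core import GenomicInterval  # noqa: E402


def plot_chromosome_density(intervals: Sequence[GenomicInterval],
                            chrom_lengths: Dict[str, int],
                            path: str, bin_size: int = 100_000,
                            title: str = "methylated region density") -> None:
    """Per-chromosome density of methylated regions (one panel per chrom)."""
    chroms = sorted(chrom_lengths)
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 1.6 * len(chroms)),
                             sharex=True, squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        L = chrom_lengths[chrom]
        edges = np.arange(0, L + bin_size, bin_size)
        mids = [iv.start for iv in intervals if iv.chrom == chrom]
        ax.hist(mids, bins=edges, color="#8c2d5c")
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
    axes.ravel()[0].set_title(title)
    axes.ravel()[-1].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_island_size_distribution(frequency_table, path: str) -> None:
    """Bar plot of the normalized methylated-region length distribution."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    t = frequency_table[frequency_table["count"] > 0]
    ax.bar(t["bin_start"], t["frequency"],
           width=(t["bin_start"].iloc[1] - t["bin_start"].iloc[0])
           if len(t) > 1 else 25, align="edge", color="#2d5c8c")
    ax.set_xlabel("region length (bp)")
    ax.set_ylabel("frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
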