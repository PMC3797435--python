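"""Core coordinate types shared by every pipeline stage.

All intervals are 0-based half-open ``[start, end)`` internally, matching the
BED convention used on disk.  Strand is ``"+"``, ``"-"`` or ``None``
(unstranded features such as CpG islands).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, the universal coordinate currency."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """Transcript structure from which feature windows derive.

    ``tss``/``tes`` are transcription start/end in genomic coordinates:
    for a ``-`` strand gene ``tss > tes``.  ``exons`` and ``cds`` are sorted,
    non-overlapping half-open interval lists in genomic orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: List[Interval]
    cds: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have >=1 exon")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.cds = sorted(self.cds)
        for s, e in self.cds:
            if not any(s >= xs and e <= xe for xs, xe in self.exons):
                raise ValueError(f"{self.gene_id}: CDS not contained in exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site (genomic coordinate of the 5' end)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcription end site (genomic coordinate of the 3' end)."""
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> List[Interval]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    def utr5(self) -> List[Interval]:
        """5' UTR: exonic sequence upstream (5') of the CDS."""
        return self._utr(five_prime=True)

    def utr3(self) -> List[Interval]:
        """3' UTR: exonic sequence downstream (3') of the CDS."""
        return self._utr(five_prime=False)

    def _utr(self, five_prime: bool) -> List[Interval]:
        if not self.cds:
            return []
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        # genomic-left UTR is 5' on + strand, 3' on - strand
        want_left = five_prime == (self.strand == "+")
        out: List[Interval] = []
        for s, e in self.exons:
            if want_left:
                if s < cds_lo:
                    out.append((s, min(e, cds_lo)))
            else:
                if e > cds_hi:
                    out.append((max(s, cds_hi), e))
        return out


@dataclass
class TagTrack:
    """Per-chromosome sorted mapped-tag 5' start positions.

    Stands in for the uniquely-mapped sequencing reads of an enriched
    (MBD2 pull-down) or input (non-enriched) library.
    """

    positions: Dict[str, np.ndarray]
    strands: Dict[str, np.ndarray] = field(default_factory=dict)
    library_size: int = 0

    def __post_init__(self) -> None:
        total = 0
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) < 0):
                pos = np.sort(pos)
            if pos.size and pos[0] < 0:
                raise ValueError(f"negative tag position on {chrom}")
            self.positions[chrom] = pos
            total += pos.size
        if self.library_size == 0:
            self.library_size = total
        elif self.library_size != total:
            raise ValueError(
                f"library_size {self.library_size} != total tags {total}"
            )

    @property
    def chroms(self) -> List[str]:
        return sorted(self.positions)

    def count(self) -> int:
        return int(sum(p.size for p in self.positions.values()))


def pool_tracks(*tracks: TagTrack) -> TagTrack:
    """Pool technical replicates by concatenating their tags.

    Mirrors the pooling of replicate sequencing runs before enrichment
    calling ("greater coverage").
    """
    if not tracks:
        raise ValueError("need at least one track to pool")
    chroms = sorted({c for t in tracks for c in t.positions})
    positions = {}
    strands = {}
    have_strands = all(t.strands for t in tracks)
    for c in chroms:
        parts = [t.positions.get(c, np.empty(0, dtype=np.int64)) for t in tracks]
        cat = np.concatenate(parts)
        order = np.argsort(cat, kind="stable")
        positions[c] = cat[order]
        if have_strands:
            scat = np.concatenate(
                [t.strands.get(c, np.empty(0, dtype="U1")) for t in tracks]
            )
            strands[c] = scat[order]
    return TagTrack(positions=positions, strands=strands)


def merge_intervals(
    intervals: Sequence[Interval], merge_abutting: bool = True
) -> List[Interval]:
    """Merge overlapping (and, by default, abutting) half-open intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s < out[-1][1] or (merge_abutting and s == out[-1][1]):
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
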