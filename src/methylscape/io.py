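"""Readers and writers for the plain-text formats the pipeline exchanges.

BED files are 0-based half-open; GTF is 1-based closed.  Gene models travel
as BED12 (primary) or GTF, auto-detected by file extension.  Malformed lines
raise :class:`FormatError` naming the file and line number.
"""

from __future__ import annotations

import math
import os
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .core import GeneModel, GenomicInterval, TagTrack


class FormatError(ValueError):
    """A parse failure that names the offending file and line."""

    def __init__(self, path: str, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


# ---------------------------------------------------------------------------
# BED6 intervals
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[GenomicInterval], path: str,
              scores: Optional[Sequence[float]] = None) -> None:
    scores = list(scores) if scores is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = 0 if scores is None else scores[i]
            name = iv.name if iv.name is not None else f"region_{i}"
            strand = iv.strand if iv.strand is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n"
            )


def read_bed(path: str) -> List[GenomicInterval]:
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(path, lineno, "expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(path, lineno, f"bad coordinates: {exc}") from None
            if start < 0 or end < start:
                raise FormatError(path, lineno, f"invalid interval {start}-{end}")
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            out.append(GenomicInterval(fields[0], start, end, name=name, strand=strand))
    return out


# ---------------------------------------------------------------------------
# Tags as BED6 (one record per mapped tag start)
# ---------------------------------------------------------------------------

def write_tags_bed(track: TagTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            pos = track.positions[chrom]
            strands = track.strands.get(chrom)
            for i, p in enumerate(pos):
                s = strands[i] if strands is not None else "+"
                fh.write(f"{chrom}\t{p}\t{p + 1}\ttag\t0\t{s}\n")


def read_tags_bed(path: str) -> TagTrack:
    positions: Dict[str, list] = {}
    strands: Dict[str, list] = {}
    for iv in read_bed(path):
        positions.setdefault(iv.chrom, []).append(iv.start)
        strands.setdefault(iv.chrom, []).append(iv.strand or "+")
    pos_arrays, strand_arrays = {}, {}
    for chrom, pos in positions.items():
        order = np.argsort(pos, kind="stable")
        pos_arrays[chrom] = np.asarray(pos, dtype=np.int64)[order]
        strand_arrays[chrom] = np.asarray(strands[chrom], dtype="U1")[order]
    return TagTrack(positions=pos_arrays, strands=strand_arrays)


# ---------------------------------------------------------------------------
# Gene models: BED12 and GTF
# ---------------------------------------------------------------------------

def write_genes_bed12(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            block_sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            block_starts = ",".join(str(s - g.start) for s, _ in g.exons) + ","
            thick_start = g.cds[0][0] if g.cds else g.start
            thick_end = g.cds[-1][1] if g.cds else g.start
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(g.exons)}\t"
                f"{block_sizes}\t{block_starts}\n"
            )


def read_genes_bed12(path: str) -> List[GeneModel]:
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(path, lineno, "expected 12 BED12 columns")
            try:
                chrom, start = f[0], int(f[1])
                strand = f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(path, lineno, f"bad BED12 fields: {exc}") from None
            exons = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            cds = []
            if thick_end > thick_start:
                for s, e in exons:
                    cs, ce = max(s, thick_start), min(e, thick_end)
                    if ce > cs:
                        cds.append((cs, ce))
            genes.append(GeneModel(f[3], chrom, strand, exons=exons, cds=cds))
    return genes


def write_genes_gtf(genes: Iterable[GeneModel], path: str,
                    source: str = "methylscape") -> None:
    """Write exon/CDS records, 1-based closed coordinates."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            for s, e in g.exons:
                fh.write(f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")
            for s, e in g.cds:
                fh.write(f"{g.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")


def read_genes_gtf(path: str) -> List[GeneModel]:
    exons: Dict[str, list] = {}
    cds: Dict[str, list] = {}
    meta: Dict[str, tuple] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(path, lineno, "expected 9 GTF columns")
            feature = f[2]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start, end = int(f[3]) - 1, int(f[4])  # to 0-based half-open
            except ValueError as exc:
                raise FormatError(path, lineno, f"bad coordinates: {exc}") from None
            gid = None
            for token in f[8].split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    gid = token.split(None, 1)[1].strip('"')
            if gid is None:
                raise FormatError(path, lineno, "missing gene_id attribute")
            meta[gid] = (f[0], f[6])
            (exons if feature == "exon" else cds).setdefault(gid, []).append(
                (start, end)
            )
    genes = []
    for gid, (chrom, strand) in meta.items():
        genes.append(GeneModel(gid, chrom, strand,
                               exons=exons.get(gid, []), cds=cds.get(gid, [])))
    return genes


def read_genes(path: str) -> List[GeneModel]:
    """Auto-detect gene-model format by extension (.bed -> BED12, else GTF)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".bed", ".bed12"):
        return read_genes_bed12(path)
    if ext in (".gtf", ".gff"):
        return read_genes_gtf(path)
    raise ValueError(f"cannot infer gene-model format from extension: {path}")


# ---------------------------------------------------------------------------
# Wiggle
# ---------------------------------------------------------------------------

def write_wiggle(coverage: Dict[str, np.ndarray], window_size: int, path: str,
                 name: str = "coverage") -> None:
    """fixedStep wiggle: one value per window per chromosome."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in sorted(coverage):
            fh.write(
                f"fixedStep chrom={chrom} start=1 step={window_size} "
                f"span={window_size}\n"
            )
            for v in coverage[chrom]:
                fh.write(f"{v:g}\n")


def bed_score_from_pvalue(p: float, cap: float = 1000.0) -> float:
    """BED score transform -10*log10(p), capped (p=1e-10 -> 100)."""
    if p <= 0:
        return cap
    return min(cap, -10.0 * math.log10(p))
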