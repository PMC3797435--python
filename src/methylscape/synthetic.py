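"""Synthetic genome, methylation truth, tag-track and expression simulator.

The simulator emulates the inputs of an MBD2 pull-down methylome study of
melanoma progression: a small multi-chromosome genome with gene models, CpG
islands drawn from a bimodal length mixture (modes near 275 and 450 bp),
14 repeat-element classes, stage-dependent per-interval methylation states
(melanocyte -> stage-I hypomethylation -> stage-III/IV hypermethylation of
short islands; repeat-class hypomethylation in late stages with three classes
moving the opposite way), Poisson-sampled enriched/input tag tracks, and
expression counts anti-correlated with promoter methylation.

Every generator is a pure function of ``(config, seed)``; randomness flows
from :func:`numpy.random.default_rng` seeded with explicit substreams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, TagTrack, pool_tracks

# 14 repeat-element classes tracked by the analysis (RepeatMasker-style).
DEFAULT_REPEAT_CLASSES: Tuple[str, ...] = (
    "LINE1", "LINE2", "SINE_Alu", "SINE_MIR",
    "LTR_ERV1", "LTR_ERVL", "LTR_ERVK", "LTR_MaLR",
    "DNA_hAT", "DNA_TcMar", "Simple_repeat", "Low_complexity",
    "Satellite", "rRNA",
)

# Classes hypermethylated (rather than hypomethylated) in late-stage lines.
HYPER_REPEAT_CLASSES: Tuple[str, ...] = ("Simple_repeat", "LINE1", "SINE_Alu")

STAGES = ("melanocyte", "I", "III", "IV")
_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

# Five study cell lines and their stages.
DEFAULT_STAGE_PROFILE: Dict[str, str] = {
    "HEM": "melanocyte",
    "WM793B": "I",
    "WM1552C": "III",
    "A375": "IV",
    "SKMEL2": "IV",
}


class PlacementError(RuntimeError):
    """Raised when intervals cannot be placed without overlap."""


@dataclass
class SyntheticGenomeConfig:
    """Parameters of the toy genome.

    Defaults give 4 chromosomes x 2 Mb, 400 genes and 2000 CpG islands —
    large enough for stable statistics, small enough to generate in seconds.
    """

    n_chroms: int = 4
    chrom_length: int = 2_000_000
    n_genes: int = 400
    n_islands: int = 2000
    island_length_modes: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (275.0, 40.0),
        (450.0, 40.0),
    )
    mode_weights: Tuple[float, float] = (0.5, 0.5)
    n_repeats_per_class: int = 40
    repeat_classes: Tuple[str, ...] = DEFAULT_REPEAT_CLASSES
    p_promoter_island: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("n_chroms and chrom_length must be positive")
        if self.n_genes < 0 or self.n_islands < 0 or self.n_repeats_per_class < 0:
            raise ValueError("counts must be non-negative")
        if len(self.island_length_modes) != 2:
            raise ValueError("island_length_modes must be two (mean, sd) pairs")
        for mean, sd in self.island_length_modes:
            if mean <= 0 or sd < 0:
                raise ValueError("island length mode means must be positive")
        if len(self.repeat_classes) != 14:
            raise ValueError("exactly 14 repeat classes are required")
        if not 0.0 <= self.p_promoter_island <= 1.0:
            raise ValueError("p_promoter_island must lie in [0, 1]")
        w = sum(self.mode_weights)
        if w <= 0:
            raise ValueError("mode weights must sum to a positive value")
        self.mode_weights = tuple(x / w for x in self.mode_weights)


@dataclass
class GenomeAnnotations:
    """Gene models, CpG islands and repeat intervals on the toy genome."""

    chrom_lengths: Dict[str, int]
    genes: List[GeneModel]
    islands: List[GenomicInterval]
    repeats: List[GenomicInterval]

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_lengths.values())

    def truth_intervals(self) -> List[GenomicInterval]:
        """All intervals that carry a methylation state (islands + repeats)."""
        return list(self.islands) + list(self.repeats)


def repeat_class_of(iv: GenomicInterval) -> str:
    """Repeat class encoded in the BED name field (``CLASS|id``)."""
    return (iv.name or "").split("|")[0]


@dataclass
class MethylationTruth:
    """Ground-truth methylation level per (cell line, interval).

    Levels are continuous in [0, 1]; downstream truth-recovery checks
    threshold them.  Used only for validation, never by the analysis.
    """

    state: Dict[Tuple[str, str], float]
    stage_profile: Dict[str, str]

    def level(self, cell_line: str, interval_id: str) -> float:
        return self.state[(cell_line, interval_id)]

    def levels_for(self, cell_line: str) -> Dict[str, float]:
        return {
            iid: lv for (line, iid), lv in self.state.items() if line == cell_line
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cell_line": line, "interval_id": iid, "level": lv,
             "stage": self.stage_profile[line]}
            for (line, iid), lv in sorted(self.state.items())
        ]
        return pd.DataFrame(rows, columns=["cell_line", "interval_id", "level",
                                           "stage"])

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def read(cls, path: str) -> "MethylationTruth":
        df = pd.read_csv(path, sep="\t")
        state = {
            (r.cell_line, r.interval_id): float(r.level)
            for r in df.itertuples()
        }
        profile = dict(df[["cell_line", "stage"]].drop_duplicates().values)
        return cls(state=state, stage_profile=profile)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _place_genes(rng: np.random.Generator, cfg: SyntheticGenomeConfig,
                 chroms: List[str]) -> List[GeneModel]:
    """Non-overlapping gene bodies via stick-breaking of the free space."""
    genes: List[GeneModel] = []
    per_chrom = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
    per_chrom[: cfg.n_genes % cfg.n_chroms] += 1
    gidx = 0
    margin = 5000   # keep promoter/downstream windows on-chromosome
    min_gap = 500
    for ci, chrom in enumerate(chroms):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        lengths = rng.integers(3000, 12000, size=n)
        usable = cfg.chrom_length - 2 * margin
        free = usable - int(lengths.sum()) - (n + 1) * min_gap
        if free < 0:
            raise PlacementError(
                f"cannot place {n} genes on {chrom}: genome too small"
            )
        gaps = rng.dirichlet(np.ones(n + 1)) * free
        pos = margin
        for i in range(n):
            pos += int(gaps[i]) + min_gap
            start, glen = pos, int(lengths[i])
            pos += glen
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _make_exons(rng, start, glen)
            cds = _make_cds(rng, exons)
            genes.append(GeneModel(f"gene_{gidx:04d}", chrom, strand,
                                   exons=exons, cds=cds))
            gidx += 1
    return genes


def _make_exons(rng: np.random.Generator, start: int, glen: int
                ) -> List[Tuple[int, int]]:
    n_exons = int(rng.integers(1, 6))
    n_seg = 2 * n_exons - 1
    # alternating exon/intron segments with minimum sizes
    mins = np.array([150 if i % 2 == 0 else 300 for i in range(n_seg)])
    while mins.sum() > glen:
        n_exons = max(1, n_exons - 1)
        n_seg = 2 * n_exons - 1
        mins = np.array([150 if i % 2 == 0 else 300 for i in range(n_seg)])
    extra = rng.dirichlet(np.ones(n_seg)) * (glen - mins.sum())
    sizes = mins + extra.astype(int)
    sizes[-1] += glen - sizes.sum()   # exact total
    exons, pos = [], start
    for i, sz in enumerate(sizes):
        if i % 2 == 0:
            exons.append((pos, pos + int(sz)))
        pos += int(sz)
    return exons


def _make_cds(rng: np.random.Generator, exons: List[Tuple[int, int]]
              ) -> List[Tuple[int, int]]:
    if rng.random() < 0.1:      # 10% of transcripts are noncoding
        return []
    first_s, first_e = exons[0]
    last_s, last_e = exons[-1]
    thick_start = first_s + int(rng.integers(0, max(1, (first_e - first_s) // 2)))
    thick_end = last_e - int(rng.integers(0, max(1, (last_e - last_s) // 2)))
    if thick_end <= thick_start:
        thick_start, thick_end = first_s, last_e
    cds = []
    for s, e in exons:
        cs, ce = max(s, thick_start), min(e, thick_end)
        if ce > cs:
            cds.append((cs, ce))
    return cds


def _sample_island_length(rng: np.random.Generator,
                          cfg: SyntheticGenomeConfig) -> int:
    mode = 0 if rng.random() < cfg.mode_weights[0] else 1
    mean, sd = cfg.island_length_modes[mode]
    return max(60, int(round(rng.normal(mean, sd))))


def _place_nonoverlapping(rng: np.random.Generator, occupied: IntervalTree,
                          chrom_length: int, length: int,
                          max_tries: int = 100) -> int:
    for _ in range(max_tries):
        start = int(rng.integers(0, max(1, chrom_length - length)))
        if not occupied.overlap(start, start + length):
            occupied.addi(start, start + length)
            return start
    raise PlacementError(
        f"could not place a {length} bp interval after {max_tries} tries"
    )


def generate_genome(config: SyntheticGenomeConfig) -> GenomeAnnotations:
    """Generate gene models, CpG islands and repeat intervals.

    Gene bodies never overlap; each gene carries a TSS-proximal CpG island
    with probability ``p_promoter_island``; island lengths come from the
    two-component normal mixture; repeats are placed uniformly avoiding
    exons and islands.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_lengths = {c: config.chrom_length for c in chroms}
    genes = _place_genes(rng, config, chroms)

    occupied: Dict[str, IntervalTree] = {c: IntervalTree() for c in chroms}
    islands: List[GenomicInterval] = []
    iid = 0

    # promoter-proximal islands first, centred on the TSS
    for g in genes:
        if len(islands) >= config.n_islands:
            break
        if rng.random() >= config.p_promoter_island:
            continue
        length = _sample_island_length(rng, config)
        start = max(0, g.tss - length // 2)
        end = min(config.chrom_length, start + length)
        if occupied[g.chrom].overlap(start, end):
            continue
        occupied[g.chrom].addi(start, end)
        islands.append(GenomicInterval(g.chrom, start, end,
                                       name=f"island_{iid:05d}"))
        iid += 1

    # remaining islands anywhere, non-overlapping
    while len(islands) < config.n_islands:
        chrom = chroms[int(rng.integers(0, config.n_chroms))]
        length = _sample_island_length(rng, config)
        start = _place_nonoverlapping(rng, occupied[chrom],
                                      config.chrom_length, length)
        islands.append(GenomicInterval(chrom, start, start + length,
                                       name=f"island_{iid:05d}"))
        iid += 1

    # repeats avoid exons and islands so truth intervals stay disjoint
    blocked = {c: IntervalTree(t) for c, t in occupied.items()}
    for g in genes:
        for s, e in g.exons:
            blocked[g.chrom].addi(s, e)
    repeats: List[GenomicInterval] = []
    rid = 0
    for cls in config.repeat_classes:
        for _ in range(config.n_repeats_per_class):
            chrom = chroms[int(rng.integers(0, config.n_chroms))]
            length = int(rng.integers(150, 600))
            start = _place_nonoverlapping(rng, blocked[chrom],
                                          config.chrom_length, length)
            repeats.append(GenomicInterval(chrom, start, start + length,
                                           name=f"{cls}|rep_{rid:05d}"))
            rid += 1

    islands.sort(key=lambda iv: (iv.chrom, iv.start))
    repeats.sort(key=lambda iv: (iv.chrom, iv.start))
    return GenomeAnnotations(chrom_lengths=chrom_lengths, genes=genes,
                             islands=islands, repeats=repeats)


# ---------------------------------------------------------------------------
# Methylation truth
# ---------------------------------------------------------------------------

# Mean methylation by (stage, island size class).  Progression model:
# moderate baseline in melanocytes, global hypomethylation in stage I,
# strong hypermethylation of short islands in stage III/IV.
_ISLAND_MEANS = {
    "melanocyte": {"short": 0.30, "long": 0.30},
    "I": {"short": 0.15, "long": 0.15},
    "III": {"short": 0.88, "long": 0.40},
    "IV": {"short": 0.88, "long": 0.40},
}
# Mean methylation by (stage, repeat direction class).
_REPEAT_MEANS = {
    "melanocyte": {"hypo": 0.60, "hyper": 0.30},
    "I": {"hypo": 0.55, "hyper": 0.30},
    "III": {"hypo": 0.25, "hyper": 0.80},
    "IV": {"hypo": 0.25, "hyper": 0.80},
}
_BETA_CONCENTRATION = 30.0


def assign_methylation_states(
    annotations: GenomeAnnotations,
    stage_profile: Dict[str, str],
    seed: int,
    short_island_threshold: int = 270,
    hyper_repeat_classes: Sequence[str] = HYPER_REPEAT_CLASSES,
) -> MethylationTruth:
    """Draw per-interval methylation levels per cell line.

    Levels are Beta-distributed around stage-dependent means: stage-III/IV
    lines hypermethylate islands shorter than ``short_island_threshold``
    (default 270 bp) and hypomethylate 11 of the 14 repeat classes, with
    the three ``hyper_repeat_classes`` (simple repeats, LINE-1, Alu) moving
    the opposite way.  Cell lines sharing a stage share a random substream,
    so equal stages yield identical states.
    """
    for line, stage in stage_profile.items():
        if stage not in _STAGE_INDEX:
            raise ValueError(f"unknown stage label {stage!r} for {line!r}")
    hyper = set(hyper_repeat_classes)
    state: Dict[Tuple[str, str], float] = {}
    for line, stage in stage_profile.items():
        rng = np.random.default_rng([seed, _STAGE_INDEX[stage]])
        for iv in annotations.islands:
            size_cls = "short" if iv.length < short_island_threshold else "long"
            m = _ISLAND_MEANS[stage][size_cls]
            state[(line, iv.name)] = _beta_level(rng, m)
        for iv in annotations.repeats:
            direction = "hyper" if repeat_class_of(iv) in hyper else "hypo"
            m = _REPEAT_MEANS[stage][direction]
            state[(line, iv.name)] = _beta_level(rng, m)
    return MethylationTruth(state=state, stage_profile=dict(stage_profile))


def _beta_level(rng: np.random.Generator, mean: float,
                concentration: float = _BETA_CONCENTRATION) -> float:
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return float(rng.beta(a, b))


# ---------------------------------------------------------------------------
# Tag simulation
# ---------------------------------------------------------------------------

def _sample_uniform_tags(rng: np.random.Generator, chrom_lengths: Dict[str, int],
                         rate: float) -> TagTrack:
    positions, strands = {}, {}
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        n = rng.poisson(rate * L)
        pos = np.sort(rng.integers(0, L, size=n))
        positions[chrom] = pos.astype(np.int64)
        strands[chrom] = np.where(rng.random(n) < 0.5, "+", "-").astype("U1")
    return TagTrack(positions=positions, strands=strands)


def simulate_tags(
    annotations: GenomeAnnotations,
    truth: MethylationTruth,
    cell_line: str,
    depth: float = 0.01,
    enrichment_factor: float = 10.0,
    n_replicates: int = 2,
    seed: int = 0,
) -> Tuple[TagTrack, TagTrack]:
    """Simulate (enriched, input) tag tracks for one cell line.

    Input tags are uniform Poisson at ``depth`` tags/bp per replicate;
    enriched tags have their local rate multiplied by
    ``1 + level * (enrichment_factor - 1)`` inside each methylated interval.
    ``n_replicates`` technical replicates are simulated independently and
    pooled, mirroring the pooling of replicate sequencing runs.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    levels = truth.levels_for(cell_line)
    if not levels:
        raise ValueError(f"no methylation truth for cell line {cell_line!r}")
    line_key = sorted(truth.stage_profile).index(cell_line)

    enriched_reps, input_reps = [], []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, line_key, rep])
        background = _sample_uniform_tags(rng, annotations.chrom_lengths, depth)
        extra_pos: Dict[str, List[np.ndarray]] = {
            c: [] for c in annotations.chrom_lengths
        }
        for iv in annotations.truth_intervals():
            m = levels[iv.name]
            lam = depth * iv.length * m * (enrichment_factor - 1.0)
            if lam <= 0:
                continue
            n = rng.poisson(lam)
            if n:
                extra_pos[iv.chrom].append(
                    rng.integers(iv.start, iv.end, size=n).astype(np.int64)
                )
        positions, strands = {}, {}
        for chrom in sorted(annotations.chrom_lengths):
            parts = [background.positions[chrom]] + extra_pos[chrom]
            pos = np.sort(np.concatenate(parts))
            positions[chrom] = pos
            strands[chrom] = np.where(
                rng.random(pos.size) < 0.5, "+", "-"
            ).astype("U1")
        enriched_reps.append(TagTrack(positions=positions, strands=strands))
        rng_in = np.random.default_rng([seed, line_key, rep, 1])
        input_reps.append(
            _sample_uniform_tags(rng_in, annotations.chrom_lengths, depth)
        )
    return pool_tracks(*enriched_reps), pool_tracks(*input_reps)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def promoter_island_of(annotations: GenomeAnnotations, gene: GeneModel,
                       window: int = 1000) -> Optional[GenomicInterval]:
    """The CpG island overlapping ``TSS +/- window``, if any."""
    lo, hi = gene.tss - window, gene.tss + window
    for iv in annotations.islands:
        if iv.chrom == gene.chrom and iv.start < hi and iv.end > lo:
            return iv
    return None


def simulate_expression(
    annotations: GenomeAnnotations,
    truth: MethylationTruth,
    seed: int = 0,
    depth: float = 2e5,
    low_expression_fraction: float = 0.1,
    silencing_strength: float = 4.0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Poisson expression counts anti-correlated with promoter methylation.

    Returns ``(counts, lengths)``: a transcript x cell-line integer count
    table and per-transcript lengths (bp).  The expected count of a
    transcript falls by ``2 ** -silencing_strength`` as its promoter island
    goes from unmethylated to fully methylated.  A ``low_expression_fraction``
    of transcripts gets a tiny baseline so they land below RPKM 1 in every
    line, exercising the low-expression filter.
    """
    rng = np.random.default_rng([seed, 7])
    cell_lines = sorted(truth.stage_profile)
    genes = annotations.genes
    lengths = pd.Series(
        {g.gene_id: sum(e - s for s, e in g.exons) for g in genes},
        name="length",
    )
    n = len(genes)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    low = rng.random(n) < low_expression_fraction
    base[low] *= 1e-4
    promoters = {
        g.gene_id: promoter_island_of(annotations, g) for g in genes
    }
    counts = {}
    for li, line in enumerate(cell_lines):
        rng_line = np.random.default_rng([seed, 7, li + 1])
        mu = np.empty(n)
        for i, g in enumerate(genes):
            isl = promoters[g.gene_id]
            m = truth.level(line, isl.name) if isl is not None else 0.0
            weight = base[i] * (lengths.iloc[i] / 1000.0) * 2.0 ** (
                -silencing_strength * m
            )
            mu[i] = weight
        total_weight = mu.sum()
        if total_weight > 0 and depth > 0:
            mu = mu / total_weight * depth
        else:
            mu = np.zeros(n)
        counts[line] = rng_line.poisson(mu)
    df = pd.DataFrame(counts, index=[g.gene_id for g in genes])
    df.index.name = "transcript_id"
    return df, lengths


# ---------------------------------------------------------------------------
# Interaction tables
# ---------------------------------------------------------------------------

def sample_power_law_degrees(n: int, gamma: float = 1.6, kmax: int = 50,
                             rng: Optional[np.random.Generator] = None
                             ) -> np.ndarray:
    """Sample ``n`` node degrees from ``p(k) proportional to k**-gamma``."""
    if rng is None:
        rng = np.random.default_rng()
    k = np.arange(1, kmax + 1)
    p = k.astype(float) ** (-gamma)
    p /= p.sum()
    degrees = rng.choice(k, size=n, p=p)
    if degrees.sum() % 2 == 1:       # configuration model needs even sum
        degrees[int(rng.integers(0, n))] += 1
    return degrees


def simulate_coexpression_edges(
    gene_ids: Sequence[str],
    seed: int = 0,
    gamma: float = 1.6,
    kmax: int = 50,
    connected_fraction: float = 0.85,
) -> pd.DataFrame:
    """Co-expression edge table with an embedded scale-free subnetwork.

    A ``connected_fraction`` of the genes joins a configuration-model graph
    whose degrees follow ``p(k) ~ k**-gamma``; the rest stay isolated
    (the analysis reports them as unconnected).
    """
    import networkx as nx

    rng = np.random.default_rng([seed, 11])
    gene_ids = list(gene_ids)
    n_connected = int(round(connected_fraction * len(gene_ids)))
    chosen = sorted(rng.choice(len(gene_ids), size=n_connected, replace=False))
    members = [gene_ids[i] for i in chosen]
    degrees = sample_power_law_degrees(n_connected, gamma=gamma, kmax=kmax,
                                       rng=rng)
    g = nx.configuration_model(degrees, seed=int(rng.integers(0, 2 ** 31)))
    g = nx.Graph(g)                       # collapse multi-edges
    g.remove_edges_from(nx.selfloop_edges(g))
    rows = [
        {"gene_a": members[u], "gene_b": members[v]} for u, v in g.edges()
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b"])


def simulate_ppi_edges(
    gene_ids: Sequence[str],
    seed: int = 0,
    n_modules: int = 5,
    module_size: Tuple[int, int] = (3, 6),
    n_neighbors: int = 4,
) -> Tuple[pd.DataFrame, List[List[str]]]:
    """Protein-interaction edges containing planted seed modules.

    Each module is a clique of 3+ query genes; every member also gets
    ``n_neighbors`` first-degree partners outside the query set.  Returns
    the edge table and the planted modules (for validation).
    """
    rng = np.random.default_rng([seed, 13])
    gene_ids = list(gene_ids)
    rows = []
    modules: List[List[str]] = []
    used = set()
    ext = 0
    for mi in range(n_modules):
        size = int(rng.integers(module_size[0], module_size[1] + 1))
        avail = [g for g in gene_ids if g not in used]
        if len(avail) < size:
            break
        pick = sorted(rng.choice(len(avail), size=size, replace=False))
        members = [avail[i] for i in pick]
        used.update(members)
        modules.append(members)
        for i in range(size):
            for j in range(i + 1, size):
                rows.append({"protein_a": members[i], "protein_b": members[j]})
            for _ in range(n_neighbors):
                partner = f"ext_{ext:04d}"
                ext += 1
                rows.append({"protein_a": members[i], "protein_b": partner})
    return pd.DataFrame(rows, columns=["protein_a", "protein_b"]), modules


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_annotations(annotations: GenomeAnnotations, outdir: str) -> Dict[str, str]:
    """Write islands/repeats (BED6), genes (BED12) and chromosome sizes."""
    import os

    from . import io as msio

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "islands": os.path.join(outdir, "islands.bed"),
        "repeats": os.path.join(outdir, "repeats.bed"),
        "genes": os.path.join(outdir, "genes.bed"),
        "chrom_sizes": os.path.join(outdir, "chrom_sizes.tsv"),
    }
    msio.write_bed(annotations.islands, paths["islands"])
    msio.write_bed(annotations.repeats, paths["repeats"])
    msio.write_genes_bed12(annotations.genes, paths["genes"])
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom in sorted(annotations.chrom_lengths):
            fh.write(f"{chrom}\t{annotations.chrom_lengths[chrom]}\n")
    return paths
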