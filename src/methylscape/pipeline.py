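"""End-to-end pipeline driver: simulate -> callpeaks -> annotate ->
signatures -> quantify -> integrate -> network, under one validated config.

All randomness flows from one root seed via named substreams; a rerun with
the same config and seed reproduces byte-identical outputs, which the run
manifest records with per-file SHA-256 checksums.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import annotation, expression, network, peaks, quantify, signatures
from . import synthetic
from .core import GenomicInterval, TagTrack
from .io import write_bed, write_tags_bed
from .synthetic import (DEFAULT_STAGE_PROFILE, GenomeAnnotations,
                        MethylationTruth, SyntheticGenomeConfig)

_DEFAULTS: Dict[str, Any] = {
    "seed": 0,
    "outdir": "methylscape_run",
    "stage_profile": dict(DEFAULT_STAGE_PROFILE),
    "genome": {
        "n_chroms": 4,
        "chrom_length": 2_000_000,
        "n_genes": 400,
        "n_islands": 2000,
        "island_length_modes": [[275.0, 40.0], [450.0, 40.0]],
        "mode_weights": [0.5, 0.5],
        "n_repeats_per_class": 40,
        "p_promoter_island": 0.7,
    },
    "simulate": {
        "depth": 0.01,              # tags per bp per replicate
        "enrichment_factor": 10.0,
        "n_replicates": 2,
    },
    "peaks": {
        "window_size": 100,
        "merge_gap": 100,
        "p_cutoff": 1.0e-10,
        "seed_p": 5.0e-2,
        "control_smoothing": 5000,
    },
    "annotation": {
        "promoter_window": 3000,
        "downstream_window": 3000,
        "extension": 200,
        "bin_width": 25,
    },
    "signatures": {
        "min_frac": 0.5,
        "core_labels": ["A375", "SKMEL2"],
        "exclude_labels": ["HEM", "WM793B", "WM1552C"],
    },
    "quantify": {
        "regulatory_window": 1000,   # +/- around the TSS
        "pseudocount": 1.0,
        "linkage": "average",
    },
    "expression": {
        "depth": 2.0e5,
        "low_expression_fraction": 0.1,
        "silencing_strength": 4.0,
        "rpkm_threshold": 1.0,
        "treated_line": "WM1552C",   # demethylation-treated sample
    },
    "network": {
        "gamma": 1.6,
        "kmax": 50,
        "connected_fraction": 0.85,
    },
    "make_plots": False,
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration with every default pinned."""

    params: Dict[str, Any]

    @classmethod
    def default(cls, seed: int = 0, outdir: str = "methylscape_run"
                ) -> "RunConfig":
        p = copy.deepcopy(_DEFAULTS)
        p["seed"] = seed
        p["outdir"] = outdir
        return cls(params=p)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls.from_dict(user)

    @classmethod
    def from_dict(cls, user: Dict[str, Any]) -> "RunConfig":
        p = copy.deepcopy(_DEFAULTS)
        _merge_validated(p, user, path="")
        _validate(p)
        return cls(params=p)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.params, fh, sort_keys=True)

    def __getitem__(self, key: str) -> Any:
        return self.params[key]


def _merge_validated(base: Dict[str, Any], user: Dict[str, Any],
                     path: str) -> None:
    for key, value in user.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {where!r}")
        if isinstance(base[key], dict) and key != "stage_profile":
            if not isinstance(value, dict):
                raise ConfigError(f"{where!r} must be a mapping")
            _merge_validated(base[key], value, where)
        else:
            base[key] = value


def _validate(p: Dict[str, Any]) -> None:
    if not isinstance(p["seed"], int) or p["seed"] < 0:
        raise ConfigError("seed must be a non-negative integer")
    for line, stage in p["stage_profile"].items():
        if stage not in synthetic.STAGES:
            raise ConfigError(
                f"stage_profile[{line!r}]: unknown stage {stage!r}; "
                f"expected one of {synthetic.STAGES}"
            )
    if p["simulate"]["depth"] <= 0:
        raise ConfigError("simulate.depth must be positive")
    if p["simulate"]["enrichment_factor"] < 1:
        raise ConfigError("simulate.enrichment_factor must be >= 1")
    if p["peaks"]["window_size"] <= 0:
        raise ConfigError("peaks.window_size must be positive")
    if not (0 < p["peaks"]["p_cutoff"] <= 1):
        raise ConfigError("peaks.p_cutoff must lie in (0, 1]")
    if not (0 < p["signatures"]["min_frac"] <= 1):
        raise ConfigError("signatures.min_frac must lie in (0, 1]")
    missing = [
        lbl for lbl in (p["signatures"]["core_labels"]
                        + p["signatures"]["exclude_labels"])
        if lbl not in p["stage_profile"]
    ]
    if missing:
        raise ConfigError(f"signature labels not in stage_profile: {missing}")
    if p["expression"]["treated_line"] not in p["stage_profile"]:
        raise ConfigError("expression.treated_line must be a known cell line")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _genome_config(p: Dict[str, Any]) -> SyntheticGenomeConfig:
    g = p["genome"]
    return SyntheticGenomeConfig(
        n_chroms=g["n_chroms"], chrom_length=g["chrom_length"],
        n_genes=g["n_genes"], n_islands=g["n_islands"],
        island_length_modes=tuple(tuple(m) for m in g["island_length_modes"]),
        mode_weights=tuple(g["mode_weights"]),
        n_repeats_per_class=g["n_repeats_per_class"],
        p_promoter_island=g["p_promoter_island"],
        seed=p["seed"],
    )


def run_pipeline(config: RunConfig) -> Dict[str, Any]:
    """Run every stage; returns (and writes) the run manifest."""
    p = config.params
    outdir = p["outdir"]
    os.makedirs(outdir, exist_ok=True)
    artifacts: Dict[str, str] = {}
    summary: Dict[str, Any] = {}

    def emit(key: str, path: str) -> str:
        artifacts[key] = path
        return path

    stage = "simulate"
    try:
        ann = synthetic.generate_genome(_genome_config(p))
        truth = synthetic.assign_methylation_states(
            ann, p["stage_profile"], seed=p["seed"]
        )
        paths = synthetic.write_annotations(ann, outdir)
        for key, path in paths.items():
            emit(key, path)
        truth_path = emit("truth", os.path.join(outdir, "truth.tsv"))
        truth.write(truth_path)

        sim = p["simulate"]
        lines = sorted(p["stage_profile"])
        tracks: Dict[str, TagTrack] = {}
        input_track: Optional[TagTrack] = None
        treated_line = p["expression"]["treated_line"]
        for line in lines:
            enriched, inp = synthetic.simulate_tags(
                ann, truth, line, depth=sim["depth"],
                enrichment_factor=sim["enrichment_factor"],
                n_replicates=sim["n_replicates"], seed=p["seed"],
            )
            tracks[line] = enriched
            # the treated (stage III) line's input doubles as the common
            # control, as in normalizing every sample to one input library
            if line == treated_line:
                input_track = inp
        assert input_track is not None
        for line in lines:
            write_tags_bed(tracks[line],
                           emit(f"tags_{line}",
                                os.path.join(outdir, f"tags_{line}.bed")))
        write_tags_bed(input_track,
                       emit("tags_input", os.path.join(outdir,
                                                       "tags_input.bed")))

        stage = "callpeaks"
        pk = p["peaks"]
        control_cov = peaks.build_coverage(input_track, pk["window_size"],
                                           ann.chrom_lengths)
        peak_sets: Dict[str, List[GenomicInterval]] = {}
        peak_lists = {}
        for line in lines:
            cov = peaks.build_coverage(tracks[line], pk["window_size"],
                                       ann.chrom_lengths)
            called = peaks.call_peaks(cov, control_cov,
                                      p_cutoff=pk["p_cutoff"],
                                      merge_gap=pk["merge_gap"],
                                      seed_p=pk["seed_p"],
                                      control_smoothing=pk["control_smoothing"])
            peak_lists[line] = called
            peak_sets[line] = [c.interval for c in called]
            peaks.write_peaks_bed(
                called, emit(f"peaks_{line}",
                             os.path.join(outdir, f"peaks_{line}.bed")))
            summary[f"n_peaks_{line}"] = len(called)
        peaks.write_coverage_wiggle(
            control_cov,
            emit("coverage_input", os.path.join(outdir, "coverage_input.wig")),
            name="input_coverage",
        )

        stage = "annotate"
        an = p["annotation"]
        all_line = lines[-1]
        feats = annotation.assign_features(
            peak_sets[all_line], ann.genes,
            promoter_window=an["promoter_window"],
            downstream_window=an["downstream_window"],
        )
        feats.to_csv(emit("feature_assignments",
                          os.path.join(outdir, "feature_assignments.tsv")),
                     sep="\t", index=False)
        if peak_sets[all_line]:
            sizes = annotation.island_size_distribution(
                peak_sets[all_line], bin_width=an["bin_width"]
            )
            sizes.to_csv(emit("peak_size_distribution",
                              os.path.join(outdir, "peak_sizes.tsv")),
                         sep="\t", index=False)
        assoc = annotation.associate_features(
            ann.islands[:200],
            {"repeat": ann.repeats},
            extension=an["extension"],
            chrom_lengths=ann.chrom_lengths,
        )
        assoc.to_csv(emit("island_associations",
                          os.path.join(outdir, "island_associations.tsv")),
                     sep="\t", index=False)

        stage = "signatures"
        sg = p["signatures"]
        collection = signatures.PeakSetCollection(
            sets={line: peak_sets[line] for line in lines}
        )
        table = signatures.venn_table(collection, min_frac=sg["min_frac"])
        table.to_csv(emit("membership_matrix",
                          os.path.join(outdir, "membership_matrix.tsv")),
                     sep="\t", index=False)
        specific = signatures.derive_stage_specific(
            collection, sg["core_labels"], sg["exclude_labels"],
            min_frac=sg["min_frac"],
        )
        write_bed(specific, emit("stage_specific",
                                 os.path.join(outdir, "stage_specific.bed")))
        summary["n_stage_specific_regions"] = len(specific)
        mapped_genes, mapped = signatures.map_regions_to_genes(
            specific, ann.genes, **signatures.GENE_SPAN_PRESET
        )
        mapped.to_csv(emit("stage_specific_genes",
                           os.path.join(outdir, "stage_specific_genes.tsv")),
                      sep="\t", index=False)
        summary["n_stage_specific_genes"] = len(mapped_genes)

        stage = "quantify"
        q = p["quantify"]
        reg_regions = []
        for g in ann.genes:
            lo, hi = signatures.gene_window(
                g, q["regulatory_window"], q["regulatory_window"], anchor="tss"
            )
            reg_regions.append(GenomicInterval(g.chrom, lo, hi,
                                               name=g.gene_id))
        counts = pd.DataFrame(
            {line: quantify.count_tags_in_regions(tracks[line], reg_regions)
             for line in lines},
            index=[iv.name for iv in reg_regions],
        )
        input_counts = pd.Series(
            quantify.count_tags_in_regions(input_track, reg_regions),
            index=counts.index,
        )
        eff = pd.DataFrame(
            {line: quantify.effective_reads(counts[line].values,
                                            tracks[line].library_size,
                                            input_track.library_size)
             for line in lines},
            index=counts.index,
        )
        fc = quantify.region_fold_change(eff, input_counts,
                                         pseudocount=q["pseudocount"])
        fc.to_csv(emit("fold_change", os.path.join(outdir, "fold_change.tsv")),
                  sep="\t", float_format="%.6f")
        normed = quantify.normalize_rows(fc)
        linkage, labels = quantify.cluster_cell_lines(normed,
                                                      method=q["linkage"])
        newick = quantify.linkage_to_newick(linkage, labels)
        with open(emit("dendrogram", os.path.join(outdir, "dendrogram.nwk")),
                  "w") as fh:
            fh.write(newick + "\n")
        repeats_by_class: Dict[str, List[GenomicInterval]] = {}
        for iv in ann.repeats:
            repeats_by_class.setdefault(
                synthetic.repeat_class_of(iv), []
            ).append(iv)
        rep = quantify.repeat_enrichment(tracks, input_track, repeats_by_class)
        quantify.repeat_enrichment_table(rep).to_csv(
            emit("repeat_enrichment",
                 os.path.join(outdir, "repeat_enrichment.tsv")),
            sep="\t", index=False, float_format="%.6g",
        )

        stage = "integrate"
        ex = p["expression"]
        counts_expr, lengths = synthetic.simulate_expression(
            ann, truth, seed=p["seed"], depth=ex["depth"],
            low_expression_fraction=ex["low_expression_fraction"],
            silencing_strength=ex["silencing_strength"],
        )
        rpkm = expression.compute_rpkm(counts_expr, lengths)
        rpkm_kept = expression.filter_low_expression(
            rpkm, threshold=ex["rpkm_threshold"]
        )
        rpkm_kept.to_csv(emit("rpkm", os.path.join(outdir, "rpkm.tsv")),
                         sep="\t", float_format="%.4f")
        summary["n_transcripts_expressed"] = int(rpkm_kept.shape[0])
        summary["n_transcripts_filtered"] = int(
            rpkm.shape[0] - rpkm_kept.shape[0]
        )

        # demethylation-treated sample: methylation truth zeroed out
        zero_truth = MethylationTruth(
            state={k: 0.0 for k in truth.state},
            stage_profile=truth.stage_profile,
        )
        treated_enriched, _ = synthetic.simulate_tags(
            ann, zero_truth, treated_line, depth=sim["depth"],
            enrichment_factor=sim["enrichment_factor"],
            n_replicates=sim["n_replicates"], seed=p["seed"] + 1,
        )
        treated_cov = peaks.build_coverage(treated_enriched,
                                           pk["window_size"],
                                           ann.chrom_lengths)
        treated_peaks = [
            c.interval for c in peaks.call_peaks(
                treated_cov, control_cov, p_cutoff=pk["p_cutoff"],
                merge_gap=pk["merge_gap"], seed_p=pk["seed_p"],
                control_smoothing=pk["control_smoothing"])
        ]
        rev = expression.reversible_regions(
            peak_sets[treated_line], treated_peaks,
            min_frac=sg["min_frac"],
        )
        reversible = [r.interval for r in rev if r.reversal]
        write_bed(reversible, emit("reversible_regions",
                                   os.path.join(outdir, "reversible.bed")))
        summary["n_reversible_regions"] = len(reversible)

        stages_iii_iv = [l for l in lines
                         if p["stage_profile"][l] in ("III", "IV")]
        early = [l for l in lines
                 if p["stage_profile"][l] in ("melanocyte", "I")]
        cand = expression.candidate_gene_set(
            reversible, ann.genes, ann.islands,
            expression_rpkm=rpkm_kept,
            methylated_lines=stages_iii_iv,
            unmethylated_lines=early,
        )
        with open(emit("candidate_genes",
                       os.path.join(outdir, "candidate_genes.txt")),
                  "w") as fh:
            fh.write("\n".join(cand.genes) + ("\n" if cand.genes else ""))
        summary["candidate_gene_cascade"] = cand.stage_counts
        summary["n_candidate_genes"] = len(cand.genes)

        stage = "network"
        nw = p["network"]
        universe = [g.gene_id for g in ann.genes]
        query = cand.genes if len(cand.genes) >= 10 else universe[:50]
        edges = synthetic.simulate_coexpression_edges(
            query, seed=p["seed"], gamma=nw["gamma"], kmax=nw["kmax"],
            connected_fraction=nw["connected_fraction"],
        )
        edges.to_csv(emit("coexpression_edges",
                          os.path.join(outdir, "coexpression_edges.tsv")),
                     sep="\t", index=False)
        graph, unconnected = network.build_network(query, edges)
        component = network.largest_component(graph)
        summary["n_connected_genes"] = component.number_of_nodes()
        summary["n_unconnected_genes"] = len(unconnected)
        fit = network.fit_power_law([d for _, d in component.degree()])
        summary["power_law_gamma"] = round(fit.gamma, 4)
        summary["power_law_r_squared"] = round(fit.r_squared, 4)
        ppi, modules = synthetic.simulate_ppi_edges(query, seed=p["seed"])
        expanded = network.expand_modules(modules, ppi)
        with open(emit("modules", os.path.join(outdir, "modules.json")),
                  "w") as fh:
            json.dump(expanded, fh, indent=1, sort_keys=True)
        term_sets = {}
        for g in ann.genes:
            term_sets.setdefault(f"chrom:{g.chrom}", []).append(g.gene_id)
        enr = network.fisher_enrichment(
            [g for g in query if g in set(universe)], term_sets, universe
        )
        network.enrichment_table(enr).to_csv(
            emit("enrichment", os.path.join(outdir, "enrichment.tsv")),
            sep="\t", index=False, float_format="%.6g",
        )

        if p["make_plots"]:
            from . import plots

            plots.plot_chromosome_density(
                peak_sets[all_line], ann.chrom_lengths,
                emit("density_plot", os.path.join(outdir, "peak_density.png")),
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": p["seed"],
        "parameters": p,
        "artifacts": {
            key: {"path": os.path.relpath(path, outdir),
                  "sha256": _sha256(path)}
            for key, path in sorted(artifacts.items())
        },
        "summary": summary,
    }
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
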