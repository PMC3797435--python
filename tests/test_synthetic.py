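"""The simulator: determinism, configured distributions, truth structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylscape.core import GenomicInterval
from methylscape.synthetic import (DEFAULT_STAGE_PROFILE,
                                   HYPER_REPEAT_CLASSES, MethylationTruth,
                                   SyntheticGenomeConfig,
                                   assign_methylation_states, generate_genome,
                                   repeat_class_of, simulate_expression,
                                   simulate_tags, write_annotations)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticGenomeConfig(n_chroms=0)
    with pytest.raises(ValueError):
        SyntheticGenomeConfig(repeat_classes=("a", "b"))
    with pytest.raises(ValueError):
        SyntheticGenomeConfig(island_length_modes=((0, 10), (450, 40)))


def test_generation_deterministic(tmp_path, small_config):
    a1 = generate_genome(small_config)
    a2 = generate_genome(small_config)
    d1, d2 = tmp_path / "r1", tmp_path / "r2"
    write_annotations(a1, str(d1))
    write_annotations(a2, str(d2))
    for name in ("islands.bed", "repeats.bed", "genes.bed", "chrom_sizes.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_gene_bodies_do_not_overlap(small_annotations):
    by_chrom = {}
    for g in small_annotations.genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for spans in by_chrom.values():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 >= e1


def test_island_length_mixture_is_bimodal():
    cfg = SyntheticGenomeConfig(n_chroms=2, chrom_length=2_000_000,
                                n_genes=0, n_islands=1000, seed=3)
    ann = generate_genome(cfg)
    assert ann.genes == []
    lengths = np.array([iv.length for iv in ann.islands])
    hist, edges = np.histogram(lengths, bins=np.arange(0, 700, 25))
    centers = (edges[:-1] + edges[1:]) / 2
    # local maxima of the histogram must sit near the configured modes
    short = centers[np.argmax(hist * (centers < 360))]
    long = centers[np.argmax(hist * (centers >= 360))]
    assert abs(short - 275) <= 25
    assert abs(long - 450) <= 25
    # two-component mixture KS check against the configured distribution
    def mixture_cdf(x):
        return 0.5 * stats.norm.cdf(x, 275, 40) + 0.5 * stats.norm.cdf(x, 450, 40)
    _, p = stats.kstest(lengths, mixture_cdf)
    assert p > 0.01


def test_methylation_states_same_stage_identical(small_annotations):
    profile = {"lineA": "melanocyte", "lineB": "melanocyte"}
    truth = assign_methylation_states(small_annotations, profile, seed=5)
    a = truth.levels_for("lineA")
    b = truth.levels_for("lineB")
    assert a == b


def test_methylation_progression_short_islands(small_annotations, small_truth):
    short = [iv for iv in small_annotations.islands if iv.length < 270]
    iv_names = [iv.name for iv in short]
    stage_iv = np.mean([small_truth.level("A375", n) for n in iv_names])
    melanocyte = np.mean([small_truth.level("HEM", n) for n in iv_names])
    stage_i = np.mean([small_truth.level("WM793B", n) for n in iv_names])
    assert stage_iv > melanocyte > stage_i


def test_repeat_class_directions(small_annotations, small_truth):
    by_class = {}
    for iv in small_annotations.repeats:
        by_class.setdefault(repeat_class_of(iv), []).append(iv.name)
    for cls, names in by_class.items():
        late = np.mean([small_truth.level("SKMEL2", n) for n in names])
        early = np.mean([small_truth.level("HEM", n) for n in names])
        if cls in HYPER_REPEAT_CLASSES:
            assert late > early, cls
        else:
            assert late < early, cls


def test_unknown_stage_rejected(small_annotations):
    with pytest.raises(ValueError, match="unknown stage"):
        assign_methylation_states(small_annotations, {"x": "stage-9"}, seed=1)


def test_truth_roundtrip(tmp_path, small_truth):
    path = str(tmp_path / "truth.tsv")
    small_truth.write(path)
    back = MethylationTruth.read(path)
    assert back.stage_profile == small_truth.stage_profile
    for key, lv in list(small_truth.state.items())[::37]:
        assert back.state[key] == pytest.approx(lv, abs=1e-6)


def test_tags_deterministic(small_annotations, small_truth):
    e1, i1 = simulate_tags(small_annotations, small_truth, "A375", seed=9)
    e2, i2 = simulate_tags(small_annotations, small_truth, "A375", seed=9)
    for c in e1.positions:
        assert np.array_equal(e1.positions[c], e2.positions[c])
        assert np.array_equal(i1.positions[c], i2.positions[c])


def test_tags_null_when_no_enrichment(small_annotations, small_truth):
    """factor=1: enriched and input window counts are rate-indistinguishable."""
    enr, inp = simulate_tags(small_annotations, small_truth, "A375",
                             enrichment_factor=1.0, seed=11)
    ok = total = 0
    for chrom, L in small_annotations.chrom_lengths.items():
        e = np.bincount(enr.positions[chrom] // 1000, minlength=L // 1000)
        i = np.bincount(inp.positions[chrom] // 1000, minlength=L // 1000)
        for ew, iw in zip(e, i):
            # two-sample Poisson rate test via binomial conditioning
            n = ew + iw
            p = stats.binomtest(int(ew), int(n), 0.5).pvalue if n else 1.0
            ok += p >= 0.01
            total += 1
    assert ok / total >= 0.99


def test_tag_density_ratio_matches_enrichment_factor():
    """A fully methylated island converges to the configured rate ratio."""
    cfg = SyntheticGenomeConfig(n_chroms=1, chrom_length=200_000, n_genes=0,
                                n_islands=1, n_repeats_per_class=2, seed=2)
    ann = generate_genome(cfg)
    island = ann.islands[0]
    profile = {"L": "IV"}
    truth = MethylationTruth(
        state={("L", iv.name): (1.0 if iv.name == island.name else 0.0)
               for iv in ann.truth_intervals()},
        stage_profile=profile,
    )
    # high depth for a tight ratio estimate
    enr, _ = simulate_tags(ann, truth, "L", depth=1.0, enrichment_factor=10,
                           n_replicates=1, seed=3)
    pos = enr.positions[island.chrom]
    inside = np.sum((pos >= island.start) & (pos < island.end))
    in_dens = inside / island.length
    out_dens = (pos.size - inside) / (200_000 - island.length)
    assert in_dens / out_dens == pytest.approx(10.0, rel=0.1)


def test_expression_monotone_in_methylation(small_annotations, small_truth):
    counts, lengths = simulate_expression(small_annotations, small_truth,
                                          seed=4)
    assert (counts.values >= 0).all()
    assert counts.values.dtype.kind == "i"
    # repeat with zero depth
    zero, _ = simulate_expression(small_annotations, small_truth, seed=4,
                                  depth=0.0)
    assert (zero.values == 0).all()
    # determinism
    again, _ = simulate_expression(small_annotations, small_truth, seed=4)
    assert counts.equals(again)


def test_expression_mean_decreases_with_methylation():
    """Monte-Carlo: expected count at level 0 strictly above level 1."""
    cfg = SyntheticGenomeConfig(n_chroms=1, chrom_length=300_000, n_genes=20,
                                n_islands=30, n_repeats_per_class=2,
                                p_promoter_island=1.0, seed=6)
    ann = generate_genome(cfg)
    from methylscape.synthetic import promoter_island_of

    gene = ann.genes[0]
    island = promoter_island_of(ann, gene)
    assert island is not None
    totals = {0.0: 0.0, 1.0: 0.0}
    for level in totals:
        state = {("L", iv.name): 0.0 for iv in ann.truth_intervals()}
        state[("L", island.name)] = level
        truth = MethylationTruth(state=state, stage_profile={"L": "IV"})
        for rep in range(60):
            counts, _ = simulate_expression(ann, truth, seed=rep)
            totals[level] += counts.loc[gene.gene_id, "L"]
    assert totals[0.0] > totals[1.0]


def test_low_expression_fraction_lands_below_rpkm_one(small_annotations,
                                                      small_truth):
    from methylscape.expression import compute_rpkm

    counts, lengths = simulate_expression(small_annotations, small_truth,
                                          seed=8, low_expression_fraction=0.2)
    rpkm = compute_rpkm(counts, lengths)
    frac_low = (rpkm.max(axis=1) < 1.0).mean()
    assert 0.1 <= frac_low <= 0.35
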