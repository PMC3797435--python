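"""RPKM, filtering, reversibility and the candidate-gene cascade."""

import numpy as np
import pandas as pd
import pytest

from methylscape.core import GeneModel, GenomicInterval
from methylscape.expression import (CandidateGeneParams, candidate_gene_set,
                                    compute_rpkm, filter_low_expression,
                                    reversible_regions)


def _table(values, columns=("s1", "s2")):
    return pd.DataFrame(values, columns=list(columns),
                        index=[f"t{i}" for i in range(len(values))])


def test_rpkm_arithmetic():
    counts = _table([[100, 0]])
    lengths = pd.Series({"t0": 1000})
    totals = pd.Series({"s1": 1_000_000, "s2": 1_000_000})
    rpkm = compute_rpkm(counts, lengths, totals)
    assert rpkm.loc["t0", "s1"] == pytest.approx(100.0)
    assert rpkm.loc["t0", "s2"] == 0.0


def test_rpkm_scale_property():
    rng = np.random.default_rng(0)
    counts = _table(rng.integers(0, 1000, size=(20, 2)))
    lengths = pd.Series(rng.integers(200, 5000, size=20),
                        index=counts.index)
    totals = pd.Series({"s1": 2_000_000, "s2": 3_000_000})
    r1 = compute_rpkm(counts, lengths, totals)
    r2 = compute_rpkm(counts, lengths, totals * 2)
    assert np.allclose(r1.values, r2.values * 2)
    # independent recomputation, spreadsheet style
    manual = counts.values * 1e9 / lengths.values[:, None] / totals.values
    assert np.allclose(r1.values, manual, rtol=1e-12)


def test_filter_low_expression_boundary():
    rpkm = _table([[0.2, 0.9], [0.2, 1.0], [5.0, 0.0]])
    kept = filter_low_expression(rpkm)
    assert list(kept.index) == ["t1", "t2"]   # 1.0 is not "less than 1"
    # column order does not matter
    kept_rev = filter_low_expression(rpkm[["s2", "s1"]])
    assert list(kept_rev.index) == list(kept.index)


def test_reversible_regions_trivial_cases():
    ivs = [GenomicInterval("chr1", 0, 200, name="a"),
           GenomicInterval("chr1", 500, 800, name="b")]
    # treated == untreated -> nothing reversible
    none = reversible_regions(ivs, ivs)
    assert all(not r.reversal for r in none)
    # treated empty -> everything reversible
    every = reversible_regions(ivs, [])
    assert all(r.reversal for r in every)
    assert all(r.methylated_in_untreated for r in every)


def test_reversible_recovers_planted_islands(small_annotations):
    """Erasing the truth recovers the untreated methylated set."""
    from methylscape import peaks as P
    from methylscape.synthetic import MethylationTruth, simulate_tags
    from methylscape.signatures import overlap_equivalence

    ann = small_annotations
    state = {}
    rng = np.random.default_rng(10)
    planted = set()
    for iv in ann.truth_intervals():
        lv = 0.95 if (iv.name.startswith("island") and rng.random() < 0.4) \
            else 0.0
        state[("U", iv.name)] = lv
        if lv > 0:
            planted.add(iv.name)
    untreated = MethylationTruth(state=state, stage_profile={"U": "III"})
    treated = MethylationTruth(state={k: 0.0 for k in state},
                               stage_profile={"U": "III"})
    def call(truth, seed):
        enr, inp = simulate_tags(ann, truth, "U", seed=seed)
        cov = P.build_coverage(enr, 100, ann.chrom_lengths)
        ctl = P.build_coverage(inp, 100, ann.chrom_lengths)
        return [c.interval for c in P.call_peaks(cov, ctl)]
    u_peaks = call(untreated, 5)
    t_peaks = call(treated, 6)
    rev = [r.interval for r in reversible_regions(u_peaks, t_peaks)
           if r.reversal]
    planted_ivs = [iv for iv in ann.islands if iv.name in planted]
    _, unmatched, _ = overlap_equivalence(planted_ivs, rev, min_frac=0.3)
    recovered = len(planted_ivs) - len(unmatched)
    jaccard = recovered / (len(planted_ivs) + len(rev) - recovered)
    assert jaccard >= 0.8


def _cascade_fixture():
    gene = GeneModel("g1", "chr1", "+", exons=[(10_000, 14_000)])
    peak = GenomicInterval("chr1", 9_500, 9_900, name="pk")   # 500 bp upstream
    island = GenomicInterval("chr1", 9_200, 9_600, name="isl")
    return gene, peak, island


def test_candidate_cascade_requires_promoter_evidence():
    gene, peak, island = _cascade_fixture()
    # no islands or promoters supplied -> empty after stage 2
    res = candidate_gene_set([peak], [gene], island_set=[])
    assert res.genes == []
    assert res.stage_counts["tss_window"] == 1
    assert res.stage_counts["promoter_evidence"] == 0
    # with the island 500 bp upstream -> retained
    res2 = candidate_gene_set([peak], [gene], island_set=[island])
    assert res2.genes == ["g1"]


def test_candidate_cascade_is_monotone():
    gene, peak, island = _cascade_fixture()
    rpkm = pd.DataFrame({"HEM": [10.0], "A375": [1.0]}, index=["g1"])
    res = candidate_gene_set([peak], [gene], island_set=[island],
                             expression_rpkm=rpkm,
                             methylated_lines=["A375"],
                             unmethylated_lines=["HEM"])
    counts = res.stage_counts
    assert counts["tss_window"] >= counts["promoter_evidence"] >= \
        counts["silencing"]
    assert res.genes == ["g1"]    # 10 >= 2 * 1 -> silenced
    # not silenced when expression is flat
    flat = pd.DataFrame({"HEM": [5.0], "A375": [5.0]}, index=["g1"])
    res_flat = candidate_gene_set([peak], [gene], island_set=[island],
                                  expression_rpkm=flat,
                                  methylated_lines=["A375"],
                                  unmethylated_lines=["HEM"])
    assert res_flat.genes == []


def test_candidate_recovery_from_simulator(small_annotations, small_truth):
    """Genes with methylated promoters and silenced expression are found."""
    from methylscape.synthetic import (promoter_island_of,
                                       simulate_expression, simulate_tags)
    from methylscape import peaks as P

    ann = small_annotations
    truth = small_truth
    line = "WM1552C"
    enr, inp = simulate_tags(ann, truth, line, seed=12)
    cov = P.build_coverage(enr, 100, ann.chrom_lengths)
    ctl = P.build_coverage(inp, 100, ann.chrom_lengths)
    pk = [c.interval for c in P.call_peaks(cov, ctl)]
    counts, lengths = simulate_expression(ann, truth, seed=12,
                                          low_expression_fraction=0.0)
    rpkm = compute_rpkm(counts, lengths)
    res = candidate_gene_set(
        pk, ann.genes, ann.islands, expression_rpkm=rpkm,
        methylated_lines=["WM1552C", "A375", "SKMEL2"],
        unmethylated_lines=["HEM", "WM793B"],
    )
    # expected: genes whose promoter island is strongly methylated in the
    # late lines (short islands) and expressed from an unmethylated promoter
    # in the early lines
    expected = set()
    for g in ann.genes:
        isl = promoter_island_of(ann, g)
        if isl is None:
            continue
        if truth.level(line, isl.name) >= 0.7 and \
                truth.level("HEM", isl.name) <= 0.5 and \
                rpkm.loc[g.gene_id].max() >= 1.0:
            expected.add(g.gene_id)
    got = set(res.genes)
    if expected:
        recall = len(got & expected) / len(expected)
        precision = len(got & expected) / max(1, len(got))
        assert recall >= 0.8
        assert precision >= 0.8
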