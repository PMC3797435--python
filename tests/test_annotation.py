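"""Feature assignment, island set algebra, transcript classification."""

import numpy as np
import pytest

from conftest import brute_force_assignment, brute_force_associations
from methylscape.annotation import (GeneIndex, assign_feature,
                                    associate_features,
                                    build_coding_exon_index,
                                    classify_transcript, gene_category_regions,
                                    island_size_distribution, union_islands)
from methylscape.core import GeneModel, GenomicInterval


def test_union_islands_basic():
    a = [GenomicInterval("chr1", 0, 100)]
    b = [GenomicInterval("chr1", 50, 150)]
    out = union_islands(a, b)
    assert [(iv.start, iv.end) for iv in out] == [(0, 150)]


def test_union_islands_disjoint_counts():
    a = [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(3)]
    b = [GenomicInterval("chr2", i * 100, i * 100 + 50) for i in range(4)]
    assert len(union_islands(a, b)) == 7


def test_union_islands_matches_mask_oracle():
    rng = np.random.default_rng(5)
    span = 20_000
    ivs = []
    for _ in range(1000):
        s = int(rng.integers(0, span - 200))
        ivs.append(GenomicInterval("chr1", s, s + int(rng.integers(1, 200))))
    half = len(ivs) // 2
    out = union_islands(ivs[:half], ivs[half:])
    mask = np.zeros(span + 200, dtype=bool)
    for iv in ivs:
        mask[iv.start:iv.end] = True
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8),
                                                   [0]))))
    expected = list(zip(edges[::2], edges[1::2]))
    assert [(iv.start, iv.end) for iv in out] == expected


def test_union_islands_idempotent():
    ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 40)]
    once = union_islands(ivs, [])
    twice = union_islands(once, once)
    assert [(iv.start, iv.end) for iv in twice] == \
        [(iv.start, iv.end) for iv in once]


def test_island_size_distribution():
    ivs = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300),
           GenomicInterval("chr1", 0, 300)]
    table = island_size_distribution(ivs, bin_width=25)
    assert table["frequency"].sum() == pytest.approx(1.0)
    assert table.loc[table.bin_start == 100, "frequency"].iloc[0] == \
        pytest.approx(2 / 3)
    assert table.loc[table.bin_start == 300, "frequency"].iloc[0] == \
        pytest.approx(1 / 3)
    single = island_size_distribution([ivs[0]])
    assert single["frequency"].max() == 1.0
    with pytest.raises(ValueError):
        island_size_distribution([])


def test_overlap_length_breaks_ties_across_genes():
    """The worked example: 300 bp promoter overlap loses to 400 bp intron."""
    gene_p = GeneModel("gP", "chr1", "-", exons=[(1_000, 2_000)])
    # gP is on '-': TSS at 2_000, promoter = [2_000, 5_000)
    gene_i = GeneModel("gI", "chr1", "+",
                       exons=[(2_200, 2_300), (6_000, 6_100)])
    # intron of gI = [2_300, 6_000)
    peak = GenomicInterval("chr1", 4_700, 5_100, name="peak")
    # overlap with gP promoter = [4_700, 5_000) = 300 bp
    # overlap with gI intron   = [4_700, 5_100) = 400 bp
    res = assign_feature(peak, GeneIndex([gene_p, gene_i]))
    assert res.category == "intron"
    assert res.gene_id == "gI"
    assert res.overlap_length == 400


def test_peak_inside_exon():
    g = GeneModel("g", "chr1", "+", exons=[(1_000, 3_000)],
                  cds=[(1_000, 3_000)])
    peak = GenomicInterval("chr1", 1_500, 1_700, name="p")
    res = assign_feature(peak, GeneIndex([g]))
    assert res.category == "exon"
    assert res.overlap_length == peak.length


def test_intergenic_when_no_overlap():
    g = GeneModel("g", "chr1", "+", exons=[(1_000, 3_000)])
    peak = GenomicInterval("chr2", 1_500, 1_700, name="p")
    res = assign_feature(peak, GeneIndex([g]))
    assert res.category == "intergenic"
    assert res.gene_id is None


def test_assignment_matches_brute_force(small_annotations):
    rng = np.random.default_rng(17)
    genes = small_annotations.genes[:50]
    index = GeneIndex(genes)
    for _ in range(300):
        chrom = f"chr{int(rng.integers(1, 3))}"
        s = int(rng.integers(0, 490_000))
        peak = GenomicInterval(chrom, s, s + int(rng.integers(50, 2_000)),
                               name="p")
        got = assign_feature(peak, index)
        cat, gid, ov = brute_force_assignment(peak, genes)
        assert (got.category, got.gene_id, got.overlap_length) == \
            (cat, gid, ov if gid else 0)


def test_categories_partition_isolated_gene_span():
    """Each base near one isolated gene belongs to exactly one category."""
    g = GeneModel("g", "chr1", "+",
                  exons=[(10_000, 10_500), (11_000, 12_000), (12_500, 13_000)],
                  cds=[(10_200, 10_500), (11_000, 12_000), (12_500, 12_800)])
    regions = gene_category_regions(g)
    for base in range(7_000, 16_000, 7):
        claims = [
            cat for cat, ivs in regions.items()
            if any(s <= base < e for s, e in ivs)
        ]
        if 7_000 <= base < 16_000:
            assert len(claims) == 1, (base, claims)


@pytest.mark.parametrize("length,orf_nt,expected", [
    (900, 363, "coding"),       # 121 codons and 363 > 300
    (1200, 375, "noncoding"),   # 125 codons but 375 <= 400
    (600, 360, "noncoding"),    # 120 codons: not > 120
])
def test_classify_transcript_orf_rule(length, orf_nt, expected):
    assert classify_transcript(length, orf_nt) == expected


def test_classify_transcript_exon_overlap_and_override():
    coding_gene = GeneModel("c", "chr1", "+", exons=[(1_000, 2_000)],
                            cds=[(1_200, 1_800)])
    index = build_coding_exon_index([coding_gene])
    # 1 bp overlap with a coding exon suffices
    assert classify_transcript(500, 0, exons=[("chr1", 1_999, 2_050)],
                               coding_exon_index=index) == "coding"
    assert classify_transcript(500, 0, exons=[("chr1", 2_000, 2_050)],
                               coding_exon_index=index) == "noncoding"
    # the override wins over everything
    assert classify_transcript(900, 900, exons=[("chr1", 1_500, 1_600)],
                               coding_exon_index=index,
                               noncoding_override=True) == "noncoding"


def test_associate_features_extension_boundary():
    island = GenomicInterval("chr1", 1_000, 1_200, name="isl")
    feature = GenomicInterval("chr1", 1_300, 1_400, name="f")
    hit = associate_features([island], {"x": [feature]}, extension=200)
    assert len(hit) == 1
    miss = associate_features([island], {"x": [feature]}, extension=0)
    assert len(miss) == 0
    with pytest.raises(ValueError):
        associate_features([island], {"x": [feature]}, extension=-1)


def test_associate_features_matches_all_pairs_oracle():
    rng = np.random.default_rng(23)
    islands = [
        GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 400)),
                        name=f"i{k}")
        for k, s in enumerate(rng.integers(0, 50_000, size=200))
    ]
    feats = {
        "lnc": [GenomicInterval("chr1", int(s), int(s) + 150, name=f"l{k}")
                for k, s in enumerate(rng.integers(0, 50_000, size=100))],
        "prom": [GenomicInterval("chr1", int(s), int(s) + 80, name=f"p{k}")
                 for k, s in enumerate(rng.integers(0, 50_000, size=100))],
    }
    got = associate_features(islands, feats, extension=200)
    got_set = set(map(tuple, got.values))
    assert got_set == brute_force_associations(islands, feats, 200)
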