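"""Normalization, fold change, clustering and repeat enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylscape.core import GenomicInterval, TagTrack
from methylscape.quantify import (cluster_cell_lines, count_tags_in_regions,
                                  effective_reads, linkage_to_newick,
                                  normalize_rows, pearson_distance_matrix,
                                  region_fold_change, repeat_enrichment,
                                  top_split)


def test_effective_reads_arithmetic():
    assert effective_reads(np.array([10]), 2_000_000, 1_000_000)[0] == 5.0
    same = effective_reads(np.array([3, 7]), 10, 10)
    assert list(same) == [3.0, 7.0]
    with pytest.raises(ValueError):
        effective_reads(np.array([1]), 0, 10)


def test_effective_reads_commutes_with_subsetting():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 50, size=100)
    full = effective_reads(counts, 123_456, 99_999)
    sub = effective_reads(counts[:10], 123_456, 99_999)
    assert np.allclose(full[:10], sub)


def test_region_fold_change_drops_all_zero_rows():
    eff = pd.DataFrame({"A": [0.0, 4.0], "B": [0.0, 2.0]},
                       index=["dead", "live"])
    inp = pd.Series([5.0, 1.0], index=["dead", "live"])
    fc = region_fold_change(eff, inp, pseudocount=1.0)
    assert list(fc.index) == ["live"]
    assert fc.loc["live", "A"] == pytest.approx(5.0 / 2.0)


def test_fold_change_identity_when_equal():
    eff = pd.DataFrame({"A": [3.0, 8.0]}, index=["r1", "r2"])
    inp = pd.Series([3.0, 8.0], index=["r1", "r2"])
    fc = region_fold_change(eff, inp, pseudocount=0.0)
    assert np.allclose(fc.values, 1.0)


def test_normalize_rows_conventions():
    m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"], columns=list("abc"))
    out = normalize_rows(m)          # sample sd (ddof=1) is the pinned choice
    assert np.allclose(out.values, [[-1.0, 0.0, 1.0]])
    out_pop = normalize_rows(m, ddof=0)
    assert np.allclose(out_pop.values, [[-1.2247449, 0.0, 1.2247449]])


def test_normalize_rows_mean_zero_sd_one():
    rng = np.random.default_rng(1)
    m = pd.DataFrame(rng.normal(size=(50, 5)))
    out = normalize_rows(m)
    assert np.abs(out.mean(axis=1)).max() < 1e-12
    assert np.abs(out.std(axis=1, ddof=1) - 1).max() < 1e-12
    # idempotent up to floating tolerance
    again = normalize_rows(out)
    assert np.abs(again.values - out.values).max() < 1e-9


def test_normalize_rows_drops_constant_rows_with_warning():
    m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 4.0]], index=["c", "v"])
    with pytest.warns(UserWarning, match="constant"):
        out = normalize_rows(m)
    assert list(out.index) == ["v"]


def test_identical_columns_merge_at_height_zero():
    rng = np.random.default_rng(2)
    x = rng.normal(size=100)
    m = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
    linkage, labels = cluster_cell_lines(m)
    # first merge joins a and b at distance ~0
    first = linkage[0]
    assert {labels[int(first[0])], labels[int(first[1])]} == {"a", "b"}
    assert first[2] == pytest.approx(0.0, abs=1e-12)


def test_anticorrelated_pair_merges_last():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    noise = np.array([0.3, -1.2, 0.8, -0.1, 1.1, -0.9])
    m = pd.DataFrame({"up": x, "down": -x, "noise": noise})
    dist = pearson_distance_matrix(m)
    assert dist.loc["up", "down"] == pytest.approx(2.0)
    linkage, labels = cluster_cell_lines(m)
    left, right = top_split(linkage, labels)
    # the root separates one of the anti-correlated pair from the rest
    assert {"up"} in (set(left), set(right)) or \
        {"down"} in (set(left), set(right))


def test_clustering_invariant_to_column_order():
    rng = np.random.default_rng(3)
    m = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
    l1, lab1 = cluster_cell_lines(m)
    l2, lab2 = cluster_cell_lines(m[["d", "b", "a", "c"]])
    def splits(linkage, labels):
        from scipy.cluster import hierarchy
        tree = hierarchy.to_tree(linkage)
        out = set()
        def walk(node):
            if node.is_leaf():
                return frozenset([labels[node.id]])
            left, right = walk(node.left), walk(node.right)
            out.add(frozenset([left, right]))
            return left | right
        walk(tree)
        return out
    assert splits(l1, lab1) == splits(l2, lab2)


def test_newick_serialization_parses():
    m = pd.DataFrame(np.random.default_rng(4).normal(size=(30, 3)),
                     columns=["x", "y", "z"])
    linkage, labels = cluster_cell_lines(m)
    nwk = linkage_to_newick(linkage, labels)
    assert nwk.endswith(";") and all(l in nwk for l in labels)


def test_count_tags_in_regions():
    track = TagTrack(positions={"chr1": np.array([5, 10, 15, 99, 100])})
    regions = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 10, 16),
               GenomicInterval("chr2", 0, 50)]
    assert list(count_tags_in_regions(track, regions)) == [4, 2, 0]


def test_repeat_enrichment_null_when_tracks_identical():
    rng = np.random.default_rng(5)
    pos = np.sort(rng.integers(0, 100_000, size=5_000))
    track = TagTrack(positions={"chr1": pos})
    repeats = {"LINE1": [GenomicInterval("chr1", 1_000, 2_000, name="r1")],
               "Alu": [GenomicInterval("chr1", 50_000, 51_000, name="r2")]}
    res = repeat_enrichment({"L": track}, track, repeats)
    for r in res:
        assert r.direction == "none"
        assert r.p_fisher == pytest.approx(1.0)
        assert r.p_ttest == pytest.approx(1.0)


def test_fisher_2x2_matches_enumeration():
    """Two-sided Fisher equals exhaustive hypergeometric enumeration."""
    a, b, c, d = 5, 95, 1, 99
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    # enumerate the support of the hypergeometric with fixed margins
    row1, col1, n = a + b, a + c, a + b + c + d
    probs = {}
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        probs[k] = stats.hypergeom.pmf(k, n, col1, row1)
    p_obs = probs[a]
    expected = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9))
    assert p == pytest.approx(expected, rel=1e-9)
    # symmetry under transposing the table
    _, p_t = stats.fisher_exact([[a, c], [b, d]], alternative="two-sided")
    assert p == pytest.approx(p_t, rel=1e-12)


def test_repeat_enrichment_recovers_line1_hypermethylation(small_annotations,
                                                           small_truth):
    from methylscape.synthetic import repeat_class_of, simulate_tags

    enr, inp = simulate_tags(small_annotations, small_truth, "SKMEL2", seed=6)
    by_class = {}
    for iv in small_annotations.repeats:
        by_class.setdefault(repeat_class_of(iv), []).append(iv)
    res = repeat_enrichment({"SKMEL2": enr}, inp, by_class)
    line1 = next(r for r in res if r.repeat_class == "LINE1")
    assert line1.direction == "hyper"
    assert line1.p_fisher < 0.01
    line2 = next(r for r in res if r.repeat_class == "LINE2")
    assert line2.direction == "hyper"  # input has no enrichment anywhere
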