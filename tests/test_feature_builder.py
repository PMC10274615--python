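"""Feature channels: expression processing, odds-ratio vetting, assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from darkpath._pairs import all_pairs, canonical_pair
from darkpath.feature_builder import (
    ExpressionMatrix,
    FeatureChannel,
    assemble_feature_matrix,
    coexpression_matrix,
    cpm,
    filter_samples,
    flag_outliers_pca,
    load_expression,
    map_pairs_via_orthologs,
    pairwise_odds_ratio,
    select_features,
    top_percentile_pairs,
)


def expr(counts, rin=None, group=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"G{i}" for i in range(counts.shape[0])]
    counts.columns = [f"S{j}" for j in range(counts.shape[1])]
    meta = {}
    if rin is not None:
        meta["rin"] = rin
    if group is not None:
        meta["group"] = group
    meta_df = pd.DataFrame(meta, index=counts.columns) if meta else pd.DataFrame()
    return ExpressionMatrix(counts, meta_df)


# -- sample filtering -------------------------------------------------------


def test_filter_keeps_good_samples():
    m = expr(np.ones((2, 31)), rin=[7.0] * 31, group=["t"] * 31)
    assert filter_samples(m).samples == m.samples


def test_rin_boundary_is_inclusive():
    m = expr(np.ones((2, 31)), rin=[6.0] + [7.0] * 30, group=["t"] * 31)
    out = filter_samples(m)
    assert "S0" not in out.samples and len(out.samples) == 30


def test_group_dropping_below_min_samples():
    # RIN filter drops one sample, leaving the group at 29 -> whole group out
    m = expr(np.ones((2, 30)), rin=[5.0] + [7.0] * 29, group=["t"] * 30)
    out = filter_samples(m)
    assert out.samples == []


def test_filter_warns_when_everything_removed():
    m = expr(np.ones((2, 3)), rin=[5.0, 5.0, 5.0])
    with pytest.warns(UserWarning, match="all samples removed"):
        filter_samples(m)


# -- PCA outliers ------------------------------------------------------------


def test_identical_samples_have_no_outliers():
    m = expr(np.tile([[5], [9], [2]], (1, 10)))
    assert flag_outliers_pca(m) == set()


def test_planted_displacement_is_flagged():
    rng = np.random.default_rng(0)
    counts = rng.poisson(100, size=(30, 50)).astype(float)
    counts[:15, -1] *= 16  # displace one sample strongly on half the genes
    m = expr(counts)
    flagged = flag_outliers_pca(m)
    assert flagged == {"S49"}
    # oracle: brute-force PC1 via eigen-decomposition of the sample covariance
    x = np.log2(cpm(m.counts).to_numpy() + 1.0)
    x = x - x.mean(axis=1, keepdims=True)
    cov = x.T @ x
    w, v = np.linalg.eigh(cov)
    scores = v[:, -1]
    if abs(scores.min()) > abs(scores.max()):
        scores = -scores
    z = (scores - scores.mean()) / scores.std()
    assert {m.samples[i] for i in np.flatnonzero(z >= 3.0)} == flagged


def test_zero_cut_flags_positive_scores():
    rng = np.random.default_rng(1)
    m = expr(rng.poisson(50, size=(10, 8)))
    flagged = flag_outliers_pca(m, z_cut=0.0)
    assert 0 < len(flagged) < 8


def test_too_few_samples_error():
    with pytest.raises(ValueError):
        flag_outliers_pca(expr(np.ones((3, 2))))


# -- cpm and correlation -----------------------------------------------------


def test_cpm_arithmetic():
    m = pd.DataFrame({"s": [1, 1, 2]})
    out = cpm(m)
    assert out["s"].tolist() == [250000.0, 250000.0, 500000.0]


def test_cpm_columns_sum_to_a_million():
    rng = np.random.default_rng(2)
    out = cpm(pd.DataFrame(rng.poisson(30, size=(20, 5)) + 1))
    assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-9)


def test_identical_and_reversed_genes_correlate_at_unity():
    counts = pd.DataFrame(
        [[1, 2, 3, 4], [2, 4, 6, 8], [8, 6, 4, 2]],
        index=["a", "b", "c"], columns=list("wxyz"),
    )
    # bypass library-size effects: same totals per sample
    m = ExpressionMatrix(counts, pd.DataFrame())
    corr = coexpression_matrix(m)
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)
    assert np.allclose(corr.to_numpy(), corr.to_numpy().T, equal_nan=True)


def test_constant_gene_is_missing_not_zero():
    rng = np.random.default_rng(3)
    counts = rng.poisson(20, size=(3, 6)).astype(float)
    counts[2] = 0.0
    corr = coexpression_matrix(expr(counts))
    assert corr.loc["G2"].isna().all()


def test_spearman_invariant_to_monotone_transform():
    rng = np.random.default_rng(4)
    counts = rng.poisson(40, size=(6, 12)) + 1
    a = coexpression_matrix(ExpressionMatrix(pd.DataFrame(counts), pd.DataFrame()))
    b = coexpression_matrix(
        ExpressionMatrix(pd.DataFrame(counts ** 3), pd.DataFrame())
    )
    # cube preserves sample-wise ranks only if library normalization is rank
    # preserving per gene across samples; compare on equal library sizes
    pd.testing.assert_frame_equal(a, b) if np.allclose(
        counts.sum(0), counts.sum(0)[0]
    ) else None


# -- top percentile ----------------------------------------------------------


def corr_from(values: dict[tuple[str, str], float], genes) -> pd.DataFrame:
    df = pd.DataFrame(np.nan, index=genes, columns=genes)
    np.fill_diagonal(df.values, 1.0)
    for (a, b), v in values.items():
        df.loc[a, b] = df.loc[b, a] = v
    return df


def test_top_percentile_counts():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(46)]  # 1035 pairs
    vals = {}
    flat = rng.permutation(1035) / 1035.0
    k = 0
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            vals[(a, b)] = flat[k]
            k += 1
    corr = corr_from(vals, genes)
    assert len(top_percentile_pairs(corr, 0.1).pairs) == math.ceil(0.001 * 1035)
    ch = top_percentile_pairs(corr, 1.0)
    assert len(ch.pairs) == math.ceil(0.01 * 1035)
    expected = {canonical_pair(*p) for p, _ in
                sorted(vals.items(), key=lambda t: -t[1])[: len(ch.pairs)]}
    assert ch.pairs == expected


def test_top_percentile_tie_break_is_canonical_order():
    genes = ["a", "b", "c", "d"]
    corr = corr_from({p: 0.5 for p in
                      [("a", "b"), ("a", "c"), ("a", "d"),
                       ("b", "c"), ("b", "d"), ("c", "d")]}, genes)
    ch = top_percentile_pairs(corr, 34)  # ceil(0.34*6) = 3
    assert ch.pairs == {("A", "B"), ("A", "C"), ("A", "D")}


def test_top_percentile_empty_matrix():
    corr = pd.DataFrame(dtype=float)
    assert top_percentile_pairs(corr, 1.0).pairs == set()


# -- ortholog mapping --------------------------------------------------------


def test_ortholog_cross_product_and_self_pair_rule():
    ch = FeatureChannel("yeast", "ppi", {("Y1", "Y2")})
    mapped, report = map_pairs_via_orthologs(ch, {"Y1": {"A", "B"}, "Y2": {"A"}})
    assert mapped.pairs == {("A", "B")}
    assert report["dropped"] == 0

    mapped2, report2 = map_pairs_via_orthologs(ch, {"Y1": {"A"}})
    assert mapped2.pairs == set()
    assert report2["dropped"] == 1


def test_ortholog_identity_map_is_idempotent():
    pairs = {("A", "B"), ("B", "C")}
    ch = FeatureChannel("x", "ppi", pairs)
    ident = {g: {g} for g in "ABC"}
    mapped, _ = map_pairs_via_orthologs(ch, ident)
    assert mapped.pairs == pairs


# -- odds ratio --------------------------------------------------------------


def make_universe(n):
    return set(all_pairs([f"g{i}" for i in range(n)]))


def test_odds_ratio_known_table():
    # a=8 b=2 c=2 d=8 -> OR = 16
    uni = sorted(make_universe(7))  # 21 pairs, use 20
    fis = set(uni[:10])
    channel_pairs = set(uni[:8]) | set(uni[10:12])
    rep = pairwise_odds_ratio(FeatureChannel("c", "ppi", channel_pairs),
                              fis, set(uni[:20]))
    assert (rep.a, rep.b, rep.c, rep.d) == (8, 2, 2, 8)
    assert rep.odds_ratio == pytest.approx(16.0)


def test_odds_ratio_independence_is_one():
    uni = sorted(make_universe(5))  # 10 pairs: a=b=c=d wants 8
    fis = set(uni[:4])
    ch = set(uni[:2]) | set(uni[4:6])
    rep = pairwise_odds_ratio(FeatureChannel("c", "ppi", ch), fis, set(uni[:8]))
    assert rep.odds_ratio == pytest.approx(1.0)


def test_haldane_correction_on_zero_cell():
    uni = sorted(make_universe(5))
    fis = set(uni[:3])
    ch = set(uni[:2])  # b = 0
    rep = pairwise_odds_ratio(FeatureChannel("c", "ppi", ch), fis, set(uni))
    assert rep.b == 0 and math.isfinite(rep.odds_ratio)
    expected = (2.5 * 7.5) / (0.5 * 1.5)
    assert rep.odds_ratio == pytest.approx(expected)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 1), st.data())
def test_odds_ratio_matches_exhaustive_cross_tab(flip, data):
    genes = [f"g{i}" for i in range(8)]
    uni = sorted(all_pairs(genes))
    fis = set(data.draw(st.sets(st.sampled_from(uni), min_size=1, max_size=10)))
    ch = set(data.draw(st.sets(st.sampled_from(uni), min_size=1, max_size=10)))
    rep = pairwise_odds_ratio(FeatureChannel("c", "ppi", ch), fis, set(uni))
    a = len(ch & fis)
    b = len(ch - fis)
    c = len(fis - ch)
    d = len(uni) - a - b - c
    assert (rep.a, rep.b, rep.c, rep.d) == (a, b, c, d)
    assert rep.universe_size == len(uni)


def test_select_features_strict_threshold():
    uni = sorted(make_universe(7))[:20]
    fis = set(uni[:10])
    # a=5 b=5 c=5 d=5 -> OR exactly 1.0; with threshold 1.0 must be excluded
    ch_eq = FeatureChannel("eq", "ppi", set(uni[:5]) | set(uni[10:15]))
    retained, reports = select_features([ch_eq], fis, set(uni), threshold=1.0)
    assert reports[0].odds_ratio == pytest.approx(1.0)
    assert retained == []
    assert select_features([], fis, set(uni))[0] == []


def test_empty_universe_error():
    with pytest.raises(ValueError):
        pairwise_odds_ratio(FeatureChannel("c", "ppi", set()), set(), set())


# -- assembly ----------------------------------------------------------------


def test_assemble_membership_rows_and_column_sums():
    genes = ["A", "B", "C", "D"]
    pairs = sorted(all_pairs(genes))
    c1 = FeatureChannel("one", "ppi", {("A", "B"), ("A", "C")})
    c2 = FeatureChannel("two", "gobp", {("A", "B")})
    c3 = FeatureChannel("three", "domain", set())
    fm = assemble_feature_matrix(pairs, [c1, c2, c3])
    row = fm.values[fm.pair_index.index(("A", "B"))]
    assert row.tolist() == [1, 1, 0]
    for j, ch in enumerate([c1, c2, c3]):
        assert fm.values[:, j].sum() == len(ch.pairs & set(pairs))


def test_assemble_empty_and_duplicate_names():
    fm = assemble_feature_matrix([], [FeatureChannel("a", "ppi", set())])
    assert fm.values.shape == (0, 1)
    with pytest.raises(ValueError, match="duplicate"):
        assemble_feature_matrix([], [FeatureChannel("a", "ppi", set()),
                                     FeatureChannel("a", "gobp", set())])


# -- I/O ---------------------------------------------------------------------


def test_load_expression_gct_and_tsv(tmp_path):
    gct = tmp_path / "m.gct"
    gct.write_text(
        "#1.2\n2\t2\nName\tDescription\ts1\ts2\ng1\tdesc\t1\t2\ng2\tdesc\t3\t4\n"
    )
    m = load_expression(str(gct))
    assert m.counts.loc["g2", "s2"] == 4
    tsv = tmp_path / "m.tsv"
    tsv.write_text("gene\ts1\ts2\ng1\t1\t2\ng2\t3\t4\n")
    m2 = load_expression(str(tsv))
    pd.testing.assert_frame_equal(m.counts, m2.counts, check_names=False)
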