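"""Diversity closed forms, PD, rates, niche breadth, ANOSIM, ANOVA+LSD,
regressions, and Pearson screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import n2onet as nn
from n2onet.datatypes import ConsistencyError, InsufficientDataError
from tests.test_netinfer import norm_from


def table_from(counts: dict, treatments: list) -> nn.CountTable:
    df = pd.DataFrame(counts)
    md = pd.DataFrame({"treatment": treatments}, index=df.columns)
    return nn.CountTable(df, md)


# ---------------------------------------------------------------------------
# alpha diversity


def test_single_taxon_sample():
    t = table_from({"s1": [10, 0]}, ["a"])
    d = nn.alpha_diversity(t).loc["s1"]
    assert d["shannon"] == 0.0
    assert d["simpson"] == 0.0
    assert d["pielou"] == 0.0  # flagged degenerate S=1
    assert d["coverage"] == 1.0  # no singletons


def test_even_community_closed_forms():
    t = table_from({"s1": [25, 25, 25, 25]}, ["a"])
    d = nn.alpha_diversity(t).loc["s1"]
    assert d["shannon"] == pytest.approx(np.log(4))
    assert d["pielou"] == pytest.approx(1.0)
    assert d["heip"] == pytest.approx(1.0)
    assert d["simpson"] == pytest.approx(0.75)
    assert d["coverage"] == 1.0


def test_coverage_counts_singletons():
    t = table_from({"s1": [1, 1, 8]}, ["a"])
    d = nn.alpha_diversity(t).loc["s1"]
    assert d["coverage"] == pytest.approx(1 - 2 / 10)


def test_shannon_maximal_at_even_composition():
    rng = np.random.default_rng(0)
    for _ in range(5):
        counts = rng.integers(1, 50, size=6)
        t = table_from({"s1": counts}, ["a"])
        d = nn.alpha_diversity(t).loc["s1"]
        assert d["shannon"] <= np.log(6) + 1e-12
        assert 0 <= d["simpson"] <= 1 - 1 / 6 + 1e-12


def test_faith_pd_hand_traversal():
    tree = "((A:1,B:1):1,(C:1,D:1):1);"
    assert nn.faith_pd(tree, ["A", "B"]) == pytest.approx(3.0)
    assert nn.faith_pd(tree, ["A", "C"]) == pytest.approx(4.0)
    assert nn.faith_pd(tree, ["A", "B", "C", "D"]) == pytest.approx(6.0)
    with pytest.raises(ConsistencyError):
        nn.faith_pd(tree, ["A", "Z"])


def test_alpha_diversity_with_generated_tree():
    df = pd.DataFrame({"s1": [5, 5, 1, 0], "s2": [2, 2, 2, 2]}, index=list("ABCD"))
    md = pd.DataFrame({"treatment": ["a", "a"]}, index=df.columns)
    t = nn.CountTable(df, md)
    tree = nn.generate_tree(list(t.counts.index), seed=3)
    d = nn.alpha_diversity(t, tree=tree)
    assert (d["pd"] > 0).all()
    assert d.loc["s2", "pd"] >= d.loc["s1", "pd"]  # superset of observed taxa


# ---------------------------------------------------------------------------
# N2O rate


def test_n2o_rate_linear_and_constant():
    beta, vg, vl = 0.5, 13.5, 5.0
    scale = (vg + beta * vl) / vl
    series = [(t, 2.0 * t / scale) for t in range(5)]
    assert nn.n2o_rate(series, beta, vg, vl) == pytest.approx(2.0)
    assert nn.n2o_rate([(0, 3.0), (1, 3.0), (2, 3.0)], beta, vg, vl) == 0.0


def test_n2o_rate_ols_closed_form():
    rng = np.random.default_rng(1)
    t = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
    c = 1.5 * t + rng.normal(0, 0.3, 5)
    beta, vg, vl = 0.4, 10.0, 5.0
    total = c * (vg + beta * vl) / vl
    slope = ((t - t.mean()) * (total - total.mean())).sum() / ((t - t.mean()) ** 2).sum()
    assert nn.n2o_rate(list(zip(t, c)), beta, vg, vl) == pytest.approx(slope, abs=1e-12)


def test_n2o_rate_errors():
    with pytest.raises(ValueError):
        nn.n2o_rate([(0, 1), (0, 2)], 0.5, 10, 5)
    with pytest.raises(InsufficientDataError):
        nn.n2o_rate([(0, 1)], 0.5, 10, 5)
    with pytest.raises(ValueError):
        nn.n2o_rate([(0, 1), (1, 2)], -1, 10, 5)


# ---------------------------------------------------------------------------
# niche breadth


def test_levins_breadth_closed_forms():
    t = table_from(
        {
            "s1": [10, 10, 20],
            "s2": [10, 0, 10],
            "s3": [10, 0, 10],
        },
        ["g", "g", "g"],
    )
    res = nn.levins_breadth(t, "g")
    b = res.levins_b
    assert b.iloc[0] == pytest.approx(3.0)  # uniform over 3 samples
    assert b.iloc[1] == pytest.approx(1.0)  # single sample
    assert b.iloc[2] == pytest.approx(1 / 0.375)  # q = (.5, .25, .25)
    assert res.community_mean == pytest.approx(np.mean([3.0, 1.0, 1 / 0.375]))
    assert ((b >= 1) & (b <= 3)).all()


def test_levins_breadth_scale_invariance_and_exclusion():
    t = table_from({"s1": [4, 0], "s2": [2, 0], "s3": [2, 0]}, ["g"] * 3)
    res = nn.levins_breadth(t, "g")
    assert res.n_excluded == 1
    t2 = table_from({"s1": [40, 0], "s2": [20, 0], "s3": [20, 0]}, ["g"] * 3)
    assert nn.levins_breadth(t2, "g").levins_b.iloc[0] == pytest.approx(
        res.levins_b.iloc[0]
    )


# ---------------------------------------------------------------------------
# ANOSIM


def test_anosim_hand_ranked_fixture():
    # within-distances get ranks {1,2}, between {3,4,5,6}: R = (4.5-1.5)/3 = 1
    d = np.array(
        [
            [0, 1, 3, 4],
            [1, 0, 5, 6],
            [3, 5, 0, 2],
            [4, 6, 2, 0],
        ],
        float,
    )
    r, p = nn.anosim(d, ["g1", "g1", "g2", "g2"], n_perm=999, seed=0)
    assert r == pytest.approx(1.0)


def test_anosim_all_ties_r_zero():
    d = np.ones((6, 6)) - np.eye(6)
    r, _ = nn.anosim(d, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
    assert r == pytest.approx(0.0)


def test_anosim_matches_skbio_statistic():
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import anosim as skbio_anosim

    rng = np.random.default_rng(6)
    x = rng.random((9, 4))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    ids = [f"s{i}" for i in range(9)]
    labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    ours, _ = nn.anosim(d, labels, n_perm=99, seed=0)
    ref = skbio_anosim(
        DistanceMatrix(d, ids),
        pd.DataFrame({"grp": labels}, index=ids),
        column="grp",
        permutations=0,
    )
    assert ours == pytest.approx(ref["test statistic"], abs=1e-12)


def test_anosim_r_bounded_and_p_reproducible():
    rng = np.random.default_rng(8)
    for _ in range(10):
        x = rng.random((8, 3))
        d = np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
        labels = ["a"] * 4 + ["b"] * 4
        r1, p1 = nn.anosim(d, labels, n_perm=199, seed=5)
        r2, p2 = nn.anosim(d, labels, n_perm=199, seed=5)
        assert -1 <= r1 <= 1
        assert (r1, p1) == (r2, p2)


def test_anosim_group_of_one_raises():
    d = np.zeros((3, 3))
    with pytest.raises(ValueError):
        nn.anosim(d, ["a", "a", "b"], n_perm=9, seed=0)


# ---------------------------------------------------------------------------
# ANOVA + LSD


def test_anova_two_group_closed_form():
    vals = [1, 2, 3, 7, 8, 9]
    groups = ["a"] * 3 + ["b"] * 3
    res = nn.anova_lsd(vals, groups)
    # SSB = 3*(2-5)^2 + 3*(8-5)^2 = 54, MSE = 1 -> F = 54
    assert res.f_stat == pytest.approx(54.0)
    f_ref, p_ref = stats.f_oneway([1, 2, 3], [7, 8, 9])
    assert res.f_stat == pytest.approx(f_ref)
    assert res.p_value == pytest.approx(p_ref)
    assert res.letters["a"] != res.letters["b"]


def test_anova_two_groups_f_equals_t_squared():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 8)
    res = nn.anova_lsd(np.concatenate([a, b]), ["a"] * 6 + ["b"] * 8)
    t, _ = stats.ttest_ind(a, b, equal_var=True)
    assert res.f_stat == pytest.approx(t**2)


def test_anova_equal_means_shared_letters():
    rng = np.random.default_rng(3)
    vals = rng.normal(0, 1, 12)
    res = nn.anova_lsd(vals, ["a", "b", "c"] * 4)
    assert res.p_value > 0.05
    letters = set(res.letters.values())
    assert len(letters) == 1  # all share one letter


def test_lsd_pairwise_closed_form_three_groups():
    vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 10.0, 11.0, 12.0])
    groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    res = nn.anova_lsd(vals, groups)
    means = {g: vals[np.array(groups) == g].mean() for g in "abc"}
    mse = 1.0  # every group has variance 1
    dfw = 6
    for gi, gj in [("a", "b"), ("a", "c"), ("b", "c")]:
        t = (means[gi] - means[gj]) / np.sqrt(mse * (2 / 3))
        p_hand = 2 * stats.t.sf(abs(t), dfw)
        assert res.pairwise_p.loc[gi, gj] == pytest.approx(p_hand, abs=1e-12)
    assert res.letters["c"] == "a"  # highest mean gets letter a
    assert res.letters["a"] != res.letters["c"]


def test_anova_degenerate_zero_variance():
    res = nn.anova_lsd([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
    assert res.degenerate and res.p_value == 1.0


# ---------------------------------------------------------------------------
# module regressions & Pearson screen


def make_part(assignment):
    return nn.ModulePartition(assignment=assignment, modularity_q=0.0)


def test_module_regression_perfect_fit():
    z = pd.DataFrame(
        [[-1.0, 0.0, 1.0, 2.0], [-1.0, 0.0, 1.0, 2.0]],
        index=["t1", "t2"],
        columns=list("wxyz"),
    )
    n2o = nn.N2OMeasurements(pd.Series([0.0, 1.0, 2.0, 3.0], index=list("wxyz")))
    res = nn.module_abundance_regression(z, make_part({"t1": 1, "t2": 1}), n2o)
    assert res[1].r_squared == pytest.approx(1.0)
    assert res[1].slope == pytest.approx(1.0)


def test_module_regression_orthogonal_predictor():
    z = pd.DataFrame([[1.0, -1.0, 1.0, -1.0]], index=["t1"], columns=list("wxyz"))
    n2o = nn.N2OMeasurements(pd.Series([1.0, 1.0, -1.0, -1.0], index=list("wxyz")))
    res = nn.module_abundance_regression(z, make_part({"t1": 1}), n2o)
    assert res[1].slope == pytest.approx(0.0, abs=1e-12)


def test_module_regression_degenerate_module_flagged():
    z = pd.DataFrame([[0.0, 0.0, 0.0]], index=["t1"], columns=list("xyz"))
    n2o = nn.N2OMeasurements(pd.Series([1.0, 2.0, 3.0], index=list("xyz")))
    res = nn.module_abundance_regression(z, make_part({"t1": 1}), n2o)
    assert res[1].degenerate


def test_pearson_screen_identity_and_negation():
    y = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
    feats = pd.DataFrame(
        {"same": y, "neg": -y, "flat": 1.0, "noise": [2.0, 1.5, 3.0, 2.2, 2.8]},
        index=y.index,
    )
    out = nn.pearson_screen(feats, nn.N2OMeasurements(y))
    assert out.loc["same", "r"] == pytest.approx(1.0)
    assert out.loc["neg", "r"] == pytest.approx(-1.0)
    assert out.loc["same", "stars"] == "***"
    assert bool(out.loc["flat", "excluded"])
    x = feats["noise"].to_numpy()
    yv = y.to_numpy()
    r_hand = ((x - x.mean()) * (yv - yv.mean())).sum() / (
        np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((yv - yv.mean()) ** 2).sum())
    )
    assert out.loc["noise", "r"] == pytest.approx(r_hand, abs=1e-12)
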