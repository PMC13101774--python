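"""Non-parametric group statistics, effect sizes, correlations, mode-wise OLS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from modemorph import (
    cohens_d,
    dunn_posthoc_bh,
    group_test_report,
    kruskal_wallis,
    modewise_glm,
    spearman_correlation,
)


def test_kruskal_wallis_hand_example():
    # ranks 1,2 vs 3,4: H = 12/(4*5) * (2*(1.5-2.5)^2 + 2*(3.5-2.5)^2) = 2.4
    h, p = kruskal_wallis({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    assert np.isclose(h, 2.4, atol=1e-12)


def test_kruskal_wallis_identical_data():
    h, p = kruskal_wallis({"a": [5.0, 5.0], "b": [5.0, 5.0], "c": [5.0, 5.0]})
    assert h == 0.0 and p == 1.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    shift=st.floats(-5, 5),
    scale=st.floats(0.1, 10),
)
def test_rank_tests_invariant_under_monotone_transform(shift, scale):
    rng = np.random.default_rng(12)
    groups = {
        "a": rng.normal(0, 1, 9),
        "b": rng.normal(0.8, 1, 7),
        "c": rng.normal(-0.3, 1, 8),
    }
    transformed = {g: np.exp(scale * v + shift) for g, v in groups.items()}
    h1, p1 = kruskal_wallis(groups)
    h2, p2 = kruskal_wallis(transformed)
    assert np.isclose(h1, h2, rtol=1e-12)
    d1 = dunn_posthoc_bh(groups)
    d2 = dunn_posthoc_bh(transformed)
    assert np.allclose(d1["z"], d2["z"], rtol=1e-12)


def test_dunn_two_group_reduction_matches_direct_z():
    """With two groups, Dunn's z equals the rank-sum normal approximation."""
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 11)
    b = rng.normal(1, 1, 14)
    table = dunn_posthoc_bh({"a": a, "b": b})
    # direct z from pooled mean ranks (no ties in continuous data)
    n = len(a) + len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    z_direct = (ranks[: len(a)].mean() - ranks[len(a):].mean()) / np.sqrt(
        n * (n + 1) / 12 * (1 / len(a) + 1 / len(b))
    )
    assert np.isclose(table["z"].iloc[0], z_direct, rtol=1e-12)
    assert np.isclose(table["p_adj"].iloc[0], table["p_raw"].iloc[0])


def test_dunn_pair_count_and_bh_properties():
    rng = np.random.default_rng(4)
    groups = {g: rng.normal(i, 1, 8) for i, g in enumerate("abc")}
    table = dunn_posthoc_bh(groups)
    assert len(table) == 3
    assert np.all(table["p_adj"] >= table["p_raw"] - 1e-15)
    assert np.all(table["p_adj"] <= 1.0)
    # BH fixed point: equal raw p-values stay unchanged
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.04, 0.04, 0.04], method="fdr_bh")[1]
    assert np.allclose(adj, 0.04)


def test_cohens_d_hand_example():
    assert np.isclose(cohens_d([2.0, 4.0], [1.0, 3.0]), 1.0 / np.sqrt(2), atol=1e-12)


def test_cohens_d_properties():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 10)
    assert cohens_d(a, a) == 0.0
    b = rng.normal(1, 1, 12)
    assert np.isclose(cohens_d(a, b), -cohens_d(b, a), atol=1e-12)
    with pytest.raises(ValueError, match="zero pooled"):
        cohens_d([1.0, 1.0], [1.0, 1.0])


def test_spearman_monotone_and_reversed():
    x = np.array([1.0, 2.5, 4.0, 7.1, 9.0])
    y = np.exp(x)
    rho, _ = spearman_correlation(x, y)
    assert np.isclose(rho, 1.0, atol=1e-12)
    rho_rev, _ = spearman_correlation(x, y[::-1])
    assert np.isclose(rho_rev, -1.0, atol=1e-12)


def test_spearman_tied_fixture_matches_rank_formula_oracle():
    x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 6.0])
    y = np.array([2.0, 1.0, 4.0, 4.0, 5.0, 8.0])
    rho, _ = spearman_correlation(x, y)
    # brute-force oracle: Pearson correlation of tie-averaged ranks
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert np.isclose(rho, oracle, rtol=1e-12)


def test_spearman_drops_incomplete_pairs_and_rejects_constants():
    x = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
    y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    rho, _ = spearman_correlation(x, y)
    assert rho == 1.0
    with pytest.raises(ValueError, match="constant"):
        spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="3 complete"):
        spearman_correlation([1.0, np.nan], [2.0, 3.0])


def test_glm_exact_linear_fit():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(rng.standard_normal((20, 3)), columns=["m1", "m9", "m13"])
    y = 2.0 + 1.5 * X["m1"] - 3.0 * X["m9"] + 0.7 * X["m13"]
    fit = modewise_glm(y.to_numpy(), X)
    resid = y.to_numpy() - (2.0 + X.to_numpy() @ fit["coef"].to_numpy())
    # with zero noise the fit is exact and every planted sign is recovered
    assert np.sum(resid**2) < 1e-16
    assert np.all(np.sign(fit["coef"]) == [1, -1, 1])


def test_glm_single_predictor_t_squared_equals_f():
    import statsmodels.api as sm

    rng = np.random.default_rng(7)
    x = rng.standard_normal(15)
    y = 0.5 * x + rng.standard_normal(15)
    fit = modewise_glm(y, pd.DataFrame({"x": x}))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    assert np.isclose(fit["t"].iloc[0] ** 2, model.fvalue, rtol=1e-10)


def test_glm_collinear_predictors_named():
    rng = np.random.default_rng(8)
    a = rng.standard_normal(20)
    X = pd.DataFrame({"m1": a, "m2": 2.0 * a, "m3": rng.standard_normal(20)})
    with pytest.raises(ValueError, match="m1|m2"):
        modewise_glm(rng.standard_normal(20), X)


def test_glm_requires_enough_complete_cases():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 4.0]})
    with pytest.raises(ValueError, match="complete cases"):
        modewise_glm(np.array([1.0, 2.0, 3.0]), X)


def test_group_report_structure():
    rng = np.random.default_rng(9)
    rep = group_test_report(
        "ai", {g: rng.normal(i * 0.5, 1, 10) for i, g in enumerate(["HC", "pre", "sym"])}
    )
    assert rep.variable == "ai"
    assert len(rep.pairwise) == 3
    assert {"group_a", "group_b", "z", "p_raw", "p_adj", "cohens_d"} <= set(rep.pairwise.columns)
    assert 0 < rep.p_value <= 1


def test_statistics_invariant_to_input_order():
    rng = np.random.default_rng(10)
    groups = {"a": rng.normal(0, 1, 9), "b": rng.normal(1, 1, 9)}
    shuffled = {g: rng.permutation(v) for g, v in groups.items()}
    assert np.isclose(kruskal_wallis(groups)[0], kruskal_wallis(shuffled)[0], rtol=1e-12)
    assert np.isclose(
        cohens_d(groups["a"], groups["b"]), cohens_d(shuffled["a"], shuffled["b"]), rtol=1e-12
    )
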