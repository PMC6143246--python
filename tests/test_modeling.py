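"""OLS fitting, sequential selection, nested tests, Tukey-Kramer."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from egobp import modeling as md


def _frame(**cols):
    return pd.DataFrame(cols)


# --- OLS --------------------------------------------------------------------

def test_exact_fit_recovers_line():
    tbl = _frame(y=[1.0, 2.0, 3.0], x=[1.0, 2.0, 3.0])
    fit = md.ols_fit(tbl, "y", ["x"])
    assert fit.params["x"] == pytest.approx(1.0, abs=1e-10)
    assert fit.params["Intercept"] == pytest.approx(0.0, abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0)


def test_ols_matches_closed_form_simple_regression():
    rng = np.random.default_rng(1)
    x = rng.normal(size=40)
    y = 2.0 + 0.7 * x + rng.normal(size=40)
    fit = md.ols_fit(_frame(y=y, x=x), "y", ["x"])
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    assert fit.params["x"] == pytest.approx(slope, abs=1e-10)
    assert fit.params["Intercept"] == pytest.approx(intercept, abs=1e-10)
    resid = y - intercept - slope * x
    se = np.sqrt((resid ** 2).sum() / (40 - 2) / sxx)
    assert fit.bse["x"] == pytest.approx(se, abs=1e-10)


def test_adjusted_r2_and_aic_conventions():
    rng = np.random.default_rng(2)
    tbl = _frame(y=rng.normal(size=25), x1=rng.normal(size=25),
                 x2=rng.normal(size=25))
    fit = md.ols_fit(tbl, "y", ["x1", "x2"])
    n, k = fit.n, fit.k
    assert fit.adj_r_squared == pytest.approx(
        1 - (1 - fit.r_squared) * (n - 1) / (n - k), abs=1e-12)
    # the Gaussian profile likelihood with sigma counted as a parameter
    assert fit.aic - n * (np.log(2 * np.pi * fit.rss / n) + 1) == pytest.approx(
        2 * (k + 1), abs=1e-9)


def test_slope_consistency_on_simulated_data():
    rng = np.random.default_rng(3)
    x = rng.normal(size=10_000)
    y = 2.0 * x + rng.normal(size=10_000)
    fit = md.ols_fit(_frame(y=y, x=x), "y", ["x"])
    assert abs(fit.params["x"] - 2.0) < 3 * fit.bse["x"]


def test_rank_deficiency_names_aliased_column():
    x = np.arange(10.0)
    tbl = _frame(y=np.arange(10.0), x=x, x2=2 * x)
    with pytest.raises(md.ModelingError, match="x2"):
        md.ols_fit(tbl, "y", ["x", "x2"])
    with pytest.raises(md.ModelingError):
        md.ols_fit(tbl.iloc[:2], "y", ["x", "x2"])  # n <= k


# --- nested F ---------------------------------------------------------------

def test_identical_models_give_f_zero():
    rng = np.random.default_rng(4)
    tbl = _frame(y=rng.normal(size=20), x=rng.normal(size=20))
    fit = md.ols_fit(tbl, "y", ["x"])
    f, df1, df2, p = md.nested_f_test(fit, fit)
    assert f == 0.0 and p == 1.0


def test_saturating_model_drives_p_to_zero():
    tbl = _frame(y=[1.0, 2.0, 4.0, 8.0, 9.0], x=[1.0, 2.0, 3.0, 4.0, 5.0])
    tbl["x2"] = tbl["y"]                      # full model fits exactly
    red = md.ols_fit(tbl, "y", ["x"])
    full = md.ols_fit(tbl, "y", ["x", "x2"])
    f, _, _, p = md.nested_f_test(red, full)
    assert p < 1e-12


def test_nested_f_matches_hand_arithmetic():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0])
    red = md.ols_fit(_frame(y=y), "y", [])
    full = md.ols_fit(_frame(y=y, x=x), "y", ["x"])
    # hand computation from closed-form sums
    rss0 = ((y - y.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    rss1 = rss0 - slope ** 2 * ((x - x.mean()) ** 2).sum()
    f_hand = (rss0 - rss1) / 1 / (rss1 / 6)
    f, df1, df2, p = md.nested_f_test(red, full)
    assert (df1, df2) == (1, 6)
    assert f == pytest.approx(f_hand, abs=1e-10)
    assert p == pytest.approx(float(st.f.sf(f_hand, 1, 6)), abs=1e-12)


def test_non_nested_models_rejected():
    rng = np.random.default_rng(5)
    tbl = _frame(y=rng.normal(size=20), a=rng.normal(size=20),
                 b=rng.normal(size=20))
    fa = md.ols_fit(tbl, "y", ["a"])
    fb = md.ols_fit(tbl, "y", ["b"])
    with pytest.raises(md.ModelingError):
        md.nested_f_test(fa, fb)


# --- Bonferroni --------------------------------------------------------------

@pytest.mark.parametrize("alpha,m,expected", [
    (0.05, 5, 0.01), (0.05, 1, 0.05), (0.10, 4, 0.025)])
def test_bonferroni_threshold(alpha, m, expected):
    assert md.bonferroni_threshold(alpha, m) == pytest.approx(expected)


def test_bonferroni_rejects_bad_arguments():
    with pytest.raises(md.ModelingError):
        md.bonferroni_threshold(0.05, 0)
    with pytest.raises(md.ModelingError):
        md.bonferroni_threshold(1.5, 5)


# --- sequential selection -----------------------------------------------------

def test_zero_candidates_returns_base_model():
    rng = np.random.default_rng(6)
    tbl = _frame(sbp=rng.normal(size=50), age=rng.normal(size=50),
                 bmi=rng.normal(size=50), sex=rng.integers(1, 3, 50))
    design = md.DesignSpec("sbp", haplotype_block=(), network_terms=())
    fits, trace = md.sequential_selection(design, tbl)
    assert fits["optimal"].terms == fits["base"].terms
    assert trace["optimal"] == []


def test_noise_candidate_is_usually_rejected_strong_candidate_kept():
    rng = np.random.default_rng(7)
    kept_noise = 0
    reps = 120
    for _ in range(reps):
        n = 300
        age = rng.normal(40, 10, n)
        noise = rng.normal(size=n)
        y = 0.5 * age + rng.normal(0, 5, n)
        tbl = _frame(sbp=y, age=age, bmi=rng.normal(30, 5, n),
                     sex=rng.integers(1, 3, n), cand=noise)
        design = md.DesignSpec("sbp", haplotype_block=(), network_terms=("cand",))
        fits, trace = md.sequential_selection(design, tbl)
        kept_noise += trace["optimal"][0].kept
    # a 1-df noise variable passes the AIC-decrease rule with prob ~ P(chi2 > 2)
    frac = kept_noise / reps
    assert frac < 0.25
    # a strong generating variable is essentially always kept
    n = 300
    age = rng.normal(40, 10, n)
    cand = rng.normal(size=n)
    y = 0.5 * age + 3.0 * cand + rng.normal(0, 5, n)
    tbl = _frame(sbp=y, age=age, bmi=rng.normal(30, 5, n),
                 sex=rng.integers(1, 3, n), cand=cand)
    design = md.DesignSpec("sbp", haplotype_block=(), network_terms=("cand",))
    fits, trace = md.sequential_selection(design, tbl)
    assert trace["optimal"][0].kept
    assert "cand" in fits["optimal"].terms


def test_haplotype_block_enters_as_one_unit():
    rng = np.random.default_rng(8)
    n = 400
    h2 = rng.integers(0, 2, n).astype(float)
    h3 = rng.integers(0, 2, n).astype(float)
    h4 = rng.integers(0, 3, n).astype(float)
    age = rng.normal(40, 10, n)
    y = 0.5 * age - 10 * h4 + rng.normal(0, 5, n)
    tbl = _frame(sbp=y, age=age, bmi=rng.normal(30, 5, n),
                 sex=rng.integers(1, 3, n), dosage_hap2=h2, dosage_hap3=h3,
                 dosage_hap4=h4)
    design = md.DesignSpec("sbp", network_terms=())
    fits, trace = md.sequential_selection(design, tbl)
    step = trace["optimal"][0]
    assert step.candidate == md.HAPLOTYPE_BLOCK
    assert step.kept
    # all three dosage columns travel together even though only hap4 matters
    assert set(md.HAPLOTYPE_BLOCK) <= set(fits["optimal"].terms)
    assert set(md.HAPLOTYPE_BLOCK) <= set(fits["genetic"].terms)


# --- Tukey-Kramer -----------------------------------------------------------

def test_equal_group_means_give_unit_pvalues():
    groups = ["a"] * 4 + ["b"] * 4
    values = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
    res = md.tukey_kramer(groups, values)
    assert res.pairs["q"].iloc[0] == pytest.approx(0.0)
    assert res.pairs["p_adjusted"].iloc[0] == pytest.approx(1.0)
    assert res.anova_p == pytest.approx(1.0)


def test_two_groups_reduce_to_t_test():
    rng = np.random.default_rng(9)
    a = rng.normal(0, 1, 12)
    b = rng.normal(0.8, 1, 9)
    res = md.tukey_kramer(["a"] * 12 + ["b"] * 9, np.concatenate([a, b]))
    t, p = st.ttest_ind(a, b, equal_var=True)
    assert res.pairs["q"].iloc[0] == pytest.approx(abs(t) * np.sqrt(2), abs=1e-10)
    assert res.pairs["p_adjusted"].iloc[0] == pytest.approx(p, abs=1e-9)


def test_three_balanced_groups_against_published_critical_value():
    """k = 3 groups of 5 (df = 12): the tabulated 5% studentized-range
    critical value is 3.77, so a pair with q above/below it must land on the
    corresponding side of p = 0.05."""
    spread = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])   # MSW = 0.625 exactly
    values = np.concatenate([spread, spread + 0.5, spread + 3.0])
    res = md.tukey_kramer(np.repeat(["a", "b", "c"], 5), values)
    pairs = res.pairs.set_index(["group_a", "group_b"])
    big = pairs.loc[("a", "c")]
    small = pairs.loc[("a", "b")]
    assert big["q"] > 3.77 and big["p_adjusted"] < 0.05
    assert small["q"] < 3.77 and small["p_adjusted"] > 0.05


def test_singleton_groups_allowed_single_group_rejected():
    res = md.tukey_kramer(["a", "a", "a", "b"], [1.0, 2.0, 3.0, 10.0])
    assert len(res.pairs) == 1
    assert np.isfinite(res.pairs["p_adjusted"].iloc[0])
    with pytest.raises(md.ModelingError):
        md.tukey_kramer(["a", "a"], [1.0, 2.0])


# --- interaction screen -------------------------------------------------------

def test_true_interaction_is_flagged():
    rng = np.random.default_rng(11)
    n = 1500
    age = rng.normal(40, 10, n)
    focal = rng.normal(size=n)
    y = 0.5 * age + 1.0 * focal + 0.3 * focal * age + rng.normal(0, 5, n)
    tbl = _frame(sbp=y, age=age, focal=focal)
    rep = md.screen_interactions(tbl, "focal", "sbp", ["age", "focal"])
    row = rep["interactions"].set_index("term").loc["age"]
    assert row["flagged"] and row["p_value"] < 1e-6


def test_null_interaction_rarely_flagged():
    rng = np.random.default_rng(12)
    flags = 0
    reps = 60
    for _ in range(reps):
        n = 250
        age = rng.normal(40, 10, n)
        focal = rng.normal(size=n)
        y = 0.5 * age + 1.0 * focal + rng.normal(0, 5, n)
        tbl = _frame(sbp=y, age=age, focal=focal)
        rep = md.screen_interactions(tbl, "focal", "sbp", ["age", "focal"],
                                     alpha=0.05)
        flags += int(rep["interactions"]["flagged"].iloc[0])
    assert flags / reps < 0.15    # nominal 5% plus Monte-Carlo slack


def test_constant_focal_term_raises():
    rng = np.random.default_rng(13)
    tbl = _frame(sbp=rng.normal(size=30), age=rng.normal(size=30),
                 focal=np.ones(30))
    with pytest.raises(md.ModelingError):
        md.screen_interactions(tbl, "focal", "sbp", ["age", "focal"])
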