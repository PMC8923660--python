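"""ANOVA, Tukey-Kramer, rank tests, proportion tests, binomial intervals —
each checked against an independent oracle (statsmodels, enumeration, or
direct quantile formulas)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from sacattn.stats import (UnbalancedDesignError, binomial_ci,
                           fit_factorial_anova, proportion_test, rank_tests,
                           tukey_kramer)


def balanced_table(rng, shape, n_units, effects=None):
    """Balanced factorial data: one observation per unit per cell."""
    factors = [f"f{i}" for i in range(len(shape))]
    rows = []
    for u in range(n_units):
        for cell in itertools.product(*[range(k) for k in shape]):
            val = rng.normal()
            if effects:
                for f, lv in zip(factors, cell):
                    val += effects.get(f, 0.0) * lv
            rows.append({**{f: lv for f, lv in zip(factors, cell)},
                         "unit": u, "value": val})
    return pd.DataFrame(rows), factors


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_one_factor_f_equals_t_squared(rng):
    x = rng.normal(0, 1, 12)
    y = rng.normal(0.8, 1, 12)
    df = pd.DataFrame({"g": ["a"] * 12 + ["b"] * 12,
                       "value": np.concatenate([x, y])})
    a = fit_factorial_anova(df, ["g"])
    t = sps.ttest_ind(x, y).statistic
    assert a.table.loc["g", "F"] == pytest.approx(t**2, rel=1e-10)
    assert a.table.loc["g", "p"] == pytest.approx(
        sps.ttest_ind(x, y).pvalue, rel=1e-10)


@pytest.mark.parametrize("shape,n_units,total,error", [
    ((5, 2, 3), 68, 2039, 2010),   # epoch x attention x microsaccade
    ((2, 2, 3), 68, 815, 804),     # window x attention x microsaccade
    ((2, 3), 68, 407, 402),        # window x microsaccade (delta analyses)
    ((2, 2, 2), 68, 543, 536),     # position-matched: msacc has 2 levels
])
def test_printed_dof_arithmetic(rng, shape, n_units, total, error):
    """Balanced designs with the published cell structure reproduce the
    printed total/error degrees of freedom exactly."""
    df, factors = balanced_table(rng, shape, n_units)
    a = fit_factorial_anova(df, factors)
    assert a.df_total == total
    assert a.df_error == error


def test_sums_of_squares_match_statsmodels(rng):
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df, factors = balanced_table(rng, (3, 2, 2), 4,
                                 effects={"f0": 0.5, "f1": -0.3})
    a = fit_factorial_anova(df, factors)
    model = ols("value ~ C(f0) * C(f1) * C(f2)", data=df).fit()
    oracle = sm.stats.anova_lm(model, typ=1)
    key = {"f0": "C(f0)", "f1": "C(f1)", "f2": "C(f2)",
           "f0:f1": "C(f0):C(f1)", "f0:f2": "C(f0):C(f2)",
           "f1:f2": "C(f1):C(f2)", "f0:f1:f2": "C(f0):C(f1):C(f2)",
           "error": "Residual"}
    for term, oterm in key.items():
        assert a.table.loc[term, "sum_sq"] == pytest.approx(
            oracle.loc[oterm, "sum_sq"], rel=1e-8)
        assert a.table.loc[term, "df"] == oracle.loc[oterm, "df"]


def test_factor_order_invariance(rng):
    df, factors = balanced_table(rng, (2, 3, 2), 5, effects={"f1": 0.4})
    a = fit_factorial_anova(df, factors)
    b = fit_factorial_anova(df, factors[::-1])
    for f in factors:
        assert a.table.loc[f, "sum_sq"] == pytest.approx(
            b.table.loc[f, "sum_sq"], rel=1e-10)


def test_unbalanced_and_empty_cells_rejected(rng):
    df, factors = balanced_table(rng, (2, 2), 4)
    with pytest.raises(UnbalancedDesignError, match="unequal"):
        fit_factorial_anova(df.iloc[:-1], factors)
    gone = df[~((df.f0 == 1) & (df.f1 == 1))]
    with pytest.raises(UnbalancedDesignError, match="empty cells"):
        fit_factorial_anova(gone, factors)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1),
       st.lists(st.integers(2, 4), min_size=1, max_size=3),
       st.integers(2, 6))
def test_dof_identities_hold(seed, shape, n_units):
    rng = np.random.default_rng(seed)
    df, factors = balanced_table(rng, tuple(shape), n_units)
    a = fit_factorial_anova(df, factors)
    n = len(df)
    assert a.df_total == n - 1
    terms = a.table.drop(index=["error", "total"])
    assert a.df_error == a.df_total - terms["df"].sum()
    assert a.table["sum_sq"].drop(index="total").sum() == pytest.approx(
        a.table.loc["total", "sum_sq"], rel=1e-8, abs=1e-10)


# ---------------------------------------------------------------------------
# Tukey-Kramer
# ---------------------------------------------------------------------------

def test_tukey_identical_means_p_one():
    df = pd.DataFrame({"g": list("aabbcc") * 3,
                       "value": [1.0, 2.0] * 9})
    a = fit_factorial_anova(df, ["g"])
    res = tukey_kramer(a)
    assert (res["q"] == 0).all()
    assert (res["p_adj"] == 1.0).all()


def test_tukey_equal_n_matches_hsd_oracle(rng):
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    vals = rng.normal(0, 1, 30) + np.repeat([0.0, 0.6, 1.1], 10)
    df = pd.DataFrame({"g": np.repeat(list("abc"), 10), "value": vals})
    a = fit_factorial_anova(df, ["g"])
    ours = tukey_kramer(a)
    oracle = pairwise_tukeyhsd(df["value"], df["g"])
    got = {tuple(sorted((r.cell_a[0], r.cell_b[0]))): r for r in
           ours.itertuples()}
    for row, p, d in zip(oracle._results_table.data[1:],
                         oracle.pvalues, oracle.meandiffs):
        r = got[tuple(sorted((row[0], row[1])))]
        assert r.p_adj == pytest.approx(p, abs=1e-6)
        assert abs(r.diff) == pytest.approx(abs(d), rel=1e-10)


def test_tukey_p_monotone_in_difference(rng):
    df = pd.DataFrame({"g": np.repeat(list("ab"), 8),
                       "value": rng.normal(0, 1, 16)})
    a = fit_factorial_anova(df, ["g"])
    ps = []
    for shift in (0.1, 0.5, 1.0, 2.0):
        cm = a.cell_means.copy()
        a2 = type(a)(table=a.table, factors=a.factors, levels=a.levels,
                     cell_means=cm.assign(
                         mean=np.where(cm["g"] == "a", 0.0, shift)),
                     mse=a.mse, df_error=a.df_error)
        ps.append(tukey_kramer(a2)["p_adj"].iloc[0])
    assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# rank tests vs enumeration oracles
# ---------------------------------------------------------------------------

def _ranksum_enumeration_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mid = len(x) * len(y) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
        total += 1
    return count / total


def _signed_rank_enumeration_p(x, y):
    """Exact two-sided signed-rank p by enumerating all sign flips."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mid = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if abs(w - mid) >= abs(w_obs - mid) - 1e-12:
            count += 1
    return count / 2**n


@pytest.mark.parametrize("x,y", [
    ([1.2, 3.4, 0.1, 5.2], [2.2, 4.1, 6.3, 7.7, 0.5]),
    ([10, 12, 14, 9], [11, 13, 20]),
    ([0.5, 1.5, 2.5, 3.5, 4.5], [0.1, 0.2, 5.0]),
])
def test_ranksum_small_sample_equals_enumeration(x, y):
    _, p = rank_tests(x, y, paired=False)
    assert p == pytest.approx(_ranksum_enumeration_p(x, y), abs=1e-12)


@pytest.mark.parametrize("x,y", [
    ([1.0, 2.5, 3.1, 4.0, 5.5, 6.1], [0.5, 2.0, 4.2, 3.0, 5.0, 7.5]),
    ([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.6, 5.3],
     [2.0, 2.0, 3.5, 2.5, 4.0, 8.0, 3.6, 4.3]),
])
def test_signed_rank_small_sample_equals_enumeration(x, y):
    _, p = rank_tests(x, y, paired=True)
    assert p == pytest.approx(_signed_rank_enumeration_p(x, y), abs=1e-12)


def test_rank_test_degenerate_inputs():
    with pytest.warns(UserWarning):
        stat, p = rank_tests([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], paired=True)
    assert p == 1.0
    with pytest.warns(UserWarning):
        _, p = rank_tests([2.0, 2.0], [2.0, 2.0, 2.0], paired=False)
    assert p == 1.0
    with pytest.raises(ValueError, match="equal lengths"):
        rank_tests([1.0], [1.0, 2.0], paired=True)


def test_rank_test_power_matches_monte_carlo(rng):
    """Rejection rate under a location shift tracks a Monte-Carlo oracle."""
    n_rep, shift, n = 400, 1.0, 15
    rej = 0
    for _ in range(n_rep):
        x = rng.normal(0, 1, n)
        y = rng.normal(shift, 1, n)
        if rank_tests(x, y)[1] < 0.05:
            rej += 1
    # oracle: same Monte-Carlo with scipy directly
    rng2 = np.random.default_rng(999)
    rej_o = sum(sps.mannwhitneyu(rng2.normal(0, 1, n),
                                 rng2.normal(shift, 1, n),
                                 alternative="two-sided").pvalue < 0.05
                for _ in range(n_rep))
    se = np.sqrt(0.25 / n_rep) * 2
    assert abs(rej / n_rep - rej_o / n_rep) < 3 * se


# ---------------------------------------------------------------------------
# proportions
# ---------------------------------------------------------------------------

def test_proportion_test_matches_scipy_oracle():
    for k1, n1, k2, n2 in [(8, 10, 3, 12), (50, 100, 60, 100), (1, 30, 5, 20)]:
        stat, p = proportion_test(k1, n1, k2, n2)
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
        o = sps.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(o.statistic, rel=1e-12)
        assert p == pytest.approx(o.pvalue, rel=1e-12)


def test_proportion_test_edge_cases():
    stat, p = proportion_test(5, 10, 10, 20)  # identical proportions
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert proportion_test(0, 10, 0, 15) == (0.0, 1.0)
    with pytest.raises(ValueError, match="outside"):
        proportion_test(11, 10, 1, 10)


def test_binomial_ci_examples_and_oracle():
    assert binomial_ci(10, 10)[1] == 1.0
    assert binomial_ci(0, 7)[0] == 0.0
    lo, hi = binomial_ci(8, 10)
    assert lo == pytest.approx(sps.beta.ppf(0.025, 8, 3), abs=1e-10)
    assert hi == pytest.approx(sps.beta.ppf(0.975, 9, 2), abs=1e-10)
    # independent scipy implementation of the exact interval
    ci = sps.binomtest(8, 10).proportion_ci(method="exact")
    assert lo == pytest.approx(ci.low, abs=1e-10)
    assert hi == pytest.approx(ci.high, abs=1e-10)
    with pytest.raises(ValueError):
        binomial_ci(5, 0)
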