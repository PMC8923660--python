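"""Statistical machinery: balanced fixed-effects full-factorial ANOVA with
Tukey-Kramer post hoc comparisons, rank tests, proportion tests, and
Clopper-Pearson binomial intervals.

The ANOVA operates on one scalar observation per unit per cell (unit
identity is not a factor), so a balanced design with U units and cells
C1 x C2 x ... has total d.o.f. U * prod(C) - 1 and error d.o.f. equal to
total minus the sum of all main-effect and interaction d.o.f.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class UnbalancedDesignError(ValueError):
    """Raised when cell counts are unequal (or a cell is empty)."""


@dataclass
class AnovaTable:
    """Fitted factorial ANOVA: term table plus what Tukey-Kramer needs."""

    table: pd.DataFrame  # index: term names + 'error'/'total'; df, sum_sq, mean_sq, F, p
    factors: list[str]
    levels: dict[str, list]
    cell_means: pd.DataFrame  # one row per cell: factor columns + mean + n
    mse: float
    df_error: int
    provenance: dict = field(default_factory=dict)

    @property
    def df_total(self) -> int:
        return int(self.table.loc["total", "df"])


def fit_factorial_anova(data: pd.DataFrame, factors: list[str],
                        value: str = "value") -> AnovaTable:
    """Fixed-effects full-factorial ANOVA on a balanced design.

    All main effects and interactions are included.  Sums of squares are
    computed from marginal means by inclusion-exclusion (Type I; identical
    to II/III on balanced data).  Unbalanced or incomplete designs raise
    ``UnbalancedDesignError`` listing the offending cells.
    """
    if len(factors) < 1:
        raise ValueError("need at least one factor")
    data = data.dropna(subset=[value])
    levels = {f: sorted(pd.unique(data[f])) for f in factors}
    for f, lv in levels.items():
        if len(lv) < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels, has {len(lv)}")

    counts = data.groupby(factors, sort=True).size()
    if len(factors) == 1:
        counts.index = pd.MultiIndex.from_arrays([counts.index], names=factors)
    full_index = pd.MultiIndex.from_product([levels[f] for f in factors],
                                            names=factors)
    counts = counts.reindex(full_index, fill_value=0)
    if counts.min() == 0:
        empty = [dict(zip(factors, idx if isinstance(idx, tuple) else (idx,)))
                 for idx in counts[counts == 0].index]
        raise UnbalancedDesignError(f"empty cells: {empty}")
    if counts.nunique() > 1:
        raise UnbalancedDesignError(
            f"unequal cell counts (min {counts.min()}, max {counts.max()}); "
            "balance the design (e.g. via condition matching) first")

    y = data[value].to_numpy(dtype=float)
    N = y.size
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    effects: dict[tuple[str, ...], pd.Series] = {}
    rows = []
    model_df = 0
    model_ss = 0.0
    for size in range(1, len(factors) + 1):
        for S in itertools.combinations(factors, size):
            margin = data.groupby(list(S), sort=True)[value].mean()
            if size == 1:
                margin.index = pd.MultiIndex.from_arrays(
                    [margin.index], names=[S[0]])
            eff = margin - grand
            for tsize in range(1, size):
                for T in itertools.combinations(S, tsize):
                    sub = effects[T]
                    # broadcast the lower-order effect over the S margin
                    key = [margin.index.get_level_values(f) for f in T]
                    eff = eff - sub.reindex(
                        pd.MultiIndex.from_arrays(key, names=list(T))).to_numpy()
            effects[S] = eff
            reps = N / len(margin)  # observations per margin cell
            ss = float(reps * (eff.to_numpy() ** 2).sum())
            df_term = int(np.prod([len(levels[f]) - 1 for f in S]))
            rows.append({"term": ":".join(S), "df": df_term, "sum_sq": ss})
            model_df += df_term
            model_ss += ss

    df_total = N - 1
    df_error = df_total - model_df
    ss_error = ss_total - model_ss
    if df_error <= 0:
        raise ValueError("no error degrees of freedom (one observation per cell)")
    mse = ss_error / df_error

    table_rows = []
    for r in rows:
        ms = r["sum_sq"] / r["df"]
        F = ms / mse if mse > 0 else np.inf
        table_rows.append({**r, "mean_sq": ms, "F": F,
                           "p": float(sps.f.sf(F, r["df"], df_error))})
    table_rows.append({"term": "error", "df": df_error, "sum_sq": ss_error,
                       "mean_sq": mse, "F": np.nan, "p": np.nan})
    table_rows.append({"term": "total", "df": df_total, "sum_sq": ss_total,
                       "mean_sq": np.nan, "F": np.nan, "p": np.nan})
    table = pd.DataFrame(table_rows).set_index("term")

    # d.o.f. and SS identities, asserted on every fit
    assert int(table.drop(index=["total"])["df"].sum()) == df_total
    if ss_total > 0:
        assert abs(table.drop(index=["total"])["sum_sq"].sum() - ss_total) \
            <= 1e-8 * ss_total + 1e-12

    cm = data.groupby(factors, sort=True)[value].agg(["mean", "size"])
    cell_means = cm.reset_index().rename(columns={"size": "n"})
    return AnovaTable(table=table, factors=list(factors), levels=levels,
                      cell_means=cell_means, mse=float(mse),
                      df_error=int(df_error))


def tukey_kramer(
    anova: AnovaTable,
    comparisons: list[tuple[tuple, tuple]] | None = None,
) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons of design cells.

    Each cell is a tuple of factor levels in ``anova.factors`` order.  For a
    pair the standard error is ``sqrt(MSE/2 * (1/n1 + 1/n2))``, the
    statistic ``q = |m1 - m2| / SE``, and the adjusted p comes from the
    studentized-range distribution with the full family's group count and
    the error d.o.f.  With equal cell sizes this is exactly Tukey's HSD.
    By default every cell pair is compared.
    """
    cm = anova.cell_means.set_index(anova.factors)
    cells = list(cm.index)
    k = len(cells)
    if comparisons is None:
        comparisons = list(itertools.combinations(cells, 2))
    rows = []
    for a, b in comparisons:
        a = a if isinstance(a, tuple) else (a,)
        b = b if isinstance(b, tuple) else (b,)
        key_a = a if len(anova.factors) > 1 else a[0]
        key_b = b if len(anova.factors) > 1 else b[0]
        if key_a not in cm.index or key_b not in cm.index:
            rows.append({"cell_a": a, "cell_b": b, "diff": np.nan, "se": np.nan,
                         "q": np.nan, "p_adj": np.nan, "skipped": True})
            continue
        ma, na = cm.loc[key_a, "mean"], cm.loc[key_a, "n"]
        mb, nb = cm.loc[key_b, "mean"], cm.loc[key_b, "n"]
        if na == 0 or nb == 0:
            rows.append({"cell_a": a, "cell_b": b, "diff": np.nan, "se": np.nan,
                         "q": np.nan, "p_adj": np.nan, "skipped": True})
            continue
        se = float(np.sqrt(anova.mse / 2.0 * (1.0 / na + 1.0 / nb)))
        diff = float(ma - mb)
        q = abs(diff) / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, k, anova.df_error)) if np.isfinite(q) else 0.0
        rows.append({"cell_a": a, "cell_b": b, "diff": diff, "se": se,
                     "q": q, "p_adj": min(max(p, 0.0), 1.0), "skipped": False})
    return pd.DataFrame(rows)


def rank_tests(x, y, paired: bool = False) -> tuple[float, float]:
    """Two-sided Wilcoxon test: signed-rank when paired, rank-sum otherwise.

    Policy: scipy's ``method='auto'`` -- the exact null distribution for
    small samples without ties, the tie-corrected normal approximation
    otherwise.  Fully tied data return p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal lengths")
        if np.all(x == y):
            warnings.warn("all paired differences are zero; p = 1")
            return 0.0, 1.0
        res = sps.wilcoxon(x, y, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("all observations tied; p = 1")
        return float(x.size * y.size / 2.0), 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """2x2 chi-square test of equal proportions, no continuity correction."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"k={k} outside [0, n={n}]")
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:  # a pooled proportion of exactly 0 or 1
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / denom
    return float(stat), float(sps.chi2.sf(stat, 1))


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson (exact) confidence interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
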