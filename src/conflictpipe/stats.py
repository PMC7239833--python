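"""The study's statistical battery as self-contained procedures.

Paired and unpaired t tests, one-way repeated-measures ANOVA with
Bonferroni post hocs, two-way between-subjects ANOVA, mixed two-way
repeated-measures ANOVA, and Pearson correlation.  The ANOVAs are
balanced-design sums-of-squares decompositions written directly in
numpy — fast enough for large null-simulation batteries — with p values
from scipy's F and t distributions.  All tests are two-sided at
alpha = 0.05 unless stated otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "paired_t",
    "unpaired_t",
    "rm_anova_1way",
    "anova_2way",
    "pearson_r",
]


@dataclass(frozen=True)
class TestResult:
    """One test statistic with its degrees of freedom and p value."""

    effect: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    adjusted_p: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p value outside [0, 1]")


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def paired_t(x, y=None) -> TestResult:
    """Paired t test; pass paired samples ``(x, y)`` or differences ``x``.

    Zero-variance differences are flagged ``degenerate``: identical
    pairs give t = 0 (p = 1); a constant non-zero difference has no
    finite t and raises.
    """
    d = _as_array(x) - (_as_array(y) if y is not None else 0.0)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    mean = d.mean()
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TestResult("paired", 0.0, (float(df),), 1.0, degenerate=True)
        raise ValueError("zero variance of differences with non-zero mean")
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("paired", float(t), (float(df),), float(p))


def unpaired_t(x, y) -> TestResult:
    """Two-sample t test with pooled variance (equal-variance form)."""
    x, y = _as_array(x), _as_array(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult("unpaired", float(t), (float(len(x) + len(y) - 2),), float(p))


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction factor."""
    S = np.cov(data, rowvar=False, ddof=1)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * grand**2)
    return float(num / den) if den > 0 else 1.0


def _rm_table_to_array(table: pd.DataFrame, subject: str, within: str,
                       response: str) -> np.ndarray:
    wide = table.pivot(index=subject, columns=within, values=response)
    if wide.isna().any().any():
        raise ValueError("incomplete subject x level table")
    return wide.to_numpy(dtype=float)


def rm_anova_1way(
    data,
    subject: str = "subject",
    within: str = "level",
    response: str = "response",
    posthoc: bool = False,
    gg: bool = False,
) -> list[TestResult]:
    """One-way repeated-measures ANOVA (within-subjects factor).

    ``data`` is either a subjects x levels array or a long DataFrame
    with the named columns.  The subject effect is removed from the
    error term: ``F = MS_condition / MS_error`` on
    ``(k-1, (k-1)(s-1))`` degrees of freedom.  ``posthoc=True`` appends
    all-pairs paired t tests with Bonferroni-adjusted p values;
    ``gg=True`` applies the Greenhouse-Geisser correction.
    """
    if isinstance(data, pd.DataFrame):
        Y = _rm_table_to_array(data, subject, within, response)
        levels = list(data.pivot(index=subject, columns=within, values=response).columns)
    else:
        Y = _as_array(data)
        levels = list(range(Y.shape[1]))
    s, k = Y.shape
    if s < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 levels")
    grand = Y.mean()
    ss_cond = s * float(((Y.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((Y.mean(axis=1) - grand) ** 2).sum())
    ss_tot = float(((Y - grand) ** 2).sum())
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (s - 1)
    ms_err = ss_err / df2
    F = (ss_cond / df1) / ms_err if ms_err > 0 else 0.0
    eps = _gg_epsilon(Y) if gg else 1.0
    p = float(sps.f.sf(F, df1 * eps, df2 * eps)) if ms_err > 0 else 1.0
    results = [TestResult(within, float(F), (float(df1 * eps), float(df2 * eps)), p,
                          degenerate=ms_err <= 0)]
    if posthoc:
        pairs = list(itertools.combinations(range(k), 2))
        m = len(pairs)
        for i, j in pairs:
            try:
                res = paired_t(Y[:, i], Y[:, j])
            except ValueError:
                continue
            results.append(
                TestResult(
                    f"{levels[i]} vs {levels[j]}", res.statistic, res.df,
                    res.p_value, adjusted_p=min(1.0, m * res.p_value),
                    degenerate=res.degenerate,
                )
            )
    return results


def _check_balanced(counts: np.ndarray) -> int:
    uniq = np.unique(counts)
    if len(uniq) != 1:
        raise ValueError("unbalanced design is not supported")
    return int(uniq[0])


def anova_2way(
    table: pd.DataFrame,
    factor_a: str = "A",
    factor_b: str = "B",
    response: str = "response",
    repeated_on: str | None = None,
    subject: str = "subject",
) -> list[TestResult]:
    """Balanced two-way ANOVA; mixed design when ``repeated_on`` is set.

    Fully between-subjects by default (both factors crossed, n per cell
    equal).  With ``repeated_on`` naming the within-subjects factor, the
    split-plot decomposition is used: the between factor is tested
    against subjects-within-groups, the within factor and interaction
    against the within-subjects residual.
    Returns results for both main effects and the interaction.
    """
    for col in (factor_a, factor_b, response):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if repeated_on is None:
        return _anova_2way_between(table, factor_a, factor_b, response)
    between = factor_b if repeated_on == factor_a else factor_a
    return _anova_2way_mixed(table, between, repeated_on, response, subject)


def _anova_2way_between(table, fa, fb, response) -> list[TestResult]:
    a_levels = np.sort(table[fa].unique())
    b_levels = np.sort(table[fb].unique())
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 1:
        raise ValueError("need at least 2 levels of the first factor")
    counts = table.groupby([fa, fb], observed=True)[response].count()
    if len(counts) != a * b:
        raise ValueError("empty design cell")
    n = _check_balanced(counts.to_numpy())
    if n < 2:
        raise ValueError("need at least 2 observations per cell")
    y = table[response].to_numpy(dtype=float)
    grand = y.mean()
    cell = table.groupby([fa, fb], observed=True)[response].mean().unstack().to_numpy()
    mean_a = cell.mean(axis=1)
    mean_b = cell.mean(axis=0)
    ss_a = b * n * float(((mean_a - grand) ** 2).sum())
    ss_b = a * n * float(((mean_b - grand) ** 2).sum())
    ss_ab = n * float(
        ((cell - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    )
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_a - ss_b - ss_ab
    df_err = a * b * (n - 1)
    ms_err = ss_err / df_err
    out = []
    for name, ss, df in (
        (fa, ss_a, a - 1),
        (fb, ss_b, b - 1),
        (f"{fa} x {fb}", ss_ab, (a - 1) * (b - 1)),
    ):
        if ms_err > 0:
            F = (ss / df) / ms_err
            p = float(sps.f.sf(F, df, df_err))
        else:
            F, p = 0.0, 1.0
        out.append(TestResult(name, float(F), (float(df), float(df_err)), p,
                              degenerate=ms_err <= 0))
    return out


def _anova_2way_mixed(table, between, within, response, subject) -> list[TestResult]:
    if subject not in table.columns:
        raise ValueError(f"missing column {subject!r}")
    wide = table.pivot_table(index=[subject, between], columns=within,
                             values=response, aggfunc="mean", observed=True)
    if wide.isna().any().any():
        raise ValueError("incomplete subject x within-level table")
    groups = wide.index.get_level_values(between).to_numpy()
    Y = wide.to_numpy(dtype=float)
    g_levels = np.sort(np.unique(groups))
    g, w = len(g_levels), Y.shape[1]
    if g < 2 or w < 2:
        raise ValueError("need at least 2 levels of each factor")
    per_group = np.array([(groups == lev).sum() for lev in g_levels])
    n = _check_balanced(per_group)
    if n < 2:
        raise ValueError("need at least 2 subjects per group")
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = np.array([Y[groups == lev].mean() for lev in g_levels])
    within_means = Y.mean(axis=0)
    cell_means = np.vstack([Y[groups == lev].mean(axis=0) for lev in g_levels])
    ss_between_subj = w * float(((subj_means - grand) ** 2).sum())
    ss_g = n * w * float(((group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_g
    ss_w = g * n * float(((within_means - grand) ** 2).sum())
    ss_gw = n * float(
        ((cell_means - group_means[:, None] - within_means[None, :] + grand) ** 2).sum()
    )
    ss_tot = float(((Y - grand) ** 2).sum())
    ss_err_w = ss_tot - ss_between_subj - ss_w - ss_gw
    df_g, df_sw = g - 1, g * (n - 1)
    df_w, df_gw, df_err = w - 1, (g - 1) * (w - 1), g * (n - 1) * (w - 1)
    ms_sw = ss_subj_within / df_sw
    ms_err = ss_err_w / df_err
    out = []
    for name, ss, df, ms_denom, df_denom in (
        (between, ss_g, df_g, ms_sw, df_sw),
        (within, ss_w, df_w, ms_err, df_err),
        (f"{between} x {within}", ss_gw, df_gw, ms_err, df_err),
    ):
        if ms_denom > 0:
            F = (ss / df) / ms_denom
            p = float(sps.f.sf(F, df, df_denom))
        else:
            F, p = 0.0, 1.0
        out.append(TestResult(name, float(F), (float(df), float(df_denom)), p,
                              degenerate=ms_denom <= 0))
    return out


def pearson_r(x, y) -> TestResult:
    """Product-moment correlation with a t-based two-sided p value."""
    x, y = _as_array(x), _as_array(y)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return TestResult("pearson", float(r), (float(len(x) - 2),), float(p))
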