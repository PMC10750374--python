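"""Group-comparison statistics: t-tests, chi-square, balanced mixed-design
ANOVA, simple effects, Benjamini-Hochberg FDR and metric-score correlation.

The mixed ANOVA is the classical balanced split-plot decomposition:
between-subject variation splits into the group effect and subjects
within groups (the group error term); within-subject variation splits
into the within factor, the interaction and the residual. No sphericity
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError, UndefinedStatisticError


@dataclass
class StatResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_raw: float
    p_adjusted: float | None = None
    comparison: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_raw <= 1:
            raise InvalidParameterError("p_raw outside [0, 1]")


# ---------------------------------------------------------------------------
# t-tests and chi-square

def ttest_independent(x=None, y=None, *, summary_x=None, summary_y=None,
                      welch: bool = False, comparison: str = "") -> StatResult:
    """Two-sided independent-samples t (pooled variance by default).

    Accepts raw samples or printed (n, mean, sd) summaries.
    """
    if summary_x is not None:
        n1, m1, s1 = summary_x
        n2, m2, s2 = summary_y
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n1, m1, s1 = len(x), x.mean(), x.std(ddof=1)
        n2, m2, s2 = len(y), y.mean(), y.std(ddof=1)
    if n1 < 2 or n2 < 2:
        raise InvalidParameterError("need n >= 2 per group")
    if s1 <= 0 and s2 <= 0:
        if m1 == m2:
            return StatResult("t_independent", 0.0, (float(n1 + n2 - 2),), 1.0,
                              comparison=comparison)
        raise UndefinedStatisticError("degenerate variance in both groups")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                   equal_var=not welch)
    df = n1 + n2 - 2 if not welch else res.df if hasattr(res, "df") else np.nan
    name = "t_welch" if welch else "t_independent"
    return StatResult(name, float(res.statistic), (float(df),),
                      float(res.pvalue), comparison=comparison)


def ttest_paired(x, y, comparison: str = "") -> StatResult:
    """Two-sided paired t on the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise InvalidParameterError("need equal-length samples, n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        raise UndefinedStatisticError("zero-variance differences")
    res = sps.ttest_rel(x, y)
    return StatResult("t_paired", float(res.statistic), (float(len(x) - 1),),
                      float(res.pvalue), comparison=comparison)


def chi2_2x2(table, yates: bool = True, comparison: str = "") -> StatResult:
    """Pearson chi-square on a 2x2 count table (optional Yates correction)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise InvalidParameterError("need a nonnegative 2x2 table")
    if not np.allclose(table, np.round(table)):
        raise InvalidParameterError("counts must be integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise UndefinedStatisticError("zero margin in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=yates)
    return StatResult("chi2_pearson", float(chi2), (float(dof),), float(p),
                      comparison=comparison)


# ---------------------------------------------------------------------------
# FDR

def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Mixed-design (split-plot) ANOVA

def _pivot_balanced(data: pd.DataFrame, dv: str, within: str, between: str,
                    subject: str) -> tuple[np.ndarray, list, list]:
    """subject x within value matrix plus group assignment, or raise."""
    counts = data.groupby([between, within], observed=True)[dv].count()
    if counts.nunique() != 1:
        raise InvalidParameterError(
            f"unbalanced design; per-cell counts:\n{counts}")
    wide = data.pivot_table(index=[between, subject], columns=within,
                            values=dv, observed=True)
    if wide.isna().any().any():
        raise InvalidParameterError("missing cells in the design")
    groups = wide.index.get_level_values(0)
    return wide.to_numpy(), list(groups), list(wide.columns)


def mixed_anova(data: pd.DataFrame, dv: str = "value", within: str = "within",
                between: str = "between", subject: str = "subject",
                ) -> dict[str, StatResult]:
    """Balanced mixed ANOVA: between main, within main, interaction.

    Returns results keyed 'between', 'within', 'interaction'; each
    carries its sums of squares in ``extras``.
    """
    y, groups, w_levels = _pivot_balanced(data, dv, within, between, subject)
    groups = np.asarray(groups)
    g_levels = sorted(set(groups))
    g, w = len(g_levels), len(w_levels)
    n = len(y) // g
    if g < 2 or w < 2:
        raise InvalidParameterError("need >= 2 levels per factor")
    if n < 2:
        raise InvalidParameterError("need >= 2 subjects per group")
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    subj_means = y.mean(axis=1)
    ss_between_subj = w * ((subj_means - grand) ** 2).sum()
    group_means = np.array([subj_means[groups == gl].mean() for gl in g_levels])
    ss_group = n * w * ((group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    w_means = y.mean(axis=0)
    ss_within_factor = g * n * ((w_means - grand) ** 2).sum()
    cell_means = np.array([y[groups == gl].mean(axis=0) for gl in g_levels])
    ss_cells = n * ((cell_means - grand) ** 2).sum()
    ss_interaction = ss_cells - ss_group - ss_within_factor
    ss_within_total = ss_total - ss_between_subj
    ss_error = ss_within_total - ss_within_factor - ss_interaction
    df_group, df_swg = g - 1, g * (n - 1)
    df_w, df_gw = w - 1, (g - 1) * (w - 1)
    df_err = df_swg * df_w

    tol = 1e-10 * max(ss_total, 1e-30)

    def _f(ss_effect: float, df_effect: int, ss_err: float, df_e: int,
           name: str) -> StatResult:
        ms_e = ss_err / df_e
        if ms_e <= tol:
            # a constant-sum dependent variable (e.g. coverage) makes the
            # between-subject error vanish; the effect is then exactly null
            if ss_effect <= tol:
                return StatResult(f"mixed_anova_{name}", 0.0,
                                  (float(df_effect), float(df_e)), 1.0,
                                  extras={"ss_effect": 0.0, "ss_error": 0.0,
                                          "ss_total": float(ss_total)})
            raise UndefinedStatisticError(f"zero error variance for {name}")
        f = (ss_effect / df_effect) / ms_e
        p = float(sps.f.sf(f, df_effect, df_e))
        return StatResult(f"mixed_anova_{name}", float(f),
                          (float(df_effect), float(df_e)), p,
                          extras={"ss_effect": float(ss_effect),
                                  "ss_error": float(ss_err),
                                  "ss_total": float(ss_total)})

    return {
        "between": _f(ss_group, df_group, ss_subj_within, df_swg, "between"),
        "within": _f(ss_within_factor, df_w, ss_error, df_err, "within"),
        "interaction": _f(ss_interaction, df_gw, ss_error, df_err,
                          "interaction"),
    }


def rm_oneway(y: np.ndarray) -> StatResult:
    """One-way repeated-measures ANOVA on a subject x level matrix."""
    y = np.asarray(y, dtype=float)
    n, w = y.shape
    if w < 2 or n < 2:
        raise InvalidParameterError("need >= 2 levels and >= 2 subjects")
    grand = y.mean()
    ss_w = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = w * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_w - ss_subj
    df_w, df_err = w - 1, (n - 1) * (w - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        raise UndefinedStatisticError("zero error variance")
    f = (ss_w / df_w) / ms_err
    return StatResult("rm_anova", float(f), (float(df_w), float(df_err)),
                      float(sps.f.sf(f, df_w, df_err)))


def simple_effects(data: pd.DataFrame, dv: str = "value", within: str = "within",
                   between: str = "between", subject: str = "subject",
                   ) -> list[StatResult]:
    """Follow-up one-way ANOVAs after a significant interaction.

    Between-factor one-way ANOVA at each within level, plus a
    repeated-measures one-way ANOVA of the within factor per group;
    the whole family is BH-FDR adjusted.
    """
    y, groups, w_levels = _pivot_balanced(data, dv, within, between, subject)
    groups = np.asarray(groups)
    g_levels = sorted(set(groups))
    results: list[StatResult] = []
    for j, wl in enumerate(w_levels):
        samples = [y[groups == gl, j] for gl in g_levels]
        f, p = sps.f_oneway(*samples)
        df1 = len(g_levels) - 1
        df2 = len(y) - len(g_levels)
        results.append(StatResult("anova_between_at_level", float(f),
                                  (float(df1), float(df2)), float(p),
                                  comparison=f"{between} at {within}={wl}"))
    if len(w_levels) >= 2:
        for gl in g_levels:
            res = rm_oneway(y[groups == gl])
            res.comparison = f"{within} within {between}={gl}"
            results.append(res)
    adj = fdr_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results


# ---------------------------------------------------------------------------
# Correlation

def correlate_metric_score(metric_values, score_values, comparison: str = "",
                           ) -> StatResult:
    """Pearson correlation with a two-sided p-value."""
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(score_values, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise InvalidParameterError("need >= 3 paired observations")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise UndefinedStatisticError("constant input")
    r, p = sps.pearsonr(x, y)
    return StatResult("pearson_r", float(r), (float(len(x) - 2),), float(p),
                      comparison=comparison)


def correlate_batch(pairs: dict[str, tuple[np.ndarray, np.ndarray]],
                    ) -> dict[str, StatResult]:
    """Pearson correlations FDR-adjusted across the named family."""
    results = {name: correlate_metric_score(x, y, comparison=name)
               for name, (x, y) in pairs.items()}
    adj = fdr_adjust([r.p_raw for r in results.values()])
    for r, a in zip(results.values(), adj):
        r.p_adjusted = float(a)
    return results
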