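import itertools

import numpy as np
import pandas as pd
import pytest

from mstate_ri.errors import InvalidParameterError, UndefinedStatisticError
from mstate_ri.stats import (
    chi2_2x2,
    correlate_batch,
    correlate_metric_score,
    fdr_adjust,
    mixed_anova,
    rm_oneway,
    simple_effects,
    ttest_independent,
    ttest_paired,
)


# ---------------------------------------------------------------------------
# t-tests

def test_independent_t_from_published_tfi_summaries():
    # pooled-variance t on (n=22, 94.76, 61.60) vs (n=22, 94.45, 52.08)
    res = ttest_independent(summary_x=(22, 94.76, 61.60),
                            summary_y=(22, 94.45, 52.08))
    assert res.p_raw == pytest.approx(0.986, abs=5e-4)


def test_independent_t_identical_groups():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = ttest_independent(x, x)
    assert res.statistic == 0.0
    assert res.p_raw == pytest.approx(1.0)


def test_independent_t_vs_permutation_oracle():
    rng = np.random.default_rng(8)
    x = rng.normal(0.0, 1.0, 6)
    y = rng.normal(1.2, 1.0, 6)
    res = ttest_independent(x, y)
    pooled = np.concatenate([x, y])
    obs = abs(x.mean() - y.mean())
    count = 0
    n_perm = 20000
    for _ in range(n_perm):
        rng.shuffle(pooled)
        count += abs(pooled[:6].mean() - pooled[6:].mean()) >= obs
    p_perm = count / n_perm
    assert abs(res.p_raw - p_perm) < 0.03


def test_paired_t_zero_variance_errors():
    x = np.array([1.0, 2.0, 3.0])
    with pytest.raises(UndefinedStatisticError):
        ttest_paired(x, x)


def test_paired_t_matches_one_sample_closed_form():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 15)
    y = x + 0.5 + rng.normal(0, 0.3, 15)
    res = ttest_paired(x, y)
    d = x - y
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    from scipy import stats as sps

    p = 2 * sps.t.sf(abs(t), len(d) - 1)
    assert res.statistic == pytest.approx(t)
    assert res.p_raw == pytest.approx(p)


def test_paired_t_sign_symmetry():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 10)
    y = rng.normal(0.3, 1, 10)
    a = ttest_paired(x, y)
    b = ttest_paired(y, x)
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p_raw == pytest.approx(b.p_raw)


# ---------------------------------------------------------------------------
# chi-square

def test_chi2_published_gender_table():
    res = chi2_2x2(((11, 11), (12, 10)), yates=True)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_raw > 0.999


def test_chi2_proportional_table():
    res = chi2_2x2(((10, 20), (20, 40)), yates=False)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_raw == pytest.approx(1.0)


def test_chi2_vs_definitional_oracle():
    rng = np.random.default_rng(9)
    for _ in range(50):
        table = rng.integers(1, 40, size=(2, 2)).astype(float)
        res = chi2_2x2(table, yates=False)
        total = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / total
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(chi2)


def test_chi2_zero_margin_errors():
    with pytest.raises(UndefinedStatisticError):
        chi2_2x2(((0, 0), (5, 5)))


# ---------------------------------------------------------------------------
# FDR

def test_fdr_single_p_unchanged():
    np.testing.assert_allclose(fdr_adjust([0.0321]), [0.0321])


def test_fdr_hand_example():
    np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def oracle_bh(p):
    """Literal step-up definition: adj_i = min_{j>=i} (m p_(j) / j), capped."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [len(p) * p[order[j - 1]] / j for j in range(rank, m + 1)]
        adj_sorted[rank - 1] = min(1.0, min(candidates))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def test_fdr_vs_brute_force_oracle():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        p = rng.random(int(rng.integers(1, 12)))
        np.testing.assert_allclose(fdr_adjust(p), oracle_bh(p), atol=1e-12)


def test_fdr_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(12)
    p = rng.random(40)
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(fdr_adjust(p), adj, atol=1e-12)


def test_fdr_monotone():
    rng = np.random.default_rng(13)
    p = rng.random(30)
    adj = fdr_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_fdr_rejects_bad_input():
    with pytest.raises(InvalidParameterError):
        fdr_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# mixed ANOVA

def _long_table(y, groups, subjects, w_levels):
    rows = []
    for i, (subj, grp) in enumerate(zip(subjects, groups)):
        for j, wl in enumerate(w_levels):
            rows.append({"subject": subj, "between": grp, "within": wl,
                         "value": y[i, j]})
    return pd.DataFrame(rows)


def _random_design(rng, g=2, n=6, w=4):
    y = rng.standard_normal((g * n, w))
    groups = [f"g{i // n}" for i in range(g * n)]
    subjects = [f"s{i}" for i in range(g * n)]
    return y, groups, subjects, [f"w{j}" for j in range(w)]


def oracle_mixed_ss(y, groups):
    """Cell-mean sums of squares computed from first principles."""
    groups = np.asarray(groups)
    g_levels = sorted(set(groups))
    n = sum(groups == g_levels[0])
    w = y.shape[1]
    grand = y.mean()
    ss = {}
    ss["total"] = ((y - grand) ** 2).sum()
    ss["group"] = sum(n * w * (y[groups == g].mean() - grand) ** 2
                      for g in g_levels)
    ss["bs"] = w * ((y.mean(axis=1) - grand) ** 2).sum()
    ss["swg"] = ss["bs"] - ss["group"]
    ss["within_factor"] = sum(len(groups) * (y[:, j].mean() - grand) ** 2
                              for j in range(w))
    ss["cells"] = sum(n * (y[groups == g][:, j].mean() - grand) ** 2
                      for g in g_levels for j in range(w))
    ss["interaction"] = ss["cells"] - ss["group"] - ss["within_factor"]
    ss["error"] = (ss["total"] - ss["bs"] - ss["within_factor"]
                   - ss["interaction"])
    return ss


def test_mixed_anova_ss_match_oracle():
    rng = np.random.default_rng(21)
    for _ in range(10):
        y, groups, subjects, w_levels = _random_design(rng)
        data = _long_table(y, groups, subjects, w_levels)
        res = mixed_anova(data)
        ss = oracle_mixed_ss(y, groups)
        assert res["between"].extras["ss_effect"] == pytest.approx(
            ss["group"], abs=1e-8)
        assert res["between"].extras["ss_error"] == pytest.approx(
            ss["swg"], abs=1e-8)
        assert res["within"].extras["ss_effect"] == pytest.approx(
            ss["within_factor"], abs=1e-8)
        assert res["interaction"].extras["ss_effect"] == pytest.approx(
            ss["interaction"], abs=1e-8)
        assert res["within"].extras["ss_error"] == pytest.approx(
            ss["error"], abs=1e-8)


def test_mixed_anova_ss_conservation():
    rng = np.random.default_rng(22)
    y, groups, subjects, w_levels = _random_design(rng)
    res = mixed_anova(_long_table(y, groups, subjects, w_levels))
    ss = oracle_mixed_ss(y, groups)
    parts = (ss["group"] + ss["swg"] + ss["within_factor"]
             + ss["interaction"] + ss["error"])
    assert parts == pytest.approx(ss["total"], abs=1e-8)


def test_mixed_anova_group_symmetry_gives_zero_f():
    # mirrored groups: group means identical -> group F exactly 0
    rng = np.random.default_rng(23)
    half = rng.standard_normal((5, 3))
    y = np.vstack([half, half])
    groups = ["a"] * 5 + ["b"] * 5
    subjects = [f"s{i}" for i in range(10)]
    res = mixed_anova(_long_table(y, groups, subjects, ["w0", "w1", "w2"]))
    assert res["between"].statistic == pytest.approx(0.0, abs=1e-9)


def test_mixed_anova_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(24)
    y, groups, subjects, w_levels = _random_design(rng, g=2, n=8, w=3)
    data = _long_table(y, groups, subjects, w_levels)
    res = mixed_anova(data)
    pg = pingouin.mixed_anova(data, dv="value", within="within",
                              between="between", subject="subject")
    pg = pg.set_index("Source")
    assert res["between"].statistic == pytest.approx(
        pg.loc["between", "F"], rel=1e-6)
    assert res["within"].statistic == pytest.approx(
        pg.loc["within", "F"], rel=1e-6)
    assert res["interaction"].statistic == pytest.approx(
        pg.loc["Interaction", "F"], rel=1e-6)


def test_mixed_anova_unbalanced_errors():
    rng = np.random.default_rng(25)
    y, groups, subjects, w_levels = _random_design(rng)
    data = _long_table(y, groups, subjects, w_levels)
    with pytest.raises(InvalidParameterError):
        mixed_anova(data.iloc[:-1])


def test_mixed_anova_type_i_rate_null():
    rng = np.random.default_rng(26)
    n_reps, hits = 200, 0
    for _ in range(n_reps):
        y, groups, subjects, w_levels = _random_design(rng, g=2, n=8, w=3)
        res = mixed_anova(_long_table(y, groups, subjects, w_levels))
        hits += res["between"].p_raw < 0.05
    assert abs(hits / n_reps - 0.05) <= 0.04


# ---------------------------------------------------------------------------
# simple effects

def test_simple_effects_single_within_level_is_oneway():
    from scipy import stats as sps

    rng = np.random.default_rng(30)
    y = rng.standard_normal((12, 1))
    groups = ["a"] * 6 + ["b"] * 6
    subjects = [f"s{i}" for i in range(12)]
    res = simple_effects(_long_table(y, groups, subjects, ["w0"]))
    between = [r for r in res if r.test == "anova_between_at_level"]
    assert len(between) == 1
    f, p = sps.f_oneway(y[:6, 0], y[6:, 0])
    assert between[0].statistic == pytest.approx(f)
    assert between[0].p_raw == pytest.approx(p)


def test_simple_effects_flags_strong_level():
    rng = np.random.default_rng(31)
    y = rng.standard_normal((20, 3)) * 0.5
    y[10:, 1] += 3.0  # strong group effect at level w1 only
    groups = ["a"] * 10 + ["b"] * 10
    subjects = [f"s{i}" for i in range(20)]
    res = simple_effects(_long_table(y, groups, subjects, ["w0", "w1", "w2"]))
    by_cmp = {r.comparison: r for r in res if "at" in r.comparison}
    assert by_cmp["between at within=w1"].p_adjusted < 0.01
    assert by_cmp["between at within=w0"].p_adjusted > 0.05


def test_rm_oneway_zero_error_raises():
    with pytest.raises(UndefinedStatisticError):
        rm_oneway(np.tile(np.array([[1.0, 2.0, 3.0]]), (4, 1)))


# ---------------------------------------------------------------------------
# correlation

def test_correlation_perfect():
    x = np.arange(10.0)
    res = correlate_metric_score(x, x * 2 + 1)
    assert res.statistic == pytest.approx(1.0)


def test_correlation_constant_errors():
    with pytest.raises(UndefinedStatisticError):
        correlate_metric_score(np.ones(5), np.arange(5.0))


def test_correlation_recovers_true_r():
    rng = np.random.default_rng(33)
    r_true, n, reps = 0.5, 22, 500
    rs = []
    for _ in range(reps):
        x = rng.standard_normal(n)
        y = r_true * x + np.sqrt(1 - r_true ** 2) * rng.standard_normal(n)
        rs.append(correlate_metric_score(x, y).statistic)
    assert abs(np.mean(rs) - r_true) < 0.05


def test_correlation_type_i_rate():
    rng = np.random.default_rng(34)
    hits = 0
    reps = 500
    for _ in range(reps):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        hits += correlate_metric_score(x, y).p_raw < 0.05
    assert abs(hits / reps - 0.05) < 0.03


def test_correlate_batch_adjusts_family():
    rng = np.random.default_rng(35)
    pairs = {f"c{i}": (rng.standard_normal(10), rng.standard_normal(10))
             for i in range(5)}
    res = correlate_batch(pairs)
    raw = [r.p_raw for r in res.values()]
    adj = [r.p_adjusted for r in res.values()]
    np.testing.assert_allclose(adj, fdr_adjust(raw))
    assert all(a >= p - 1e-12 for a, p in zip(adj, raw))
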