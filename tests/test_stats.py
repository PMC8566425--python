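"""Cohort statistics layer: regressions, ANOVA/Tukey, t-tests, boxplots."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mammilieu.stats import (
    age_regression,
    group_anova,
    paired_compare,
    significance_symbol,
    tukey_boxplot_stats,
    unpaired_compare,
)


def _table(age, pe=None, ils=None, **extra):
    data = {"age_y": age}
    if pe is not None:
        data["density_T_PE"] = pe
    if ils is not None:
        data["density_T_ILS"] = ils
    data.update(extra)
    return pd.DataFrame(data)


def test_exact_linear_relation_gives_r_one():
    age = np.linspace(25, 70, 30)
    res = age_regression(_table(age, pe=3.0 * age + 10.0), "T", "PE")
    assert res.r == pytest.approx(1.0)
    assert res.slope == pytest.approx(3.0)
    assert res.p_value < 1e-30


def test_regression_requires_age_variance_and_n():
    with pytest.raises(ValueError, match="zero age variance"):
        age_regression(_table(np.full(5, 50.0), pe=np.arange(5.0)), "T", "PE")
    with pytest.raises(ValueError, match=">= 3"):
        age_regression(_table(np.array([40.0, 50.0]), pe=np.array([1.0, 2.0])), "T", "PE")


def test_slope_coverage_against_generating_model():
    """Estimated slope falls within 2 se of the generating slope in >= 95%
    of seeds (normal-theory coverage, checked by simulation)."""
    hits = 0
    n_seeds = 60
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        age = rng.uniform(24, 74, size=102)
        y = 500.0 - 4.0 * age + rng.normal(0, 120, size=102)
        res = age_regression(_table(age, pe=y), "T", "PE")
        if abs(res.slope - (-4.0)) < 2 * res.slope_se:
            hits += 1
    assert hits / n_seeds >= 0.90


def test_null_regression_p_values_are_uniform():
    rng = np.random.default_rng(0)
    ps = []
    for _ in range(200):
        age = rng.uniform(24, 74, size=30)
        y = rng.normal(100, 20, size=30)
        ps.append(age_regression(_table(age, pe=y), "T", "PE").p_value)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_two_group_anova_equals_squared_t():
    rng = np.random.default_rng(1)
    g = np.repeat(["a", "b"], 20)
    y = rng.normal(0, 1, 40)
    tab = _table(np.linspace(30, 60, 40), pe=y, group=g)
    a = group_anova(tab, "group", "T", "PE")
    t = unpaired_compare(tab, "group", "T", "PE", levels=("a", "b"))
    assert a.statistic == pytest.approx(t.statistic**2, abs=1e-10)
    assert a.p_value == pytest.approx(t.p_value, abs=1e-12)


def test_anova_detects_shifted_group_via_tukey():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(3, 1, 10)])
        tab = _table(np.linspace(30, 60, 30), pe=y, group=np.repeat(["a", "b", "c"], 10))
        res = group_anova(tab, "group", "T", "PE")
        pairs = res.adjusted
        c_pairs = pairs[(pairs.group_a == "c") | (pairs.group_b == "c")]
        if (c_pairs.adjusted_p < 0.01).all():
            hits += 1
    assert hits >= 9


def test_anova_excludes_tiny_groups():
    y = np.arange(9.0)
    tab = _table(np.linspace(30, 60, 9), pe=y, group=list("aaaabbbbc"))
    res = group_anova(tab, "group", "T", "PE")
    assert set(res.adjusted.group_a) | set(res.adjusted.group_b) == {"a", "b"}


def test_tukey_adjusted_p_at_least_raw_pairwise():
    rng = np.random.default_rng(3)
    y = rng.normal(0, 1, 30)
    tab = _table(np.linspace(30, 60, 30), pe=y, group=np.repeat(["a", "b", "c"], 10))
    res = group_anova(tab, "group", "T", "PE")
    for row in res.adjusted.itertuples():
        a = tab.loc[tab.group == row.group_a, "density_T_PE"]
        b = tab.loc[tab.group == row.group_b, "density_T_PE"]
        raw = sps.ttest_ind(a, b).pvalue
        assert row.adjusted_p >= raw - 1e-12


def test_paired_identical_compartments_give_t_zero_p_one():
    v = np.array([100.0, 150.0, 200.0, 250.0])
    res = paired_compare(_table(np.arange(4.0) + 30, pe=v, ils=v.copy()), "T")
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_paired_antisymmetry():
    rng = np.random.default_rng(4)
    pe, ils = rng.normal(300, 50, 20), rng.normal(100, 50, 20)
    t1 = paired_compare(_table(np.linspace(30, 60, 20), pe=pe, ils=ils), "T")
    t2 = paired_compare(_table(np.linspace(30, 60, 20), pe=ils, ils=pe), "T")
    assert t1.statistic == pytest.approx(-t2.statistic)
    assert t1.p_value == pytest.approx(t2.p_value)


def test_paired_power_for_planted_offset():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        ils = rng.normal(300, 80, 20)
        pe = ils + 200 + rng.normal(0, 100, 20)
        res = paired_compare(_table(np.linspace(30, 60, 20), pe=pe, ils=ils), "T")
        if res.p_value < 0.001 and res.statistic > 0:
            hits += 1
    assert hits >= 9


def test_unpaired_group_order_flips_sign_only():
    rng = np.random.default_rng(5)
    tab = _table(
        np.linspace(30, 60, 24),
        pe=rng.normal(0, 1, 24),
        risk=np.repeat(["AR", "HR"], 12),
    )
    a = unpaired_compare(tab, "risk", "T", "PE", levels=("AR", "HR"))
    b = unpaired_compare(tab, "risk", "T", "PE", levels=("HR", "AR"))
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p_value == pytest.approx(b.p_value)


def test_tukey_boxplot_hand_computed_fixture():
    # sorted values 1..7 and 20; linear-interpolation quartiles:
    # q1 = 2.75, median = 4.5, q3 = 6.25, IQR = 3.5,
    # fences at -2.5 / 11.5 -> whiskers 1 and 7, outlier 20
    out = tukey_boxplot_stats([4, 2, 7, 1, 20, 3, 6, 5])
    assert out["q1"] == pytest.approx(2.75)
    assert out["median"] == pytest.approx(4.5)
    assert out["q3"] == pytest.approx(6.25)
    assert out["whisker_low"] == 1.0
    assert out["whisker_high"] == 7.0
    assert out["outliers"] == [20.0]


def test_tukey_boxplot_symmetric_data_has_no_outliers():
    out = tukey_boxplot_stats(np.linspace(-1, 1, 50))
    assert out["outliers"] == []


def test_significance_symbols():
    assert significance_symbol(0.2) == "NS"
    assert significance_symbol(0.05) == "*"
    assert significance_symbol(0.01) == "**"
    assert significance_symbol(0.001) == "***"
    assert significance_symbol(0.00005) == "****"
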