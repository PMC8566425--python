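"""Cohort-level statistics over density tables.

The analysis layer mirrors a conventional clinical-correlates workup:
simple linear regression of density on age with Pearson's r, one-way ANOVA
with Tukey HSD post-hoc for categorical groupings (age bins, BMI class,
tissue type, parity), paired t-tests for PE vs ILS within donors, unpaired
t-tests for between-donor groupings (risk, menopause), and Tukey boxplot
summaries.  All tests are two-sided at alpha = 0.05; t-tests assume equal
variances by default with Welch behind a flag.

Density tables are tidy DataFrames with one row per donor carrying
covariates plus ``density_<class>_<compartment>`` columns (the layout
produced by the cohort generator and by joining DensityRecords).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "significance_symbol",
    "density_column",
    "age_regression",
    "group_anova",
    "paired_compare",
    "unpaired_compare",
    "tukey_boxplot_stats",
]


def significance_symbol(p: float) -> str:
    """* p<=0.05, ** p<=0.01, *** p<=0.001, **** p<=0.0001, else NS."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    n: dict[str, int] = field(default_factory=dict)
    r: float | None = None
    slope: float | None = None
    intercept: float | None = None
    slope_se: float | None = None
    adjusted: pd.DataFrame | None = None  # post-hoc pairwise table

    @property
    def symbol(self) -> str:
        return significance_symbol(self.p_value)


def density_column(cell_class: str, compartment: str) -> str:
    return f"density_{cell_class}_{compartment}"


def _col(table: pd.DataFrame, cell_class: str, compartment: str) -> pd.Series:
    col = density_column(cell_class, compartment)
    if col not in table.columns:
        raise KeyError(f"table lacks column {col!r}")
    return table[col]


def age_regression(
    table: pd.DataFrame,
    cell_class: str,
    compartment: str,
    subgroup: pd.Series | None = None,
) -> StatResult:
    """OLS of density on age: slope, Pearson r, two-sided p for the slope.

    ``subgroup`` is an optional boolean filter aligned with the table
    (e.g. table.risk == "HR").
    """
    df = table if subgroup is None else table.loc[np.asarray(subgroup, dtype=bool)]
    if len(df) < 3:
        raise ValueError("need >= 3 donors for regression")
    age = df["age_y"].to_numpy(dtype=float)
    y = _col(df, cell_class, compartment).to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("zero age variance")
    fit = sps.linregress(age, y)
    return StatResult(
        test="age_regression",
        statistic=float(fit.slope / fit.stderr) if fit.stderr > 0 else np.inf,
        p_value=float(fit.pvalue),
        n={"donors": len(df)},
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
    )


def group_anova(
    table: pd.DataFrame, grouping: str, cell_class: str, compartment: str
) -> StatResult:
    """One-way ANOVA across the levels of ``grouping`` followed by Tukey
    HSD pairwise adjusted p-values.  Levels with < 2 members are excluded
    (noted in the group-size dict with n as recorded)."""
    y = _col(table, cell_class, compartment)
    groups, ns = [], {}
    for level, vals in y.groupby(table[grouping]):
        v = vals.to_numpy(dtype=float)
        ns[str(level)] = len(v)
        if len(v) >= 2:
            groups.append((str(level), v))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    f, p = sps.f_oneway(*(v for _, v in groups))
    tuk = sps.tukey_hsd(*(v for _, v in groups))
    names = [n for n, _ in groups]
    rows = [
        {
            "group_a": names[i],
            "group_b": names[j],
            "adjusted_p": float(tuk.pvalue[i, j]),
        }
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
    return StatResult(
        test=f"anova[{grouping}]",
        statistic=float(f),
        p_value=float(p),
        n=ns,
        adjusted=pd.DataFrame(rows),
    )


def paired_compare(table: pd.DataFrame, cell_class: str) -> StatResult:
    """Two-sided paired t-test of PE vs ILS densities within donors."""
    pe = _col(table, cell_class, "PE").to_numpy(dtype=float)
    ils = _col(table, cell_class, "ILS").to_numpy(dtype=float)
    ok = ~(np.isnan(pe) | np.isnan(ils))
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete PE/ILS pairs")
    if np.all(pe[ok] == ils[ok]):
        t, p = 0.0, 1.0  # degenerate zero-difference case
    else:
        t, p = sps.ttest_rel(pe[ok], ils[ok])
    return StatResult(
        test="paired_t[PE-ILS]",
        statistic=float(t),
        p_value=float(p),
        n={"pairs": int(ok.sum())},
    )


def unpaired_compare(
    table: pd.DataFrame,
    grouping: str,
    cell_class: str,
    compartment: str,
    levels: tuple[str, str] | None = None,
    welch: bool = False,
) -> StatResult:
    """Two-sided unpaired t-test between two levels of a donor grouping
    (risk AR vs HR, menopause pre vs post, ...); equal-variance by
    default, Welch with ``welch=True``."""
    y = _col(table, cell_class, compartment)
    g = table[grouping].astype(str)
    if levels is None:
        uniq = sorted(g.unique())
        if len(uniq) != 2:
            raise ValueError(f"grouping {grouping!r} has {len(uniq)} levels; pass `levels`")
        levels = (uniq[0], uniq[1])
    a = y[g == levels[0]].to_numpy(dtype=float)
    b = y[g == levels[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 members")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return StatResult(
        test=f"unpaired_t[{grouping}:{levels[0]}-{levels[1]}]",
        statistic=float(t),
        p_value=float(p),
        n={levels[0]: len(a), levels[1]: len(b)},
    )


def tukey_boxplot_stats(values) -> dict:
    """Tukey boxplot summary: quartiles (linear interpolation), whiskers
    at the most extreme points within 1.5 IQR of the quartiles, points
    beyond flagged as outliers."""
    v = np.sort(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no values")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": v[(v < lo_fence) | (v > hi_fence)].tolist(),
    }
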