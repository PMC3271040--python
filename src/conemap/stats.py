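"""Statistical layer: group tests on densities and method normalization.

Densities measured by different counting techniques on the same tissue
series differ by a systematic offset but share the distribution shape.
Rank-wise quantile-quantile equalization removes exactly that offset: the
rank-r value of every method is replaced by the across-method mean at
rank r, after which the sorted vectors of all methods are identical. A
two-way ANOVA (day x method) fitted to equalized data therefore has a
method sum of squares of exactly zero and a method p-value of 1, for any
input — a data-independent identity that certifies the normalization.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "AnovaTable",
    "welch_t",
    "paired_t",
    "two_way_anova",
    "quantile_equalize",
    "enumerate_equalizations",
    "significance_marks",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    zero_variance: bool = False


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"{name} needs at least 2 observations")
    return arr


def welch_t(a, b) -> TTestResult:
    """Unpaired two-sample t-test with Welch's correction.

    Satterthwaite degrees of freedom, two-sided p. Two samples with zero
    variance and equal means return t = 0, p = 1 by convention; zero
    variance with different means returns p = 0 with the flag set.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, float(len(a) + len(b) - 2), 1.0, True)
        return TTestResult(math.inf, float(len(a) + len(b) - 2), 0.0, True)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def paired_t(a, b) -> TTestResult:
    """Paired t-test: one-sample t on the within-pair differences.

    df = n - 1, two-sided p. A constant nonzero difference (zero
    difference variance) is a degenerate case reported as p = 0 with the
    zero-variance flag; identical samples give t = 0, p = 1.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    if len(a) != len(b):
        raise ValueError("paired samples must have equal lengths")
    d = a - b
    n = len(d)
    if d.var(ddof=1) == 0.0:
        if d[0] == 0.0:
            return TTestResult(0.0, float(n - 1), 1.0, True)
        return TTestResult(math.copysign(math.inf, d[0]), float(n - 1), 0.0, True)
    res = sps.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(n - 1), float(res.pvalue))


@dataclass
class AnovaTable:
    """Two-way fixed-effects decomposition (day, method, interaction)."""

    table: pd.DataFrame  # index: day, method, (interaction), residual

    def p(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])

    def F(self, factor: str) -> float:
        return float(self.table.loc[factor, "F"])

    def sum_sq(self, factor: str) -> float:
        return float(self.table.loc[factor, "sum_sq"])


def two_way_anova(
    data: pd.DataFrame,
    value: str = "density",
    day: str = "day",
    method: str = "method",
    interaction: bool | None = None,
) -> AnovaTable:
    """Two-way fixed-effects ANOVA with factors day and method.

    Uses an OLS fit with type-II sums of squares, which is exact for
    balanced designs and the standard choice for mildly unbalanced ones.
    ``interaction=None`` includes the interaction term when the design has
    replication within cells. An all-constant response returns F = 0,
    p = 1 for every factor. A day x method cell with no observations is an
    error naming the cell.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[value, day, method]].copy()
    df.columns = ["value", "day", "method"]
    if len(df) == 0:
        raise ValueError("empty dataset")
    for lv_d in df["day"].unique():
        for lv_m in df["method"].unique():
            n_cell = ((df["day"] == lv_d) & (df["method"] == lv_m)).sum()
            if n_cell == 0:
                raise ValueError(f"empty design cell: day={lv_d!r}, method={lv_m!r}")
    if df["day"].nunique() < 2 or df["method"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")

    cell_sizes = df.groupby(["day", "method"]).size()
    if interaction is None:
        interaction = bool((cell_sizes > 1).all())

    rows = ["C(day)", "C(method)"] + (["C(day):C(method)"] if interaction else [])
    labels = ["day", "method"] + (["interaction"] if interaction else [])

    if float(np.ptp(df["value"])) == 0.0:
        # constant response: every factor explains nothing
        out = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": 0.0, "p": 1.0}, index=labels
        )
        out.loc["residual"] = [0.0, float(len(df) - 1), np.nan, np.nan]
        return AnovaTable(out)

    formula = "value ~ " + " + ".join(rows)
    fit = smf.ols(formula, data=df).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    aov = aov.rename(
        index={
            "C(day)": "day",
            "C(method)": "method",
            "C(day):C(method)": "interaction",
            "Residual": "residual",
        }
    )
    aov = aov.rename(columns={"PR(>F)": "p"})
    # a factor with (numerically) zero SS has F = 0, p = 1 exactly
    zero = aov["sum_sq"].abs() < 1e-9 * max(float(aov["sum_sq"].sum()), 1e-300)
    aov.loc[zero & (aov.index != "residual"), "F"] = 0.0
    aov.loc[zero & (aov.index != "residual"), "p"] = 1.0
    return AnovaTable(aov[["sum_sq", "df", "F", "p"]])


def quantile_equalize(datasets: list) -> list[np.ndarray]:
    """Rank-wise quantile-quantile equalization across equal-size datasets.

    Each dataset is sorted; the rank-r value of every dataset is replaced
    by the mean over datasets of their rank-r values; values are then
    returned to their original positions (ties keep their stable original
    order). Afterwards the sorted vectors of all datasets are identical,
    and the grand sum of all values is preserved exactly.
    """
    arrays = [np.asarray(d, dtype=float).ravel() for d in datasets]
    if len(arrays) < 2:
        raise ValueError("need at least two datasets")
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError(
            "datasets must have equal sizes; resize them first "
            "(see enumerate_equalizations)"
        )
    order = [np.argsort(a, kind="stable") for a in arrays]
    sorted_vals = np.stack([a[o] for a, o in zip(arrays, order)])
    rank_means = sorted_vals.mean(axis=0)
    out = []
    for o in order:
        res = np.empty(n)
        res[o] = rank_means
        out.append(res)
    return out


def enumerate_equalizations(
    datasets: list, limit: int = 1_000_000
):
    """Enumerate every way of trimming oversized datasets to the common size.

    The target size is the minimum dataset length; for each oversized
    dataset every choice of surplus values to delete is enumerated, and
    the cartesian product over datasets yields all equal-size
    combinations. The caller applies :func:`quantile_equalize` (and e.g.
    a two-way ANOVA) to each combination. Guards against combinatorial
    explosion beyond ``limit`` combinations.
    """
    arrays = [np.asarray(d, dtype=float).ravel() for d in datasets]
    target = min(len(a) for a in arrays)
    per_dataset_choices = []
    total = 1
    for a in arrays:
        surplus = len(a) - target
        n_choices = math.comb(len(a), surplus)
        total *= n_choices
        if total > limit:
            raise ValueError(
                f"more than {limit} trim combinations; sample instead of "
                "enumerating"
            )
        keeps = [
            np.array([i for i in range(len(a)) if i not in set(drop)], dtype=int)
            for drop in itertools.combinations(range(len(a)), surplus)
        ]
        per_dataset_choices.append(keeps)
    combos = []
    for keep_tuple in itertools.product(*per_dataset_choices):
        combos.append([a[k] for a, k in zip(arrays, keep_tuple)])
    return combos


def significance_marks(p: float) -> str:
    """Conventional significance stars: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
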