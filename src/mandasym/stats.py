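"""Statistical layer: summaries, tests, reliability and ANOVA power.

Mirrors the study design: per-subject pooled signed/absolute distances are
summarized by skeletal class (sagittal and vertical) and by anatomical
region; differences across groups use a one-way ANOVA with Bonferroni
pairwise comparisons, variance homogeneity is checked with Levene's test,
normality with a Lilliefors-corrected Kolmogorov-Smirnov test, reliability
with ICC(2,1), and design power with the noncentral F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "SummaryStats",
    "AnovaResult",
    "summarize",
    "one_sample_t",
    "one_way_anova",
    "levene_test",
    "ks_normality",
    "icc",
    "anova_power",
    "cohort_tables",
]


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    median: float
    ci95_low: float
    ci95_high: float

    def row(self) -> dict:
        return {
            "N": self.n,
            "Mean": self.mean,
            "SD": self.sd,
            "Minimum": self.min,
            "Maximum": self.max,
            "Median": self.median,
            "CI95_low": self.ci95_low,
            "CI95_high": self.ci95_high,
        }


def summarize(values) -> SummaryStats:
    """Mean, sample SD, range, median and t-based 95% CI of the mean."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values to summarize")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = float(sps.t.ppf(0.975, v.size - 1) * sd / np.sqrt(v.size))
    return SummaryStats(
        n=int(v.size),
        mean=mean,
        sd=sd,
        min=float(v.min()),
        max=float(v.max()),
        median=float(np.median(v)),
        ci95_low=mean - half,
        ci95_high=mean + half,
    )


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample t-test of the mean against ``mu0``."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if v.std(ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(v, popmean=mu0)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    pairwise_bonferroni: dict


def _check_groups(groups):
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    return groups


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way ANOVA with Bonferroni-corrected pairwise t-tests."""
    groups = _check_groups(groups)
    F, p = sps.f_oneway(*groups)
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    pairwise = {}
    for i, j in combinations(range(k), 2):
        raw = sps.ttest_ind(groups[i], groups[j], equal_var=True).pvalue
        pairwise[(i, j)] = float(min(1.0, raw * n_pairs))
    n_total = sum(g.size for g in groups)
    return AnovaResult(float(F), float(p), k - 1, n_total - k, pairwise)


def levene_test(groups) -> tuple[float, float]:
    """Levene's test (ANOVA on absolute deviations from group means)."""
    groups = _check_groups(groups)
    W, p = sps.levene(*groups, center="mean")
    return float(W), float(p)


def ks_normality(values) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with estimated parameters.

    Uses the Lilliefors correction because mean and SD are fitted from the
    sample; a raw KS p-value against fitted parameters would be
    anticonservative.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 8:
        raise ValueError("need at least 8 values for the KS normality test")
    D, p = lilliefors(v, dist="norm")
    return float(D), float(p)


def icc(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a subjects x raters table")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 raters and >= 3 subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        raise ValueError("degenerate ratings table: ICC undefined")
    return float((msr - mse) / denom)


def anova_power(k_groups: int, total_n: int, effect_f: float, alpha: float = 0.05) -> float:
    """Power of a one-way ANOVA via the noncentral F distribution.

    power = P( F'(k-1, N-k, lambda = f^2 N) > F_crit(1-alpha) ).
    """
    if k_groups < 2 or total_n <= k_groups:
        raise ValueError("need k >= 2 groups and N > k")
    if effect_f < 0 or not (0 < alpha < 1):
        raise ValueError("invalid effect size or alpha")
    df1, df2 = k_groups - 1, total_n - k_groups
    if effect_f == 0:
        return float(alpha)
    fcrit = sps.f.ppf(1.0 - alpha, df1, df2)
    return float(sps.ncf.sf(fcrit, df1, df2, effect_f**2 * total_n))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------


def _summary_row(values) -> dict:
    """Summary row tolerant of n = 1 (dispersion reported as NaN)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size >= 2:
        return summarize(v).row()
    return {
        "N": int(v.size),
        "Mean": float(v.mean()) if v.size else np.nan,
        "SD": np.nan,
        "Minimum": float(v.min()) if v.size else np.nan,
        "Maximum": float(v.max()) if v.size else np.nan,
        "Median": float(np.median(v)) if v.size else np.nan,
        "CI95_low": np.nan,
        "CI95_high": np.nan,
    }


def _grouped_table(df: pd.DataFrame, value: str, factor: str, order, include_total=True) -> pd.DataFrame:
    rows = []
    if include_total:
        total = _summary_row(df[value])
        try:
            _, p = one_sample_t(df[value])
        except ValueError:
            p = np.nan
        total.update({"Group": "TOTAL", "p": p, "test": "t vs 0"})
        rows.append(total)
    groups = [df.loc[df[factor] == g, value].to_numpy() for g in order if (df[factor] == g).any()]
    try:
        p_f = one_way_anova(groups).p if len(groups) >= 2 else np.nan
    except ValueError:
        p_f = np.nan
    for g in order:
        sel = df[factor] == g
        if not sel.any():
            continue
        row = _summary_row(df.loc[sel, value])
        row.update({"Group": str(g), "p": p_f, "test": "F"})
        rows.append(row)
    cols = ["Group", "N", "Mean", "SD", "Minimum", "Maximum", "Median", "CI95_low", "CI95_high", "p", "test"]
    return pd.DataFrame(rows)[cols]


def cohort_tables(subject_table: pd.DataFrame, point_table: pd.DataFrame):
    """Build the two study-shaped summary tables.

    ``subject_table``: one row per subject with columns ``mean_signed``,
    ``mean_absolute``, ``sagittal_class``, ``vertical_type``.
    ``point_table``: pooled per-point rows with ``signed``, ``absolute``,
    ``region``.  Returns ``(by_class, by_region)`` DataFrames: per-class
    summaries of the per-subject means (with t/F tests) and per-region
    summaries of the pooled point distances with counts and percentages.
    """
    if len(subject_table) == 0:
        raise ValueError("empty cohort")
    frames = []
    for value in ("mean_signed", "mean_absolute"):
        for factor, order in (
            ("sagittal_class", ("I", "II", "III")),
            ("vertical_type", ("brachycephalic", "mesocephalic", "dolichocephalic")),
        ):
            tab = _grouped_table(
                subject_table, value, factor, order,
                include_total=factor == "sagittal_class",
            )
            tab.insert(0, "Factor", factor)
            tab.insert(0, "Distance", value.replace("mean_", ""))
            frames.append(tab)
    by_class = pd.concat(frames, ignore_index=True)

    rows = []
    n_total = len(point_table)
    for value in ("signed", "absolute"):
        for region in ("all", "condyle", "ramus", "corpus"):
            sel = point_table if region == "all" else point_table[point_table["region"] == region]
            if len(sel) < 2:
                continue
            row = summarize(sel[value]).row()
            try:
                _, p = one_sample_t(sel[value])
            except ValueError:
                p = np.nan
            row.update(
                {
                    "Distance": value,
                    "Region": "Total" if region == "all" else region,
                    "percent": 100.0 * len(sel) / n_total,
                    "p": p,
                    "test": "t vs 0",
                }
            )
            rows.append(row)
    by_region = pd.DataFrame(rows)[
        ["Distance", "Region", "N", "percent", "Mean", "SD", "Minimum", "Maximum", "Median", "CI95_low", "CI95_high", "p", "test"]
    ]
    return by_class, by_region
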