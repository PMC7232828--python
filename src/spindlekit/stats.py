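"""Group-level statistical battery.

Two-sample comparisons are gated by Anderson-Darling normality on both
samples: if both pass at the chosen alpha the Welch two-sample t-test is
used, otherwise the Wilcoxon rank-sum test.  Effect size is the classical
pooled-SD Cohen's d regardless of the variance assumption of the test.
Families of p-values are adjusted with the step-down Holm procedure.
Within-subject drug/genotype contrasts are one-way ANOVAs on the per-subject
week-2 minus week-1 differences across the four treatment groups, and the
spindle-behavior link is a Pearson correlation between the Rest1-to-Rest2
change in spindle density and mean latency to fall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.diagnostic import normal_ad
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    test_name: str            # t | wilcoxon_ranksum | paired_t | anova1
    statistic: float
    df: float | tuple
    p: float
    effect_d: float = np.nan  # pooled-SD Cohen's d (two-sample only)
    n_per_group: tuple = ()

    def to_dict(self) -> dict:
        return {"test_name": self.test_name, "statistic": self.statistic,
                "df": self.df, "p": self.p, "effect_d": self.effect_d,
                "n_per_group": list(self.n_per_group)}


def cohens_d(x, y) -> float:
    """Classical pooled-SD standardized mean difference (mean_x - mean_y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        raise ValueError("zero pooled variance")
    return float((x.mean() - y.mean()) / pooled)


def choose_test(x, y, alpha: float = 0.05) -> str:
    """Anderson-Darling gate: both samples normal -> Welch t, else rank-sum."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if min(x.size, y.size) < 4:
        raise ValueError("need n >= 4 per sample for the normality gate")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("degenerate (constant) sample")
    p_x, p_y = normal_ad(x)[1], normal_ad(y)[1]
    name = "t" if (p_x > alpha and p_y > alpha) else "wilcoxon_ranksum"
    log.debug("normality p = (%.3g, %.3g) at alpha %.3g -> %s", p_x, p_y, alpha, name)
    return name


def two_sample_compare(x, y, test_name: str | None = None,
                       alpha: float = 0.05) -> ComparisonResult:
    """Two-sided two-sample comparison with pooled-SD Cohen's d.

    With ``test_name=None`` the Anderson-Darling gate picks the test.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if test_name is None:
        test_name = choose_test(x, y, alpha)
    d = cohens_d(x, y)
    if test_name == "t":
        res = spstats.ttest_ind(x, y, equal_var=False)
        return ComparisonResult("t", float(res.statistic), float(res.df),
                                float(res.pvalue), d, (x.size, y.size))
    if test_name == "wilcoxon_ranksum":
        stat, p = spstats.ranksums(x, y)
        return ComparisonResult("wilcoxon_ranksum", float(stat), np.nan, float(p),
                                d, (x.size, y.size))
    if test_name == "paired_t":
        if x.size != y.size:
            raise ValueError("paired test needs equal-length samples")
        res = spstats.ttest_rel(x, y)
        return ComparisonResult("paired_t", float(res.statistic), float(x.size - 1),
                                float(res.pvalue), d, (x.size, y.size))
    raise ValueError(f"unknown test {test_name!r}")


def holm_adjust(pvals) -> np.ndarray:
    """Step-down Holm adjustment; input order preserved, monotone, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def within_subject_contrast(week1, week2, groups) -> ComparisonResult:
    """One-way ANOVA of the per-subject (week2 - week1) difference across groups."""
    week1, week2 = np.asarray(week1, float), np.asarray(week2, float)
    groups = np.asarray(groups)
    if not week1.size == week2.size == groups.size:
        raise ValueError("week1, week2 and groups must be paired by subject")
    diff = week2 - week1
    levels, counts = np.unique(groups, return_counts=True)
    if np.any(counts < 2):
        small = levels[counts < 2].tolist()
        raise ValueError(f"groups with n < 2: {small}")
    samples = [diff[groups == g] for g in levels]
    if all(s.var() == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
        # all differences identical: no between- or within-group variance
        return ComparisonResult("anova1", 0.0, (len(levels) - 1, diff.size - len(levels)),
                                1.0, n_per_group=tuple(counts))
    f, p = spstats.f_oneway(*samples)
    return ComparisonResult("anova1", float(f),
                            (len(levels) - 1, diff.size - len(levels)), float(p),
                            n_per_group=tuple(counts))


def learning_slope(trials: pd.DataFrame, alpha: float = 0.05) -> dict:
    """OLS of latency on trial number; the day counts as a learning day when
    the slope is positive with p < alpha.

    ``trials`` needs columns ``trial`` and ``latency_s`` (>= 5 rows).
    """
    if len(trials) < 5:
        raise ValueError("need >= 5 trials for a learning slope")
    x = trials["trial"].to_numpy(float)
    y = trials["latency_s"].to_numpy(float)
    if np.ptp(y) == 0:
        return {"slope": 0.0, "t": 0.0, "p": 1.0, "learning_day": False}
    res = spstats.linregress(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    return {"slope": float(res.slope), "t": float(t), "p": float(res.pvalue),
            "learning_day": bool(res.slope > 0 and res.pvalue < alpha)}


def spindle_behavior_correlation(delta_density, performance) -> tuple[float, float]:
    """Pearson R (two-sided p) between spindle-density change and mean latency."""
    x = np.asarray(delta_density, float)
    y = np.asarray(performance, float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need paired vectors with n >= 5")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = spstats.pearsonr(x, y)
    return float(r), float(p)


def compare_groups_table(df: pd.DataFrame, metric_cols, group_col: str,
                         group_a, group_b, alpha: float = 0.05,
                         holm_family: bool = True) -> pd.DataFrame:
    """Gated two-sample comparison of each metric between two groups.

    Returns one row per metric with test, statistic, df, raw and (optionally)
    Holm-adjusted p within the metric family, |d| and group sizes.
    """
    records = []
    for col in metric_cols:
        x = df.loc[df[group_col] == group_a, col].dropna().to_numpy()
        y = df.loc[df[group_col] == group_b, col].dropna().to_numpy()
        res = two_sample_compare(x, y, alpha=alpha)
        rec = res.to_dict()
        rec["metric"] = col
        rec["mean_a"], rec["mean_b"] = float(np.mean(x)), float(np.mean(y))
        records.append(rec)
    out = pd.DataFrame(records)
    if holm_family and len(out):
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out
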