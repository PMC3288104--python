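"""Group-level statistics for paired baseline / post-drug outcome measures.

Implements the study's battery: paired two-tailed t-tests with
paired-difference Cohen's d, per-subject percent change, a split-plot
repeated-measures ANOVA (region within scan, condition between scans — the
two scans of each subject are treated as separate scan units), and Pearson
correlation preceded by a Kolmogorov-Smirnov normality check.  No multiple-
comparison correction is applied anywhere (uncorrected alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedComparison",
    "paired_t",
    "percent_change",
    "rm_anova",
    "pearson_with_normality",
    "paired_comparison",
]


@dataclass(frozen=True)
class PairedComparison:
    """Paired baseline/post summary for one region or composite.

    Sign convention: d = mean(base − post) / SD(base − post), so an
    *increase* post-drug yields a negative d.
    """

    n: int
    baseline_mean: float
    baseline_sd: float
    post_mean: float
    post_sd: float
    percent_change_mean: float
    percent_change_sd: float
    t: float
    p: float
    cohen_d: float


def paired_t(baseline, post):
    """Classical paired two-tailed t-test plus paired-difference Cohen's d.

    Returns (t, p, d) with d = mean(base − post) / SD(base − post, ddof=1).
    Zero-variance differences make d undefined (NaN); t is 0 and p is 1
    when the differences are identically zero.
    """
    base = np.asarray(baseline, dtype=float)
    post = np.asarray(post, dtype=float)
    if base.shape != post.shape or base.size < 2:
        raise ValueError("paired samples of equal length n >= 2 required")
    diff = base - post
    sd = np.std(diff, ddof=1)
    if sd == 0:
        d = np.nan
        if np.all(diff == 0):
            return 0.0, 1.0, d
        # constant non-zero difference: t is infinite in the limit
        return np.inf * np.sign(diff[0]), 0.0, d
    res = stats.ttest_rel(base, post)
    d = float(np.mean(diff) / sd)
    return float(res.statistic), float(res.pvalue), d


def percent_change(baseline, post):
    """Mean ± SD over subjects of 100·(post − base)/base.

    Note this is a mean of per-subject ratios; it is *not* recoverable from
    the group means (mean-of-ratios ≠ ratio-of-means).
    """
    base = np.asarray(baseline, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(base == 0):
        raise ValueError("percent change undefined for zero baseline")
    pct = 100.0 * (post - base) / base
    sd = float(np.std(pct, ddof=1)) if pct.size > 1 else 0.0
    return float(np.mean(pct)), sd


def paired_comparison(baseline, post) -> PairedComparison:
    """Full Table-style row: means, SDs, percent change, t, p, d."""
    base = np.asarray(baseline, dtype=float)
    postv = np.asarray(post, dtype=float)
    t, p, d = paired_t(base, postv)
    pc_mean, pc_sd = percent_change(base, postv)
    return PairedComparison(
        n=base.size,
        baseline_mean=float(base.mean()),
        baseline_sd=float(base.std(ddof=1)),
        post_mean=float(postv.mean()),
        post_sd=float(postv.std(ddof=1)),
        percent_change_mean=pc_mean,
        percent_change_sd=pc_sd,
        t=t,
        p=p,
        cohen_d=d,
    )


def rm_anova(values: pd.DataFrame, design: str = "between-scan") -> pd.DataFrame:
    """Repeated-measures ANOVA of subject × region × condition outcome values.

    Parameters
    ----------
    values : DataFrame
        Long format with columns ``subject``, ``region``, ``condition``,
        ``value``; the design must be balanced and complete.
    design : {"between-scan", "within-subject"}
        ``"between-scan"`` (default, the study design): each
        subject × condition scan is a separate unit, region is the
        within-scan factor and condition the between-scan factor
        (split-plot ANOVA).  ``"within-subject"`` instead treats both
        region and condition as within-subject factors (fully repeated
        two-way ANOVA) — provided as an alternative, not the study method.

    Returns
    -------
    DataFrame with one row per effect (condition, region,
    region × condition) and columns ``effect``, ``F``, ``df1``, ``df2``,
    ``p``.
    """
    import pingouin as pg

    df = values.copy()
    required = {"subject", "region", "condition", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"need columns {sorted(required)}")
    counts = df.groupby(["subject", "region", "condition"]).size()
    if counts.size != df["subject"].nunique() * df["region"].nunique() * df["condition"].nunique() or (
        counts != 1
    ).any():
        raise ValueError("design must be balanced and complete (one value per cell)")
    if design == "between-scan":
        df["scan"] = df["subject"].astype(str) + "/" + df["condition"].astype(str)
        aov = pg.mixed_anova(
            data=df, dv="value", within="region", subject="scan", between="condition"
        )
        key = {"condition": "condition", "region": "region", "Interaction": "region:condition"}
        rows = []
        for _, r in aov.iterrows():
            rows.append(
                {
                    "effect": key.get(r["Source"], r["Source"]),
                    "F": float(r["F"]),
                    "df1": float(r["DF1"]),
                    "df2": float(r["DF2"]),
                    "p": float(r["p_unc"]),
                }
            )
        return pd.DataFrame(rows)
    if design == "within-subject":
        aov = pg.rm_anova(
            data=df, dv="value", within=["region", "condition"], subject="subject"
        )
        rows = []
        for _, r in aov.iterrows():
            name = r["Source"].replace(" * ", ":")
            rows.append(
                {
                    "effect": name,
                    "F": float(r["F"]),
                    "df1": float(r["ddof1"]),
                    "df2": float(r["ddof2"]),
                    "p": float(r["p_unc"]),
                }
            )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown design {design!r}")


def pearson_with_normality(x, y, alpha: float = 0.05):
    """Pearson r with a Kolmogorov-Smirnov normality pre-check on each variable.

    The KS test compares each variable against a normal distribution with
    the sample mean and SD (estimated-parameter reference).  Returns
    (r, p, ks_pass) where ks_pass is True when neither variable rejects
    normality at ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("paired samples of equal length n >= 3 required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    ks_pass = True
    for v in (x, y):
        ks = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
        if ks.pvalue < alpha:
            ks_pass = False
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), ks_pass
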