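"""Cohort aggregation and descriptive statistics for per-segment metrics.

The unit of exchange is a *tidy* table with one row per participant x
condition x segment x metric (columns: ``participant``, ``group``,
``condition``, ``segment``, ``metric``, ``value``).  Inferential modelling
(mixed-effects and the like) is deliberately out of scope — the tidy table
is the hand-off boundary to any statistics package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from gaitvar._exceptions import DataError

TIDY_COLUMNS = ["participant", "group", "condition", "segment", "metric", "value"]

BOOT_RESAMPLES = 5000
CI_LEVEL = 0.99


@dataclass
class EffectSizeResult:
    """Hedges' g with a bias-corrected percentile bootstrap CI."""

    g: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    level: float = CI_LEVEL


def validate_tidy(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"tidy metric table is missing columns {missing}")
    return df


def aggregate_segments(df: pd.DataFrame) -> pd.DataFrame:
    """Mean of available segments per participant x condition x metric.

    Participants with a single segment for a metric keep that segment's
    value and are flagged (``single_segment`` column).
    """
    validate_tidy(df)
    grouped = (
        df.groupby(["participant", "group", "condition", "metric"], sort=True)
        ["value"]
        .agg(value="mean", n_segments="count")
        .reset_index()
    )
    grouped["single_segment"] = grouped["n_segments"] == 1
    return grouped


def pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled standard deviation with n-1 weighting."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    return float(np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)))


def _hedges_correction(n_total: int) -> float:
    return 1.0 - 3.0 / (4.0 * n_total - 9.0)


def hedges_g_from_summary(mean1: float, sd1: float, n1: int,
                          mean2: float, sd2: float, n2: int) -> float:
    """Hedges' g from group summary statistics (no CI)."""
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if sp == 0:
        raise DataError("zero pooled standard deviation; effect undefined")
    return float((mean1 - mean2) / sp * _hedges_correction(n1 + n2))


def hedges_g(group_a, group_b, *, level: float = CI_LEVEL,
             n_boot: int = BOOT_RESAMPLES, seed: int = 0) -> EffectSizeResult:
    """Hedges' g for group_a minus group_b with a bootstrap CI.

    g = d * (1 - 3 / (4 N - 9)) with d the pooled-SD standardized mean
    difference.  The CI is a bias-corrected percentile bootstrap
    (independent resampling within groups, ``n_boot`` resamples, seeded).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("need at least 2 observations per group")
    sp = pooled_sd(a, b)
    if sp == 0:
        raise DataError("zero pooled standard deviation; effect undefined")
    corr = _hedges_correction(len(a) + len(b))
    g = float((a.mean() - b.mean()) / sp * corr)

    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    ra, rb = a[ia], b[ib]
    va = ra.var(axis=1, ddof=1)
    vb = rb.var(axis=1, ddof=1)
    sp_b = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb)
                   / (len(a) + len(b) - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = (ra.mean(axis=1) - rb.mean(axis=1)) / sp_b * corr
    boots = boots[np.isfinite(boots)]
    if len(boots) == 0:
        raise DataError("all bootstrap resamples degenerate")

    # bias-corrected percentile interval
    prop = np.clip(np.mean(boots < g), 1.0 / (len(boots) + 1),
                   1.0 - 1.0 / (len(boots) + 1))
    z0 = sps.norm.ppf(prop)
    zc = sps.norm.ppf(0.5 + level / 2.0)
    p_lo = sps.norm.cdf(2 * z0 - zc)
    p_hi = sps.norm.cdf(2 * z0 + zc)
    ci_low, ci_high = np.quantile(boots, [p_lo, p_hi])

    return EffectSizeResult(
        g=g, ci_low=float(min(ci_low, g)), ci_high=float(max(ci_high, g)),
        n1=len(a), n2=len(b),
        mean1=float(a.mean()), mean2=float(b.mean()),
        sd1=float(a.std(ddof=1)), sd2=float(b.std(ddof=1)),
        level=level,
    )


def relative_change(normal_mean: float, metronome_mean: float) -> float:
    """Percent change from the normal-condition mean to the other condition."""
    if normal_mean == 0:
        raise DataError("zero baseline mean; relative change undefined")
    return 100.0 * (metronome_mean - normal_mean) / normal_mean


def remove_outliers(df: pd.DataFrame, n_sd: float = 3.0) -> pd.DataFrame:
    """Drop rows whose value lies beyond ``n_sd`` SDs of its metric mean.

    Off by default in every pipeline; removals are returned dropped from a
    copy (callers log the difference).
    """
    validate_tidy(df)
    out = []
    for _, sub in df.groupby("metric", sort=False):
        mu, sd = sub["value"].mean(), sub["value"].std(ddof=1)
        if sd > 0:
            sub = sub[np.abs(sub["value"] - mu) <= n_sd * sd]
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def cohort_table(records: pd.DataFrame, metrics: list[str] | None = None,
                 group_a: str = "older", group_b: str = "young",
                 *, level: float = CI_LEVEL, n_boot: int = BOOT_RESAMPLES,
                 seed: int = 0) -> pd.DataFrame:
    """Descriptive cohort summary from segment-aggregated records.

    One row per metric x condition with per-group N/mean/SD and, when both
    groups are present, Hedges' g (group_a minus group_b) with its CI.
    Missing-group cells are left as NaN and flagged.
    """
    if "n_segments" not in records.columns:
        records = aggregate_segments(records)
    metrics = metrics or sorted(records["metric"].unique())
    rows = []
    for metric in metrics:
        sub_m = records[records["metric"] == metric]
        for condition in sorted(sub_m["condition"].unique()):
            sub = sub_m[sub_m["condition"] == condition]
            a = sub.loc[sub["group"] == group_a, "value"].dropna().to_numpy()
            b = sub.loc[sub["group"] == group_b, "value"].dropna().to_numpy()
            row = {
                "metric": metric, "condition": condition,
                f"n_{group_a}": len(a),
                f"mean_{group_a}": a.mean() if len(a) else np.nan,
                f"sd_{group_a}": a.std(ddof=1) if len(a) > 1 else np.nan,
                f"n_{group_b}": len(b),
                f"mean_{group_b}": b.mean() if len(b) else np.nan,
                f"sd_{group_b}": b.std(ddof=1) if len(b) > 1 else np.nan,
                "g": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "flag": "",
            }
            if len(a) >= 2 and len(b) >= 2:
                es = hedges_g(a, b, level=level, n_boot=n_boot, seed=seed)
                row.update(g=es.g, ci_low=es.ci_low, ci_high=es.ci_high)
            else:
                row["flag"] = "missing_group"
            rows.append(row)
    return pd.DataFrame(rows)


def metric_correlation(records: pd.DataFrame, metric_x: str, metric_y: str,
                       ) -> tuple[float, float, int]:
    """Pearson r between two metrics across participant x condition cells.

    Returns ``(r, p, n)``.
    """
    if "n_segments" not in records.columns:
        records = aggregate_segments(records)
    wide = records.pivot_table(index=["participant", "condition"],
                               columns="metric", values="value")
    if metric_x not in wide.columns or metric_y not in wide.columns:
        raise DataError(f"metrics {metric_x!r}/{metric_y!r} not both present")
    sub = wide[[metric_x, metric_y]].dropna()
    if len(sub) < 3:
        raise DataError("need at least 3 complete pairs for a correlation")
    r, p = sps.pearsonr(sub[metric_x], sub[metric_y])
    return float(r), float(p), len(sub)
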