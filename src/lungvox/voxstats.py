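"""Voxel-wise statistics comparing diffusion metrics across CT patterns.

The analysis pools overlapping co-registered voxels across subjects into a
flat table (subject, voxel, pattern, ADC, Lm_D, timepoint), keeps every
20th voxel in raster order (the cohort-scale analyses used ~4 million
overlapping voxels), and then runs:

* one-way ANOVA plus Tukey-Kramer post hoc comparisons of the diffusion
  metrics between the five consolidated CT patterns;
* a relevance classification of each significant difference against the
  a-priori same-day reproducibility ranges (+/-0.041 cm^2/s for ADC,
  +/-18.5 um for Lm_D): a difference is practically relevant when the
  bound of its 95% CI farthest from zero exceeds the half-width;
* an abnormality threshold for Lm_D from the 95% upper limit of healthy
  voxel values, and a Bland-Altman comparison of the lung percentage
  flagged abnormal by Lm_D versus by CT ILD patterns (ground-glass,
  reticular, honeycomb);
* Welch t-tests between groups and per-pattern longitudinal comparisons
  of year-1 versus baseline voxel values, stratified by the pattern
  observed on the baseline CT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import CONSOLIDATED5, ILD_PATTERNS

#: a-priori relevance half-widths (same-day reproducibility): metric -> units
DEFAULT_RELEVANCE = {"ADC": 0.041, "LmD": 18.5}

VOXEL_TABLE_COLUMNS = ["subject_id", "voxel_index", "pattern", "ADC", "LmD", "timepoint"]


@dataclass(frozen=True)
class RelevanceRange:
    metric: str  # ADC or LmD
    half_width: float

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("relevance half-width must be positive")


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class BlandAltmanResult:
    pairs: list
    bias: float
    loa_low: float
    loa_high: float
    sd: float


# ---------------------------------------------------------------------------
# table construction

def build_overlap_table(
    metric_maps: dict,
    caliper5,
    subject_id: str,
    timepoint: str = "baseline",
) -> pd.DataFrame:
    """Rows for voxels where metric validity and a nonzero pattern overlap.

    ``metric_maps`` maps 'ADC'/'LmD' to ParameterMaps on the common grid;
    ``caliper5`` is the consolidated label map on the same grid.  A voxel
    contributes a row only if every supplied metric is valid there and the
    consolidated pattern is nonzero.
    """
    if caliper5.scheme != "consolidated5":
        raise ValueError("expected a consolidated5 label map")
    shape = caliper5.labels.shape
    for name, pmap in metric_maps.items():
        if pmap.values.shape != shape:
            raise ValueError(f"metric map {name!r} is not on the common grid")
    ok = caliper5.labels > 0
    for pmap in metric_maps.values():
        ok &= pmap.validity_mask
    idx = np.flatnonzero(ok.ravel())  # raster order
    name_of = dict(CONSOLIDATED5)
    rows = {
        "subject_id": np.repeat(subject_id, idx.size),
        "voxel_index": idx,
        "pattern": [name_of[int(c)] for c in caliper5.labels.ravel()[idx]],
        "ADC": np.nan,
        "LmD": np.nan,
        "timepoint": np.repeat(timepoint, idx.size),
    }
    for name in ("ADC", "LmD"):
        if name in metric_maps:
            rows[name] = metric_maps[name].values.ravel()[idx]
    return pd.DataFrame(rows, columns=VOXEL_TABLE_COLUMNS)


def sample_every_k(table: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Keep rows at positions 0, k, 2k, ... per subject and timepoint.

    Deterministic raster-order decimation: the cohort analyses keep 5% of
    the overlapping voxels (every 20th).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1 or len(table) == 0:
        return table.copy()
    keep = table.groupby(["subject_id", "timepoint"], sort=False).cumcount() % k == 0
    return table[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# ANOVA / Tukey

def _group_arrays(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))  # stable order of appearance
    arrs = [values[groups == g] for g in labels]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    for g, a in zip(labels, arrs):
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than two values")
    return labels, arrs


def anova_oneway(values, groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on pooled voxel values."""
    labels, arrs = _group_arrays(values, groups)
    k = len(arrs)
    n = sum(len(a) for a in arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = k - 1, n - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    F = ms_b / ms_w if ms_w > 0 else np.inf
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p)


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons with studentized-range CIs.

    Handles unequal group sizes; returns one row per unordered pair with
    the mean difference (group_a - group_b), the simultaneous 95% CI, the
    adjusted p-value and a significance flag.
    """
    labels, arrs = _group_arrays(values, groups)
    k = len(arrs)
    n = sum(len(a) for a in arrs)
    df_w = n - k
    ms_w = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_w
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, df_w))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrs[i], arrs[j]
            diff = a.mean() - b.mean()
            # Tukey-Kramer: q = |diff| / sqrt(MSW/2 (1/na + 1/nb))
            se = np.sqrt(ms_w / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
            half = q_crit * se
            q_obs = abs(diff) / se if se > 0 else np.inf
            p_adj = float(stats.studentized_range.sf(q_obs, k, df_w))
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_difference": diff,
                    "ci_low": diff - half,
                    "ci_high": diff + half,
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return pd.DataFrame(rows)


def relevance_classify(ci: tuple[float, float], rng: RelevanceRange) -> bool:
    """Is a significant difference practically relevant?

    A difference is relevant when its 95% CI reaches beyond the a-priori
    reproducibility half-width: the CI bound farthest from zero exceeds
    the half-width.
    """
    low, high = ci
    if low > high:
        raise ValueError("CI low bound exceeds high bound")
    return bool(max(abs(low), abs(high)) > rng.half_width)


# ---------------------------------------------------------------------------
# abnormality threshold / Bland-Altman

def healthy_threshold(healthy_values, level: float = 0.95) -> float:
    """Empirical upper percentile of healthy voxel values (order-statistic
    interpolation), used as the abnormality threshold."""
    v = np.asarray(healthy_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 100:
        raise ValueError("need at least 100 healthy voxel values")
    return float(np.percentile(v, 100.0 * level, method="linear"))


def abnormal_percentages(lmd_map, caliper5, mask, threshold_um: float):
    """(% of mask voxels with Lm_D above threshold, % carrying an ILD pattern).

    ILD patterns are ground-glass, reticular and honeycomb; hyperlucent
    (emphysema-like) voxels are structurally abnormal but not interstitial
    and are never counted on the CT side.
    """
    if threshold_um <= 0:
        raise ValueError("threshold must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    lmd = np.asarray(lmd_map.values if hasattr(lmd_map, "values") else lmd_map, dtype=float)
    if lmd.shape != mask.shape or caliper5.labels.shape != mask.shape:
        raise ValueError("inputs must share the common grid")
    n = int(mask.sum())
    pct_lmd = 100.0 * float(np.nansum((lmd > threshold_um) & mask)) / n
    ild_codes = [c for c, name in CONSOLIDATED5.items() if name in ILD_PATTERNS]
    pct_cal = 100.0 * float((np.isin(caliper5.labels, ild_codes) & mask).sum()) / n
    return pct_lmd, pct_cal


def bland_altman(pairs) -> BlandAltmanResult:
    """Agreement between per-subject abnormal percentages.

    Differences are CT minus Lm_D, so a negative bias means the diffusion
    metric flags more of the lung than CT.  Limits are bias +/- 1.96 times
    the sample SD of the differences.
    """
    pairs = [(float(c), float(l)) for c, l in pairs]
    if len(pairs) < 2:
        raise ValueError("need at least two subjects for Bland-Altman")
    d = np.array([c - l for c, l in pairs])
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(pairs, bias, bias - 1.96 * sd, bias + 1.96 * sd, sd)


# ---------------------------------------------------------------------------
# group comparisons

def compare_groups(values_a, values_b, pooled: bool = False):
    """Independent t-test (Welch by default) with a mean-difference CI.

    Returns dict with t, df, p, mean_difference (a - b) and its 95% CI.
    Degenerate zero-variance identical groups are flagged undefined.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return {
            "t": np.nan, "df": np.nan, "p": np.nan,
            "mean_difference": diff, "ci_low": diff, "ci_high": diff,
            "defined": False,
        }
    if pooled:
        df = len(a) + len(b) - 2
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    else:
        se2a, se2b = va / len(a), vb / len(b)
        se = np.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (
            se2a**2 / (len(a) - 1) + se2b**2 / (len(b) - 1)
        )
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return {
        "t": float(t), "df": float(df), "p": p,
        "mean_difference": diff,
        "ci_low": diff - tcrit * se, "ci_high": diff + tcrit * se,
        "defined": True,
    }


def longitudinal_compare(
    table_baseline: pd.DataFrame,
    table_year1: pd.DataFrame,
    relevance_ranges: dict[str, float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pattern year-1 vs baseline comparison, stratified by the pattern
    observed on the *baseline* CT (both tables carry baseline labels).

    One row per (pattern, metric) plus a global row per metric: baseline
    and year-1 mean +/- SD, mean difference (year 1 - baseline) with 95%
    CI, significance and practical relevance.  Patterns present at only
    one timepoint yield a row of NaN statistics.
    """
    ranges = dict(DEFAULT_RELEVANCE)
    if relevance_ranges:
        ranges.update(relevance_ranges)
    patterns = [name for code, name in CONSOLIDATED5.items() if code != 0]
    rows = []
    for metric in ("ADC", "LmD"):
        if metric not in table_baseline.columns:
            continue
        for pat in patterns + ["global"]:
            if pat == "global":
                vb = table_baseline[metric].to_numpy(dtype=float)
                vy = table_year1[metric].to_numpy(dtype=float)
            else:
                vb = table_baseline.loc[table_baseline["pattern"] == pat, metric].to_numpy(dtype=float)
                vy = table_year1.loc[table_year1["pattern"] == pat, metric].to_numpy(dtype=float)
            vb, vy = vb[np.isfinite(vb)], vy[np.isfinite(vy)]
            row = {
                "pattern": pat, "metric": metric,
                "n_baseline": len(vb), "n_year1": len(vy),
                "baseline_mean": vb.mean() if len(vb) else np.nan,
                "baseline_sd": vb.std(ddof=1) if len(vb) > 1 else np.nan,
                "year1_mean": vy.mean() if len(vy) else np.nan,
                "year1_sd": vy.std(ddof=1) if len(vy) > 1 else np.nan,
            }
            if len(vb) >= 2 and len(vy) >= 2:
                res = compare_groups(vy, vb)
                sig = bool(res["defined"] and res["p"] < alpha)
                row.update(
                    mean_difference=res["mean_difference"],
                    ci_low=res["ci_low"], ci_high=res["ci_high"],
                    p=res["p"], significant=sig,
                    relevant=sig
                    and relevance_classify(
                        (res["ci_low"], res["ci_high"]),
                        RelevanceRange(metric, ranges[metric]),
                    ),
                )
            else:
                row.update(
                    mean_difference=np.nan, ci_low=np.nan, ci_high=np.nan,
                    p=np.nan, significant=False, relevant=False,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def pattern_comparison_report(
    table: pd.DataFrame,
    metric: str,
    relevance_ranges: dict[str, float] | None = None,
    alpha: float = 0.05,
):
    """ANOVA + Tukey + relevance for one metric of a pooled voxel table."""
    ranges = dict(DEFAULT_RELEVANCE)
    if relevance_ranges:
        ranges.update(relevance_ranges)
    sub = table[np.isfinite(table[metric].to_numpy(dtype=float))]
    anova = anova_oneway(sub[metric].to_numpy(dtype=float), sub["pattern"].to_numpy())
    tukey = tukey_hsd(sub[metric].to_numpy(dtype=float), sub["pattern"].to_numpy(), alpha)
    rng = RelevanceRange(metric, ranges[metric])
    tukey["relevant"] = [
        bool(s and relevance_classify((lo, hi), rng))
        for s, lo, hi in zip(tukey["significant"], tukey["ci_low"], tukey["ci_high"])
    ]
    return anova, tukey
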