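"""Intra-/inter-reader agreement statistics for paired lesion measurements.

Given a measurement table (three estimates per lesion: reader 1 twice,
reader 2 once), this module builds per-subject difference sets and computes
the repeatability/reproducibility battery:

* within-subject SD ``s_w = sqrt( (1/2N) * sum_n (d_n - dbar)^2 )`` from the
  per-subject differences ``d_n`` between two estimates,
* coefficient of variation ``CoV = 100 * s_w / group mean``,
* Bland-Altman 95% limits of agreement ``+/- 1.96 * sqrt(2) * s_w``,
* mean difference with a t-based confidence interval,
* one-way random-effects single-measurement ICC with an F-based CI and the
  conventional poor/moderate/good/excellent banding,
* Levene's test comparing the difference variances of the small- and
  large-lesion groups,
* group-mean comparison (mean of the three estimates per lesion) with a
  paired t-test,
* the pilot-style sweep of the inter-reader difference SD ratio over a
  lesion-size threshold,

and assembles the full study grid (all six metrics x intra/inter x
small/large) plus Bland-Altman point sets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import LESION_CLASSES, METRIC_COLUMNS, METRICS
from .exceptions import (
    CompletenessError,
    ConfigurationError,
    DegenerateDataError,
    SampleSizeError,
)

COMPARISONS = ("intra", "inter")

#: (reader, replicate) of the two estimates entering each comparison.
_COMPARISON_PAIRS = {
    "intra": ((1, 1), (1, 2)),
    "inter": ((1, 1), (2, 1)),
}

LOA_FACTOR = 1.96 * math.sqrt(2.0)


# ---------------------------------------------------------------------------
# Difference construction


@dataclass
class DifferenceSet:
    """Per-subject differences for one metric x comparison x size class."""

    metric: str
    comparison: str
    lesion_class: str
    subject_ids: List[str]
    differences: np.ndarray
    pair_means: np.ndarray  # Bland-Altman x coordinates

    @property
    def n(self) -> int:
        return len(self.differences)

    @property
    def mean_difference(self) -> float:
        return float(np.mean(self.differences))


def _estimate_matrix(
    table: pd.DataFrame, metric: str, lesion_class: str, pairs
) -> Tuple[List[str], np.ndarray]:
    """Per-subject values of the two requested estimates, in table order."""
    if metric not in METRIC_COLUMNS:
        raise ConfigurationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    map_type, column = METRIC_COLUMNS[metric]
    sub = table[(table["map"] == map_type) & (table["lesion_class"] == lesion_class)]
    subjects = list(pd.unique(table["subject_id"]))
    values = np.empty((len(subjects), 2))
    missing = []
    for i, sid in enumerate(subjects):
        rows = sub[sub["subject_id"] == sid]
        for j, (reader, replicate) in enumerate(pairs):
            sel = rows[(rows["reader"] == reader) & (rows["replicate"] == replicate)]
            if len(sel) != 1:
                missing.append(f"{sid} (reader {reader}, replicate {replicate})")
                continue
            values[i, j] = float(sel[column].iloc[0])
    if missing:
        raise CompletenessError(
            f"measurement table incomplete for {metric}/{lesion_class}: missing " + "; ".join(missing)
        )
    return subjects, values


def build_differences(
    table: pd.DataFrame, metric: str, comparison: str, lesion_class: str
) -> DifferenceSet:
    """Per-subject paired differences for one cell of the study grid.

    ``intra`` pairs reader 1's first and second estimates
    (``d = x_rep1 - x_rep2``); ``inter`` pairs the first estimates of
    readers 1 and 2 (``d = x_reader1 - x_reader2``). One difference per
    subject, subject order as in the table.
    """
    if comparison not in _COMPARISON_PAIRS:
        raise ConfigurationError(f"comparison must be 'intra' or 'inter', got {comparison!r}")
    subjects, values = _estimate_matrix(table, metric, lesion_class, _COMPARISON_PAIRS[comparison])
    return DifferenceSet(
        metric=metric,
        comparison=comparison,
        lesion_class=lesion_class,
        subject_ids=subjects,
        differences=values[:, 0] - values[:, 1],
        pair_means=values.mean(axis=1),
    )


# ---------------------------------------------------------------------------
# Scalar agreement statistics


def _as_differences(d) -> np.ndarray:
    if isinstance(d, DifferenceSet):
        return np.asarray(d.differences, dtype=float)
    return np.asarray(d, dtype=float)


def within_subject_sd(d) -> float:
    """Within-subject SD ``sqrt( (1/2N) * sum (d_n - dbar)^2 )``.

    Accepts a :class:`DifferenceSet` or a plain sequence of differences.
    The 1/(2N) factor halves the difference variance because each
    difference carries the measurement noise of two estimates.
    """
    dn = _as_differences(d)
    if dn.size < 2:
        raise SampleSizeError(f"need at least 2 differences, got {dn.size}")
    return float(np.sqrt(np.sum((dn - dn.mean()) ** 2) / (2.0 * dn.size)))


def cov_percent(sw: float, group_mean: float) -> float:
    """Coefficient of variation: ``100 * s_w / group_mean`` (percent)."""
    if group_mean == 0:
        raise DegenerateDataError("group mean is zero; CoV undefined")
    return 100.0 * sw / group_mean


def limits_of_agreement(sw: float) -> float:
    """Bland-Altman 95% limits-of-agreement half-width ``1.96*sqrt(2)*s_w``.

    The limits are centred at zero: with no change in the underlying
    parameter, a difference between two measurements falls inside
    ``+/- 1.96*sqrt(2)*s_w`` with 95% probability.
    """
    if sw < 0:
        raise ConfigurationError(f"sw must be >= 0, got {sw}")
    return LOA_FACTOR * sw


def mean_difference_ci(d, alpha: float = 0.05) -> Tuple[float, float, float]:
    """Mean difference with its ``1-alpha`` t-interval ``(dbar, lo, hi)``."""
    dn = _as_differences(d)
    if dn.size < 2:
        raise SampleSizeError(f"need at least 2 differences, got {dn.size}")
    dbar = float(dn.mean())
    half = float(stats.t.ppf(1.0 - alpha / 2.0, dn.size - 1) * dn.std(ddof=1) / math.sqrt(dn.size))
    return dbar, dbar - half, dbar + half


# ---------------------------------------------------------------------------
# ICC


@dataclass
class IccResult:
    """One-way random-effects single-measurement ICC with F-based CI."""

    icc: float
    ci: Tuple[float, float]
    band: str
    n: int
    k: int


def icc_band(icc: float) -> str:
    """Agreement band: <0.5 poor, [0.5,0.75) moderate, [0.75,0.9) good, >=0.9 excellent."""
    if not np.isfinite(icc):
        return "not-computable"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def icc_oneway(pairs: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(1): one-way random-effects, single measurement.

    ``pairs`` is an (n_subjects, k) array of repeated measurements (k=2 in
    this study). The point estimate is ``(MSB - MSW) / (MSB + (k-1)*MSW)``
    from the one-way ANOVA over subjects; the CI comes from F-distribution
    quantiles of ``MSB/MSW`` with degrees of freedom ``(n-1, n*(k-1))``.
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ConfigurationError("pairs must be a 2-D array with k >= 2 measurements per subject")
    n, k = x.shape
    if n < 3:
        raise SampleSizeError(f"need at least 3 subjects for ICC, got {n}")
    row_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - row_means[:, None]) ** 2) / (n * (k - 1))
    if msb == 0.0 and msw == 0.0:
        raise DegenerateDataError("constant measurements: ICC undefined")
    if msw == 0.0:
        return IccResult(icc=1.0, ci=(1.0, 1.0), band="excellent", n=n, k=k)
    f_obs = msb / msw
    icc = (f_obs - 1.0) / (f_obs + k - 1.0)
    f_l = f_obs / stats.f.ppf(1.0 - alpha / 2.0, n - 1, n * (k - 1))
    f_u = f_obs * stats.f.ppf(1.0 - alpha / 2.0, n * (k - 1), n - 1)
    lo = (f_l - 1.0) / (f_l + k - 1.0)
    hi = (f_u - 1.0) / (f_u + k - 1.0)
    return IccResult(icc=float(icc), ci=(float(lo), float(hi)), band=icc_band(icc), n=n, k=k)


# ---------------------------------------------------------------------------
# Levene's test


@dataclass
class LeveneResult:
    """Levene's test of equal variances across groups."""

    statistic: float
    df: Tuple[int, int]
    p_value: float
    center: str


def levene_equal_variance(
    d_small, d_large, center: str = "mean"
) -> LeveneResult:
    """Classic Levene test on the absolute deviations from the group center.

    ``W`` is the one-way ANOVA F statistic of the ``z_ij = |x_ij - c_i|``
    with ``c_i`` the group mean (or median, Brown-Forsythe style, with
    ``center='median'``); the p-value comes from ``F(k-1, N-k)``.
    """
    groups = [np.asarray(d_small, dtype=float), np.asarray(d_large, dtype=float)]
    if any(g.size < 2 for g in groups):
        raise SampleSizeError("each group needs at least 2 values for Levene's test")
    if center not in ("mean", "median"):
        raise ConfigurationError(f"center must be 'mean' or 'median', got {center!r}")
    cfun = np.mean if center == "mean" else np.median
    z = [np.abs(g - cfun(g)) for g in groups]
    n_i = np.array([g.size for g in z])
    k = len(z)
    n_total = int(n_i.sum())
    z_means = np.array([g.mean() for g in z])
    grand = float(np.concatenate(z).mean())
    ssb = float(np.sum(n_i * (z_means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(z, z_means)))
    df = (k - 1, n_total - k)
    if ssw == 0.0:
        if ssb == 0.0:
            raise DegenerateDataError("all absolute deviations identical: Levene W undefined")
        return LeveneResult(statistic=math.inf, df=df, p_value=0.0, center=center)
    w = (n_total - k) / (k - 1) * ssb / ssw
    return LeveneResult(
        statistic=float(w), df=df, p_value=float(stats.f.sf(w, *df)), center=center
    )


# ---------------------------------------------------------------------------
# Group means and thresholds


@dataclass
class GroupComparison:
    """Small- vs large-lesion group means with a paired t-test."""

    metric: str
    mean_small: float
    mean_large: float
    p_value: float
    zero_variance: bool
    n: int


def lesion_values(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-lesion value: mean of its three estimates, one row per subject x class."""
    if metric not in METRIC_COLUMNS:
        raise ConfigurationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    map_type, column = METRIC_COLUMNS[metric]
    sub = table[table["map"] == map_type]
    out = (
        sub.groupby(["subject_id", "lesion_class"], sort=False, observed=True)[column]
        .agg(["mean", "count"])
        .reset_index()
    )
    bad = out[out["count"] != 3]
    if len(bad):
        raise CompletenessError(
            f"{metric}: expected 3 estimates per lesion, offending subjects: "
            + ", ".join(f"{r.subject_id}/{r.lesion_class}" for r in bad.itertuples())
        )
    return out.rename(columns={"mean": "value"})[["subject_id", "lesion_class", "value"]]


def group_mean_comparison(table: pd.DataFrame, metric: str) -> GroupComparison:
    """Compare small- and large-lesion group means with a paired t-test.

    The per-lesion value is the mean of its three estimates. Subjects
    lacking either lesion raise a completeness error. When the paired
    differences have zero variance the t statistic is undefined; the
    result then reports p = 1 with ``zero_variance=True``.
    """
    per_lesion = lesion_values(table, metric)
    subjects = list(pd.unique(table["subject_id"]))
    wide = per_lesion.pivot(index="subject_id", columns="lesion_class", values="value")
    missing = [
        s for s in subjects
        if s not in wide.index or wide.loc[s].isna().any()
    ]
    if missing:
        raise CompletenessError(
            f"{metric}: subjects without both a small and a large lesion: " + ", ".join(missing)
        )
    wide = wide.loc[subjects]
    small = wide["small"].to_numpy(float)
    large = wide["large"].to_numpy(float)
    diffs = small - large
    if np.std(diffs, ddof=1) == 0.0:
        return GroupComparison(
            metric=metric,
            mean_small=float(small.mean()),
            mean_large=float(large.mean()),
            p_value=1.0,
            zero_variance=True,
            n=len(subjects),
        )
    t_res = stats.ttest_rel(small, large)
    return GroupComparison(
        metric=metric,
        mean_small=float(small.mean()),
        mean_large=float(large.mean()),
        p_value=float(t_res.pvalue),
        zero_variance=False,
        n=len(subjects),
    )


def sd_ratio_by_threshold(
    diameters_mm: Sequence[float],
    estimates_reader1: Sequence[float],
    estimates_reader2: Sequence[float],
    thresholds_mm: Sequence[float],
    ddof: int = 0,
) -> pd.DataFrame:
    """Pilot-style sweep of the inter-reader difference SD over a size threshold.

    For each threshold t, the SD of the two-reader differences among
    lesions with diameter < t is compared with the SD among lesions with
    diameter >= t; thresholds with fewer than two lesions on either side
    are marked not evaluable. The population (1/n) SD convention is the
    default (``ddof=0``).
    """
    d = np.asarray(diameters_mm, dtype=float)
    e1 = np.asarray(estimates_reader1, dtype=float)
    e2 = np.asarray(estimates_reader2, dtype=float)
    if d.size == 0:
        raise ConfigurationError("empty lesion list")
    if not (d.size == e1.size == e2.size):
        raise ConfigurationError("diameters and estimates must have equal length")
    diffs = e1 - e2
    rows = []
    for t in thresholds_mm:
        below = diffs[d < t]
        above = diffs[d >= t]
        evaluable = below.size >= 2 and above.size >= 2
        if evaluable:
            sd_below = float(np.std(below, ddof=ddof))
            sd_above = float(np.std(above, ddof=ddof))
            ratio = sd_below / sd_above if sd_above > 0 else math.inf
        else:
            sd_below = sd_above = ratio = math.nan
        rows.append(
            {
                "threshold_mm": float(t),
                "n_below": int(below.size),
                "n_above": int(above.size),
                "sd_below": sd_below,
                "sd_above": sd_above,
                "ratio": ratio,
                "evaluable": evaluable,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full study analysis


@dataclass
class AgreementSummary:
    """One cell of the study grid: metric x comparison x size class."""

    sw: float
    cov_percent: float
    loa_halfwidth: float
    mean_diff: float
    mean_diff_ci: Tuple[float, float]
    icc: float
    icc_ci: Tuple[float, float]
    icc_band: str
    n: int


@dataclass
class StudyReport:
    """The full agreement analysis of one measurement table.

    ``summaries`` maps (metric, comparison, lesion_class) to the cell
    summary; ``levene`` maps (metric, comparison) to the small-vs-large
    variance test; ``group_means`` maps metric to the paired group-mean
    comparison; ``bland_altman`` maps (metric, comparison) to the plot
    point set (per-subject mean of the two estimates vs their difference,
    with the size class and the zero-centred LoA half-width).
    """

    alpha: float
    summaries: Dict[Tuple[str, str, str], AgreementSummary]
    levene: Dict[Tuple[str, str], LeveneResult]
    group_means: Dict[str, GroupComparison]
    bland_altman: Dict[Tuple[str, str], pd.DataFrame]

    # -- serialisation -----------------------------------------------------

    def to_json_dict(self) -> dict:
        metrics: dict = {}
        for metric in METRICS:
            g = self.group_means[metric]
            node: dict = {
                "group_means": {
                    "mean_small": g.mean_small,
                    "mean_large": g.mean_large,
                    "paired_t_p": g.p_value,
                    "zero_variance": g.zero_variance,
                    "n": g.n,
                }
            }
            for comparison in COMPARISONS:
                lev = self.levene[(metric, comparison)]
                cnode: dict = {
                    "levene": {
                        "statistic": lev.statistic,
                        "df": list(lev.df),
                        "p_value": lev.p_value,
                        "center": lev.center,
                    }
                }
                for lesion_class in LESION_CLASSES:
                    s = self.summaries[(metric, comparison, lesion_class)]
                    cnode[lesion_class] = {
                        "sw": s.sw,
                        "cov_percent": s.cov_percent,
                        "loa_halfwidth": s.loa_halfwidth,
                        "mean_diff": s.mean_diff,
                        "mean_diff_ci": list(s.mean_diff_ci),
                        "icc": s.icc,
                        "icc_ci": list(s.icc_ci),
                        "icc_band": s.icc_band,
                        "n": s.n,
                    }
                ba = self.bland_altman[(metric, comparison)]
                cnode["bland_altman"] = {
                    "subject_id": ba["subject_id"].tolist(),
                    "lesion_class": ba["lesion_class"].tolist(),
                    "mean": ba["mean"].tolist(),
                    "difference": ba["difference"].tolist(),
                    "loa_center": ba["loa_center"].tolist(),
                    "loa_halfwidth": ba["loa_halfwidth"].tolist(),
                }
                node[comparison] = cnode
            metrics[metric] = node
        return {"alpha": self.alpha, "metrics": metrics}

    @classmethod
    def from_json_dict(cls, payload: dict) -> "StudyReport":
        summaries = {}
        levene = {}
        group_means = {}
        bland_altman = {}
        for metric, node in payload["metrics"].items():
            g = node["group_means"]
            group_means[metric] = GroupComparison(
                metric=metric,
                mean_small=g["mean_small"],
                mean_large=g["mean_large"],
                p_value=g["paired_t_p"],
                zero_variance=g["zero_variance"],
                n=g["n"],
            )
            for comparison in COMPARISONS:
                cnode = node[comparison]
                lev = cnode["levene"]
                levene[(metric, comparison)] = LeveneResult(
                    statistic=lev["statistic"],
                    df=tuple(lev["df"]),
                    p_value=lev["p_value"],
                    center=lev["center"],
                )
                for lesion_class in LESION_CLASSES:
                    s = cnode[lesion_class]
                    summaries[(metric, comparison, lesion_class)] = AgreementSummary(
                        sw=s["sw"],
                        cov_percent=s["cov_percent"],
                        loa_halfwidth=s["loa_halfwidth"],
                        mean_diff=s["mean_diff"],
                        mean_diff_ci=tuple(s["mean_diff_ci"]),
                        icc=s["icc"],
                        icc_ci=tuple(s["icc_ci"]),
                        icc_band=s["icc_band"],
                        n=s["n"],
                    )
                ba = cnode["bland_altman"]
                bland_altman[(metric, comparison)] = pd.DataFrame(
                    {
                        "subject_id": ba["subject_id"],
                        "lesion_class": ba["lesion_class"],
                        "mean": ba["mean"],
                        "difference": ba["difference"],
                        "loa_center": ba["loa_center"],
                        "loa_halfwidth": ba["loa_halfwidth"],
                    }
                )
        return cls(
            alpha=payload["alpha"],
            summaries=summaries,
            levene=levene,
            group_means=group_means,
            bland_altman=bland_altman,
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StudyReport":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))

    def _round_sig(self, x: float, sig: int) -> float:
        if x == 0 or not np.isfinite(x):
            return x
        return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)

    def to_table(self, rounded: bool = False) -> pd.DataFrame:
        """The study grid as a flat table, one row per metric x comparison.

        ``rounded=True`` applies presentation rounding: s_w and CoV to 3
        significant figures, ICC to 3 decimal places.
        """
        rows = []
        for metric in METRICS:
            g = self.group_means[metric]
            for comparison in COMPARISONS:
                lev = self.levene[(metric, comparison)]
                row = {"metric": metric, "comparison": comparison}
                for lesion_class in LESION_CLASSES:
                    s = self.summaries[(metric, comparison, lesion_class)]
                    sw = self._round_sig(s.sw, 3) if rounded else s.sw
                    cov = self._round_sig(s.cov_percent, 3) if rounded else s.cov_percent
                    icc = round(s.icc, 3) if rounded else s.icc
                    row.update(
                        {
                            f"sw_{lesion_class}": sw,
                            f"cov_{lesion_class}": cov,
                            f"meandiff_{lesion_class}": s.mean_diff,
                            f"meandiff_{lesion_class}_lo": s.mean_diff_ci[0],
                            f"meandiff_{lesion_class}_hi": s.mean_diff_ci[1],
                            f"icc_{lesion_class}": icc,
                            f"icc_{lesion_class}_lo": s.icc_ci[0],
                            f"icc_{lesion_class}_hi": s.icc_ci[1],
                            f"icc_band_{lesion_class}": s.icc_band,
                            f"loa_halfwidth_{lesion_class}": s.loa_halfwidth,
                        }
                    )
                row.update(
                    {
                        "levene_p": lev.p_value,
                        "mean_small": g.mean_small,
                        "mean_large": g.mean_large,
                        "ttest_p": g.p_value,
                        "n": g.n,
                    }
                )
                rows.append(row)
        return pd.DataFrame(rows)


def analyze_study(
    table: pd.DataFrame,
    alpha: float = 0.05,
    levene_center: str = "mean",
    loa_center_at_zero: bool = True,
) -> StudyReport:
    """Run the full agreement analysis on a complete measurement table.

    For every metric x comparison x size class: s_w, CoV (denominator =
    that class's group mean), zero-centred limits of agreement, mean
    difference with its t-interval, and ICC(1) with CI and band; per
    metric x comparison, Levene's test of the small vs large difference
    variances; per metric, the paired group-mean comparison. Bland-Altman
    point sets (x = mean of the two estimates, y = their difference) are
    attached per metric x comparison. Non-computable cells (degenerate
    variance) are marked NaN / ``not-computable`` rather than failing the
    whole report.
    """
    summaries: Dict[Tuple[str, str, str], AgreementSummary] = {}
    levene: Dict[Tuple[str, str], LeveneResult] = {}
    group_means: Dict[str, GroupComparison] = {}
    bland_altman: Dict[Tuple[str, str], pd.DataFrame] = {}

    for metric in METRICS:
        group = group_mean_comparison(table, metric)
        group_means[metric] = group
        per_lesion = lesion_values(table, metric)
        class_means = {
            cls: float(per_lesion[per_lesion["lesion_class"] == cls]["value"].mean())
            for cls in LESION_CLASSES
        }
        for comparison in COMPARISONS:
            diff_sets = {}
            ba_frames = []
            for lesion_class in LESION_CLASSES:
                dset = build_differences(table, metric, comparison, lesion_class)
                diff_sets[lesion_class] = dset
                sw = within_subject_sd(dset)
                dbar, lo, hi = mean_difference_ci(dset, alpha=alpha)
                subjects, values = _estimate_matrix(
                    table, metric, lesion_class, _COMPARISON_PAIRS[comparison]
                )
                try:
                    icc_res = icc_oneway(values, alpha=alpha)
                    icc_val, icc_ci_val, band = icc_res.icc, icc_res.ci, icc_res.band
                except DegenerateDataError:
                    icc_val, icc_ci_val, band = math.nan, (math.nan, math.nan), "not-computable"
                loa = limits_of_agreement(sw)
                summaries[(metric, comparison, lesion_class)] = AgreementSummary(
                    sw=sw,
                    cov_percent=cov_percent(sw, class_means[lesion_class]),
                    loa_halfwidth=loa,
                    mean_diff=dbar,
                    mean_diff_ci=(lo, hi),
                    icc=icc_val,
                    icc_ci=icc_ci_val,
                    icc_band=band,
                    n=dset.n,
                )
                ba_frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": dset.subject_ids,
                            "lesion_class": lesion_class,
                            "mean": dset.pair_means,
                            "difference": dset.differences,
                            "loa_center": 0.0 if loa_center_at_zero else dbar,
                            "loa_halfwidth": loa,
                        }
                    )
                )
            try:
                levene[(metric, comparison)] = levene_equal_variance(
                    diff_sets["small"].differences,
                    diff_sets["large"].differences,
                    center=levene_center,
                )
            except DegenerateDataError:
                levene[(metric, comparison)] = LeveneResult(
                    statistic=math.nan, df=(1, 2 * group.n - 2), p_value=math.nan,
                    center=levene_center,
                )
            bland_altman[(metric, comparison)] = pd.concat(ba_frames, ignore_index=True)

    return StudyReport(
        alpha=alpha,
        summaries=summaries,
        levene=levene,
        group_means=group_means,
        bland_altman=bland_altman,
    )
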