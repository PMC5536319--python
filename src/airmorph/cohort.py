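"""Cohort-level statistics: airway matching, regional aggregation, paired
tests and linear regression.

Summaries follow the per-airway-first averaging order: every quantity
(hydraulic diameter, percent change, diameter ratio, distensibility) is
computed per matched airway and then averaged within a group.  The
alternative — computing a quantity from group means — generally gives a
different number; the per-airway order is the one that matches how the
emulated study reports its tables.

Cells with fewer than ``min_n`` airways are suppressed (kept in the
output with their count, statistics set to NaN) rather than deleted, so
raising the threshold can only suppress more cells, never fewer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .anatomy import (
    AirwayMeasurement,
    LungVolumeState,
    MatchedAirway,
    parse_label,
)
from .distensibility import distensibility_table

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "match_airways",
    "PairedTestResult",
    "paired_t_test",
    "RegressionResult",
    "linear_regression",
    "summarize_region_generation",
    "fraction_decreasing",
    "gen3_vs_gen4_distensibility",
    "TWO_STATE_METRICS",
]

TWO_STATE_METRICS = ("dh", "ai", "pi", "din", "din_dh_ratio")
DEFAULT_MIN_N = 8


@dataclass(frozen=True)
class MatchResult:
    """Airways present at both inflations, plus what failed to match."""

    matches: list[MatchedAirway]
    n_unmatched_mlv: int
    n_unmatched_tlc: int
    unmatched_mlv: list[tuple[str, str]] = field(default_factory=list)
    unmatched_tlc: list[tuple[str, str]] = field(default_factory=list)


def match_airways(dataset) -> MatchResult:
    """Pair each (subject, label) present at both MLV and TLC.

    Unmatched measurements are counted per state and their keys returned;
    an empty result is legitimate (nothing matched).
    """
    by_key: dict[tuple[str, str], dict[LungVolumeState, AirwayMeasurement]] = {}
    for m in dataset.measurements:
        by_key.setdefault((m.subject_id, m.label.name), {})[m.state] = m
    matches: list[MatchedAirway] = []
    unmatched_mlv: list[tuple[str, str]] = []
    unmatched_tlc: list[tuple[str, str]] = []
    for (subject_id, label), states in sorted(by_key.items()):
        if LungVolumeState.MLV in states and LungVolumeState.TLC in states:
            matches.append(
                MatchedAirway(
                    subject_id=subject_id,
                    label=parse_label(label),
                    mlv=states[LungVolumeState.MLV],
                    tlc=states[LungVolumeState.TLC],
                )
            )
        elif LungVolumeState.MLV in states:
            unmatched_mlv.append((subject_id, label))
        else:
            unmatched_tlc.append((subject_id, label))
    logger.info(
        "matched %d airways; unmatched: %d MLV-only, %d TLC-only",
        len(matches),
        len(unmatched_mlv),
        len(unmatched_tlc),
    )
    return MatchResult(
        matches=matches,
        n_unmatched_mlv=len(unmatched_mlv),
        n_unmatched_tlc=len(unmatched_tlc),
        unmatched_mlv=unmatched_mlv,
        unmatched_tlc=unmatched_tlc,
    )


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_two_sided: float
    degenerate: bool = False


def paired_t_test(x, y) -> PairedTestResult:
    """Two-sided paired Student t-test of paired samples ``x`` vs ``y``.

    Computed in closed form: t = mean(d) / (sd(d)/sqrt(n)) on the paired
    differences d = x - y, with n-1 degrees of freedom.  Zero-variance
    differences give a degenerate result (flagged, statistics NaN) rather
    than a misleading number.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise ValueError("paired_t_test requires two equal-length 1-d samples")
    n = x_arr.size
    if n < 2:
        raise ValueError(f"paired_t_test requires >= 2 pairs, got {n}")
    d = x_arr - y_arr
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedTestResult(
            t_statistic=float("nan"),
            degrees_of_freedom=n - 1,
            p_two_sided=float("nan"),
            degenerate=True,
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(t_statistic=float(t), degrees_of_freedom=n - 1, p_two_sided=float(p))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares y = a*x + b with the squared Pearson
    correlation as R^2.  Requires >= 3 points and non-degenerate x."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise ValueError("linear_regression requires two equal-length 1-d samples")
    n = x_arr.size
    if n < 3:
        raise ValueError(f"linear_regression requires >= 3 points, got {n}")
    x_c = x_arr - x_arr.mean()
    y_c = y_arr - y_arr.mean()
    sxx = float(x_c @ x_c)
    if sxx == 0:
        raise ValueError("linear_regression: x has zero variance")
    sxy = float(x_c @ y_c)
    syy = float(y_c @ y_c)
    slope = sxy / sxx
    intercept = float(y_arr.mean() - slope * x_arr.mean())
    r_squared = 0.0 if syy == 0 else sxy**2 / (sxx * syy)
    return RegressionResult(slope=slope, intercept=intercept, r_squared=r_squared, n=n)


def _metric_values(m: MatchedAirway, metric: str) -> tuple[float, float]:
    if metric == "dh":
        return 4 * m.mlv.ai / m.mlv.pi, 4 * m.tlc.ai / m.tlc.pi
    if metric == "ai":
        return m.mlv.ai, m.tlc.ai
    if metric == "pi":
        return m.mlv.pi, m.tlc.pi
    if metric == "din":
        return m.mlv.din, m.tlc.din
    if metric == "din_dh_ratio":
        return (
            m.mlv.din * m.mlv.pi / (4 * m.mlv.ai),
            m.tlc.din * m.tlc.pi / (4 * m.tlc.ai),
        )
    raise ValueError(f"unknown metric {metric!r}; use one of {TWO_STATE_METRICS + ('ad',)}")


def matched_frame(matches, metric: str) -> pd.DataFrame:
    """Tidy per-matched-airway table of one metric at both states."""
    rows = []
    for m in matches:
        v_mlv, v_tlc = _metric_values(m, metric)
        rows.append(
            {
                "subject_id": m.subject_id,
                "label": m.label.name,
                "root": m.label.root,
                "generation": m.generation,
                "region": m.region.value,
                "side": m.side.value,
                "mlv": v_mlv,
                "tlc": v_tlc,
                "pct_change": 100.0 * (v_tlc - v_mlv) / v_mlv,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "label",
            "root",
            "generation",
            "region",
            "side",
            "mlv",
            "tlc",
            "pct_change",
        ],
    )


def _summarize_two_state(frame: pd.DataFrame, by: str, min_n: int) -> pd.DataFrame:
    group_col = "region" if by == "region" else "root"
    rows = []
    for (group, gen), sub in frame.groupby([group_col, "generation"], sort=True):
        n = len(sub)
        row = {
            group_col: group,
            "generation": gen,
            "n": n,
            "suppressed": n < min_n,
        }
        stat_fields = (
            "mlv_mean",
            "mlv_sd",
            "tlc_mean",
            "tlc_sd",
            "pct_change_mean",
            "pct_change_sd",
            "paired_t_p",
            "r_squared",
        )
        if n < min_n:
            row.update({k: np.nan for k in stat_fields})
        else:
            test = paired_t_test(sub["tlc"], sub["mlv"])
            try:
                reg_r2 = linear_regression(sub["mlv"], sub["tlc"]).r_squared
            except ValueError:
                reg_r2 = np.nan
            row.update(
                {
                    "mlv_mean": sub["mlv"].mean(),
                    "mlv_sd": sub["mlv"].std(ddof=1),
                    "tlc_mean": sub["tlc"].mean(),
                    "tlc_sd": sub["tlc"].std(ddof=1),
                    "pct_change_mean": sub["pct_change"].mean(),
                    "pct_change_sd": sub["pct_change"].std(ddof=1),
                    "paired_t_p": np.nan if test.degenerate else test.p_two_sided,
                    "r_squared": reg_r2,
                }
            )
        rows.append(row)
    columns = [group_col, "generation", "n", "mlv_mean", "mlv_sd", "tlc_mean", "tlc_sd",
               "pct_change_mean", "pct_change_sd", "paired_t_p", "r_squared", "suppressed"]
    return pd.DataFrame(rows, columns=columns)


def summarize_ad(ad_frame: pd.DataFrame, by: str = "root", min_n: int = DEFAULT_MIN_N) -> pd.DataFrame:
    """Distensibility summary per group: mean, SD, n and the R^2 of the
    regression of relative area change on relative volume change.

    Operates on a distensibility table; invalid and outlier-flagged
    records are excluded before aggregation.
    """
    usable = ad_frame[ad_frame["valid"].astype(bool) & ~ad_frame["outlier"].astype(bool)].copy()
    if by == "root":
        usable["group"] = usable["label"].map(lambda name: parse_label(name).root)
    elif by == "region":
        usable["group"] = usable["region"]
    else:
        raise ValueError(f"unknown grouping {by!r}; use 'root' or 'region'")
    rows = []
    for (group, gen), sub in usable.groupby(["group", "generation"], sort=True):
        n = len(sub)
        row = {by: group, "generation": gen, "n": n, "suppressed": n < min_n}
        if n < min_n:
            row.update({"ad_mean": np.nan, "ad_sd": np.nan, "r_squared": np.nan})
        else:
            try:
                r2 = linear_regression(sub["delta_v_rel"], sub["delta_ai_rel"]).r_squared
            except ValueError:
                r2 = np.nan
            row.update(
                {
                    "ad_mean": sub["ad"].mean(),
                    "ad_sd": sub["ad"].std(ddof=1),
                    "r_squared": r2,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=[by, "generation", "n", "ad_mean", "ad_sd", "r_squared", "suppressed"])


def summarize_region_generation(
    matches,
    metric: str,
    min_n: int = DEFAULT_MIN_N,
    volumes=None,
    by: str = "region",
) -> pd.DataFrame:
    """Per (region|subtree, generation) summary of a per-airway metric.

    For the two-state metrics (dh, ai, pi, din, din_dh_ratio) each cell
    carries state-wise mean and SD, the mean and SD of per-airway percent
    change, the paired-t p-value between states and the R^2 of the
    MLV-vs-TLC regression.  For ``metric="ad"`` (requires ``volumes``)
    each cell carries the distensibility mean, SD and area-vs-volume R^2.
    Cells with n < ``min_n`` are suppressed.
    """
    if metric == "ad":
        if volumes is None:
            raise ValueError("metric 'ad' requires the per-subject lung volumes")
        ad = distensibility_table(matches, volumes)
        return summarize_ad(ad, by="region" if by == "region" else "root", min_n=min_n)
    if metric not in TWO_STATE_METRICS:
        raise ValueError(f"unknown metric {metric!r}; use one of {TWO_STATE_METRICS + ('ad',)}")
    frame = matched_frame(matches, metric)
    return _summarize_two_state(frame, by=by, min_n=min_n)


def fraction_decreasing(matches, metric: str = "dh") -> float:
    """Share of matched airways whose metric is lower at TLC than at MLV."""
    matches = list(matches)
    if not matches:
        raise ValueError("fraction_decreasing requires at least one matched airway")
    n_down = 0
    for m in matches:
        v_mlv, v_tlc = _metric_values(m, metric)
        if v_tlc < v_mlv:
            n_down += 1
    return n_down / len(matches)


def gen3_vs_gen4_distensibility(
    ad_frame: pd.DataFrame,
    exclude: tuple[str, ...] = (),
) -> tuple[RegressionResult, pd.DataFrame]:
    """Regress per-subtree mean distensibility at generation 4 on that at
    generation 3.

    Each point is one segmental subtree (RB1..LB10) with valid,
    non-outlier records at both generations; subtrees listed in
    ``exclude`` are dropped before regressing.  Requires >= 3 points.
    Returns the regression and the point table.
    """
    usable = ad_frame[ad_frame["valid"].astype(bool) & ~ad_frame["outlier"].astype(bool)].copy()
    usable["root"] = usable["label"].map(lambda name: parse_label(name).root)
    means = (
        usable[usable["generation"].isin([3, 4])]
        .groupby(["root", "generation"])["ad"]
        .mean()
        .unstack("generation")
    )
    means = means.dropna()
    if means.empty or means.shape[1] < 2:
        points = pd.DataFrame(columns=["root", "ad_gen3", "ad_gen4"])
    else:
        points = means.reset_index().rename(columns={3: "ad_gen3", 4: "ad_gen4"})
    points = points[~points["root"].isin(exclude)]
    if len(points) < 3:
        raise ValueError(
            f"gen3-vs-gen4 regression requires >= 3 subtrees with both generations, "
            f"got {len(points)}"
        )
    reg = linear_regression(points["ad_gen3"].to_numpy(), points["ad_gen4"].to_numpy())
    return reg, points.reset_index(drop=True)
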