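"""Matching, paired tests, regression and regional aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from airmorph import (
    CohortDataset,
    LungVolumeRecord,
    fraction_decreasing,
    gen3_vs_gen4_distensibility,
    linear_regression,
    match_airways,
    paired_t_test,
    summarize_region_generation,
)
from airmorph.cohort import matched_frame, summarize_ad
from airmorph.distensibility import distensibility_table

from conftest import circular_measurement, matched


def test_match_airways_counts_unmatched():
    measurements = [
        circular_measurement("S01", "RB1", "MLV"),
        circular_measurement("S01", "RB1", "TLC", radius=2.2),
        circular_measurement("S01", "RB2", "TLC"),
    ]
    volumes = [
        LungVolumeRecord("S01", "right", 1.3, 2.3),
        LungVolumeRecord("S01", "left", 1.1, 2.0),
    ]
    dataset = CohortDataset(measurements, volumes).validate()
    result = match_airways(dataset)
    assert len(result.matches) == 1
    assert result.n_unmatched_tlc == 1 and result.n_unmatched_mlv == 0
    assert result.unmatched_tlc == [("S01", "RB2")]


def test_match_airways_empty_dataset():
    result = match_airways(CohortDataset([], []).validate())
    assert result.matches == [] and result.n_unmatched_mlv == 0


def test_gen5_matches_only_in_stated_segments(default_cohort):
    """Generation-5 matched airways exist only in the six subtrees where
    MLV segmentation is reliable."""
    dataset, _ = default_cohort
    matches = match_airways(dataset).matches
    gen5_roots = {m.label.root for m in matches if m.generation == 5}
    assert gen5_roots
    assert gen5_roots <= {"RB1", "RB3", "RB6", "RB10", "LB3", "LB10"}


def test_paired_t_closed_form():
    """Differences {1, 0, 2}: t = sqrt(3), df = 2, two-sided p = 0.2254."""
    result = paired_t_test([1.0, 0.0, 2.0], [0.0, 0.0, 0.0])
    assert result.t_statistic == pytest.approx(math.sqrt(3), rel=1e-12)
    assert result.degrees_of_freedom == 2
    assert result.p_two_sided == pytest.approx(0.2254, abs=5e-5)


def test_paired_t_degenerate_and_antisymmetric():
    degenerate = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert degenerate.degenerate and np.isnan(degenerate.p_two_sided)
    antisym = paired_t_test([-0.5, 0.5], [0.0, 0.0])
    assert antisym.t_statistic == pytest.approx(0.0)
    assert antisym.p_two_sided == pytest.approx(1.0)
    with pytest.raises(ValueError):
        paired_t_test([1.0], [2.0])


def test_linear_regression_exact_line_and_errors():
    result = linear_regression([0, 1, 2, 3], [1, 3, 5, 7])
    assert (result.slope, result.intercept, result.r_squared) == pytest.approx((2.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        linear_regression([0, 1], [1, 2])
    with pytest.raises(ValueError):
        linear_regression([2, 2, 2], [1, 2, 3])


def test_linear_regression_independent_noise_has_low_r2():
    rng = np.random.default_rng(7)
    x = rng.normal(size=2000)
    y = rng.normal(size=2000)
    assert linear_regression(x, y).r_squared < 0.05


def _matches_for_groups(n_per_label, labels=("RB1", "RB2"), growth=1.3):
    matches = []
    for label in labels:
        for i in range(n_per_label):
            matches.append(
                matched(subject=f"S{i:02d}", label=label, ai_mlv=10 + i, ai_tlc=(10 + i) * growth)
            )
    return matches


def test_summary_suppresses_small_cells():
    summary = summarize_region_generation(_matches_for_groups(7), "dh", min_n=8)
    row = summary[(summary["region"] == "RU") & (summary["generation"] == 3)].iloc[0]
    assert row["n"] == 14 and not row["suppressed"]
    by_root = summarize_region_generation(_matches_for_groups(7), "dh", min_n=8, by="root")
    assert by_root["suppressed"].all()  # 7 per subtree < 8
    assert by_root["mlv_mean"].isna().all()


def test_suppression_monotonicity(default_cohort):
    """Raising min_n can only suppress more cells, never fewer."""
    dataset, _ = default_cohort
    matches = match_airways(dataset).matches
    loose = summarize_region_generation(matches, "dh", min_n=5, by="root")
    strict = summarize_region_generation(matches, "dh", min_n=15, by="root")
    merged = loose.merge(strict, on=["root", "generation"], suffixes=("_5", "_15"))
    assert (merged["suppressed_5"] <= merged["suppressed_15"]).all()


def test_constant_metric_gives_zero_change_and_degenerate_test():
    summary = summarize_region_generation(_matches_for_groups(8, growth=1.0), "dh", min_n=8)
    row = summary.iloc[0]
    assert row["pct_change_mean"] == pytest.approx(0.0)
    assert np.isnan(row["paired_t_p"])  # degenerate paired differences


def test_unknown_metric_rejected():
    with pytest.raises(ValueError):
        summarize_region_generation(_matches_for_groups(3), "wall_area")


def test_ad_metric_requires_volumes(tiny_dataset):
    matches = match_airways(tiny_dataset).matches
    with pytest.raises(ValueError):
        summarize_region_generation(matches, "ad")
    summary = summarize_region_generation(
        matches, "ad", min_n=2, volumes=tiny_dataset.volumes, by="root"
    )
    assert {"ad_mean", "ad_sd", "r_squared"} <= set(summary.columns)


def test_aggregation_consistency(default_cohort):
    """The grand mean of per-airway percent change equals the n-weighted
    mean of unsuppressed group means."""
    dataset, _ = default_cohort
    matches = match_airways(dataset).matches
    frame = matched_frame(matches, "dh")
    summary = summarize_region_generation(matches, "dh", min_n=1)
    weighted = (summary["pct_change_mean"] * summary["n"]).sum() / summary["n"].sum()
    assert weighted == pytest.approx(frame["pct_change"].mean(), rel=1e-12)


def test_fraction_decreasing():
    all_up = [matched(subject=f"S{i}", ai_mlv=10, ai_tlc=12) for i in range(5)]
    assert fraction_decreasing(all_up, "dh") == 0.0
    one_down = all_up[:-1] + [matched(subject="S9", ai_mlv=10, ai_tlc=9)]
    assert fraction_decreasing(one_down, "ai") == pytest.approx(1 / 5)
    with pytest.raises(ValueError):
        fraction_decreasing([], "dh")


def _proportional_ad_frame():
    rows = []
    for i, root in enumerate(("RB1", "RB2", "RB3", "LB8", "LB9")):
        for gen, value in ((3, 0.3 + 0.1 * i), (4, 2 * (0.3 + 0.1 * i))):
            for j in range(3):
                rows.append(
                    {
                        "subject_id": f"S{j}",
                        "label": root if gen == 3 else f"{root}.1",
                        "generation": gen,
                        "region": "RU",
                        "side": "right",
                        "delta_ai_rel": 0.3,
                        "delta_v_rel": 0.8,
                        "ad": value,
                        "valid": True,
                        "reason": "",
                        "outlier": False,
                    }
                )
    return pd.DataFrame(rows)


def test_gen3_vs_gen4_perfectly_proportional():
    reg, points = gen3_vs_gen4_distensibility(_proportional_ad_frame())
    assert reg.r_squared == pytest.approx(1.0)
    assert reg.slope == pytest.approx(2.0)
    assert len(points) == 5


def test_gen3_vs_gen4_exclusion_and_minimum():
    frame = _proportional_ad_frame()
    reg, points = gen3_vs_gen4_distensibility(frame, exclude=("RB1", "LB9"))
    assert len(points) == 3
    with pytest.raises(ValueError):
        gen3_vs_gen4_distensibility(frame, exclude=("RB1", "RB2", "RB3"))


def test_summarize_ad_excludes_outliers_and_invalid():
    frame = _proportional_ad_frame()
    frame.loc[0, "outlier"] = True
    frame.loc[1, "valid"] = False
    summary = summarize_ad(frame, by="root", min_n=1)
    rb1_gen3 = summary[(summary["root"] == "RB1") & (summary["generation"] == 3)].iloc[0]
    assert rb1_gen3["n"] == 1
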