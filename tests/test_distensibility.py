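"""Volume-normalized distensibility: formula, outlier rule, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from airmorph import (
    LungVolumeRecord,
    compute_distensibility,
    distensibility_table,
    distribution_diagnostics,
    flag_outliers,
)

from conftest import matched


def right_volumes(subject="S01", v_mlv=1.294, v_tlc=2.286):
    return LungVolumeRecord(subject_id=subject, side="right", v_mlv=v_mlv, v_tlc=v_tlc)


def test_distensibility_cohort_mean_example():
    """Upper-lobe cohort means: area 47.85->63.28 mm2, right lung
    1.294->2.286 L gives AD = 0.3850."""
    airway = matched(label="RU", ai_mlv=47.85, ai_tlc=63.28)
    record = compute_distensibility(airway, right_volumes())
    assert record.valid
    assert record.ad == pytest.approx(0.3850, abs=1e-4)
    assert record.delta_ai_rel == pytest.approx(0.32247, abs=1e-5)


def test_distensibility_zero_when_area_unchanged():
    record = compute_distensibility(matched(label="RU", ai_mlv=50, ai_tlc=50), right_volumes())
    assert record.ad == 0.0


def test_distensibility_unit_invariance():
    """AD is a ratio of ratios: volumes in mL give the identical value."""
    airway = matched(label="RU", ai_mlv=47.85, ai_tlc=63.28)
    litres = compute_distensibility(airway, right_volumes())
    millilitres = compute_distensibility(airway, right_volumes(v_mlv=1294, v_tlc=2286))
    assert millilitres.ad == litres.ad
    scaled_area = matched(label="RU", ai_mlv=478.5, ai_tlc=632.8)
    assert compute_distensibility(scaled_area, right_volumes()).ad == pytest.approx(
        litres.ad, rel=1e-12
    )


def test_distensibility_monotonicity():
    """AD increases with TLC area and decreases with TLC volume."""
    base = compute_distensibility(matched(label="RU", ai_mlv=50, ai_tlc=60), right_volumes()).ad
    more_dilation = compute_distensibility(
        matched(label="RU", ai_mlv=50, ai_tlc=65), right_volumes()
    ).ad
    more_inflation = compute_distensibility(
        matched(label="RU", ai_mlv=50, ai_tlc=60), right_volumes(v_tlc=2.8)
    ).ad
    assert more_dilation > base
    assert more_inflation < base


def test_trachea_excluded_with_reason():
    airway = matched(label="T", ai_mlv=160, ai_tlc=180)
    with pytest.raises(ValueError, match="no single subtended lung"):
        compute_distensibility(airway, right_volumes())


def test_wrong_lung_rejected():
    airway = matched(label="LB10", ai_mlv=10, ai_tlc=13)
    with pytest.raises(ValueError, match="left"):
        compute_distensibility(airway, right_volumes())


def test_non_inflating_lung_flagged_not_dropped(caplog):
    airway = matched(label="RU", ai_mlv=50, ai_tlc=60)
    with caplog.at_level("WARNING"):
        record = compute_distensibility(airway, right_volumes(v_mlv=2.0, v_tlc=1.9))
    assert not record.valid
    assert np.isnan(record.ad)
    assert record.reason == "v_tlc <= v_mlv"


def test_distensibility_table_proximal_modes(tiny_dataset):
    from airmorph import match_airways

    matches = match_airways(tiny_dataset).matches
    excluded = distensibility_table(matches, tiny_dataset.volumes, proximal_mode="exclude")
    assert "T" not in set(excluded["label"])
    summed = distensibility_table(matches, tiny_dataset.volumes, proximal_mode="summed")
    trachea = summed[summed["label"] == "T"]
    assert len(trachea) == 2 and trachea["valid"].all()
    # circular lumen scaled by 1.15 in radius: dAi/Ai = 1.15^2 - 1, dV/V = 0.8
    expected = (1.15**2 - 1) / 0.8 ** (2 / 3)
    assert trachea["ad"].iloc[0] == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        distensibility_table(matches, tiny_dataset.volumes, proximal_mode="bogus")


def _ad_frame(values, side="right", generation=3):
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:02d}" for i in range(len(values))],
            "label": ["RB1"] * len(values),
            "generation": generation,
            "region": "RU",
            "side": side,
            "delta_ai_rel": 0.3,
            "delta_v_rel": 0.8,
            "ad": values,
            "valid": True,
            "reason": "",
            "outlier": False,
        }
    )


def test_outlier_rule_flags_single_extreme_value():
    """Hand-computed: sample SD 1.8385, the 5.00 point sits 2.04 SD out."""
    flagged = flag_outliers(_ad_frame([0.40, 0.45, 0.50, 0.55, 0.60, 5.00]))
    assert flagged["outlier"].tolist() == [False] * 5 + [True]


def test_outlier_rule_all_equal_and_borderline():
    assert not flag_outliers(_ad_frame([0.5] * 6))["outlier"].any()
    # max deviation 1.49 SD: nothing flagged
    assert not flag_outliers(_ad_frame([0.4, 0.5, 0.45, 3.0]))["outlier"].any()


def test_outlier_rule_small_group_warns(caplog):
    with caplog.at_level("WARNING"):
        flagged = flag_outliers(_ad_frame([0.4, 9.0]))
    assert not flagged["outlier"].any()
    assert any("only 2 valid" in message for message in caplog.messages)


def test_outlier_rule_groupings():
    frame = pd.concat(
        [_ad_frame([0.40, 0.45, 0.50, 0.55, 0.60, 5.00], side="right"),
         _ad_frame([0.40, 0.45, 0.50, 0.55, 0.60, 0.65], side="left")],
        ignore_index=True,
    )
    per_lung = flag_outliers(frame, grouping="per-lung-generation")
    assert per_lung["outlier"].sum() == 1
    global_rule = flag_outliers(frame, grouping="global")
    assert global_rule["outlier"].sum() == 1
    with pytest.raises(ValueError):
        flag_outliers(frame, grouping="per-subject")


def test_distribution_diagnostics_normal_sample():
    rng = np.random.default_rng(42)
    values = rng.standard_normal(500)
    diag = distribution_diagnostics(values, bins=12)
    assert abs(diag.mean) < 0.15 and abs(diag.sd - 1.0) < 0.15
    assert diag.counts.sum() == 500 and len(diag.bin_edges) == 13
    assert not diag.degenerate


def test_distribution_diagnostics_degenerate_and_small():
    diag = distribution_diagnostics([0.4] * 10)
    assert diag.degenerate and diag.sd == 0.0
    with pytest.raises(ValueError):
        distribution_diagnostics([0.1, 0.2, 0.3])


def test_probability_plot_of_exact_normal_quantiles_is_on_the_line():
    """A sample placed exactly at the plotting-position quantiles maps onto
    the reference line with zero deviation."""
    (positions, _), _ = scipy.stats.probplot(np.linspace(-1, 1, 40), dist="norm")
    diag = distribution_diagnostics(positions)
    deviation = np.abs(diag.sample_quantiles - diag.theoretical_quantiles)
    assert deviation.max() < 1e-9
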