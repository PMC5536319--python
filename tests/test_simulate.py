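"""The synthetic-cohort generator: ellipse model, calibration, determinism."""

import math
from dataclasses import replace

import numpy as np
import pytest

from airmorph import (
    SimulatorConfig,
    ellipse_geometry,
    ellipse_perimeter,
    ellipse_perimeter_exact,
    expected_region_ad,
    generate_cohort,
    match_airways,
    shape_factor,
    solve_aspect_ratio,
)
from airmorph.distensibility import distensibility_table
from airmorph.morphometry import add_shape_columns
from airmorph.simulate import ConfigError, build_roster


def test_ellipse_geometry_examples():
    perimeter, equiv = ellipse_geometry(2 * math.pi, 2.0)
    assert perimeter == pytest.approx(9.6884, abs=5e-4)
    assert equiv == pytest.approx(2 * math.sqrt(2), rel=1e-12)
    # circle: perimeter is pi times the equivalent diameter
    perimeter, equiv = ellipse_geometry(7.5, 1.0)
    assert perimeter == pytest.approx(math.pi * equiv, rel=1e-12)
    # scaling the area by 4 at fixed aspect doubles the perimeter
    p1, _ = ellipse_geometry(3.0, 1.7)
    p4, _ = ellipse_geometry(12.0, 1.7)
    assert p4 == pytest.approx(2 * p1, rel=1e-12)


def test_ellipse_geometry_rejects_invalid():
    with pytest.raises(ValueError):
        ellipse_geometry(-1.0, 2.0)
    with pytest.raises(ValueError):
        ellipse_geometry(1.0, 0.8)


def test_solve_aspect_ratio():
    assert solve_aspect_ratio(1.0) == 1.0
    assert solve_aspect_ratio(1.0902) == pytest.approx(2.000, abs=2e-3)
    # the generator's default MLV aspect ratio
    assert solve_aspect_ratio(1.124) == pytest.approx(2.25, abs=0.02)
    with pytest.raises(ConfigError):
        solve_aspect_ratio(0.9)


def test_shape_factor_inverts_solve():
    for target in (1.01, 1.108, 1.124, 1.3):
        assert shape_factor(solve_aspect_ratio(target)) == pytest.approx(target, abs=1e-7)


def test_ramanujan_close_to_exact():
    for k in (1.0, 1.5, 2.25, 4.0, 5.0):
        a, b = math.sqrt(k), 1 / math.sqrt(k)
        assert ellipse_perimeter(a, b) == pytest.approx(
            ellipse_perimeter_exact(a, b), rel=5e-5
        )


def test_determinism_bit_identical():
    config = SimulatorConfig(n_subjects=6)
    first_ds, first_truth = generate_cohort(config, seed=11)
    second_ds, second_truth = generate_cohort(config, seed=11)
    assert first_ds.measurements == second_ds.measurements
    assert first_ds.volumes == second_ds.volumes
    assert first_truth.equals(second_truth)
    third_ds, _ = generate_cohort(config, seed=12)
    assert third_ds.measurements != first_ds.measurements


def test_generated_cohort_is_isoperimetrically_feasible(default_cohort):
    """Construction guarantees every cross-section is a possible closed
    curve, even after measurement noise."""
    dataset, _ = default_cohort
    shape = add_shape_columns(dataset.measurements_frame())
    assert shape["isoperimetric_ok"].all()


def test_volumes_always_inflate(default_cohort):
    dataset, _ = default_cohort
    assert all(v.v_tlc > v.v_mlv for v in dataset.volumes)


def test_noise_free_config_recovers_true_ad_exactly():
    config = replace(
        SimulatorConfig(),
        noise_rel_ai=0.0,
        noise_rel_pi=0.0,
        noise_rel_din=0.0,
        artifact_prob=0.0,
    )
    dataset, truth = generate_cohort(config, seed=5)
    matches = match_airways(dataset).matches
    table = distensibility_table(matches, dataset.volumes)
    joined = table.join(
        truth.set_index(["subject_id", "label"])["ad_true"], on=["subject_id", "label"]
    )
    rel_err = (joined["ad"] - joined["ad_true"]).abs() / joined["ad_true"].abs()
    assert len(joined) > 500
    assert rel_err.max() < 1e-12


def test_gen5_mlv_only_in_stated_segments(default_cohort):
    _, truth = default_cohort
    gen5_mlv = truth[(truth["generation"] == 5) & truth["detected_mlv"]]
    assert set(gen5_mlv["root"]) <= {"RB1", "RB3", "RB6", "RB10", "LB3", "LB10"}
    # TLC-only distal cells exist but never acquire an MLV measurement
    lb2_gen4 = truth[(truth["root"] == "LB2") & (truth["generation"] == 4)]
    assert not lb2_gen4["detected_mlv"].any()


def test_roster_matches_published_cells():
    roster = build_roster(SimulatorConfig())
    by_gen = {}
    for slot in roster:
        by_gen.setdefault(slot.generation, set()).add(slot.root)
    assert by_gen[0] == {"T"} and by_gen[1] == {"R", "L"}
    assert len(by_gen[3]) == 19  # all segmental bronchi (no LB7)
    assert "LB7" not in by_gen[3]


def test_expected_region_ad_structure():
    truth_means = expected_region_ad(SimulatorConfig())
    assert set(truth_means) == {"RU", "RM", "RL", "LU", "LL"}
    assert all(0.1 < v < 0.8 for v in truth_means.values())


@pytest.mark.parametrize(
    "overrides",
    [
        {"n_subjects": 0},
        {"constriction_prob": 1.5},
        {"aspect_ratio_sd": -0.1},
        {"aspect_ratio_bounds": (0.5, 3.0)},
        {"detection_tlc": (1.0, 1.0, 1.0, 0.9, 0.8, 1.2)},
        {"volume_correlation": 1.0},
        {"target_din_dh_mlv": 0.9},
    ],
)
def test_invalid_configs_rejected(overrides):
    with pytest.raises(ConfigError):
        replace(SimulatorConfig(), **overrides).validate()


def test_tlc_rounder_than_mlv_required():
    """A TLC ratio target above the MLV target would need airways to
    flatten, not circularize, at full inflation."""
    config = replace(SimulatorConfig(), target_din_dh_tlc=1.2).validate()
    with pytest.raises(ConfigError):
        _ = config.circularization_decrement


def test_config_hash_tracks_content():
    base = SimulatorConfig()
    assert base.config_hash() == SimulatorConfig().config_hash()
    assert base.config_hash() != replace(base, n_subjects=10).config_hash()
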