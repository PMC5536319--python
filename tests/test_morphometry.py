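"""Hydraulic diameter, shape ratios and the Poiseuille scaling law."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from airmorph import (
    din_dh_ratio,
    equivalent_area_diameter,
    hydraulic_diameter,
    normalize_to_trachea,
    percent_change,
    poiseuille_pressure_factor,
    shape_metrics,
)


@pytest.mark.parametrize(
    "ai, pi, expected",
    [
        (162.2, 47.8, 13.573),  # cohort-mean trachea geometry
        (math.pi * 25, 10 * math.pi, 10.0),  # circle of radius 5
        (6.28319, 9.68845, 2.5944),  # ellipse with semi-axes (2, 1)
    ],
)
def test_hydraulic_diameter_examples(ai, pi, expected):
    assert hydraulic_diameter(ai, pi) == pytest.approx(expected, abs=5e-4)


@pytest.mark.parametrize("ai, pi", [(0, 5), (-1, 5), (5, 0), (5, -2)])
def test_hydraulic_diameter_rejects_nonpositive(ai, pi):
    with pytest.raises(ValueError):
        hydraulic_diameter(ai, pi)


@pytest.mark.parametrize(
    "x_mlv, x_tlc, expected",
    [
        (13.48, 14.61, 8.383),  # trachea cohort means; per-airway averages differ
        (3.0, 3.0, 0.0),
        (2.88, 3.65, 26.74),
    ],
)
def test_percent_change_examples(x_mlv, x_tlc, expected):
    assert percent_change(x_mlv, x_tlc) == pytest.approx(expected, abs=5e-3)


def test_percent_change_rejects_nonpositive_baseline():
    with pytest.raises(ValueError):
        percent_change(0.0, 1.0)


def test_din_dh_ratio_examples():
    assert din_dh_ratio(10.0, 10.0) == pytest.approx(1.0)
    # ellipse (2,1): equal-area diameter 2*sqrt(2), Dh from the exact perimeter
    assert din_dh_ratio(2 * math.sqrt(2), 2.59437) == pytest.approx(1.0902, abs=1e-4)
    with pytest.raises(ValueError):
        din_dh_ratio(2.8284, 0.0)


@pytest.mark.parametrize(
    "ratio, expected",
    [(0.9, 52.4158), (1.0, 0.0), (0.5, 1500.0)],
)
def test_poiseuille_pressure_factor(ratio, expected):
    assert poiseuille_pressure_factor(ratio) == pytest.approx(expected, abs=1e-3)


@given(st.floats(min_value=0.3, max_value=2.0), st.floats(min_value=1e-4, max_value=0.5))
def test_poiseuille_strictly_decreasing(ratio, step):
    """More narrowing always costs more driving pressure."""
    assert poiseuille_pressure_factor(ratio) > poiseuille_pressure_factor(ratio + step)


@given(
    area=st.floats(min_value=0.5, max_value=300.0),
    aspect=st.floats(min_value=1.0, max_value=6.0),
    scale=st.floats(min_value=0.2, max_value=5.0),
)
def test_isoperimetric_bound_and_scale_equivariance_on_ellipses(area, aspect, scale):
    """Dh never exceeds the equal-area diameter; scaling a cross-section by
    s scales Dh by s and leaves the Din/Dh ratio unchanged."""
    from airmorph import ellipse_geometry

    perimeter, d_equiv = ellipse_geometry(area, aspect)
    dh = hydraulic_diameter(area, perimeter)
    assert dh <= d_equiv * (1 + 1e-9)
    scaled_perimeter, scaled_equiv = ellipse_geometry(area * scale**2, aspect)
    scaled_dh = hydraulic_diameter(area * scale**2, scaled_perimeter)
    assert scaled_dh == pytest.approx(scale * dh, rel=1e-9)
    assert din_dh_ratio(scaled_equiv, scaled_dh) == pytest.approx(
        din_dh_ratio(d_equiv, dh), rel=1e-9
    )


@given(
    n=st.integers(min_value=3, max_value=12),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_isoperimetric_bound_on_random_convex_polygons(n, seed):
    """Exact shoelace area and perimeter of a random convex polygon obey
    Dh <= 2*sqrt(A/pi)."""
    rng = np.random.default_rng(seed)
    angles = np.sort(rng.uniform(0, 2 * math.pi, n))
    if np.min(np.diff(angles)) < 1e-3:
        angles = np.linspace(0, 2 * math.pi, n, endpoint=False)
    a_axis, b_axis = rng.uniform(0.5, 5.0, 2)
    x, y = a_axis * np.cos(angles), b_axis * np.sin(angles)  # convex (on an ellipse)
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    perimeter = np.hypot(np.diff(np.append(x, x[0])), np.diff(np.append(y, y[0]))).sum()
    dh = hydraulic_diameter(area, perimeter)
    assert dh <= equivalent_area_diameter(area) * (1 + 1e-12)


def test_shape_metrics_circle_detection():
    metrics = shape_metrics(ai=math.pi * 4, pi=4 * math.pi, din=4.0)
    assert metrics.is_circular
    assert metrics.din_dh_ratio == pytest.approx(1.0)


def test_normalize_to_trachea():
    frame = pd.DataFrame(
        {
            "subject_id": ["A", "A", "A", "B"],
            "label": ["T", "R", "T", "R"],
            "state": ["TLC", "TLC", "MLV", "TLC"],
            "dh_mm": [14.61, 12.86, 13.48, 11.0],
        }
    )
    normalized, excluded = normalize_to_trachea(frame)
    by_key = normalized.set_index(["subject_id", "label", "state"])["dh_normalized"]
    assert by_key[("A", "T", "TLC")] == pytest.approx(1.0)
    assert by_key[("A", "R", "TLC")] == pytest.approx(0.880, abs=5e-4)
    # subject B has no tracheal measurement: excluded, not silently kept
    assert ("B", "R", "TLC") not in by_key.index
    assert excluded == ["B@TLC"]
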