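"""Per-airway geometric quantities.

The central quantity is the hydraulic diameter ``Dh = 4*Ai/Pi``, the
standard fluid-dynamics characterization of flow in a non-circular duct:
for a circle it equals the geometric diameter, and by the isoperimetric
inequality (``Pi^2 >= 4*pi*Ai`` for any closed curve) it can never exceed
the equivalent-area diameter ``2*sqrt(Ai/pi)``.  The more elongated or
corrugated the lumen, the further Dh falls below the equivalent-area
diameter — which is why Dh, not an averaged inner diameter, governs
laminar resistance.

All functions accept scalars or numpy arrays and are vectorized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ShapeMetrics",
    "hydraulic_diameter",
    "equivalent_area_diameter",
    "din_dh_ratio",
    "shape_metrics",
    "percent_change",
    "poiseuille_pressure_factor",
    "add_shape_columns",
    "normalize_to_trachea",
]

#: relative tolerance below which a lumen counts as circular
CIRCLE_RTOL = 1e-9


def _require_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be positive and finite, got {value!r}")
    return arr


def hydraulic_diameter(ai, pi):
    """Hydraulic diameter 4*Ai/Pi (mm) from lumen area (mm^2) and inner
    perimeter (mm)."""
    ai_arr = _require_positive("ai", ai)
    pi_arr = _require_positive("pi", pi)
    out = 4.0 * ai_arr / pi_arr
    return float(out) if out.ndim == 0 else out


def equivalent_area_diameter(ai):
    """Diameter of the circle with the same area: 2*sqrt(Ai/pi)."""
    ai_arr = _require_positive("ai", ai)
    out = 2.0 * np.sqrt(ai_arr / math.pi)
    return float(out) if out.ndim == 0 else out


def din_dh_ratio(din, dh):
    """Ratio of average inner diameter to hydraulic diameter.

    Values above 1 indicate a non-circular (or corrugated) lumen whose
    resistance-relevant caliber is smaller than its nominal diameter.
    """
    din_arr = _require_positive("din", din)
    dh_arr = _require_positive("dh", dh)
    out = din_arr / dh_arr
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ShapeMetrics:
    """Shape summary of one lumen cross-section."""

    dh: float
    din_dh_ratio: float
    equiv_area_diameter: float

    @property
    def is_circular(self) -> bool:
        return abs(self.dh - self.equiv_area_diameter) <= CIRCLE_RTOL * self.equiv_area_diameter


def shape_metrics(ai: float, pi: float, din: float) -> ShapeMetrics:
    """Compute the lumen shape summary from (Ai, Pi, Din)."""
    dh = hydraulic_diameter(ai, pi)
    return ShapeMetrics(
        dh=dh,
        din_dh_ratio=din_dh_ratio(din, dh),
        equiv_area_diameter=equivalent_area_diameter(ai),
    )


def percent_change(x_mlv, x_tlc):
    """Percent change 100*(x_TLC - x_MLV)/x_MLV of a per-airway quantity.

    Cohort summaries average this per-airway quantity; the percent change
    of two cohort means is a different (and generally unequal) number.
    """
    base = _require_positive("x_mlv", x_mlv)
    x_t = np.asarray(x_tlc, dtype=float)
    if not np.all(np.isfinite(x_t)):
        raise ValueError(f"x_tlc must be finite, got {x_tlc!r}")
    out = 100.0 * (x_t - base) / base
    return float(out) if out.ndim == 0 else out


def poiseuille_pressure_factor(diameter_ratio):
    """Percent increase in laminar pressure drop for a caliber ratio.

    For fully developed laminar flow the pressure drop scales with the
    inverse fourth power of diameter, so a duct narrowed to ``r`` times
    its reference diameter costs ``100*(r**-4 - 1)`` percent more driving
    pressure at the same flow (e.g. a 10 % narrowing costs ~52 % more).
    """
    ratio = _require_positive("diameter_ratio", diameter_ratio)
    out = 100.0 * (ratio**-4.0 - 1.0)
    return float(out) if out.ndim == 0 else out


def add_shape_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Append dh_mm, d_equiv_mm, din_dh and isoperimetric feasibility to a
    measurements table (columns ai_mm2, pi_mm, din_mm)."""
    out = frame.copy()
    out["dh_mm"] = 4.0 * out["ai_mm2"] / out["pi_mm"]
    out["d_equiv_mm"] = 2.0 * np.sqrt(out["ai_mm2"] / math.pi)
    out["din_dh"] = out["din_mm"] / out["dh_mm"]
    out["isoperimetric_ok"] = out["pi_mm"] ** 2 >= 4.0 * math.pi * out["ai_mm2"] * (1 - 1e-12)
    return out


def normalize_to_trachea(frame: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Divide each airway's Dh by its own subject's tracheal Dh at the same
    inflation state.

    Expects columns ``subject_id, label, state, dh_mm``.  Subjects without
    a tracheal measurement at a given state cannot be normalized at that
    state; their rows are excluded and the subject/state pairs logged and
    returned.  The trachea itself normalizes to exactly 1.
    """
    required = {"subject_id", "label", "state", "dh_mm"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"normalize_to_trachea: missing columns {sorted(missing)}")
    trachea = (
        frame.loc[frame["label"] == "T", ["subject_id", "state", "dh_mm"]]
        .rename(columns={"dh_mm": "trachea_dh_mm"})
    )
    merged = frame.merge(trachea, on=["subject_id", "state"], how="left")
    excluded_mask = merged["trachea_dh_mm"].isna()
    excluded = sorted(
        {
            f"{row.subject_id}@{row.state}"
            for row in merged.loc[excluded_mask, ["subject_id", "state"]].itertuples()
        }
    )
    for key in excluded:
        logger.info("normalize_to_trachea: excluding %s (no tracheal measurement)", key)
    out = merged.loc[~excluded_mask].copy()
    out["dh_normalized"] = out["dh_mm"] / out["trachea_dh_mm"]
    return out, excluded
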