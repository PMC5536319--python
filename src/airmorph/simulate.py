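"""Synthetic airway-cohort generator.

Generates cohorts with the statistical structure the analysis pipeline
assumes, calibrated to the published summary tables in
:mod:`airmorph.reference`:

* per-subject right/left lung air volumes at MLV and TLC drawn from the
  cohort distributions (truncated normal), with the TLC volume drawn
  conditionally on the MLV volume under a positive correlation — lung
  size is a subject trait, so the same lung's two volumes co-vary — and
  TLC > MLV enforced by redraw;
* per-airway MLV lumen areas drawn from the per-(airway, generation)
  targets, with a truncation window to exclude non-physical draws;
* a true distensibility ``AD`` per airway drawn from the per-airway
  targets: a positive-truncated residual whose location is solved so the
  post-truncation mean matches the target, scaled by a unit-mean
  lognormal subject-level factor (so subjects differ systematically but
  cell means stay calibrated and the non-constricted channel stays
  positive), with occasional constrictions (``AD < 0``) injected at a
  configured rate chosen so the share of airways whose hydraulic
  diameter shrinks at TLC — injected constrictions plus measurement-noise
  sign flips on barely-dilating airways — stays rare, matching the
  emulated study;
* the TLC lumen area constructed by inverting the distensibility
  definition: ``Ai_TLC = Ai_MLV * (1 + AD * (dV/V)^(2/3))`` — so a
  noise-free cohort lets the pipeline recover every true AD exactly;
* elliptical cross-sections: the inner perimeter comes from the lumen
  area and a drawn aspect ratio via Ramanujan's second approximation, and
  the average inner diameter is modeled as the equivalent-area diameter.
  The default MLV aspect ratio is solved (bisection against the exact
  elliptic-integral perimeter) so that the cohort-mean Din/Dh ratio hits
  its published MLV value, and aspect ratios shrink by a fixed
  circularization decrement at TLC so the TLC ratio is lower — lungs
  stretch airways toward circularity as they inflate;
* multiplicative measurement noise on area, perimeter and diameter, with
  the perimeter floored at isoperimetric feasibility so every emitted
  cross-section remains a possible closed curve;
* rare gross segmentation artifacts: a small fraction of TLC
  measurements have their whole cross-section mis-scaled (area,
  perimeter and diameter consistently), producing the implausibly large
  apparent distensibilities that a 2-SD outlier rule is there to catch.
  The published per-airway statistics are post-removal values, so a
  generator calibrated to them must add such contaminants back for the
  analysis pipeline's outlier step to behave as it does on real data;
* missingness mirroring what CT segmentation can resolve: distal airways
  drop out more often, MLV segmentation fails where the published table
  has no MLV entry, and generation-5 MLV airways exist only in the six
  segmental subtrees where the study could match them.

Every generated cohort is returned together with its ground truth so
parameter-recovery tests can compare pipeline estimates with what was
actually simulated.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import reference
from .anatomy import (
    AirwayMeasurement,
    LungVolumeRecord,
    LungVolumeState,
    Region,
    Side,
    parse_label,
)
from .io_tables import CohortDataset

__all__ = [
    "ConfigError",
    "SimulatorConfig",
    "AirwaySlot",
    "ellipse_perimeter",
    "ellipse_perimeter_exact",
    "ellipse_geometry",
    "shape_factor",
    "solve_aspect_ratio",
    "build_roster",
    "expected_region_ad",
    "generate_cohort",
]


class ConfigError(ValueError):
    """Raised for infeasible simulator configurations."""


# -- ellipse geometry ----------------------------------------------------


def ellipse_perimeter(a, b):
    """Ramanujan's second approximation to the ellipse perimeter.

    Relative error is below 5e-5 for aspect ratios up to 5 (and far
    smaller for mildly elongated lumens), which is orders of magnitude
    under the measurement noise it feeds.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    h = ((a - b) / (a + b)) ** 2
    out = math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))
    return float(out) if out.ndim == 0 else out


def ellipse_perimeter_exact(a, b):
    """Exact ellipse perimeter 4*a*E(1 - (b/a)^2) via the complete
    elliptic integral of the second kind (semi-axes a >= b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = 1.0 - (b / a) ** 2
    out = 4.0 * a * special.ellipe(m)
    return float(out) if out.ndim == 0 else out


def ellipse_geometry(area, aspect_ratio):
    """Perimeter and equivalent-area diameter of an ellipse with the given
    lumen area (mm^2) and aspect ratio k = a/b >= 1.

    Semi-axes are a = sqrt(area*k/pi), b = a/k; the perimeter uses
    Ramanujan's approximation.
    """
    area = np.asarray(area, dtype=float)
    k = np.asarray(aspect_ratio, dtype=float)
    if np.any(area <= 0):
        raise ValueError(f"area must be positive, got {area!r}")
    if np.any(k < 1):
        raise ValueError(f"aspect ratio must be >= 1, got {aspect_ratio!r}")
    a = np.sqrt(area * k / math.pi)
    b = a / k
    perimeter = ellipse_perimeter(a, b)
    equiv = 2.0 * np.sqrt(area / math.pi)
    if np.ndim(perimeter) == 0:
        return float(perimeter), float(equiv)
    return perimeter, equiv


def shape_factor(aspect_ratio):
    """Ratio of equivalent-area diameter to hydraulic diameter of an
    ellipse, (2/pi)*sqrt(k)*E(1-1/k^2); equals 1 iff circular.

    With the average inner diameter modeled as the equivalent-area
    diameter, this is exactly the Din/Dh ratio of the simulated lumen.
    """
    k = np.asarray(aspect_ratio, dtype=float)
    if np.any(k < 1):
        raise ValueError(f"aspect ratio must be >= 1, got {aspect_ratio!r}")
    out = (2.0 / math.pi) * np.sqrt(k) * special.ellipe(1.0 - 1.0 / k**2)
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=128)
def solve_aspect_ratio(target_din_dh_ratio: float, tol: float = 1e-8) -> float:
    """Invert :func:`shape_factor`: the ellipse aspect ratio whose Din/Dh
    ratio equals the target (bisection against the exact perimeter)."""
    target = float(target_din_dh_ratio)
    if target < 1.0:
        raise ConfigError(f"Din/Dh ratio target must be >= 1, got {target}")
    if target == 1.0:
        return 1.0
    lo, hi = 1.0, 2.0
    while shape_factor(hi) < target:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for sane targets
            raise ConfigError(f"Din/Dh ratio target {target} is unreachable")
    return float(optimize.brentq(lambda k: shape_factor(k) - target, lo, hi, xtol=tol))


# -- configuration -------------------------------------------------------


@dataclass(frozen=True)
class SimulatorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the emulated study: 24 subjects, the published
    lung-volume, lumen-geometry and distensibility targets, Din/Dh ratio
    targets of 1.124 (MLV) and 1.108 (TLC), rare constrictions, and the
    published distal-MLV missingness pattern.
    """

    n_subjects: int = reference.N_SUBJECTS
    # lumen shape
    target_din_dh_mlv: float = reference.DIN_DH_RATIO["MLV"][0]
    target_din_dh_tlc: float = reference.DIN_DH_RATIO["TLC"][0]
    aspect_ratio_sd: float = 0.4
    aspect_ratio_bounds: tuple[float, float] = (1.05, 5.0)
    # measurement noise (relative SD, multiplicative)
    noise_rel_ai: float = 0.02
    noise_rel_pi: float = 0.02
    noise_rel_din: float = 0.02
    # distensibility structure
    subject_ad_sd: float = 0.10  # SD of the subject random effect at the
    # cohort-typical AD (applied as a unit-mean lognormal factor)
    min_ad_resid_sd: float = 0.05  # floor for the within-cell residual SD
    ad_floor: float = 0.01  # positive floor of non-constricted AD draws
    implied_ad_sd_proximal: float = 0.15  # SD for generations 0-2 (no published SD)
    constriction_prob: float = 0.025
    constriction_mean: float = 0.08  # magnitude of injected negative AD
    constriction_sd: float = 0.04
    constriction_clip: tuple[float, float] = (0.01, 0.5)
    # lumen-area draws
    area_trunc: tuple[float, float] = (0.2, 5.0)  # window as multiples of the target mean
    # gross TLC segmentation artifacts (whole cross-section mis-scaled)
    artifact_prob: float = 0.015
    artifact_mean: float = 1.5  # mean of the extra area scale |N(mean, sd)|
    artifact_sd: float = 0.5
    # lung volumes
    min_lung_volume_l: float = 0.3
    volume_correlation: float = 0.8  # corr(V_MLV, V_TLC) of the same lung
    # missingness: P(segmented at TLC) and P(segmented at MLV | TLC) per generation
    detection_tlc: tuple[float, ...] = (1.0, 1.0, 1.0, 0.95, 0.80, 0.60)
    detection_mlv_given_tlc: tuple[float, ...] = (1.0, 1.0, 1.0, 0.90, 0.75, 0.55)
    gen5_mlv_segments: tuple[str, ...] = reference.GEN5_MLV_SEGMENTS
    children_per_branch: int = 2

    def validate(self) -> "SimulatorConfig":
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.target_din_dh_mlv < 1 or self.target_din_dh_tlc < 1:
            raise ConfigError("Din/Dh ratio targets must be >= 1")
        lo, hi = self.aspect_ratio_bounds
        if not (1.0 <= lo < hi):
            raise ConfigError(f"invalid aspect-ratio bounds {self.aspect_ratio_bounds}")
        for name in ("aspect_ratio_sd", "noise_rel_ai", "noise_rel_pi", "noise_rel_din",
                     "subject_ad_sd", "min_ad_resid_sd", "implied_ad_sd_proximal",
                     "constriction_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.constriction_prob <= 1.0:
            raise ConfigError("constriction_prob must be in [0, 1]")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise ConfigError("artifact_prob must be in [0, 1]")
        if not -1.0 < self.volume_correlation < 1.0:
            raise ConfigError("volume_correlation must be in (-1, 1)")
        for p in self.detection_tlc + self.detection_mlv_given_tlc:
            if not 0.0 <= p <= 1.0:
                raise ConfigError("detection probabilities must be in [0, 1]")
        if not solve_aspect_ratio(self.target_din_dh_mlv) <= hi:
            raise ConfigError("MLV Din/Dh target needs an aspect ratio beyond the bounds")
        return self

    @property
    def aspect_mlv(self) -> float:
        """Aspect ratio whose Din/Dh ratio equals the MLV target."""
        return solve_aspect_ratio(self.target_din_dh_mlv)

    @property
    def circularization_decrement(self) -> float:
        """Drop in aspect ratio from MLV to TLC implied by the two ratio
        targets; must be >= 0 (airways get rounder, not flatter, at TLC)."""
        delta = self.aspect_mlv - solve_aspect_ratio(self.target_din_dh_tlc)
        if delta < 0:
            raise ConfigError(
                "target_din_dh_tlc exceeds target_din_dh_mlv: circularization "
                "would need aspect ratios to grow at TLC"
            )
        return delta

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# -- roster ---------------------------------------------------------------


@dataclass(frozen=True)
class AirwaySlot:
    """One airway position of the synthetic tree: its label, calibration
    targets, and whether MLV segmentation is possible for it."""

    label: str
    root: str
    generation: int
    region: str
    side: str
    ai_mean: float  # MLV target when matchable, else TLC target
    ai_sd: float
    ad_mean: float | None  # None for TLC-only slots
    ad_sd: float | None
    mlv_possible: bool


def _implied_proximal_ad(geom: dict, side: Side) -> float:
    """Distensibility implied by the published MLV/TLC mean areas of a
    proximal airway and the cohort-mean relative volume change of its
    subtended lung(s)."""
    ai_mlv = geom["ai_mlv"][0]
    ai_tlc = geom["ai_tlc"][0]
    if side is Side.NONE:
        # trachea: summed-lung volume change from the cohort means
        v_mlv = (
            reference.LUNG_AIR_VOLUMES_L[("right", "MLV")][0]
            + reference.LUNG_AIR_VOLUMES_L[("left", "MLV")][0]
        )
        v_tlc = (
            reference.LUNG_AIR_VOLUMES_L[("right", "TLC")][0]
            + reference.LUNG_AIR_VOLUMES_L[("left", "TLC")][0]
        )
        dv = (v_tlc - v_mlv) / v_mlv
    else:
        dv = reference.mean_rel_volume_change(side.value)
    return (ai_tlc / ai_mlv - 1.0) / dv ** (2.0 / 3.0)


def _ad_target(label: str, generation: int) -> tuple[float, float] | None:
    """Distensibility target for a segmental subtree, falling back to the
    nearest published generation of the same subtree."""
    for gen in (generation, generation - 1, generation + 1, generation - 2):
        entry = reference.DISTENSIBILITY.get((label, gen))
        if entry is not None:
            return entry[0], entry[1]
    return None


def build_roster(config: SimulatorConfig) -> list[AirwaySlot]:
    """Expand the published geometry table into concrete airway slots.

    Generation <= 3 cells map to their own label; generation-4 cells to
    ``root.i`` children and generation-5 cells to ``root.1.i`` children
    (``children_per_branch`` each).  A slot supports MLV segmentation only
    if the published table has an MLV entry for its cell — and, at
    generation 5, only inside the six subtrees where matched airways were
    obtainable.
    """
    slots: list[AirwaySlot] = []
    for (label, gen) in sorted(reference.LUMEN_GEOMETRY, key=lambda item: (item[1], item[0])):
        geom = reference.LUMEN_GEOMETRY[(label, gen)]
        parsed = parse_label(label)
        mlv_possible = geom["ai_mlv"] is not None and (
            gen < 5 or label in config.gen5_mlv_segments
        )
        if mlv_possible:
            ai_mean, ai_sd = geom["ai_mlv"]
            if gen <= 2:
                ad_mean = _implied_proximal_ad(geom, parsed.side)
                ad_sd = config.implied_ad_sd_proximal
            else:
                target = _ad_target(label, gen)
                if target is None:  # pragma: no cover - every table cell has a fallback
                    raise ConfigError(f"no distensibility target for {label} gen {gen}")
                ad_mean, ad_sd = target
        else:
            ai_mean, ai_sd = geom["ai_tlc"]
            ad_mean = ad_sd = None
        if gen <= 3:
            child_labels = [label]
        elif gen == 4:
            child_labels = [f"{label}.{i}" for i in range(1, config.children_per_branch + 1)]
        else:
            child_labels = [f"{label}.1.{i}" for i in range(1, config.children_per_branch + 1)]
        for child in child_labels:
            slots.append(
                AirwaySlot(
                    label=child,
                    root=label,
                    generation=gen,
                    region=parsed.region.value,
                    side=parsed.side.value,
                    ai_mean=ai_mean,
                    ai_sd=ai_sd,
                    ad_mean=ad_mean,
                    ad_sd=ad_sd,
                    mlv_possible=mlv_possible,
                )
            )
    return slots


def expected_region_ad(config: SimulatorConfig, generations=(3, 4, 5)) -> dict[str, float]:
    """Configured-truth mean distensibility per lobe region.

    The analytic expectation of a region's matched-airway AD under the
    configuration: per-slot target means mixed with the injected
    constriction component, weighted by each slot's expected matched
    count.  This is what parameter-recovery checks compare against.
    """
    p_c = config.constriction_prob
    mu_neg = -np.clip(config.constriction_mean, *config.constriction_clip)
    totals: dict[str, float] = {}
    weights: dict[str, float] = {}
    for slot in build_roster(config):
        if not slot.mlv_possible or slot.generation not in generations:
            continue
        if slot.region in (Region.PROXIMAL.value,):
            continue
        w = (
            config.detection_tlc[slot.generation]
            * config.detection_mlv_given_tlc[slot.generation]
        )
        mu = (1.0 - p_c) * slot.ad_mean + p_c * mu_neg
        totals[slot.region] = totals.get(slot.region, 0.0) + w * mu
        weights[slot.region] = weights.get(slot.region, 0.0) + w
    return {region: totals[region] / weights[region] for region in totals}


# -- draws ----------------------------------------------------------------


def _trunc_ppf(u, mean, sd, lo, hi=np.inf):
    if sd == 0:
        return np.full_like(np.asarray(u, dtype=float), mean)
    a = (lo - mean) / sd
    b = (hi - mean) / sd if np.isfinite(hi) else np.inf
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


@lru_cache(maxsize=512)
def _mean_matched_loc(target: float, sd: float, lo: float) -> float:
    """Location of a lower-truncated normal whose post-truncation mean
    equals ``target`` (so truncation does not bias the calibration)."""
    if sd == 0:
        return target

    def truncated_mean(loc: float) -> float:
        a = (lo - loc) / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd))

    hi = target
    lo_bracket = target - 12.0 * sd
    # truncated mean at loc=target always exceeds target; shrink downward
    return float(optimize.brentq(lambda loc: truncated_mean(loc) - target, lo_bracket, hi))


# -- generation -----------------------------------------------------------


def _draw_volumes(config: SimulatorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    records = {}
    rho = config.volume_correlation
    for side in ("right", "left"):
        m_mlv, s_mlv = reference.LUNG_AIR_VOLUMES_L[(side, "MLV")]
        m_tlc, s_tlc = reference.LUNG_AIR_VOLUMES_L[(side, "TLC")]
        v_mlv = _trunc_ppf(rng.random(n), m_mlv, s_mlv, config.min_lung_volume_l)
        # V_TLC | V_MLV: same-lung volumes co-vary (lung size is a trait)
        cond_mean = m_tlc + rho * (s_tlc / s_mlv) * (v_mlv - m_mlv)
        cond_sd = s_tlc * math.sqrt(1.0 - rho**2)
        v_tlc = np.array(
            [
                _trunc_ppf(u, mu, cond_sd, config.min_lung_volume_l)
                for u, mu in zip(rng.random(n), cond_mean)
            ]
        )
        bad = v_tlc <= v_mlv
        rounds = 0
        while bad.any():
            v_tlc[bad] = np.array(
                [
                    _trunc_ppf(u, mu, cond_sd, config.min_lung_volume_l)
                    for u, mu in zip(rng.random(int(bad.sum())), cond_mean[bad])
                ]
            )
            bad = v_tlc <= v_mlv
            rounds += 1
            if rounds > 200:  # pragma: no cover - astronomically unlikely
                v_tlc[bad] = v_mlv[bad] * 1.05
                break
        records[side] = (v_mlv, v_tlc)
    frame = pd.DataFrame(
        {
            "v_mlv_right": records["right"][0],
            "v_tlc_right": records["right"][1],
            "v_mlv_left": records["left"][0],
            "v_tlc_left": records["left"][1],
        }
    )
    return frame


def generate_cohort(
    config: SimulatorConfig | None = None, seed: int = 0
) -> tuple[CohortDataset, pd.DataFrame]:
    """Generate a synthetic cohort and its ground truth.

    Returns ``(dataset, truth)`` where ``dataset`` is a validated
    :class:`~airmorph.io_tables.CohortDataset` and ``truth`` one row per
    airway slot per subject with the noise-free geometry, the true AD and
    aspect ratios, and the detection flags.  Identical ``(config, seed)``
    pairs yield bit-identical output.
    """
    config = (config or SimulatorConfig()).validate()
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    subjects = [f"S{i + 1:02d}" for i in range(n)]

    volumes = _draw_volumes(config, rng)
    # relative volume-change normalizer (dV/V)^(2/3) per subject and side
    x_right = ((volumes["v_tlc_right"] - volumes["v_mlv_right"]) / volumes["v_mlv_right"]) ** (2 / 3)
    x_left = ((volumes["v_tlc_left"] - volumes["v_mlv_left"]) / volumes["v_mlv_left"]) ** (2 / 3)
    v_mlv_sum = volumes["v_mlv_right"] + volumes["v_mlv_left"]
    v_tlc_sum = volumes["v_tlc_right"] + volumes["v_tlc_left"]
    x_sum = ((v_tlc_sum - v_mlv_sum) / v_mlv_sum) ** (2 / 3)
    x_by_side = {
        "right": x_right.to_numpy(),
        "left": x_left.to_numpy(),
        "none": x_sum.to_numpy(),
    }

    # subject-level multiplicative effect on AD: unit-mean lognormal whose
    # SD equals subject_ad_sd at the cohort-typical distensibility
    ad_cv = config.subject_ad_sd / reference.MEAN_DISTENSIBILITY[0]
    ad_sigma = math.sqrt(math.log1p(ad_cv**2))
    subject_ad_factor = np.exp(rng.normal(-0.5 * ad_sigma**2, ad_sigma, n)) if ad_sigma > 0 else np.ones(n)
    k_mlv_center = config.aspect_mlv
    delta_k = config.circularization_decrement
    k_lo, k_hi = config.aspect_ratio_bounds

    measurements: list[AirwayMeasurement] = []
    truth_rows: list[dict] = []

    for slot in build_roster(config):
        # fixed per-slot draw layout keeps the stream deterministic
        u_area = rng.random(n)
        u_ad = rng.random(n)
        u_constrict = rng.random(n)
        z_constrict = rng.standard_normal(n)
        u_aspect = rng.random(n)
        u_det_tlc = rng.random(n)
        u_det_mlv = rng.random(n)
        z_noise = rng.standard_normal((n, 6))
        u_artifact = rng.random(n)
        z_artifact = rng.standard_normal(n)

        area_lo = max(config.area_trunc[0] * slot.ai_mean, 1e-6)
        area_hi = config.area_trunc[1] * slot.ai_mean
        ai_base = _trunc_ppf(u_area, slot.ai_mean, slot.ai_sd, area_lo, area_hi)

        aspect_mlv = _trunc_ppf(u_aspect, k_mlv_center, config.aspect_ratio_sd, k_lo, k_hi)
        aspect_tlc = np.maximum(aspect_mlv - delta_k, 1.0)

        x = x_by_side[slot.side]
        if slot.mlv_possible:
            # split the cell SD into subject-factor and residual components:
            # var(F*R) = resid^2*(1+cv^2) + mean^2*cv^2 for unit-mean F
            resid_var = (slot.ad_sd**2 - (slot.ad_mean * ad_cv) ** 2) / (1.0 + ad_cv**2)
            resid_sd = max(math.sqrt(max(resid_var, 0.0)), config.min_ad_resid_sd)
            loc = _mean_matched_loc(round(slot.ad_mean, 12), round(resid_sd, 12), config.ad_floor)
            ad_true = subject_ad_factor * _trunc_ppf(u_ad, loc, resid_sd, config.ad_floor)
            constricted = u_constrict < config.constriction_prob
            magnitude = np.clip(
                np.abs(config.constriction_mean + config.constriction_sd * z_constrict),
                *config.constriction_clip,
            )
            ad_true = np.where(constricted, -magnitude, ad_true)
            # keep the TLC area physical; the clip is recorded back as truth
            growth = np.maximum(1.0 + ad_true * x, 0.05)
            ad_true = (growth - 1.0) / x
            ai_mlv_true = ai_base
            ai_tlc_true = ai_base * growth
        else:
            constricted = np.zeros(n, dtype=bool)
            ad_true = np.full(n, np.nan)
            ai_mlv_true = np.full(n, np.nan)
            ai_tlc_true = ai_base

        pi_tlc_true, din_tlc_true = ellipse_geometry(ai_tlc_true, aspect_tlc)
        if slot.mlv_possible:
            pi_mlv_true, din_mlv_true = ellipse_geometry(ai_mlv_true, aspect_mlv)
        else:
            pi_mlv_true = np.full(n, np.nan)
            din_mlv_true = np.full(n, np.nan)

        detected_tlc = u_det_tlc < config.detection_tlc[slot.generation]
        detected_mlv = (
            slot.mlv_possible
            & detected_tlc
            & (u_det_mlv < config.detection_mlv_given_tlc[slot.generation])
        )

        def measured(true_values, z_col, rel_sd):
            return true_values * (1.0 + rel_sd * z_noise[:, z_col])

        ai_mlv_meas = measured(ai_mlv_true, 0, config.noise_rel_ai)
        pi_mlv_meas = measured(pi_mlv_true, 1, config.noise_rel_pi)
        din_mlv_meas = measured(din_mlv_true, 2, config.noise_rel_din)
        ai_tlc_meas = measured(ai_tlc_true, 3, config.noise_rel_ai)
        pi_tlc_meas = measured(pi_tlc_true, 4, config.noise_rel_pi)
        din_tlc_meas = measured(din_tlc_true, 5, config.noise_rel_din)
        # gross TLC segmentation artifacts: the wrong contour scales area,
        # perimeter and diameter together, so shape ratios stay plausible
        # while the apparent dilation (hence AD) becomes an outlier
        artifact = u_artifact < config.artifact_prob
        artifact_scale = np.where(
            artifact,
            1.0 + np.abs(config.artifact_mean + config.artifact_sd * z_artifact),
            1.0,
        )
        ai_tlc_meas = ai_tlc_meas * artifact_scale
        pi_tlc_meas = pi_tlc_meas * np.sqrt(artifact_scale)
        din_tlc_meas = din_tlc_meas * np.sqrt(artifact_scale)
        # noisy perimeters may not undercut the isoperimetric bound
        pi_mlv_meas = np.maximum(pi_mlv_meas, np.sqrt(4 * math.pi * ai_mlv_meas) * (1 + 1e-9))
        pi_tlc_meas = np.maximum(pi_tlc_meas, np.sqrt(4 * math.pi * ai_tlc_meas) * (1 + 1e-9))

        for i, subject in enumerate(subjects):
            if detected_mlv[i]:
                measurements.append(
                    AirwayMeasurement(
                        subject_id=subject,
                        label=slot.label,
                        state=LungVolumeState.MLV,
                        din=float(din_mlv_meas[i]),
                        ai=float(ai_mlv_meas[i]),
                        pi=float(pi_mlv_meas[i]),
                    )
                )
            if detected_tlc[i]:
                measurements.append(
                    AirwayMeasurement(
                        subject_id=subject,
                        label=slot.label,
                        state=LungVolumeState.TLC,
                        din=float(din_tlc_meas[i]),
                        ai=float(ai_tlc_meas[i]),
                        pi=float(pi_tlc_meas[i]),
                    )
                )
            truth_rows.append(
                {
                    "subject_id": subject,
                    "label": slot.label,
                    "root": slot.root,
                    "generation": slot.generation,
                    "region": slot.region,
                    "side": slot.side,
                    "ad_true": float(ad_true[i]),
                    "aspect_mlv": float(aspect_mlv[i]),
                    "aspect_tlc": float(aspect_tlc[i]),
                    "ai_mlv_true": float(ai_mlv_true[i]),
                    "ai_tlc_true": float(ai_tlc_true[i]),
                    "pi_mlv_true": float(pi_mlv_true[i]),
                    "pi_tlc_true": float(pi_tlc_true[i]),
                    "din_mlv_true": float(din_mlv_true[i]),
                    "din_tlc_true": float(din_tlc_true[i]),
                    "constricted": bool(constricted[i]),
                    "artifact": bool(artifact[i]),
                    "detected_mlv": bool(detected_mlv[i]),
                    "detected_tlc": bool(detected_tlc[i]),
                }
            )

    volume_records = []
    for i, subject in enumerate(subjects):
        for side in ("right", "left"):
            volume_records.append(
                LungVolumeRecord(
                    subject_id=subject,
                    side=Side(side),
                    v_mlv=float(volumes[f"v_mlv_{side}"][i]),
                    v_tlc=float(volumes[f"v_tlc_{side}"][i]),
                )
            )

    dataset = CohortDataset(
        measurements=measurements,
        volumes=volume_records,
        provenance=f"synthetic(seed={seed},config={config.config_hash()})",
    ).validate()
    truth = pd.DataFrame(truth_rows)
    return dataset, truth
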