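"""Volume-normalized airway distensibility.

Distensibility compares how much an airway lumen dilates between two
inflation levels with how much the surrounding lung inflates:

    AD = (dAi/Ai) / (dV/V)^(2/3)
       = ((Ai_TLC - Ai_MLV)/Ai_MLV) / (((V_TLC - V_MLV)/V_MLV)^(2/3))

where V is the air volume of the lung subtended by the airway (right or
left, depending on the bronchus).  The 2/3 exponent converts the volume
expansion of the parenchyma into the equivalent isotropic area expansion,
so AD = 1 means the airway dilates exactly as much as the tissue around
it, AD < 1 a stiffer-than-parenchyma airway, and AD < 0 an airway that
constricts despite lung inflation.  Being a ratio of ratios, AD is
invariant to the units of both area and volume.

The trachea subtends both lungs and is excluded by default (an optional
mode normalizes proximal airways by the summed right+left volumes).
Airways whose lung-volume record is not inflating (V_TLC <= V_MLV) are
flagged invalid rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .anatomy import LungVolumeRecord, MatchedAirway, Side

logger = logging.getLogger(__name__)

__all__ = [
    "DistensibilityRecord",
    "compute_distensibility",
    "distensibility_table",
    "flag_outliers",
    "distribution_diagnostics",
    "DistributionDiagnostics",
    "OUTLIER_GROUPINGS",
]

#: supported outlier-rule groupings
OUTLIER_GROUPINGS = ("global", "per-lung-generation", "per-region")

#: generation below which airways are considered proximal for AD purposes
#: (trachea and main bronchi; excluded unless summed-volume mode is on)
MIN_AD_GENERATION = 2


@dataclass(frozen=True)
class DistensibilityRecord:
    """Distensibility of one matched airway."""

    subject_id: str
    label: str
    generation: int
    region: str
    side: str
    delta_ai_rel: float  # (Ai_TLC - Ai_MLV)/Ai_MLV
    delta_v_rel: float  # (V_TLC - V_MLV)/V_MLV
    ad: float  # distensibility; NaN when invalid
    valid: bool
    reason: str = ""
    outlier: bool = False


def compute_distensibility(
    matched: MatchedAirway,
    volumes: LungVolumeRecord,
    *,
    allow_trachea_sum: bool = False,
) -> DistensibilityRecord:
    """Distensibility of one matched airway given its subtended-lung volumes.

    ``volumes`` must belong to the same subject and, for sided airways, to
    the airway's subtended lung.  For the trachea pass a combined
    (right+left summed) record and set ``allow_trachea_sum`` — otherwise
    the trachea is rejected, as it has no single subtended lung.
    """
    side = matched.side
    if side is Side.NONE and not allow_trachea_sum:
        raise ValueError(
            f"{matched.subject_id}/{matched.label.name}: the trachea has no single "
            f"subtended lung; excluded from distensibility"
        )
    if volumes.subject_id != matched.subject_id:
        raise ValueError(
            f"volume record subject {volumes.subject_id!r} does not match airway "
            f"subject {matched.subject_id!r}"
        )
    if side is not Side.NONE and volumes.side is not side:
        raise ValueError(
            f"{matched.subject_id}/{matched.label.name}: needs {side.value}-lung "
            f"volumes, got {volumes.side.value}"
        )
    delta_ai_rel = (matched.tlc.ai - matched.mlv.ai) / matched.mlv.ai
    delta_v_rel = volumes.rel_volume_change
    if delta_v_rel <= 0:
        # not silently dropped: surfaced as an invalid record
        logger.warning(
            "distensibility %s/%s flagged invalid: lung did not inflate (dV/V=%.4f)",
            matched.subject_id,
            matched.label.name,
            delta_v_rel,
        )
        return DistensibilityRecord(
            subject_id=matched.subject_id,
            label=matched.label.name,
            generation=matched.generation,
            region=matched.region.value,
            side=side.value,
            delta_ai_rel=delta_ai_rel,
            delta_v_rel=delta_v_rel,
            ad=float("nan"),
            valid=False,
            reason="v_tlc <= v_mlv",
        )
    ad = delta_ai_rel / delta_v_rel ** (2.0 / 3.0)
    return DistensibilityRecord(
        subject_id=matched.subject_id,
        label=matched.label.name,
        generation=matched.generation,
        region=matched.region.value,
        side=side.value,
        delta_ai_rel=delta_ai_rel,
        delta_v_rel=delta_v_rel,
        ad=ad,
        valid=True,
    )


def _combined_volume_record(per_side: Mapping[Side, LungVolumeRecord]) -> LungVolumeRecord | None:
    right = per_side.get(Side.RIGHT)
    left = per_side.get(Side.LEFT)
    if right is None or left is None:
        return None
    # summed-lungs pseudo-record used only for the trachea
    return LungVolumeRecord(
        subject_id=right.subject_id,
        side=Side.RIGHT,  # placeholder side; only the volumes are used
        v_mlv=right.v_mlv + left.v_mlv,
        v_tlc=right.v_tlc + left.v_tlc,
    )


def distensibility_table(
    matches: Iterable[MatchedAirway],
    volumes: Iterable[LungVolumeRecord],
    *,
    proximal_mode: str = "exclude",
) -> pd.DataFrame:
    """Distensibility records for a matched cohort as a tidy table.

    ``proximal_mode`` is ``"exclude"`` (default: trachea and main bronchi
    are skipped, with a log entry each) or ``"summed"`` (the trachea is
    normalized by the summed right+left volumes and main bronchi by their
    own lung).  Records with missing volumes are skipped with a log entry;
    non-inflating lungs yield invalid records that stay in the table.
    """
    if proximal_mode not in ("exclude", "summed"):
        raise ValueError(f"unknown proximal_mode {proximal_mode!r}")
    lookup: dict[str, dict[Side, LungVolumeRecord]] = {}
    for rec in volumes:
        lookup.setdefault(rec.subject_id, {})[rec.side] = rec
    rows = []
    n_excluded_proximal = 0
    for m in matches:
        per_side = lookup.get(m.subject_id, {})
        if proximal_mode == "exclude" and m.generation < MIN_AD_GENERATION:
            n_excluded_proximal += 1
            continue
        if m.side is Side.NONE:
            if proximal_mode != "summed":
                n_excluded_proximal += 1
                continue
            vol = _combined_volume_record(per_side)
            if vol is None:
                logger.warning(
                    "distensibility: %s/%s skipped (missing volumes)", m.subject_id, m.label.name
                )
                continue
            rec = compute_distensibility(m, vol, allow_trachea_sum=True)
            rec = DistensibilityRecord(**{**rec.__dict__, "side": Side.NONE.value})
        else:
            vol = per_side.get(m.side)
            if vol is None:
                logger.warning(
                    "distensibility: %s/%s skipped (missing %s-lung volumes)",
                    m.subject_id,
                    m.label.name,
                    m.side.value,
                )
                continue
            rec = compute_distensibility(m, vol)
        rows.append(rec.__dict__)
    if n_excluded_proximal:
        logger.info(
            "distensibility: excluded %d proximal airway(s) (generation < %d; "
            "no single subtended lung)",
            n_excluded_proximal,
            MIN_AD_GENERATION,
        )
    columns = [
        "subject_id",
        "label",
        "generation",
        "region",
        "side",
        "delta_ai_rel",
        "delta_v_rel",
        "ad",
        "valid",
        "reason",
        "outlier",
    ]
    return pd.DataFrame(rows, columns=columns)


def flag_outliers(
    table: pd.DataFrame,
    k: float = 2.0,
    grouping: str = "per-lung-generation",
) -> pd.DataFrame:
    """Flag distensibility outliers: |AD - group mean| > k * group sample SD.

    A single pass over each group (no iterative re-trimming).  Flagged
    records are retained in the table — downstream summaries exclude them
    but nothing is deleted.  Groups with fewer than 3 valid records are
    left unflagged with a warning.
    """
    if grouping not in OUTLIER_GROUPINGS:
        raise ValueError(f"unknown outlier grouping {grouping!r}; use one of {OUTLIER_GROUPINGS}")
    out = table.copy()
    out["outlier"] = False
    if out.empty:
        return out
    valid = out["valid"].astype(bool) & np.isfinite(out["ad"].astype(float))
    if grouping == "global":
        group_keys = pd.Series("all", index=out.index)
    elif grouping == "per-lung-generation":
        group_keys = out["side"].astype(str) + "/" + out["generation"].astype(str)
    else:  # per-region
        group_keys = out["region"].astype(str) + "/" + out["generation"].astype(str)
    for key, idx in out.groupby(group_keys.where(valid)).groups.items():
        values = out.loc[idx, "ad"]
        if len(values) < 3:
            logger.warning(
                "outlier rule skipped for group %s: only %d valid record(s)", key, len(values)
            )
            continue
        sd = values.std(ddof=1)
        if sd == 0:
            continue
        deviation = (values - values.mean()).abs()
        out.loc[idx, "outlier"] = deviation > k * sd
    return out


@dataclass(frozen=True)
class DistributionDiagnostics:
    """Histogram, normal fit and probability-plot points for AD values."""

    n: int
    mean: float
    sd: float
    counts: np.ndarray
    bin_edges: np.ndarray
    theoretical_quantiles: np.ndarray
    sample_quantiles: np.ndarray
    degenerate: bool


def distribution_diagnostics(values: Sequence[float], bins: int = 10) -> DistributionDiagnostics:
    """Distributional diagnostics of a distensibility sample.

    Returns the histogram, the moment-fitted normal parameters and the
    ordered (theoretical, sample) normal quantile pairs of a probability
    plot.  Requires at least 8 values; a zero-variance sample is flagged
    degenerate (no probability plot is meaningful).
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 8:
        raise ValueError(f"distribution diagnostics need >= 8 values, got {arr.size}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    counts, bin_edges = np.histogram(arr, bins=bins)
    if sd == 0:
        return DistributionDiagnostics(
            n=arr.size,
            mean=mean,
            sd=0.0,
            counts=counts,
            bin_edges=bin_edges,
            theoretical_quantiles=np.empty(0),
            sample_quantiles=np.empty(0),
            degenerate=True,
        )
    (osm, osr), _ = scipy.stats.probplot(arr, dist="norm")
    return DistributionDiagnostics(
        n=arr.size,
        mean=mean,
        sd=sd,
        counts=counts,
        bin_edges=bin_edges,
        theoretical_quantiles=np.asarray(osm),
        sample_quantiles=np.asarray(osr),
        degenerate=False,
    )
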