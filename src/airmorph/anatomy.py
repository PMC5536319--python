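"""Bronchial-tree nomenclature, generation numbering and lobe topology.

The human bronchial tree is addressed here with the standard anatomical
acronyms: ``T`` (trachea), ``R``/``L`` (main bronchi), ``RMI`` (right
intermediate bronchus), the lobar roots ``RU``, ``RM``, ``RL``, ``LU``,
``LL``, the lingular trunk ``LB4+5`` and left-lower-lobe basal trunk
``LLR``, and the segmental bronchi ``RB1``–``RB10`` and ``LB1``–``LB10``.
Sub-segmental branches (generations 4–5) carry dotted child indices in
segmentation order, e.g. ``RB10.1.2`` — a pure bookkeeping convention,
since sub-segmental airways have no universally agreed names.

Generation numbering follows the convention trachea = 0, main bronchi = 1,
lobar bronchi = 2, segmental bronchi = 3, with each dotted child suffix
adding one.  Note that the right intermediate bronchus ``RMI`` is counted
with the lobar (generation-2) airways, and the trunks ``LB4+5`` and
``LLR`` are likewise placed in generation 2 — their exact depth is an
anatomical judgement call, made here so that they sit with the other
proximal conducting airways they are grouped with in practice.

Every airway below the carina subtends exactly one lung, which determines
the lung-volume record used when normalizing caliber change; the trachea
subtends both and therefore has side ``none``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

logger = logging.getLogger(__name__)

__all__ = [
    "UnknownLabelError",
    "ValidationError",
    "LungVolumeState",
    "Side",
    "Region",
    "AirwayLabel",
    "AirwayMeasurement",
    "LungVolumeRecord",
    "MatchedAirway",
    "BASE_VOCABULARY",
    "SEGMENTAL_LABELS",
    "MAX_GENERATION",
    "assign_generation",
    "subtended_side",
    "lobe_region",
    "parse_label",
]


class UnknownLabelError(ValueError):
    """Raised when an airway name is not in the controlled vocabulary."""


class ValidationError(ValueError):
    """Raised when a domain record violates its invariants."""


class LungVolumeState(str, Enum):
    """Lung inflation level at which a breath-hold CT was acquired."""

    MLV = "MLV"  # mean lung volume (intermediate inflation)
    TLC = "TLC"  # total lung capacity (maximal inflation)


class Side(str, Enum):
    """Which lung an airway ventilates."""

    RIGHT = "right"
    LEFT = "left"
    NONE = "none"  # trachea: no single subtended lung


class Region(str, Enum):
    """Lobe-level grouping used for regional summaries."""

    PROXIMAL = "proximal"  # trachea, main bronchi, intermediate bronchus
    RU = "RU"
    RM = "RM"
    RL = "RL"
    LU = "LU"
    LL = "LL"


PROXIMAL_LABELS = ("T", "R", "L", "RMI")
LOBAR_LABELS = ("RU", "RM", "RL", "LU", "LL")
TRUNK_LABELS = ("LB4+5", "LLR")  # lingular trunk; left-lower-lobe basal trunk
SEGMENTAL_LABELS = tuple(f"RB{i}" for i in range(1, 11)) + tuple(
    f"LB{i}" for i in range(1, 11)
)
BASE_VOCABULARY = PROXIMAL_LABELS + LOBAR_LABELS + TRUNK_LABELS + SEGMENTAL_LABELS

MAX_GENERATION = 5

_BASE_GENERATION = {"T": 0, "R": 1, "L": 1, "RMI": 2}
_BASE_GENERATION.update({name: 2 for name in LOBAR_LABELS})
_BASE_GENERATION.update({name: 2 for name in TRUNK_LABELS})
_BASE_GENERATION.update({name: 3 for name in SEGMENTAL_LABELS})

# Segmental bronchi grouped by parent lobe: RB1-3 upper, RB4-5 middle,
# RB6-10 lower on the right; LB1-5 upper (incl. lingula), LB6-10 lower.
_SEGMENT_REGION = {}
for _i in range(1, 11):
    _SEGMENT_REGION[f"RB{_i}"] = Region.RU if _i <= 3 else (Region.RM if _i <= 5 else Region.RL)
    _SEGMENT_REGION[f"LB{_i}"] = Region.LU if _i <= 5 else Region.LL

_BASE_REGION = {name: Region.PROXIMAL for name in PROXIMAL_LABELS}
_BASE_REGION.update({name: Region(name) for name in LOBAR_LABELS})
_BASE_REGION["LB4+5"] = Region.LU
_BASE_REGION["LLR"] = Region.LL
_BASE_REGION.update(_SEGMENT_REGION)


@dataclass(frozen=True)
class AirwayLabel:
    """A validated anatomical airway name.

    ``root`` is the base-vocabulary name and ``child_path`` the dotted
    sub-segmental indices (empty for named airways).
    """

    name: str
    root: str
    child_path: tuple[int, ...]

    @classmethod
    def parse(cls, name: str) -> "AirwayLabel":
        if not isinstance(name, str) or not name:
            raise UnknownLabelError(f"airway label must be a non-empty string, got {name!r}")
        parts = name.split(".")
        root = parts[0]
        if root not in BASE_VOCABULARY:
            raise UnknownLabelError(
                f"unknown airway label {name!r}: root {root!r} is not in the vocabulary"
            )
        children: list[int] = []
        if len(parts) > 1:
            if root not in SEGMENTAL_LABELS:
                raise UnknownLabelError(
                    f"unknown airway label {name!r}: sub-segmental suffixes are only "
                    f"valid on segmental roots (RB1-RB10, LB1-LB10)"
                )
            for part in parts[1:]:
                if not part.isdigit() or int(part) < 1:
                    raise UnknownLabelError(
                        f"unknown airway label {name!r}: child index {part!r} must be a "
                        f"positive integer"
                    )
                children.append(int(part))
        label = cls(name=name, root=root, child_path=tuple(children))
        if label.generation > MAX_GENERATION:
            raise UnknownLabelError(
                f"unknown airway label {name!r}: generation {label.generation} exceeds "
                f"the supported maximum of {MAX_GENERATION}"
            )
        return label

    @property
    def generation(self) -> int:
        return _BASE_GENERATION[self.root] + len(self.child_path)

    @property
    def side(self) -> Side:
        if self.root == "T":
            return Side.NONE
        return Side.RIGHT if self.root.startswith("R") else Side.LEFT

    @property
    def region(self) -> Region:
        return _BASE_REGION[self.root]

    @property
    def parent(self) -> "AirwayLabel | None":
        if not self.child_path:
            return None
        return AirwayLabel.parse(".".join([self.root] + [str(i) for i in self.child_path[:-1]]))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@lru_cache(maxsize=4096)
def parse_label(name: str) -> AirwayLabel:
    """Parse and validate an airway name (cached)."""
    return AirwayLabel.parse(name)


def _as_label(label: "str | AirwayLabel") -> AirwayLabel:
    return label if isinstance(label, AirwayLabel) else parse_label(label)


def assign_generation(label: "str | AirwayLabel") -> int:
    """Bifurcation depth: trachea 0, main bronchi 1, lobar 2, segmental 3,
    plus one per dotted child suffix."""
    return _as_label(label).generation


def subtended_side(label: "str | AirwayLabel") -> Side:
    """The lung ventilated through this airway (``none`` for the trachea)."""
    return _as_label(label).side


def lobe_region(label: "str | AirwayLabel") -> Region:
    """Lobe-level region for regional aggregation."""
    return _as_label(label).region


@dataclass(frozen=True)
class AirwayMeasurement:
    """Lumen geometry of one airway segment of one subject at one inflation.

    Lengths in mm, areas in mm^2.  ``wt`` (wall thickness) and ``po``
    (outer perimeter) are optional — they are reported by the segmentation
    software but unused by the core analysis.
    """

    subject_id: str
    label: AirwayLabel
    state: LungVolumeState
    din: float  # average inner diameter, mm
    ai: float  # average lumen area, mm^2
    pi: float  # average inner perimeter, mm
    wt: float | None = None
    po: float | None = None

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        object.__setattr__(self, "label", _as_label(self.label))
        object.__setattr__(self, "state", LungVolumeState(self.state))
        for field_name in ("din", "ai", "pi"):
            value = getattr(self, field_name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValidationError(
                    f"{field_name} must be a positive finite number, got {value!r} "
                    f"({self.subject_id}/{self.label.name}/{self.state.value})"
                )
        for field_name in ("wt", "po"):
            value = getattr(self, field_name)
            if value is not None and not (math.isfinite(value) and value > 0):
                raise ValidationError(
                    f"{field_name} must be positive when present, got {value!r}"
                )

    @property
    def isoperimetric_feasible(self) -> bool:
        """Whether (ai, pi) can belong to a closed curve: pi^2 >= 4*pi*ai.

        An infeasible pair means the reported perimeter is too short to
        enclose the reported area — a measurement inconsistency worth
        flagging, never silently accepted downstream.
        """
        return self.pi**2 >= 4.0 * math.pi * self.ai * (1.0 - 1e-12)


@dataclass(frozen=True)
class LungVolumeRecord:
    """Per-subject air volume (litres) of one lung at both inflations."""

    subject_id: str
    side: Side
    v_mlv: float
    v_tlc: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "side", Side(self.side))
        if self.side is Side.NONE:
            raise ValidationError("lung volume records are per lung: side must be right/left")
        for field_name in ("v_mlv", "v_tlc"):
            value = getattr(self, field_name)
            if not (math.isfinite(value) and value > 0):
                raise ValidationError(
                    f"{field_name} must be positive, got {value!r} "
                    f"({self.subject_id}/{self.side.value})"
                )
        if self.v_tlc <= self.v_mlv:
            # Physiologically TLC > MLV; keep the record but never silently.
            logger.warning(
                "lung volume record %s/%s has v_tlc (%.3f L) <= v_mlv (%.3f L); "
                "distensibility for its airways will be flagged invalid",
                self.subject_id,
                self.side.value,
                self.v_tlc,
                self.v_mlv,
            )

    @property
    def is_inflated(self) -> bool:
        return self.v_tlc > self.v_mlv

    @property
    def rel_volume_change(self) -> float:
        """(V_TLC - V_MLV) / V_MLV, dimensionless."""
        return (self.v_tlc - self.v_mlv) / self.v_mlv


@dataclass(frozen=True)
class MatchedAirway:
    """The same subject's airway observed at both inflations.

    Only airways segmentable at both lung volumes enter paired analyses;
    everything else is reported as unmatched, not dropped silently.
    """

    subject_id: str
    label: AirwayLabel
    mlv: AirwayMeasurement
    tlc: AirwayMeasurement

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", _as_label(self.label))
        if self.mlv.state is not LungVolumeState.MLV or self.tlc.state is not LungVolumeState.TLC:
            raise ValidationError("matched airway requires one MLV and one TLC measurement")
        if (
            self.mlv.subject_id != self.subject_id
            or self.tlc.subject_id != self.subject_id
            or self.mlv.label != self.label
            or self.tlc.label != self.label
        ):
            raise ValidationError(
                f"matched airway {self.subject_id}/{self.label.name}: both measurements "
                f"must share subject and label"
            )

    @property
    def generation(self) -> int:
        return self.label.generation

    @property
    def side(self) -> Side:
        return self.label.side

    @property
    def region(self) -> Region:
        return self.label.region
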