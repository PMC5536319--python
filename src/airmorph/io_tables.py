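"""Reading and writing cohort tables.

Canonical CSV schemas (UTF-8, ``.`` decimal point, header required):

* measurements: ``subject_id,label,state,din_mm,ai_mm2,pi_mm,wt_mm,po_mm``
  (wt_mm / po_mm may be empty; everything else is mandatory)
* volumes: ``subject_id,side,v_mlv_l,v_tlc_l``

A cohort can also be ingested from a ZIP-packed spreadsheet workbook laid
out with one per-airway measurement sheet and one lung-volume sheet (the
shape of the study's deposited data-processing workbook); sheets holding
derived statistics are ignored.  Unrecognized layouts fail loudly with
the sheet names — the reader never guesses.
"""

from __future__ import annotations

import io
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import openpyxl
import pandas as pd
import yaml

from .anatomy import (
    AirwayMeasurement,
    LungVolumeRecord,
    LungVolumeState,
    Side,
    UnknownLabelError,
    ValidationError,
    parse_label,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "CohortDataset",
    "MEASUREMENT_COLUMNS",
    "VOLUME_COLUMNS",
    "read_measurements_csv",
    "read_volumes_csv",
    "read_cohort",
    "write_cohort",
    "ingest_s1_workbook",
    "write_s1_style_workbook",
    "write_summary_tables",
    "read_summary_table",
    "load_config",
]

MEASUREMENT_COLUMNS = ["subject_id", "label", "state", "din_mm", "ai_mm2", "pi_mm", "wt_mm", "po_mm"]
VOLUME_COLUMNS = ["subject_id", "side", "v_mlv_l", "v_tlc_l"]

MEASUREMENT_SHEET = "airway_measurements"
VOLUME_SHEET = "lung_volumes"


class SchemaError(ValueError):
    """A table does not conform to the expected schema."""


@dataclass
class CohortDataset:
    """A validated cohort: per-airway measurements plus per-lung volumes."""

    measurements: list[AirwayMeasurement]
    volumes: list[LungVolumeRecord]
    provenance: str = ""

    def validate(self) -> "CohortDataset":
        seen: set[tuple[str, str, str]] = set()
        for m in self.measurements:
            key = (m.subject_id, m.label.name, m.state.value)
            if key in seen:
                raise SchemaError(f"duplicate measurement key {key}")
            seen.add(key)
        vol_keys = {(v.subject_id, v.side) for v in self.volumes}
        dup = len(vol_keys) != len(self.volumes)
        if dup:
            raise SchemaError("duplicate (subject, side) lung-volume records")
        missing = set()
        for m in self.measurements:
            if m.label.side is Side.NONE:
                continue
            if (m.subject_id, m.label.side) not in vol_keys:
                missing.add((m.subject_id, m.label.side.value))
        if missing:
            raise SchemaError(
                f"missing lung-volume records for subjects referenced by airways: "
                f"{sorted(missing)}"
            )
        return self

    # -- tidy views ------------------------------------------------------
    def measurements_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": m.subject_id,
                "label": m.label.name,
                "state": m.state.value,
                "din_mm": m.din,
                "ai_mm2": m.ai,
                "pi_mm": m.pi,
                "wt_mm": m.wt if m.wt is not None else np.nan,
                "po_mm": m.po if m.po is not None else np.nan,
            }
            for m in self.measurements
        ]
        return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)

    def volumes_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": v.subject_id,
                "side": v.side.value,
                "v_mlv_l": v.v_mlv,
                "v_tlc_l": v.v_tlc,
            }
            for v in self.volumes
        ]
        return pd.DataFrame(rows, columns=VOLUME_COLUMNS)


def _optional(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _measurements_from_frame(frame: pd.DataFrame, source: str) -> list[AirwayMeasurement]:
    missing = [c for c in MEASUREMENT_COLUMNS[:6] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{source}: missing measurement column(s) {missing}")
    measurements = []
    for offset, row in enumerate(frame.to_dict("records")):
        where = f"{source}, row {offset + 2}"  # +2: header + 1-based
        try:
            measurements.append(
                AirwayMeasurement(
                    subject_id=str(row["subject_id"]),
                    label=parse_label(str(row["label"])),
                    state=LungVolumeState(str(row["state"])),
                    din=float(row["din_mm"]),
                    ai=float(row["ai_mm2"]),
                    pi=float(row["pi_mm"]),
                    wt=_optional(row.get("wt_mm")),
                    po=_optional(row.get("po_mm")),
                )
            )
        except (UnknownLabelError, ValidationError, ValueError, TypeError) as exc:
            raise SchemaError(f"{where}: {exc}") from exc
    return measurements


def _volumes_from_frame(frame: pd.DataFrame, source: str) -> list[LungVolumeRecord]:
    missing = [c for c in VOLUME_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{source}: missing volume column(s) {missing}")
    volumes = []
    for offset, row in enumerate(frame.to_dict("records")):
        where = f"{source}, row {offset + 2}"
        try:
            volumes.append(
                LungVolumeRecord(
                    subject_id=str(row["subject_id"]),
                    side=Side(str(row["side"])),
                    v_mlv=float(row["v_mlv_l"]),
                    v_tlc=float(row["v_tlc_l"]),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise SchemaError(f"{where}: {exc}") from exc
    return volumes


def read_measurements_csv(path) -> list[AirwayMeasurement]:
    """Read and validate a measurements CSV; errors carry row context."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            dtype={"subject_id": str, "label": str, "state": str},
            float_precision="round_trip",
        )
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    return _measurements_from_frame(frame, str(path))


def read_volumes_csv(path) -> list[LungVolumeRecord]:
    """Read and validate a lung-volumes CSV; errors carry row context."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, dtype={"subject_id": str, "side": str}, float_precision="round_trip"
        )
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    return _volumes_from_frame(frame, str(path))


def read_cohort(measurements_path, volumes_path, provenance: str = "") -> CohortDataset:
    dataset = CohortDataset(
        measurements=read_measurements_csv(measurements_path),
        volumes=read_volumes_csv(volumes_path),
        provenance=provenance or f"csv:{measurements_path}",
    )
    return dataset.validate()


def write_cohort(dataset: CohortDataset, measurements_path, volumes_path) -> None:
    dataset.measurements_frame().to_csv(measurements_path, index=False)
    dataset.volumes_frame().to_csv(volumes_path, index=False)


# -- workbook ingestion -------------------------------------------------


def _frame_from_sheet(sheet) -> pd.DataFrame:
    rows = list(sheet.iter_rows(values_only=True))
    if not rows:
        return pd.DataFrame()
    header = [str(c) if c is not None else "" for c in rows[0]]
    return pd.DataFrame(rows[1:], columns=header)


def ingest_s1_workbook(path) -> CohortDataset:
    """Ingest a cohort from a ZIP-packed (or bare) spreadsheet workbook.

    The workbook must contain a sheet named ``airway_measurements`` and a
    sheet named ``lung_volumes`` whose header rows match the canonical CSV
    schemas; any other sheets (derived statistics, plots) are ignored.  An
    archive without a spreadsheet, or a workbook without the expected
    sheets, raises :class:`SchemaError` listing what was found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if zipfile.is_zipfile(path) and path.suffix.lower() not in (".xlsx", ".xlsm"):
        with zipfile.ZipFile(path) as archive:
            members = [n for n in archive.namelist() if n.lower().endswith((".xlsx", ".xlsm"))]
            if not members:
                raise SchemaError(
                    f"{path}: archive contains no spreadsheet workbook; members: "
                    f"{sorted(archive.namelist())}"
                )
            payload = archive.read(members[0])
        workbook = openpyxl.load_workbook(io.BytesIO(payload), data_only=True, read_only=True)
        source = f"{path}!{members[0]}"
    else:
        try:
            workbook = openpyxl.load_workbook(path, data_only=True, read_only=True)
        except Exception as exc:
            raise SchemaError(f"{path}: not a readable workbook or ZIP archive: {exc}") from exc
        source = str(path)
    sheet_names = workbook.sheetnames
    if MEASUREMENT_SHEET not in sheet_names or VOLUME_SHEET not in sheet_names:
        raise SchemaError(
            f"{source}: unsupported workbook layout; expected sheets "
            f"{MEASUREMENT_SHEET!r} and {VOLUME_SHEET!r}, found {sheet_names}"
        )
    ignored = [n for n in sheet_names if n not in (MEASUREMENT_SHEET, VOLUME_SHEET)]
    if ignored:
        logger.info("workbook %s: ignoring derived-statistics sheet(s) %s", source, ignored)
    meas_frame = _frame_from_sheet(workbook[MEASUREMENT_SHEET])
    vol_frame = _frame_from_sheet(workbook[VOLUME_SHEET])
    dataset = CohortDataset(
        measurements=_measurements_from_frame(meas_frame, f"{source}#{MEASUREMENT_SHEET}"),
        volumes=_volumes_from_frame(vol_frame, f"{source}#{VOLUME_SHEET}"),
        provenance=f"workbook:{path}",
    )
    return dataset.validate()


def write_s1_style_workbook(dataset: CohortDataset, path, pack_zip: bool = True) -> Path:
    """Write a synthetic workbook in the layout :func:`ingest_s1_workbook`
    reads — a stand-in for the study's deposited data-processing file,
    used for round-trip testing.  Includes a derived-statistics sheet (a
    hydraulic-diameter column recomputed per airway) that ingestion must
    ignore.  Returns the path written (.zip when ``pack_zip``)."""
    path = Path(path)
    workbook = openpyxl.Workbook()
    ws_meas = workbook.active
    ws_meas.title = MEASUREMENT_SHEET
    meas = dataset.measurements_frame()
    ws_meas.append(list(meas.columns))
    for row in meas.itertuples(index=False):
        ws_meas.append([None if (isinstance(v, float) and np.isnan(v)) else v for v in row])
    ws_vol = workbook.create_sheet(VOLUME_SHEET)
    vols = dataset.volumes_frame()
    ws_vol.append(list(vols.columns))
    for row in vols.itertuples(index=False):
        ws_vol.append(list(row))
    ws_stats = workbook.create_sheet("derived_statistics")
    ws_stats.append(["subject_id", "label", "state", "dh_mm"])
    for m in dataset.measurements:
        ws_stats.append([m.subject_id, m.label.name, m.state.value, 4 * m.ai / m.pi])
    if pack_zip:
        xlsx_bytes = io.BytesIO()
        workbook.save(xlsx_bytes)
        zip_path = path if path.suffix == ".zip" else path.with_suffix(".zip")
        with zipfile.ZipFile(zip_path, "w", compression=zipfile.ZIP_DEFLATED) as archive:
            archive.writestr("S1_data_processing.xlsx", xlsx_bytes.getvalue())
        return zip_path
    workbook.save(path)
    return path


# -- summary tables ------------------------------------------------------


def write_summary_tables(tables: dict[str, pd.DataFrame], outdir) -> dict[str, Path]:
    """Write named summary tables as CSVs with stable column order and
    6-significant-digit floats; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in tables.items():
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.6g")
        paths[name] = path
    return paths


def read_summary_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    """Load a YAML key-value configuration file."""
    with open(path, "r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: configuration must be a mapping, got {type(data).__name__}")
    return data
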