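"""End-to-end drivers: simulate a cohort, analyze a cohort, render a report.

``analyze_dataset`` is the single entry point the numbered analysis
scripts, the command-line interface and the acceptance machinery all
share: it matches airways across inflations, computes the caliber tables
(hydraulic-diameter and lumen-geometry summaries, diameter ratios,
trachea-normalized calibers), runs the distensibility pipeline (records,
outlier rule, per-subtree summaries, distribution diagnostics, the
generation-3-vs-4 regression) and collects headline numbers.  All
thresholds live in :class:`PipelineConfig` and are echoed into the output
so a report always states what was applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_stats
from . import distensibility as dist
from . import morphometry
from .io_tables import (
    CohortDataset,
    ingest_s1_workbook,
    read_cohort,
    write_cohort,
    write_summary_tables,
)
from .simulate import SimulatorConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "AnalysisResult",
    "run_simulate",
    "analyze_dataset",
    "analyze_files",
    "run_report",
]

SUMMARY_JSON = "analysis_summary.json"


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis thresholds (all exposed; defaults follow the emulated study)."""

    min_n: int = 8  # cells below this count are suppressed
    outlier_k: float = 2.0  # outlier rule: |AD - mean| > k * SD
    outlier_grouping: str = "per-lung-generation"
    outliers_before_summary: bool = True  # apply the rule before Table-style means
    alpha: float = 0.05  # significance threshold for paired comparisons
    alpha_ratio: float = 0.01  # threshold used for the Din/Dh state comparison
    proximal_ad_mode: str = "exclude"  # or "summed" (trachea via summed lungs)
    histogram_bins: int = 10
    gen34_exclude: tuple[str, ...] = ("LB1",)  # subtrees excluded in the second fit

    def validate(self) -> "PipelineConfig":
        if self.min_n < 1:
            raise ValueError("min_n must be >= 1")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")
        if self.outlier_grouping not in dist.OUTLIER_GROUPINGS:
            raise ValueError(f"unknown outlier grouping {self.outlier_grouping!r}")
        if self.proximal_ad_mode not in ("exclude", "summed"):
            raise ValueError(f"unknown proximal_ad_mode {self.proximal_ad_mode!r}")
        return self


@dataclass
class AnalysisResult:
    tables: dict[str, pd.DataFrame]
    headline: dict
    match: cohort_stats.MatchResult
    config: PipelineConfig


def run_simulate(outdir, seed: int = 0, config: SimulatorConfig | None = None) -> dict[str, Path]:
    """Generate a cohort and write measurements, volumes and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or SimulatorConfig()
    dataset, truth = generate_cohort(config, seed=seed)
    paths = {
        "measurements": outdir / "measurements.csv",
        "volumes": outdir / "volumes.csv",
        "ground_truth": outdir / "ground_truth.csv",
        "log": outdir / "simulation_log.json",
    }
    write_cohort(dataset, paths["measurements"], paths["volumes"])
    truth.to_csv(paths["ground_truth"], index=False)
    log = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_measurements": len(dataset.measurements),
        "n_subjects": config.n_subjects,
        "provenance": dataset.provenance,
    }
    paths["log"].write_text(json.dumps(log, indent=2, default=str) + "\n")
    logger.info("simulated cohort seed=%d config=%s -> %s", seed, config.config_hash(), outdir)
    return paths


def _jsonable(value):
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, (np.floating, np.integer)):
        value = value.item()
    if isinstance(value, float) and not np.isfinite(value):
        return None
    return value


def analyze_dataset(dataset: CohortDataset, config: PipelineConfig | None = None) -> AnalysisResult:
    """Run the full morphometry + distensibility analysis on a cohort."""
    config = (config or PipelineConfig()).validate()
    match = cohort_stats.match_airways(dataset)
    matches = match.matches

    shape = morphometry.add_shape_columns(dataset.measurements_frame())
    n_infeasible = int((~shape["isoperimetric_ok"]).sum())
    if n_infeasible:
        logger.warning(
            "%d measurement(s) violate the isoperimetric bound (pi^2 < 4*pi*ai); "
            "they remain flagged in the shape table",
            n_infeasible,
        )

    tables: dict[str, pd.DataFrame] = {}
    tables["shape_by_measurement"] = shape
    tables["dh_by_region_generation"] = cohort_stats.summarize_region_generation(
        matches, "dh", min_n=config.min_n, by="region"
    )
    tables["ai_by_subtree_generation"] = cohort_stats.summarize_region_generation(
        matches, "ai", min_n=config.min_n, by="root"
    )
    tables["pi_by_subtree_generation"] = cohort_stats.summarize_region_generation(
        matches, "pi", min_n=config.min_n, by="root"
    )
    tables["din_dh_by_region_generation"] = cohort_stats.summarize_region_generation(
        matches, "din_dh_ratio", min_n=config.min_n, by="region"
    )
    tables["dh_matched_scatter"] = cohort_stats.matched_frame(matches, "dh")

    normalized, excluded_norm = morphometry.normalize_to_trachea(
        shape[["subject_id", "label", "state", "dh_mm"]]
    )
    if not normalized.empty:
        normalized = normalized.assign(
            region=[str(_region(label)) for label in normalized["label"]],
            generation=[_generation(label) for label in normalized["label"]],
        )
        norm_summary = (
            normalized.groupby(["region", "generation", "state"])["dh_normalized"]
            .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
            .reset_index()
        )
    else:
        norm_summary = pd.DataFrame(
            columns=["region", "generation", "state", "n", "mean", "sd"]
        )
    tables["dh_normalized_to_trachea"] = norm_summary

    ad = dist.distensibility_table(
        matches, dataset.volumes, proximal_mode=config.proximal_ad_mode
    )
    ad = dist.flag_outliers(ad, k=config.outlier_k, grouping=config.outlier_grouping)
    if not config.outliers_before_summary:
        summary_input = ad.assign(outlier=False)
    else:
        summary_input = ad
    tables["distensibility_records"] = ad
    tables["ad_by_subtree_generation"] = cohort_stats.summarize_ad(
        summary_input, by="root", min_n=config.min_n
    )
    tables["ad_by_region_generation"] = cohort_stats.summarize_ad(
        summary_input, by="region", min_n=config.min_n
    )

    diag_rows = []
    probplot_rows = []
    usable_ad = ad[ad["valid"].astype(bool) & ~ad["outlier"].astype(bool)]
    for (side, gen), sub in usable_ad[usable_ad["generation"].isin([3, 4])].groupby(
        ["side", "generation"]
    ):
        try:
            diag = dist.distribution_diagnostics(sub["ad"], bins=config.histogram_bins)
        except ValueError:
            logger.warning("diagnostics skipped for %s gen %s: too few records", side, gen)
            continue
        for lo, hi, count in zip(diag.bin_edges[:-1], diag.bin_edges[1:], diag.counts):
            diag_rows.append(
                {
                    "side": side,
                    "generation": gen,
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "count": int(count),
                    "fit_mean": diag.mean,
                    "fit_sd": diag.sd,
                }
            )
        for tq, sq in zip(diag.theoretical_quantiles, diag.sample_quantiles):
            probplot_rows.append(
                {"side": side, "generation": gen, "theoretical_q": tq, "sample_q": sq}
            )
    tables["ad_distribution_histogram"] = pd.DataFrame(
        diag_rows,
        columns=["side", "generation", "bin_lo", "bin_hi", "count", "fit_mean", "fit_sd"],
    )
    tables["ad_probability_plot"] = pd.DataFrame(
        probplot_rows, columns=["side", "generation", "theoretical_q", "sample_q"]
    )

    gen34 = {}
    for name, exclude in (("full", ()), ("excluded", tuple(config.gen34_exclude))):
        try:
            reg, points = cohort_stats.gen3_vs_gen4_distensibility(ad, exclude=exclude)
            gen34[name] = {
                "r_squared": reg.r_squared,
                "slope": reg.slope,
                "intercept": reg.intercept,
                "n_subtrees": reg.n,
                "excluded": list(exclude),
            }
            if name == "full":
                tables["ad_gen3_vs_gen4"] = points
        except ValueError as exc:
            logger.warning("gen3-vs-gen4 regression (%s) unavailable: %s", name, exc)
            gen34[name] = None

    headline = _headline(dataset, shape, matches, ad, gen34, match, config)
    if not matches:
        logger.warning("no matched airways: summaries are empty")
    return AnalysisResult(tables=tables, headline=headline, match=match, config=config)


def _region(label: str) -> str:
    from .anatomy import lobe_region

    return lobe_region(label).value


def _generation(label: str) -> int:
    from .anatomy import assign_generation

    return assign_generation(label)


def _headline(dataset, shape, matches, ad, gen34, match, config) -> dict:
    def mean_sd(series):
        series = series.dropna()
        if series.empty:
            return None, None
        return float(series.mean()), float(series.std(ddof=1)) if len(series) > 1 else None

    mlv_ratio = shape.loc[shape["state"] == "MLV", "din_dh"]
    tlc_ratio = shape.loc[shape["state"] == "TLC", "din_dh"]
    ratio_mlv_mean, ratio_mlv_sd = mean_sd(mlv_ratio)
    ratio_tlc_mean, ratio_tlc_sd = mean_sd(tlc_ratio)

    if matches:
        dh_frame = cohort_stats.matched_frame(matches, "dh")
        pct_mean, pct_sd = mean_sd(dh_frame["pct_change"])
        frac_down = cohort_stats.fraction_decreasing(matches, "dh")
    else:
        pct_mean = pct_sd = frac_down = None

    usable = ad[ad["valid"].astype(bool) & ~ad["outlier"].astype(bool)]
    segmental = usable[usable["generation"] >= 3]
    ad_mean, ad_sd = mean_sd(segmental["ad"])

    return {
        "n_measurements": len(dataset.measurements),
        "n_matched": len(matches),
        "n_unmatched_mlv": match.n_unmatched_mlv,
        "n_unmatched_tlc": match.n_unmatched_tlc,
        "n_isoperimetric_violations": int((~shape["isoperimetric_ok"]).sum()),
        "din_dh_mlv_mean": ratio_mlv_mean,
        "din_dh_mlv_sd": ratio_mlv_sd,
        "din_dh_tlc_mean": ratio_tlc_mean,
        "din_dh_tlc_sd": ratio_tlc_sd,
        "dh_pct_change_mean": pct_mean,
        "dh_pct_change_sd": pct_sd,
        "fraction_dh_decreasing": frac_down,
        "mean_distensibility": ad_mean,
        "sd_distensibility": ad_sd,
        "n_distensibility_records": int(len(ad)),
        "n_distensibility_outliers": int(ad["outlier"].astype(bool).sum()),
        "n_distensibility_invalid": int((~ad["valid"].astype(bool)).sum()),
        "gen3_vs_gen4": gen34,
        "config": asdict(config),
        "provenance": dataset.provenance,
    }


def analyze_files(
    measurements_path=None,
    volumes_path=None,
    outdir="analysis",
    config: PipelineConfig | None = None,
    s1_workbook=None,
) -> dict[str, Path]:
    """File-level wrapper: read a cohort (CSV pair or workbook), analyze,
    write all summary tables and the headline JSON."""
    if s1_workbook is not None:
        dataset = ingest_s1_workbook(s1_workbook)
    else:
        if measurements_path is None or volumes_path is None:
            raise ValueError("need either --s1-workbook or both measurement and volume CSVs")
        dataset = read_cohort(measurements_path, volumes_path)
    result = analyze_dataset(dataset, config)
    outdir = Path(outdir)
    paths = write_summary_tables(result.tables, outdir)
    summary_path = outdir / SUMMARY_JSON
    summary_path.write_text(json.dumps(_jsonable(result.headline), indent=2) + "\n")
    paths["summary"] = summary_path
    return paths


# -- report ---------------------------------------------------------------

_REPORT_TABLES = [
    ("dh_by_region_generation", "Hydraulic diameter by lobe region and generation"),
    ("ai_by_subtree_generation", "Lumen area by segmental subtree and generation"),
    ("pi_by_subtree_generation", "Inner perimeter by segmental subtree and generation"),
    ("din_dh_by_region_generation", "Din/Dh ratio by lobe region and generation"),
    ("ad_by_subtree_generation", "Distensibility by segmental subtree and generation"),
    ("ad_by_region_generation", "Distensibility by lobe region and generation"),
    ("dh_normalized_to_trachea", "Hydraulic diameter normalized to the trachea"),
]


def _format_cell(value) -> str:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return "—"
    if isinstance(value, (bool, np.bool_)):
        return "yes" if value else "no"
    if isinstance(value, (float, np.floating)):
        return f"{value:.4g}"
    return str(value)


def _markdown_table(frame: pd.DataFrame) -> str:
    if frame.empty:
        return "*(no rows)*\n"
    header = "| " + " | ".join(str(c) for c in frame.columns) + " |"
    sep = "| " + " | ".join("---" for _ in frame.columns) + " |"
    lines = [header, sep]
    for row in frame.itertuples(index=False):
        lines.append("| " + " | ".join(_format_cell(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def run_report(indir, out_path=None) -> Path:
    """Render the analysis directory into a human-readable markdown report."""
    indir = Path(indir)
    summary_path = indir / SUMMARY_JSON
    if not summary_path.exists():
        raise FileNotFoundError(f"{summary_path}: run the analysis first")
    headline = json.loads(summary_path.read_text())
    out_path = Path(out_path) if out_path else indir / "report.md"

    def fmt(key, scale=1.0, digits=4):
        value = headline.get(key)
        return "n/a" if value is None else f"{value * scale:.{digits}g}"

    lines = ["# Airway morphometry report", ""]
    lines.append(f"Cohort: {headline.get('provenance', 'unknown')}")
    lines.append("")
    lines.append("## Headline numbers")
    lines.append("")
    lines.append(f"- measurements: {headline['n_measurements']}, matched airways: {headline['n_matched']} "
                 f"(unmatched: {headline['n_unmatched_mlv']} MLV-only, {headline['n_unmatched_tlc']} TLC-only)")
    lines.append(f"- mean hydraulic-diameter change MLV→TLC: {fmt('dh_pct_change_mean')} % "
                 f"(SD {fmt('dh_pct_change_sd')})")
    lines.append(f"- Din/Dh ratio: {fmt('din_dh_mlv_mean')} (MLV) vs {fmt('din_dh_tlc_mean')} (TLC)")
    lines.append(f"- mean distensibility (segmental, after outlier rule): {fmt('mean_distensibility')} "
                 f"(SD {fmt('sd_distensibility')}); outliers flagged: {headline['n_distensibility_outliers']}, "
                 f"invalid: {headline['n_distensibility_invalid']}")
    frac = headline.get("fraction_dh_decreasing")
    lines.append(f"- airways with Dh decreasing at TLC: "
                 f"{'n/a' if frac is None else format(100 * frac, '.2f') + ' %'}")
    gen34 = headline.get("gen3_vs_gen4") or {}
    for name, entry in gen34.items():
        if entry:
            lines.append(
                f"- distensibility generation 3 vs 4 ({name}"
                + (f", excluding {','.join(entry['excluded'])}" if entry["excluded"] else "")
                + f"): R² = {entry['r_squared']:.4f} over {entry['n_subtrees']} subtrees"
            )
    lines.append("")
    for name, title in _REPORT_TABLES:
        path = indir / f"{name}.csv"
        if not path.exists():
            continue
        frame = pd.read_csv(path)
        lines.append(f"## {title}")
        lines.append("")
        lines.append(_markdown_table(frame))
    config = headline.get("config", {})
    lines.append("---")
    lines.append(
        "Active thresholds: "
        f"min n per cell = {config.get('min_n')}, outlier rule = {config.get('outlier_k')} SD "
        f"({config.get('outlier_grouping')}), alpha = {config.get('alpha')} "
        f"(ratio comparison {config.get('alpha_ratio')}), "
        f"proximal distensibility mode = {config.get('proximal_ad_mode')}."
    )
    lines.append("")
    out_path.write_text("\n".join(lines))
    logger.info("report written to %s", out_path)
    return out_path
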