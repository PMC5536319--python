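"""Assemble the full analysis and render the markdown report.

Runs the complete pipeline on the cohort tables (everything scripts 02
and 03 compute, in one pass), writes all summary CSVs plus the headline
JSON, and renders them as a single human-readable report with the active
thresholds in the footer.
"""

import argparse
from pathlib import Path

from airmorph.pipeline import analyze_files, run_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = parser.parse_args()

    analyze_files(
        measurements_path=args.cohort / "measurements.csv",
        volumes_path=args.cohort / "volumes.csv",
        outdir=args.out,
    )
    report_path = run_report(args.out)
    print(f"Report: {report_path}")


if __name__ == "__main__":
    main()
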