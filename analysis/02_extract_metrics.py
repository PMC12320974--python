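#!/usr/bin/env python
"""Extract cardiac endpoints from the rendered recordings.

Reads the manifest written by 01_simulate_cohorts.py, runs the full
measurement pipeline on every kymograph (wall-profile extraction, beat
detection, heart rate, arrhythmicity index, fractional shortening, and
Poincare ellipse areas), and writes per-recording tables.

Usage: python analysis/02_extract_metrics.py [--study results/study]
"""

import argparse
from pathlib import Path

import pandas as pd

from flyheart.config import RunConfig
from flyheart.pipeline import analyze_manifest, ellipse_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    manifest = pd.read_csv(args.study / "manifest.csv")
    config = RunConfig()
    metrics, ellipses = analyze_manifest(manifest, config)
    metrics.to_csv(args.study / "metrics.csv", index=False)
    ellipses.to_csv(args.study / "ellipses.csv", index=False)
    ellipse_table(ellipses).to_csv(args.study / "ellipse_deltas.csv", index=False)

    truth = pd.read_csv(args.study / "ground_truth_metrics.csv")
    merged = metrics.merge(
        truth, on=["animal_id", "condition"], suffixes=("", "_true")
    )
    for col in ("hr_bpm", "ai_au", "fs_pct"):
        err = (merged[col] - merged[f"{col}_true"]).abs()
        print(f"{col}: mean abs recovery error {err.mean():.4g} (max {err.max():.4g})")


if __name__ == "__main__":
    main()
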