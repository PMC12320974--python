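#!/usr/bin/env python
"""Poincare beat-to-beat variability figures for each animal.

Re-runs event detection on the rendered recordings, builds lagged interval
pairs (I_n, I_n+1) for the before- and after-pacing recordings of each
animal, fits 0.99 confidence ellipses, and writes one superimposed figure
per animal plus a summary of ellipse-area changes.

Usage: python analysis/04_poincare_variability.py [--study results/study] [--max-figs 10]
"""

import argparse
from pathlib import Path

import pandas as pd

from flyheart.beats import detect_contractions, extract_profile
from flyheart.config import RunConfig
from flyheart.io import read_kymograph
from flyheart.pipeline import ellipse_table, poincare_figures


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--max-figs", type=int, default=10)
    args = ap.parse_args()

    manifest = pd.read_csv(args.study / "manifest.csv")
    config = RunConfig()
    fig_dir = args.study / "poincare"
    fig_dir.mkdir(exist_ok=True)

    made = 0
    for animal_id, group in manifest.groupby("animal_id"):
        if made >= args.max_figs:
            break
        series = {}
        for _, row in group.iterrows():
            kymo = read_kymograph(Path(row["path"]))
            trace = extract_profile(
                kymo, window=config.smoothing_window, row_strategy=config.row_strategy
            )
            series[row["condition"]] = detect_contractions(
                trace,
                polarity=config.polarity,
                prominence_k=config.prominence_k,
                refractory_s=config.refractory_s,
            )
        if "BTP" not in series:
            continue
        poincare_figures(
            series, str(fig_dir / f"{animal_id}.png"),
            level=config.ellipse_level, title=animal_id,
        )
        made += 1
    print(f"wrote {made} Poincare figures to {fig_dir}")

    ellipses = pd.read_csv(args.study / "ellipses.csv")
    strains = manifest[["animal_id", "strain"]].drop_duplicates()
    deltas = ellipse_table(ellipses).merge(strains, on="animal_id")
    deltas.to_csv(args.study / "poincare_deltas.csv", index=False)
    print(deltas.groupby("strain")["delta_pct"].describe().round(1))


if __name__ == "__main__":
    main()
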