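#!/usr/bin/env python
"""Run the study-level statistics on the extracted endpoints.

Paired Wilcoxon signed-rank tests (before vs after tachypacing, per strain
and endpoint), Kruskal-Wallis across strains within each condition, the
contractile-dysfunction flags, and the summary bar/paired-line figures.

Usage: python analysis/03_group_comparisons.py [--study results/study]
"""

import argparse
from pathlib import Path

import pandas as pd

from flyheart.plotting import bar_summary, paired_lines
from flyheart.stats import run_study_comparisons


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    metrics = pd.read_csv(args.study / "metrics.csv")
    tables = run_study_comparisons(metrics)
    for name, df in tables.items():
        df.to_csv(args.study / f"comparisons_{name}.csv", index=False)

    paired = tables["paired"]
    print(paired[["strain", "endpoint", "mean_delta", "p", "stars", "dysfunction"]]
          .to_string(index=False))

    for endpoint, col in (("HR", "hr_bpm"), ("AI", "ai_au"), ("FS", "fs_pct")):
        bar_summary(metrics, col, path=args.study / f"bars_{endpoint.lower()}.png")
        paired_lines(metrics, col, path=args.study / f"paired_{endpoint.lower()}.png")
    print(f"figures and comparison tables written to {args.study}")


if __name__ == "__main__":
    main()
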