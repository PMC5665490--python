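#!/usr/bin/env python
"""Correlate binding enrichment, microsatellite length and target-gene
expression, stratified into promoter-like vs enhancer-like microsatellites
of activated vs repressed genes.

Writes associations.tsv, quadrant_counts.tsv and correlations.tsv under
results/scan/ and prints the four-quadrant Spearman summary that
distinguishes length-dependent activation at close range from
length-independent repression.
"""

import argparse
from pathlib import Path

import pandas as pd

from ggaasat.association_stats import null_band
from ggaasat.pipeline import PipelineConfig, run_associate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--peaks", type=Path,
                        default=Path("results") / "simulation" / "peaks.narrowPeak")
    parser.add_argument("--genes", type=Path,
                        default=Path("results") / "simulation" / "genes.tsv")
    parser.add_argument("--de", type=Path,
                        default=Path("results") / "simulation" / "de.tsv")
    parser.add_argument("--out-dir", type=Path, default=Path("results") / "scan")
    args = parser.parse_args()

    config = PipelineConfig(peaks=str(args.peaks), genes=str(args.genes),
                            de=str(args.de), out_dir=str(args.out_dir))
    run_associate(config)
    counts = pd.read_csv(args.out_dir / "quadrant_counts.tsv", sep="\t")
    print("bound microsatellites per quadrant:")
    for row in counts.itertuples(index=False):
        print(f"  {row.range_class:14s} x {row.regulation:9s}: {row.n:5,}")
    corr = pd.read_csv(args.out_dir / "correlations.tsv", sep="\t")
    print("\nSpearman r (enrichment / expression vs consecutive motifs):")
    for quadrant, sub in corr.groupby("quadrant", sort=False):
        sub = sub.set_index("pair")
        fe = sub.loc["enrichment_vs_max_consecutive"]
        ex = sub.loc["expression_vs_max_consecutive"]
        band = null_band(int(fe.n)) if fe.n >= 2 else float("nan")
        print(f"  {quadrant:28s} n={int(fe.n):5,}  binding r={fe.r:6.2f}  "
              f"expression r={ex.r:6.2f}  (95% null band +/-{band:.3f})")
    print("\nreading: binding tracks length everywhere; expression tracks "
          "length only for promoter-like microsatellites of activated genes.")


if __name__ == "__main__":
    main()
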