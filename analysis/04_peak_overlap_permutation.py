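#!/usr/bin/env python
"""Test whether microsatellites overlap binding peaks more than chance.

Runs the universe-resampling permutation test (random microsatellite-sized
sets drawn from all repeat regions), the uniform-relocation null, and the
shifted z-score profile that probes positional specificity.  Writes
permutation.tsv and shift_profile.tsv under results/scan/ and prints the
observed overlap against both nulls.
"""

import argparse
from pathlib import Path

import pandas as pd

from ggaasat.pipeline import PipelineConfig, run_permtest


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--genome", type=Path,
                        default=Path("results") / "simulation" / "genome.fa")
    parser.add_argument("--peaks", type=Path,
                        default=Path("results") / "simulation" / "peaks.narrowPeak")
    parser.add_argument("--out-dir", type=Path, default=Path("results") / "scan")
    parser.add_argument("--n-perm", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    config = PipelineConfig(genome=str(args.genome), peaks=str(args.peaks),
                            out_dir=str(args.out_dir), n_perm=args.n_perm,
                            seed=args.seed)
    run_permtest(config)
    perm = pd.read_csv(args.out_dir / "permutation.tsv", sep="\t")
    for row in perm.itertuples(index=False):
        print(f"{row.strategy:10s} observed={row.observed:6,}  "
              f"null mean={row.perm_mean:8.1f} sd={row.perm_sd:6.2f}  "
              f"z={row.z:8.1f}  p={row.p_empirical:.4g}")
    shift = pd.read_csv(args.out_dir / "shift_profile.tsv", sep="\t")
    peak_row = shift.loc[shift.z.idxmax()]
    print(f"shifted-z profile peaks at offset {int(peak_row.offset):,} bp "
          f"(z={peak_row.z:.1f}); association is positional, not regional")


if __name__ == "__main__":
    main()
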