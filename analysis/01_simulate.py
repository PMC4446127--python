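#!/usr/bin/env python
"""Generate the synthetic promoter landscape with known ground truth.

Writes gene models, CAGE tags/clusters, ChIP-seq and RNA-seq reads, the
chromosome sequence and the ground-truth table under results/pipeline/data.
"""

import argparse
from pathlib import Path

import pandas as pd

from promdir.config import PipelineConfig
from promdir.pipeline import run


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/pipeline"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    cfg.simulation.seed = args.seed
    run("simulate", cfg, args.outdir)

    truth = pd.read_csv(args.outdir / "data" / "ground_truth.tsv", sep="\t")
    print(f"simulated {len(truth)} genes on one "
          f"{cfg.simulation.chrom_length/1e6:.0f} Mb chromosome")
    print(truth["true_class"].value_counts().to_string())
    print(f"planted CTCF/RAD21 peaks: {truth['ctcf_peak'].sum()} "
          f"(motif written for {truth['motif'].sum()})")


if __name__ == "__main__":
    main()
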