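#!/usr/bin/env python
"""Optional full-scale experiment on a real m6A benchmark (hours of CPU).

This script is NOT part of the test suite or the acceptance run.  It
documents how to reproduce a full-scale RS + LOCO comparison of all three
model variants, given a benchmark file in the package's tabular format
(columns id, chrom, sequence, label; windows of 2001 nt; chromosome labels
chr1..chr23; ~10k positives / ~55k negatives):

    python scripts/full_scale.py benchmark.csv -o runs/full --seed 1

Expect roughly: 5 balanced replicates x 2 protocols x 3 variants, each
trained 70 epochs at L=2001 — days of single-core CPU time.  Use
--replicates/--variants/--epochs to scope a partial run.
"""

from __future__ import annotations

import argparse

from m6aloco.experiment import ExperimentConfig, run_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("dataset", help="tabular benchmark file (id,chrom,sequence,label)")
    ap.add_argument("-o", "--out", required=True)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=5)
    ap.add_argument("--variants", default="SM,HM,DHM")
    ap.add_argument("--epochs", type=int, default=70)
    args = ap.parse_args()

    cfg = ExperimentConfig(
        dataset_path=args.dataset,
        n_subsets=args.replicates,
        modes=("RS", "LOCO"),
        variants=tuple(v.strip() for v in args.variants.split(",")),
        fast_profile=False,  # faithful L=2001 geometry
        training={"epochs": args.epochs},
        out_dir=args.out,
        seed=args.seed,
    )
    results = run_experiment(cfg)
    print(results["summary"].to_string(index=False))


if __name__ == "__main__":
    main()
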