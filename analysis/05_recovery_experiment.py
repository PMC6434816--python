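#!/usr/bin/env python
"""Contamination-recovery benchmark across known host fractions.

Simulates 3 donors with 500 donor-private marker sites each at read depth
200, true host fractions 0.1-0.9 across the grafted time points, runs the
full estimation chain and summarizes the error of the recovered
contamination. Writes results/recovery.tsv and results/recovery_summary.tsv.
"""

import argparse
import os

from pearldecon.validation import (
    contamination_recovery_experiment,
    recovery_summary,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    result = contamination_recovery_experiment(seed=args.seed)
    summary = recovery_summary(result)

    os.makedirs(args.out, exist_ok=True)
    result.to_csv(os.path.join(args.out, "recovery.tsv"), sep="\t",
                  index=False, float_format="%.6g")
    summary.to_csv(os.path.join(args.out, "recovery_summary.tsv"), sep="\t",
                   index=False, float_format="%.6g")

    print(summary.to_string(index=False))
    mixed = result[result["h_true"] > 0]
    print(f"\nmax |error| over mixed samples: "
          f"{mixed['error_percent_points'].abs().max():.2f} points "
          f"(n={len(mixed)})")


if __name__ == "__main__":
    main()
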