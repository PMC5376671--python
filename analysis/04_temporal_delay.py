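#!/usr/bin/env python
"""Feed-forward delay and early noise filtering in RA-driven differentiation.

Simulates a homogeneous group of cells exposed to an RA step (no FGF), as
in ES-cell-derived motor-neuron differentiation, for wild-type and
Dicer-null genotypes.  Writes Hoxa5-protein time courses and the day-3
histogram under results/04_differentiation/ and prints the half-rise times
and early-time variances.  Expected: mir-x delays the Hoxa5 rise by roughly
2 days and suppresses early cell-to-cell dispersion; Dicer-null cells turn
on precociously with a broad day-3 distribution.
"""

import sys
from pathlib import Path

from hoxmir.runner import ExperimentConfig, run_experiment

OUT = Path("results/04_differentiation")


def main(seed: int = 1) -> None:
    for genotype in ("wild_type", "dicer_null"):
        cfg = ExperimentConfig(
            protocol="differentiate",
            seed=seed,
            out_dir=str(OUT / genotype),
            mutant=genotype,
        )
        s = run_experiment(cfg)["summary"]
        print(
            f"{genotype}: half_rise={s['half_rise_time']:.2f} d  "
            f"day3 mean={s['day3_mean']:.3f} var={s['day3_var']:.4f}"
        )
    print(f"artifacts in {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
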