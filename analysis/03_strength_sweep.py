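#!/usr/bin/env python
"""Sensitivity of the screen to the candidate-interaction strength.

Repeats the topology screen at six interaction strengths spanning 0.2-1.2
and reports the winning topology per strength.  Weak interactions (0.2-0.4)
underdetermine the wiring; from mid strengths on the winners belong to the
coherent feed-forward family identified by the main screen.  Uses 10
replicates per topology to keep the six screens tractable; expect winner
identity to fluctuate within the top family at this replicate budget.
"""

import sys
from pathlib import Path

from hoxmir.runner import ExperimentConfig, run_experiment

OUT = Path("results/03_sweep")


def main(seed: int = 1) -> None:
    cfg = ExperimentConfig(protocol="sweep", seed=seed, out_dir=str(OUT))
    bundle = run_experiment(cfg)
    df = bundle["sweep"]
    print(df[["strength", "best_topology", "best_score", "stable"]].to_string(index=False))
    print(f"artifacts in {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
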