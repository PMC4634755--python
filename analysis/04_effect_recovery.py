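#!/usr/bin/env python
"""Can the pipeline recover a programmed glycolytic condition effect?

Simulates 50 independent crossover cohorts (n = 10) with a +3.6 kJ per
round glycolytic offset in the caffeine condition, estimates each
cohort's CAF−PLA difference in round-mean W_[La-] through the full
energy-partition pipeline, and summarises sign consistency and bias.
Writes results/effect_recovery.csv.
"""

from pathlib import Path

import pandas as pd

from combatmet.experiments import glycolytic_recovery_experiment

SEED = 42


def main() -> None:
    rec = glycolytic_recovery_experiment(n_cohorts=50, seed=SEED, n_subjects=10, offset_kj=3.6)
    out = Path(__file__).resolve().parents[1] / "results" / "effect_recovery.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cohort": range(1, 51), "caf_minus_pla_wla_kj": rec.diffs}).to_csv(out, index=False)
    print(f"programmed offset: {rec.programmed_kj:.1f} kJ/round")
    print(f"estimated mean difference: {rec.mean_diff:.2f} kJ "
          f"(relative error {rec.relative_error * 100:.1f}%)")
    print(f"correct sign in {rec.sign_rate * 100:.0f}% of 50 cohorts")
    print(f"per-cohort estimates written to {out}")


if __name__ == "__main__":
    main()
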