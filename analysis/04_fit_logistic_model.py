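#!/usr/bin/env python
"""Multivariable logistic model with backward elimination.

Runs the full development pipeline (screen -> discretize -> backward
selection) on the derivation cohort and writes the coefficient report —
beta (SE), OR (95 % CI), Wald p per retained term — plus the audit trail of
dropped candidates.  The published scale's point assignments are kept as the
instrument; this step shows which factors the same selection procedure
retains on synthetic data.
"""

from pathlib import Path

import pandas as pd

from strokescale.cohort import read_cohort
from strokescale.pipeline import RunConfig, run_develop

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort_derivation.csv")
    result = run_develop(RunConfig(), cohort)

    coef = result.coef_report()
    coef.to_csv(RESULTS / "logistic_coefficients.csv", index=False)
    print("retained terms (backward elimination at Wald p < 0.05):")
    for _, row in coef[coef.term != "const"].iterrows():
        print(f"  {row.term:24s} beta {row.coefficient:6.2f} ({row.se:.2f})  "
              f"OR {row.odds_ratio:6.2f} ({row.ci95_low:.2f}-{row.ci95_high:.2f})  "
              f"p = {row.p_value:.4f}")
    if result.dropped:
        print("dropped during elimination:",
              ", ".join(f"{t} (p={p:.2f})" for t, p in result.dropped))

    from strokescale.scale import save_scale

    save_scale(result.scale, RESULTS / "scale.json")
    print(f"coefficients -> {RESULTS / 'logistic_coefficients.csv'}")
    print(f"scale (published weights, cutoff re-derived: "
          f"{result.cutoff}) -> {RESULTS / 'scale.json'}")


if __name__ == "__main__":
    main()
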