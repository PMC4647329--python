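#!/usr/bin/env python
"""Tree-based discretization of the continuous predictors.

Finds Gini-optimal cutpoints for age and the NIHSS change (depth 1, binary)
and for day-1 NIHSS (depth 2, up to three categories) on the derivation
cohort, and prints per-bin poor-outcome rates.  The published instrument
uses boundaries 56.44 (age), {2, 6} (NIHSS) and -1 (NIHSS change); this step
shows what the same procedure recovers on the synthetic cohort.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from strokescale.cohort import Outcome, read_cohort
from strokescale.tree import bin_variable, grow_thresholds

RESULTS = Path(__file__).resolve().parent.parent / "results"

DEPTHS = {"age": 1, "nihss_d1": 2, "delta_nihss": 1}


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort_derivation.csv")
    y = np.array([1 if r.outcome is Outcome.POOR else 0 for r in cohort.records])
    values = {
        "age": np.array([r.age for r in cohort.records]),
        "nihss_d1": np.array([r.nihss_day1 for r in cohort.records]),
        "delta_nihss": np.array([r.delta_nihss for r in cohort.records]),
    }

    rows = []
    for var, depth in DEPTHS.items():
        disc = grow_thresholds(values[var], y, max_depth=depth, min_leaf=20,
                               variable=var)
        print(f"{var}: thresholds {[round(t, 2) for t in disc.thresholds]}")
        bins = np.array([bin_variable(v, disc) for v in values[var]])
        for b, label in enumerate(disc.labels):
            mask = bins == b
            rate = float(y[mask].mean()) if mask.any() else float("nan")
            print(f"  bin {b} {label:12s} n={int(mask.sum()):4d} poor-rate={rate:.3f}")
            rows.append({"variable": var, "bin": b, "interval": label,
                         "n": int(mask.sum()), "poor_rate": rate,
                         "thresholds": list(disc.thresholds)})
    pd.DataFrame(rows).to_csv(RESULTS / "discretization.csv", index=False)
    print(f"table -> {RESULTS / 'discretization.csv'}")


if __name__ == "__main__":
    main()
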