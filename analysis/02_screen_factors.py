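#!/usr/bin/env python
"""Stage-1 univariate screening on the derivation cohort.

Applies the 5 % prevalence filter, then compares every candidate factor
between good and poor recovery (chi-square for binary factors and
symptom-change tables, Mann-Whitney U for continuous ones), and writes the
full screening report with selection flags at p < 0.05.
"""

from pathlib import Path

import pandas as pd

from strokescale.cohort import read_cohort
from strokescale.screening import prevalence_filter, screen_candidates

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort_derivation.csv")
    kept = prevalence_filter(cohort)
    print(f"prevalence filter (>= 5 % on day 1): {len(kept)} of "
          f"{len(cohort.panel)} panel symptoms kept")

    results = screen_candidates(cohort)
    df = pd.DataFrame([r.__dict__ for r in results])
    out = RESULTS / "screen_report.csv"
    df.to_csv(out, index=False)

    selected = df[df.selected]
    print(f"{len(selected)} of {len(df)} factors significant at p < 0.05:")
    for _, row in selected.sort_values("p_value").iterrows():
        print(f"  {row.factor:28s} {row.test:13s} p = {row.p_value:.4f}")
    print(f"report -> {out}")


if __name__ == "__main__":
    main()
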