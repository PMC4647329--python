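#!/usr/bin/env python
"""Score both cohorts with the published scale and validate.

Applies the published 8-item scale (cutoff 9.5) to the derivation and
validation cohorts, reports the ROC sweep with Youden's index, the
Youden-optimal cutoff on the derivation cohort, and the confusion counts
(TG/FP/TP/FG) with sensitivity, specificity and accuracy on both cohorts.
"""

import json
from pathlib import Path

import pandas as pd

from strokescale.cohort import read_cohort
from strokescale.roc import confusion, metrics, roc_curve, youden_cutoff
from strokescale.scale import default_scale, score_patient

RESULTS = Path(__file__).resolve().parent.parent / "results"


def evaluate(name: str, cohort, scale, cutoff: float) -> dict:
    scores = [score_patient(scale, r).total for r in cohort.records]
    cm = confusion(scores, cohort.outcomes(), cutoff)
    sens, spec, acc = metrics(cm)
    print(f"{name} (n={len(cohort)}, cutoff {cutoff}): "
          f"TG={cm.tg} FP={cm.fp} FG={cm.fg} TP={cm.tp}  "
          f"sens {100 * sens:.1f} % spec {100 * spec:.1f} % acc {100 * acc:.1f} %")
    return {"cohort": name, "cutoff": cutoff, "n": len(cohort),
            "tg": cm.tg, "fp": cm.fp, "fg": cm.fg, "tp": cm.tp,
            "sensitivity": sens, "specificity": spec, "accuracy": acc}


def main() -> None:
    scale = default_scale()
    derivation = read_cohort(RESULTS / "cohort_derivation.csv")
    validation = read_cohort(RESULTS / "cohort_validation.csv")

    scores = [score_patient(scale, r).total for r in derivation.records]
    curve = roc_curve(scores, derivation.outcomes())
    opt = youden_cutoff(curve)
    print(f"derivation ROC: Youden-optimal cutoff {opt} "
          f"(published operating point: {scale.cutoff})")
    pd.DataFrame({
        "cutoff": curve.cutoffs, "sensitivity": curve.sens,
        "specificity": curve.spec, "youden": curve.youden,
    }).to_csv(RESULTS / "roc_table.csv", index=False)

    rows = [
        evaluate("derivation@published", derivation, scale, scale.cutoff),
        evaluate("derivation@youden", derivation, scale, opt),
        evaluate("validation@published", validation, scale, scale.cutoff),
    ]
    with open(RESULTS / "validation_metrics.json", "w") as fh:
        json.dump({"youden_optimal_cutoff": opt, "rows": rows}, fh, indent=2)
    print(f"ROC table -> {RESULTS / 'roc_table.csv'}")
    print(f"metrics -> {RESULTS / 'validation_metrics.json'}")


if __name__ == "__main__":
    main()
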