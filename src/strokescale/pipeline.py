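"""End-to-end scale development and the self-check harness.

``run_develop`` executes the construction procedure in its published order:

1. univariate screening of all candidate factors (prevalence filter, then
   chi-square / rank tests) at ``alpha``;
2. CART-style discretization of the continuous survivors (age and NIHSS
   change at depth 1, day-1 NIHSS at depth 2);
3. multivariable logistic regression with backward elimination at Wald
   ``p < alpha``;
4. item weighting — by default the published point assignments are used
   verbatim (the original coefficient-to-weight step is not algorithmically
   specified); an explicitly experimental proportional-weight heuristic is
   available behind ``use_published_weights=False``;
5. cutoff selection on the scored development cohort by maximum Youden index.

``run_end_to_end_check`` wires simulate -> develop -> score -> validate on
fresh synthetic cohorts and reports machine-readable invariant checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import CohortTable, Outcome
from .errors import FitError, PipelineError, ScreeningError
from .logistic import LogisticFit, select_factors
from .roc import RocCurve, confusion, metrics, roc_curve, youden_cutoff
from .scale import ScaleDefinition, ScaleItem, default_scale, score_patient
from .screening import ScreenResult, screen_candidates
from .simulate import default_params, generate_cohort
from .tree import Discretization, grow_thresholds

__all__ = ["RunConfig", "DevelopResult", "run_develop", "run_end_to_end_check"]

#: Continuous factors that are discretized before entering the model, with
#: the tree depth used for each (2- or 3-category targets).
_DISCRETIZE_DEPTH = {"age": 1, "nihss_d1": 2, "delta_nihss": 1}


@dataclass(frozen=True)
class RunConfig:
    """Knobs of the development pipeline; defaults follow the published settings."""

    alpha: float = 0.05
    prevalence_threshold: float = 0.05
    correlation_method: str = "spearman"
    continuous_method: str = "mann_whitney"
    selection_strategy: str = "backward"
    absent_pair_policy: str = "keep"
    use_published_weights: bool = True
    min_leaf: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "prevalence_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise PipelineError(f"{name} must be in (0, 1), got {v}")


@dataclass(frozen=True)
class DevelopResult:
    """Everything the development run produced, for reporting and audit."""

    scale: ScaleDefinition
    screen_results: list[ScreenResult]
    discretizations: dict[str, Discretization]
    fit: LogisticFit
    dropped: list[tuple[str, float]]
    cutoff: float
    roc: RocCurve

    def screen_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"factor": r.factor, "test": r.test, "statistic": r.statistic,
                 "p_value": r.p_value, "selected": r.selected}
                for r in self.screen_results
            ]
        )

    def coef_report(self) -> pd.DataFrame:
        return self.fit.coef_table()


def _experimental_weights(fit: LogisticFit, discretizations) -> list[ScaleItem]:
    """Proportional-weight heuristic (EXPERIMENTAL, not the published scheme).

    Each retained term gets weight round(2 * beta / min retained beta) / 2,
    and each category scores weight x level.  Provided only for sensitivity
    analyses of the weighting step.
    """
    betas = {t: b for t, b in zip(fit.terms, fit.beta) if t != "const"}
    min_beta = min(abs(b) for b in betas.values())
    items: list[ScaleItem] = []
    for term, b in betas.items():
        w = max(0.5, round(2 * abs(b) / min_beta) / 2)
        if term == "age":
            disc = discretizations["age"]
            items.append(ScaleItem(f"w_{term}", w, "age", thresholds=disc.thresholds,
                                   points=tuple(w * i for i in range(len(disc.thresholds) + 1))))
        elif term == "nihss_d1":
            disc = discretizations["nihss_d1"]
            items.append(ScaleItem(f"w_{term}", w, "nihss_day1", thresholds=disc.thresholds,
                                   points=tuple(w * i for i in range(len(disc.thresholds) + 1))))
        elif term == "delta_nihss":
            disc = discretizations["delta_nihss"]
            items.append(ScaleItem(f"w_{term}", w, "delta_nihss", thresholds=disc.thresholds,
                                   points=tuple(w * i for i in range(len(disc.thresholds) + 1))))
        elif term.startswith("hx_"):
            items.append(ScaleItem(f"w_{term}", w, "history", key=term[3:], points=(0, w)))
        elif term == "sex_male":
            continue  # no scale item for sex; never retained in practice
        elif term.startswith("sym_") and term.endswith("_d1"):
            items.append(ScaleItem(f"w_{term}", w, "symptom_day1", key=term[4:-3],
                                   points=(0, w)))
        elif term.startswith("chg_"):
            items.append(ScaleItem(f"w_{term}", w, "change", key=term[4:],
                                   points=(0, w, 2 * w)))
    return items


def run_develop(config: RunConfig, cohort: CohortTable) -> DevelopResult:
    """Run screen -> discretize -> select -> weight -> cutoff on a cohort."""
    try:
        screen = screen_candidates(
            cohort,
            alpha=config.alpha,
            prevalence_threshold=config.prevalence_threshold,
            continuous_method=config.continuous_method,
        )
    except ScreeningError as exc:
        raise PipelineError(f"screening stage failed: {exc}") from exc

    candidates = [r.factor for r in screen if r.selected]
    if not candidates:
        raise PipelineError(
            "empty model: no factor passed univariate screening; "
            "check that the cohort carries real outcome associations "
            "or relax alpha"
        )

    outcome01 = [1 if r.outcome is Outcome.POOR else 0 for r in cohort.records]
    discretizations: dict[str, Discretization] = {}
    for var, depth in _DISCRETIZE_DEPTH.items():
        if var not in candidates:
            continue
        values = {
            "age": [r.age for r in cohort.records],
            "nihss_d1": [r.nihss_day1 for r in cohort.records],
            "delta_nihss": [r.delta_nihss for r in cohort.records],
        }[var]
        disc = grow_thresholds(values, outcome01, max_depth=depth,
                               min_leaf=config.min_leaf, variable=var)
        if disc.thresholds:
            discretizations[var] = disc

    try:
        fit, dropped = select_factors(
            cohort, candidates, alpha=config.alpha,
            discretizations=discretizations,
            absent_pair_policy=config.absent_pair_policy,
            strategy=config.selection_strategy,
        )
    except FitError as exc:
        raise PipelineError(f"selection stage failed: {exc}") from exc

    if config.use_published_weights:
        items = default_scale().items
    else:
        items = tuple(_experimental_weights(fit, discretizations))
        if not items:
            raise PipelineError("weighting stage produced no items")

    # provisional cutoff placed mid-range; replaced by the Youden optimum below
    provisional = ScaleDefinition(items=items,
                                  cutoff=sum(max(i.points) for i in items) / 2)
    scores = [
        score_patient(provisional, r, config.absent_pair_policy).total
        for r in cohort.records
    ]
    curve = roc_curve(scores, cohort.outcomes())
    cutoff = youden_cutoff(curve)
    max_total = provisional.max_total
    if not 0 < cutoff < max_total:
        # Youden optimum at an extreme (sentinel) cutoff: clamp strictly inside
        cutoff = min(max(cutoff, 0.5), max_total - 0.5)
    scale = ScaleDefinition(items=items, cutoff=cutoff)
    return DevelopResult(
        scale=scale, screen_results=screen, discretizations=discretizations,
        fit=fit, dropped=dropped, cutoff=cutoff, roc=curve,
    )


def run_end_to_end_check(seed: int = 1) -> dict:
    """Simulate -> develop -> score -> validate; return a pass/fail report.

    Develops on one synthetic cohort (n = 2000) and validates the resulting
    scale on an independent held-out cohort (n = 1000) drawn with a distinct
    sub-seed.  Checks are structural invariants and sanity bands, not
    reproductions of any published figure.
    """
    checks: list[dict] = []

    def check(name: str, ok: bool, detail: str = "") -> None:
        checks.append({"name": name, "passed": bool(ok), "detail": detail})

    train = generate_cohort(default_params(n=2000, seed=seed))
    holdout = generate_cohort(default_params(n=1000, seed=seed + 1_000_003))
    config = RunConfig(seed=seed)
    result = run_develop(config, train)

    check("eight_items", len(result.scale.items) == 8,
          f"{len(result.scale.items)} items")
    check("max_total_16_5", abs(result.scale.max_total - 16.5) < 1e-9,
          f"max total {result.scale.max_total}")
    check("cutoff_in_range", 0 < result.cutoff < result.scale.max_total,
          f"cutoff {result.cutoff}")

    scores = [score_patient(result.scale, r).total for r in holdout.records]
    cm = confusion(scores, holdout.outcomes(), result.cutoff)
    sens, spec, acc = metrics(cm)
    check("holdout_sensitivity_band", 0.5 < sens < 1.0, f"sensitivity {sens:.3f}")
    check("holdout_specificity_band", 0.5 < spec < 1.0, f"specificity {spec:.3f}")
    check("accuracy_consistent",
          abs(acc - (cm.tg + cm.tp) / cm.n) < 1e-12, f"accuracy {acc:.3f}")

    totals = np.array([score_patient(result.scale, r).total for r in train.records])
    check("totals_in_scale_range",
          bool((totals >= 0).all() and (totals <= result.scale.max_total + 1e-9).all()))
    check("totals_half_point_grid",
          bool(np.allclose(totals * 2, np.rint(totals * 2))))

    return {
        "seed": seed,
        "passed": all(c["passed"] for c in checks),
        "checks": checks,
        "metrics": {"sensitivity": sens, "specificity": spec, "accuracy": acc,
                    "cutoff": result.cutoff,
                    "confusion": {"tg": cm.tg, "fp": cm.fp, "tp": cm.tp, "fg": cm.fg}},
    }
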