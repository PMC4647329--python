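"""Synthetic stroke-cohort generator with the study's tabulated structure.

No patient-level data accompany the published scale, so every pipeline stage
is exercised on cohorts drawn from a generative model whose marginals match
the published summary tables of the derivation cohort (413 patients from
three TCM hospitals):

* demographics and histories — age ~ Normal(66.4, 10.8) truncated to
  [25, 95] years; 61.5 % male; history prevalences hypertension 0.608,
  prior stroke 0.327, CHD 0.245, DM 0.199, AF 0.058;
* onset-to-admission delay ~ Normal(10.0, 7.17) hours truncated to [0, 24];
* day-1 NIHSS — a rounded lognormal matched to mean 6.3, SD 4.6, clipped to
  [0, 42]; the day-1 -> day-3 change is a rounded Normal(-0.5, 2.2), and
  day-3 NIHSS is day 1 plus the change clipped to [0, 42];
* symptom panel — each symptom has a day-1 prevalence (pooled good+poor
  counts where published) and a two-probability day-3 transition:
  P(resolve | present day 1) and P(appear | absent day 1);
* outcome — poor recovery ~ Bernoulli(logistic(a + sum(beta_j * code_j)))
  on the eight published ordinal category codes with the published
  coefficient vector (1.20, 0.79, 1.15, 1.12, 1.53, 0.91, 2.05, 2.58); the
  intercept ``a`` is calibrated by bisection so the expected poor fraction
  equals 181/413;
* Barthel Index at day 90 is back-filled consistently with the drawn label
  (poor -> a multiple of 5 in [0, 85], good -> in [90, 100]); it carries no
  information beyond the dichotomy and is explicitly synthetic.

Predictors are drawn independently of one another; only the outcome depends
on them.  See docs/methods.md for which features of real cohorts this does
and does not emulate.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .cohort import CohortTable, PatientRecord
from .errors import StrokeScaleError

__all__ = [
    "SymptomDynamics",
    "CohortParams",
    "default_params",
    "generate_cohort",
    "calibrate_intercept",
]


@dataclass(frozen=True)
class SymptomDynamics:
    """Day-1 prevalence and day-1 -> day-3 transition probabilities."""

    prev_day1: float
    p_resolve: float  # P(absent day 3 | present day 1)
    p_appear: float   # P(present day 3 | absent day 1)

    def __post_init__(self) -> None:
        for name in ("prev_day1", "p_resolve", "p_appear"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise StrokeScaleError(f"{name} must be a probability, got {v}")


#: Pooled day-1 prevalences computed from the published good/poor counts
#: (derivation cohort, n = 413), plus assumed values (marked) for symptoms
#: whose counts were not printed.
_SYMPTOMS: dict[str, SymptomDynamics] = {
    "spiritlessness": SymptomDynamics((107 + 105) / 413, 0.2, 0.02),
    "anxiety": SymptomDynamics((49 + 94) / 413, 0.2, 0.02),
    "cough_due_to_drinking": SymptomDynamics((48 + 69) / 413, 0.2, 0.02),
    "anorexia": SymptomDynamics((27 + 39) / 413, 0.2, 0.02),
    "salivation": SymptomDynamics((22 + 31) / 413, 0.2, 0.02),
    "analeptic": SymptomDynamics((17 + 27) / 413, 0.2, 0.02),
    "limb_flaccid_paralysis": SymptomDynamics((11 + 28) / 413, 0.2, 0.02),
    "thirst_hot_drink": SymptomDynamics((25 + 9) / 413, 0.2, 0.02),
    # change transitions for the three scale symptoms follow the published
    # pooled change counts: resolve = disappear / present-day-1,
    # appear = appear / absent-day-1
    "circumrotating": SymptomDynamics((25 + 8) / 413, 15 / 33, 4 / 380),
    "emaciation": SymptomDynamics((9 + 24) / 413, 0.2, 0.02),
    "stiffness_tension_limbs": SymptomDynamics((12 + 22) / 413, 0.2, 0.02),
    "tinnitus": SymptomDynamics((23 + 5) / 413, 12 / 28, 3 / 385),
    "irritability": SymptomDynamics((5 + 18) / 413, 14 / 23, 3 / 390),
    "incontinence_urinary": SymptomDynamics((10 + 19) / 413, 0.2, 0.02),
    # prevalences below are assumptions (no published counts), chosen as
    # plausible values above the 5 % screening floor
    "difficult_to_cough_sputum": SymptomDynamics(0.06, 8 / 25, 11 / 388),
    "dizziness": SymptomDynamics(0.30, 0.2, 0.02),
    "dry_mouth": SymptomDynamics(0.25, 0.2, 0.02),
    "frequent_micturition": SymptomDynamics(0.12, 0.2, 0.02),
    "purple_lips": SymptomDynamics(0.10, 0.2, 0.02),
    "respiratory_rude": SymptomDynamics(0.08, 0.2, 0.02),
}

#: Published coefficient vector of the eight-item outcome model, on the
#: ordinal category codes of the scale items.
DEFAULT_COEFFS: dict[str, float] = {
    "age_degree": 1.20,
    "history_dm": 0.79,
    "anxiety_day1": 1.15,
    "nihss_degree_day1": 1.12,
    "irritability_day1": 1.53,
    "delta_nihss_degree": 0.91,
    "circumrotating_change": 2.05,
    "tinnitus_change": 2.58,
}


@dataclass(frozen=True)
class CohortParams:
    """Full parameterization of the generative model."""

    n: int = 413
    seed: int = 0
    age_mean: float = 66.4
    age_sd: float = 10.8
    age_bounds: tuple[float, float] = (25.0, 95.0)
    male_prop: float = 0.615
    history_prev: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.608, "stroke": 0.327, "chd": 0.245,
            "dm": 0.199, "af": 0.058,
        }
    )
    onset_mean: float = 10.0
    onset_sd: float = 7.17
    symptoms: dict[str, SymptomDynamics] = field(default_factory=lambda: dict(_SYMPTOMS))
    nihss_mean: float = 6.3
    nihss_sd: float = 4.6
    delta_mean: float = -0.5
    delta_sd: float = 2.2
    outcome_coeffs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COEFFS))
    intercept: float | None = None     # None => calibrate to target_poor_prop
    target_poor_prop: float = 181 / 413
    age_threshold: float = 56.44
    nihss_thresholds: tuple[float, float] = (2, 6)
    delta_threshold: float = -1
    #: Gaussian-copula loading of severity-related predictors on one latent
    #: factor (age, day-1 NIHSS, NIHSS change, anxiety, irritability load
    #: positively; circumrotating and tinnitus negatively).  0 = the default
    #: independence assumption; nonzero values are for robustness testing.
    severity_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise StrokeScaleError("n must be positive")
        if not 0 < self.target_poor_prop < 1:
            raise StrokeScaleError("target_poor_prop must be in (0, 1)")
        for name, p in [("male_prop", self.male_prop), *self.history_prev.items()]:
            if not 0 <= p <= 1:
                raise StrokeScaleError(f"proportion {name} out of [0, 1]: {p}")

    def _calibration_key(self) -> tuple:
        return (
            tuple(sorted(self.outcome_coeffs.items())),
            round(self.target_poor_prop, 12),
            self.age_mean, self.age_sd, self.age_bounds, self.male_prop,
            tuple(sorted(self.history_prev.items())),
            tuple(sorted((k, v.prev_day1, v.p_resolve, v.p_appear)
                         for k, v in self.symptoms.items())),
            self.nihss_mean, self.nihss_sd, self.delta_mean, self.delta_sd,
            self.age_threshold, self.nihss_thresholds, self.delta_threshold,
            self.severity_rho,
        )


def default_params(n: int = 413, seed: int = 0) -> CohortParams:
    """Generator defaults matching the derivation cohort's published tables."""
    return CohortParams(n=n, seed=seed)


# -- low-level array simulation ------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


#: Copula loadings (sign only; magnitude comes from ``severity_rho``).
_SEVERITY_SIGNS = {
    "age": 1.0, "nihss1": 1.0, "delta": 1.0,
    "anxiety": 1.0, "irritability": 1.0,
    "circumrotating": -1.0, "tinnitus": -1.0,
}


def _simulate_covariates(params: CohortParams, rng: np.random.Generator) -> dict:
    """Draw all predictors and their ordinal codes as arrays.

    With ``severity_rho > 0`` the marginals are unchanged but the severity
    family shares a latent Gaussian factor through a Gaussian copula.
    """
    n = params.n
    rho = params.severity_rho
    z = rng.standard_normal(n)  # latent severity factor (unused when rho = 0)

    def coupled_u(name: str) -> np.ndarray:
        """Uniform(0,1) draws, copula-tied to the latent factor if loaded."""
        sign = _SEVERITY_SIGNS.get(name)
        if rho == 0.0 or sign is None:
            return rng.random(n)
        g = sign * rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        return stats.norm.cdf(g)

    lo, hi = params.age_bounds
    a_, b_ = (lo - params.age_mean) / params.age_sd, (hi - params.age_mean) / params.age_sd
    age = stats.truncnorm.ppf(coupled_u("age"), a_, b_,
                              loc=params.age_mean, scale=params.age_sd)
    male = rng.random(n) < params.male_prop
    history = {k: rng.random(n) < p for k, p in params.history_prev.items()}
    onset = _truncated_normal(rng, params.onset_mean, params.onset_sd, 0.0, 24.0, n)

    mu, sigma = _lognormal_params(params.nihss_mean, params.nihss_sd)
    nihss1 = np.clip(
        np.rint(stats.lognorm.ppf(coupled_u("nihss1"), sigma, scale=np.exp(mu))), 0, 42
    ).astype(int)
    delta = np.rint(
        params.delta_mean + params.delta_sd * stats.norm.ppf(coupled_u("delta"))
    ).astype(int)
    nihss3 = np.clip(nihss1 + delta, 0, 42).astype(int)
    delta = nihss3 - nihss1  # re-derive after clipping so codes stay coherent

    sym1: dict[str, np.ndarray] = {}
    sym3: dict[str, np.ndarray] = {}
    for s, dyn in params.symptoms.items():
        # presence iff u exceeds 1 - prevalence, so a positively loaded
        # symptom becomes MORE likely as the latent severity rises
        d1 = coupled_u(s) > 1.0 - dyn.prev_day1
        stays = rng.random(n) >= dyn.p_resolve
        appears = rng.random(n) < dyn.p_appear
        sym1[s] = d1
        sym3[s] = np.where(d1, stays, appears)

    t1, t2 = params.nihss_thresholds

    def change_code(s: str) -> np.ndarray:
        # disappear=0, keep=1, appear=2
        code = np.ones(n, dtype=int)
        code[sym1[s] & ~sym3[s]] = 0
        code[~sym1[s] & sym3[s]] = 2
        return code

    codes = {
        "age_degree": (age > params.age_threshold).astype(int),
        "history_dm": history["dm"].astype(int),
        "anxiety_day1": sym1["anxiety"].astype(int),
        "nihss_degree_day1": (nihss1 > t1).astype(int) + (nihss1 > t2).astype(int),
        "irritability_day1": sym1["irritability"].astype(int),
        "delta_nihss_degree": (delta > params.delta_threshold).astype(int),
        "circumrotating_change": change_code("circumrotating"),
        "tinnitus_change": change_code("tinnitus"),
    }
    return {
        "age": age, "male": male, "history": history, "onset": onset,
        "nihss1": nihss1, "nihss3": nihss3, "sym1": sym1, "sym3": sym3,
        "codes": codes,
    }


def _linear_predictor(codes: dict, coeffs: dict[str, float]) -> np.ndarray:
    missing = set(coeffs) - set(codes)
    if missing:
        raise StrokeScaleError(f"outcome coefficients reference unknown codes: {missing}")
    n = len(next(iter(codes.values())))
    eta = np.zeros(n)
    for k, b in coeffs.items():
        eta += b * codes[k]
    return eta


def calibrate_intercept(
    coeffs: dict[str, float],
    covariate_sampler,
    target_poor_prop: float,
    tol: float = 1e-4,
    sim_n: int = 200_000,
    sim_seed: int = 20_151_116,
) -> float:
    """Bisect the intercept until the expected poor fraction hits the target.

    ``covariate_sampler(rng, n)`` must return a code dict as produced by the
    generator.  The expected fraction ``mean(sigmoid(a + eta))`` is computed
    on one large fixed-seed draw of the covariates, so the result is
    deterministic and monotone in ``a``.
    """
    if not 0 < target_poor_prop < 1:
        raise StrokeScaleError("target_poor_prop must be in (0, 1)")
    rng = np.random.default_rng(sim_seed)
    codes = covariate_sampler(rng, sim_n)
    eta = _linear_predictor(codes, coeffs)

    def frac(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + eta)))))

    lo, hi = -30.0, 30.0
    for _ in range(4):
        if frac(lo) < target_poor_prop < frac(hi):
            break
        lo *= 2
        hi *= 2
    else:
        raise StrokeScaleError("could not bracket the intercept")
    while hi - lo > 1e-10:
        mid = (lo + hi) / 2
        if frac(mid) < target_poor_prop:
            lo = mid
        else:
            hi = mid
    a = (lo + hi) / 2
    if abs(frac(a) - target_poor_prop) > tol:
        raise StrokeScaleError("intercept calibration did not reach tolerance")
    return a


@functools.lru_cache(maxsize=32)
def _cached_intercept(key: tuple, coeffs_items: tuple, target: float) -> float:
    # reconstruct enough of the params to sample covariates
    params = _params_from_key.get(key)
    if params is None:  # pragma: no cover - cache misuse guard
        raise StrokeScaleError("internal calibration cache miss")

    def sampler(rng, n):
        return _simulate_covariates(replace(params, n=n), rng)["codes"]

    return calibrate_intercept(dict(coeffs_items), sampler, target)


_params_from_key: dict[tuple, CohortParams] = {}


def _resolve_intercept(params: CohortParams) -> float:
    if params.intercept is not None:
        return params.intercept
    key = params._calibration_key()
    _params_from_key.setdefault(key, params)
    return _cached_intercept(key, tuple(sorted(params.outcome_coeffs.items())),
                             params.target_poor_prop)


def generate_cohort(params: CohortParams) -> CohortTable:
    """Draw a reproducible synthetic cohort under ``params``.

    The same params (including ``seed``) always produce the identical
    cohort.  Records pass full domain validation; the panel is the key order
    of ``params.symptoms``.
    """
    rng = np.random.default_rng(params.seed)
    cov = _simulate_covariates(params, rng)
    a = _resolve_intercept(params)
    eta = a + _linear_predictor(cov["codes"], params.outcome_coeffs)
    poor = rng.random(params.n) < 1.0 / (1.0 + np.exp(-eta))

    # BI back-fill: synthetic, consistent with the drawn dichotomy only
    bi_poor = rng.integers(0, 18, params.n) * 5          # {0, 5, ..., 85}
    bi_good = 90 + rng.integers(0, 3, params.n) * 5      # {90, 95, 100}
    bi = np.where(poor, bi_poor, bi_good)

    panel = tuple(params.symptoms.keys())
    width = len(str(params.n))
    records = []
    sym1, sym3 = cov["sym1"], cov["sym3"]
    for i in range(params.n):
        records.append(
            PatientRecord(
                id=f"S{params.seed}-{i:0{width}d}",
                age=round(float(cov["age"][i]), 1),
                sex="male" if cov["male"][i] else "female",
                history={k: bool(v[i]) for k, v in cov["history"].items()},
                onset_to_admission=round(float(cov["onset"][i]), 1),
                nihss_day1=int(cov["nihss1"][i]),
                nihss_day3=int(cov["nihss3"][i]),
                symptoms_day1={s: bool(sym1[s][i]) for s in panel},
                symptoms_day3={s: bool(sym3[s][i]) for s in panel},
                bi_day90=int(bi[i]),
            )
        )
    return CohortTable(records=tuple(records), panel=panel)
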