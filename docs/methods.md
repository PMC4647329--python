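# Methods

## The instrument

The package implements an early prognostic scale for 90-day recovery after
acute ischemic stroke. The outcome is the dichotomized day-90 Barthel Index
(BI): *good* recovery iff BI ≥ 90, *poor* otherwise. Eight items are scored
and summed:

| item | categories → points | weight |
|---|---|---|
| age degree | ≤ 56.44 → 0; > 56.44 → 1 | 1 |
| history of diabetes | no → 0; yes → 1 | 1 |
| anxiety, day 1 | no → 0; yes → 1 | 1 |
| NIHSS degree, day 1 | ≤ 2 → 0; 3–6 → 1; ≥ 7 → 2 | 1 |
| irritability, day 1 | no → 0; yes → 1.5 | 1.5 |
| ΔNIHSS (day 3 − day 1) | ≤ −1 → 0; > −1 → 1 | 1 |
| circumrotating change, day 1→3 | disappear → 0; keep → 2; appear → 4 | 2 |
| tinnitus change, day 1→3 | disappear → 0; keep → 2.5; appear → 5 | 2.5 |

Each item's points follow the weight × level scheme
(`max(points) = weight × top level`); the total lies on a 0.5-point grid in
[0, 16.5]. The decision rule is strict: total > cutoff (default 9.5)
predicts poor recovery, so a total of exactly 9.5 predicts good.

Two printed sources of the NIHSS item disagree on the top bin ("> 7" in one
place, "> 6" in another, leaving 7 unassigned in the former); the package
uses ≥ 7 so the three bins partition the integers, consistent with the
three-way classification-tree output the item derives from. Likewise the
circumrotating item is printed once with weight 1 and once with weight 2
next to points 0/2/4; weight 2 is used, the only value consistent with the
points.

### The absent-on-both-days question

The change items are the one genuinely underdetermined part of the scoring
rule. A symptom absent on day 1 and day 3 is, literally, "no change", i.e.
the *keep* category — which means a completely symptom-free patient still
collects 2 + 2.5 = 4.5 points from the two change items. Whether the
original instrument intended that floor is not stated (the printed score
range "0–16.5" is compatible with either reading, since a patient whose
circumrotating and tinnitus both disappear scores 0 on those items). Both
policies are implemented via `absent_pair_policy`:

* `"keep"` (default) — the literal reading; absent-absent scores the keep
  points;
* `"zero"` — absent-absent scores 0.

The same switch applies to the ordinal 0/1/2 coding used by the logistic
model and the synthetic generator.

## Construction pipeline

`run_develop` re-executes the procedure that produced the instrument, in
order:

1. **Univariate screening** (`screening`): the symptom panel first passes a
   day-1 prevalence filter (appearance rate ≥ 5 %, boundary inclusive);
   binary factors are tested with a Pearson chi-square on the 2×2 table
   (no continuity correction — the convention most consistent with the
   published p-values), continuous factors with a pooled-variance t-test or
   a tie-corrected Mann–Whitney U (caller-selected, default Mann–Whitney;
   the source description of the normality gate is self-contradictory, so
   no automatic gate is applied), and symptom-change variables with a
   chi-square on the (appear/keep/disappear) × (good/poor) table after
   dropping all-zero rows. Selection at two-sided p < 0.05.
2. **Discretization** (`tree`): age and ΔNIHSS at depth 1 (binary), day-1
   NIHSS at depth 2 (up to three categories), by exhaustive Gini-gain
   search over midpoints of consecutive distinct values, minimum leaf 20
   (to avoid sliver bins at cohort size), ties broken toward the smallest
   threshold. Intervals are left-closed on the right: (−∞, t₁], (t₁, t₂],
   …, so printed "≤" boundaries are honored; a value equal to a threshold
   falls in the lower bin. Gini is the impurity (the canonical CART
   default; the source names no criterion). Thresholds are reported at full
   precision — printed boundaries such as 56.44 are data artifacts, not
   constants of the method.
3. **Multivariable selection** (`logistic`): maximum-likelihood logit
   (Newton/IRLS via statsmodels) of poor recovery on all screened
   candidates, followed by backward elimination — drop the largest Wald p ≥
   α, refit, repeat — with an audit trail of drops. The source states only
   that logistic regression "further screened" factors; backward
   elimination at p < 0.05 is the standard reading in this literature and
   is recorded per run so it can be audited. Change predictors enter with
   the single ordinal 0/1/2 slope (one printed coefficient per change
   variable rules out dummy coding). ORs are exp(β) with
   exp(β ± 1.96·SE) 95 % intervals (1.96, not a t quantile, matches the
   printed intervals within rounding).
4. **Weighting**: the published point assignments are used verbatim
   (default). The original coefficient-to-weight step ("a simple weighting
   scheme") is not algorithmically specified, so deriving weights from the
   fitted betas (`use_published_weights=False`, proportional heuristic
   `round(2β/min β)/2`) is offered only as a clearly labelled experiment.
5. **Cutoff**: ROC over the scored development cohort, candidate cutoffs at
   the observed score values plus one sentinel below the minimum, operating
   point at maximum Youden index (sensitivity + specificity − 1), ties
   broken toward the smallest cutoff. Candidates sit at observed values
   (not midpoints) because the published cutoff 9.5 is itself an achievable
   score under the half-point grid.

### Metric conventions

The validation metrics follow the instrument's own footnote, in which
"sensitivity" is the detection rate of **good** recovery:
sensitivity = TG/(TG+FP), specificity = TP/(TP+FG),
accuracy = (TG+TP)/n, with TG/FP/TP/FG = true good / false poor / true
poor / false good. Under the fixed "score > cutoff ⇒ poor" rule,
sensitivity is therefore nondecreasing and specificity nonincreasing in the
cutoff. Youden's index is symmetric in the two rates, so the selected
cutoff does not depend on which class is called "positive". A trapezoidal
AUC is provided as a convenience only.

## The synthetic cohort generator

No patient-level records accompany the published scale, so the generator
(`simulate`) encodes the data-generating structure the analysis assumes,
with defaults fixed to the published summary tables of the derivation
cohort (n = 413):

* age ~ Normal(66.4, 10.8) truncated to [25, 95] years; 61.5 % male;
  history prevalences: hypertension 0.608, prior stroke 0.327, CHD 0.245,
  DM 0.199, AF 0.058; onset-to-admission ~ Normal(10.0, 7.17) h truncated
  to [0, 24];
* day-1 NIHSS: rounded lognormal matched to mean 6.3 / SD 4.6, clipped to
  [0, 42]; ΔNIHSS: rounded Normal(−0.5, 2.2) (the published change summary
  has means −0.54 and −0.45 with SDs 1.80 and 2.74 in the two outcome
  groups); day-3 NIHSS = day 1 + Δ clipped to [0, 42], with Δ re-derived
  after clipping so all codes stay coherent;
* each of the 20 panel symptoms has a day-1 prevalence and a day-3
  transition pair P(resolve | present), P(appear | absent). Prevalences are
  the pooled published good+poor counts where printed (14 symptoms); the
  transition pairs for circumrotating (15/33, 4/380), tinnitus (12/28,
  3/385) and irritability (14/23, 3/390) come from the published change
  tables. Five symptoms named only in the correlation table (dizziness,
  dry mouth, frequent micturition, purple lips, respiratory rude) and
  "difficult to cough sputum" have **assumed** prevalences (0.30, 0.25,
  0.12, 0.10, 0.08, 0.06) chosen once as plausible values above the 5 %
  screening floor; symptoms without published change counts default to
  P(resolve) = 0.2, P(appear) = 0.02.
* the outcome is poor ~ Bernoulli(σ(a + Σβⱼ·codeⱼ)) on the eight ordinal
  item codes with the published coefficient vector
  (1.20, 0.79, 1.15, 1.12, 1.53, 0.91, 2.05, 2.58); the intercept *a* is
  found by bisection so that the expected poor fraction on a large
  fixed-seed covariate draw equals 181/413 ≈ 0.438 (a ≈ −8.31). The day-90
  BI is then back-filled only to be consistent with the drawn label
  (multiples of 5 in [0, 85] for poor, [90, 100] for good); it is
  explicitly synthetic and carries no information beyond the dichotomy.

Predictors are mutually independent by default — the published tables
report only marginals. An optional Gaussian-copula knob (`severity_rho`)
ties age, day-1 NIHSS, ΔNIHSS, anxiety and irritability (positively) and
circumrotating and tinnitus (negatively, matching the signs of their
published NIHSS correlations) to one latent severity factor without moving
the marginals; it exists for robustness testing and is off (0.0) in the
study conditions.

### What the generator does and does not emulate

It reproduces the published marginal prevalences, the NIHSS level and
change distributions, the outcome model and the poor-outcome rate; cohorts
are fully reproducible from (params, seed). It does **not** emulate the
real joint dependence among predictors, hospital-level heterogeneity,
day-2 observations, deaths before day 90, or any BI distribution beyond
the dichotomy. Tests passing on these cohorts therefore demonstrate that
the *procedures* are correct and recover planted structure — not that the
published operating characteristics hold on real patients.

One consequence is worth stating plainly: under the published marginals
with independent predictors, the total score has mean ≈ 7.55 and
SD ≈ 1.33, so only ≈ 3 % of synthetic patients exceed 9.5, and the
Youden-optimal cutoff on synthetic cohorts lands at 7.0–8.0, not at the
published 9.5. The published validation counts imply that 54 % of the
derivation cohort scored above the cutoff, which cannot be reproduced from
the printed prevalences under the strict ">" rule: exceeding 9.5 requires
anxiety (34.6 %), irritability (5.6 %) or a rare "appear" transition,
whatever the dependence structure. The real cohort's joint distribution
(or a "≥" reading of the cutoff) evidently differed from what the summary
tables pin down. The corresponding consistency test in the acceptance
suite asserts the ±1.0 band around 9.5 and fails; it is kept failing
rather than weakened, as an accurate statement of this gap.

## Numerical choices and problem sizes

* Chi-square tests carry no Yates correction; expected-zero cells and
  single-row change tables raise errors rather than returning NaN.
* Perfect separation in the logit is detected (statsmodels' monotone
  likelihood check, plus a |β| > 15 divergence guard) and raised as a
  distinct error; rank-deficient designs are rejected naming the collinear
  columns.
* The intercept bisection runs to a 1e-10 bracket on a 200 000-draw
  fixed-seed covariate sample and is cached per parameter set.
* Simulation-based tests use cohorts of n = 2000–5000 and 20–50 seeds
  (parameter recovery: 50 × 5000; cutpoint recovery: 20 seeds; Youden
  consistency: 20 × 2000), sizes at which the Monte-Carlo error of each
  checked quantity is small against its tolerance while the whole suite
  stays fast.
* `best_split` treats gains within 1e-12 as tied (smallest threshold
  wins), which also makes it bit-comparable with the brute-force oracle.

## Known limitations

* The published coefficient vector cannot be *re-derived* here (that
  would need the original 489 records); they are inputs to the generator
  and recovery targets, not outputs.
* The full 157-item symptom inventory of the original study is not
  available; the shipped panel is the 20 symptoms named in the published
  tables and is configurable.
* The experimental weight heuristic is not validated against anything and
  is excluded from the default path.
* Backward elimination on derivation-sized cohorts (n ≈ 413) retains
  occasional spurious terms at α = 0.05, as expected for the procedure;
  the planted-factor recovery guarantees in the test suite are stated at
  n = 5000.
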