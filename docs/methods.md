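# Methods

## Scoring model

The AdHOC score counts positive prognostic aspects. An aspect is a group
of dichotomized clinical parameters evaluable in the trauma bay within
about 30 minutes; it is *positive* if any one observed, applicable
parameter crosses its threshold, *negative* if at least one applicable
parameter is observed and none crosses, and *indeterminate* if no
applicable parameter is observed. The total is the number of positive
aspects (0–4) and maps to risk classes 0–1 stable / 2 borderline / 3–4
unstable.

Boundary semantics follow the printed comparators literally: age > 65
(66 triggers, 65 does not), GCS < 12, base excess ≤ −6 mmol/L, Horowitz
ratio ≤ 200 (applicable only while intubated), SBP ≤ 90 mmHg, INR > 1.4
(1.4 itself does not trigger), Hb < 7 (7 does not trigger). Hemoglobin's
unit and threshold travel together in `AdhocConfig` (default g/dL with
threshold 7, the standard severe-anemia cutoff; a g/L registry configures
70) because registry exports disagree on the unit.

**Missing data.** An indeterminate aspect contributes 0 points and clears
the result's `complete` flag. Counting it as zero is the only reading
under which missingness can underestimate but never overestimate severity
(score monotone in observedness — a tested invariant); the flag preserves
the stricter reading ("incomplete totals are not comparable") for
downstream consumers who want it.

**Eppendorf–Cologne Scale.** The ECS total is the sum of motor, pupil-size
and pupil-reactivity subscores, maximum 8, with a fully normal exam at 0.
The per-category point values of the original multi-level scale are not
needed by the AdHOC head aspect (which uses only the dichotomized
categories), so the bundled `EcsMapping` is a synthetic assignment — motor
0/2/3, pupil size 0/2, pupil reactivity 0/3 — chosen only to satisfy the
structural constraints (normal = 0 per subscale, maxima summing to 8).
Sites using the original scale should supply their own mapping.

## Score-definition engine

`adhocscore.comparators` expresses point scores declaratively as ordered
items: numeric parameters binned into disjoint, contiguous intervals with
explicit bound closure, or any-of indicator groups generalizing the AdHOC
aspect rule. The hand-coded AdHOC scorer and the engine applied to the
bundled `adhoc.yaml` are deliberately independent code paths and are tested
for equality on randomized records. `score_range` has an analytic mode
(items are additive and independent, so per-item extremes suffice) and a
brute-force mode that enumerates one representative synthetic record per
bin/predicate-state combination through the full engine; the two modes are
cross-checked on every bundled definition, and the bundled GAP and mREMS
tables (transcribed from their original publications) are validated
against their published ranges 3–24 and 0–26.

ISS and NISS square the three highest AIS severities (per distinct body
region for ISS, regardless of region for NISS), cap at 75, and by default
apply the standard AIS-6 → 75 convention to both; a flag disables it.

## Simulator

The generator emulates the *marginal* structure of the reference cohort,
not its full joint distribution:

* **Age** — truncated normal, location 49.9 y, scale 21.4, bounds
  [16, 100], floored to whole years. The location/scale are the normal's
  parameters before truncation; because truncation removes more left than
  right tail, the realized mean is ≈ 51.4 y.
* **Binary risk parameters** — each indicator is the event that a latent
  standard normal exceeds the quantile matching its configured prevalence
  (GCS < 12: 0.241; SBP ≤ 90: 0.155; INR > 1.4: 0.156; Hb < 7: 0.038;
  hemothorax: 0.100; BE ≤ −6: 0.223; PaO₂/FiO₂ ≤ 200 among intubated:
  0.525; male 0.665; blunt 0.975). The latent variable mixes a single
  shared "severity" factor with idiosyncratic noise (loading per parameter,
  default 0.3 for clinical indicators, 0 for demographics); marginals are
  exact by construction at any loading, while pairwise association rises
  with the loadings. With nonzero loadings the Horowitz indicator's
  prevalence *conditional on intubation* drifts slightly above its
  configured value (both indicators load on the factor); the zero-loading
  configuration reproduces it exactly.
* **Unpublished prevalences** — intubation (0.40) and pRBC transfusion
  (0.15) are not reported for the reference cohort and are modeling
  choices; the three ECS abnormality rates (0.12 each) were chosen to give
  an ECS total of plausible registry magnitude (mean ≈ 1). All are
  configurable.
* **Continuous values** — drawn uniformly from a sub- or supra-threshold
  interval conditional on the parameter's own indicator (e.g. SBP from
  [50, 90] when the shock indicator is set, [92, 160] otherwise), so
  values and indicators can never disagree. Interval defaults are
  clinically plausible trauma-bay ranges and are configuration.
* **Fractures** — every simulated patient has at least one major fracture
  (the cohort is defined by them): the joint pelvis/femur/tibia pattern is
  drawn from the independent-flags distribution conditioned on "at least
  one", with marginals 0.49 / 0.43 / 0.34.
* **Outcomes** — two modes. *aspect_logistic* (default for mortality):
  death is Bernoulli with logit = intercept + Σ log-OR × aspect indicator,
  default ORs 4.9 / 5.1 / 2.6 / 4.1; the intercept, unless given, is
  calibrated by bisection on a fixed companion-seed cohort of 100 000
  aspect draws to hit the target overall mortality (default 11.9%) within
  0.1 percentage points. *score_table*: death probability looked up by the
  true score, defaults 0.3 / 5.3 / 15.6 / 42.5 / 62.6%, constrained
  monotone unless the flag is cleared. MOF uses the same machinery
  (default: score table 5.5 / 18.9 / 37.7 / 62.4 / 76.3%). Death and MOF
  are conditionally independent given the aspects — their empirical
  association arises only through shared risk factors, since no joint
  model is available to calibrate against. Lengths of stay are lognormal
  with score-indexed means (ICU 4.1 / 7.2 / 13.2 / 14.3 / 12.1 d; hospital
  21.2 / 24.8 / 29.6 / 25.6 / 18.1 d) and common σ = 0.8.
* **Randomness** — every variable owns a named substream derived from the
  root seed and consumed in record order, so growing `n` extends the
  cohort without reshuffling earlier records and identical (config, seed)
  is byte-reproducible.

What passing tests on this simulator do **not** show: behaviour under the
real registry's joint correlation structure (only one shared factor is
modeled), realistic measurement error (values are exactly consistent with
their indicators), informative missingness (missingness is independent of
severity), or the real per-score outcome rates, which require the
non-public registry.

## Evaluation statistics

AUROC is the Mann–Whitney statistic computed from midranks — the natural
convention for an integer score where ties dominate. Confidence intervals:
DeLong's structural-components variance with a normal-approximation
interval truncated to [0, 1] (default: deterministic and fast), or a
class-stratified percentile bootstrap (default 2000 resamples, seeded) for
small strata. Odds ratios come either from a 2×2 table (Woolf log-SE
interval; Haldane–Anscombe 0.5-correction on any zero cell, flagged in the
method label; undefined when a diagonal is all zero) or from multivariable
logistic regression (maximum likelihood via iteratively reweighted least
squares, Wald intervals from the inverse observed information; a
coefficient beyond |15| is treated as separation and raises). Stratified
outcome tables report empty strata with n = 0 and NaN rates rather than
fabricating a 0% rate. No multiple-testing adjustment is applied anywhere.

## Numerical and design choices

* The cohort inclusion filter (age ≥ 16, ISS ≥ 9, major fracture present,
  no secondary admission, no transfer out < 48 h) reports the *first*
  failing check in that fixed order; a record whose ISS is unobtainable is
  excluded with its own reason, and unknown age counts as failing the age
  check since adulthood cannot be confirmed.
* CSV parsing is lenient by default (bad rows skipped and reported),
  strict on request; empty cells and a configurable token (default "NA")
  both mean absent; categoricals are normalized case-insensitively.
* Bisection for the intercept runs on [−15, 5]; targets outside the
  attainable mortality range (notably 0) raise rather than clamp.
* Logistic fitting is delegated to statsmodels' IRLS (GLM/Binomial,
  tolerance 1e-8, 100 iterations); closed-form cases (intercept-only,
  single binary covariate) are verified against the sample log-odds and
  the 2×2 log-OR to 1e-6.
* Problem sizes in the test and acceptance runs — 100 000 records for
  odds-ratio recovery and calibration, 50 000 for distributional checks,
  500 × n ≤ 200 instances for the AUROC oracle, 1000 records for
  engine/hand-coded equivalence — are chosen so each check's sampling
  error is small against its tolerance (3 binomial SEs per stratum; 10%
  relative error on ORs; ±0.5 pp on calibrated mortality).

## Known limitations

The simulator's dependence structure is exchangeable through one factor
and cannot express negative association; AIS item lists are not simulated
(fracture flags are set directly), so simulated cohorts carry no ISS and
the inclusion filter is exercised on hand-built and randomized records
instead; the bundled mREMS point table can be validated against its
published range only, as the original bin table is not reproduced in the
sources this package models; real-data discrimination (development AUROC
0.858 / validation 0.877 for AdHOC) is not reproducible without the
registry and is not claimed by any test here.
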