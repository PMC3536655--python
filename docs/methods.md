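# Methods

## The dose–response model

The package models the probability of grade-3+ xerostomia as a probit
function of the equivalent uniform dose (EUD) to a parotid gland
(the Lyman–Kutcher–Burman model):

    NTCP(EUD) = Φ((EUD − TD50) / (m · TD50)),
    EUD       = ( Σᵢ vᵢ Dᵢ^(1/n) )ⁿ .

`TD50` (Gy) is the dose giving a 50% complication probability; `m`
(dimensionless) sets the relative slope — the response rises from ~2.3%
to ~97.7% over TD50·(1 ± 2m); `n` is the volume exponent of the
generalized-mean DVH reduction.  The parotid is treated as a parallel
organ: `n` is fixed at 1 by default, making the EUD the mean gland dose.
A free-`n` fit is available but flagged experimental — when the analysis
units are scalar mean doses rather than full DVHs, `n` is not
identifiable and only the fixed-`n` path is meaningful.

Φ is evaluated with the erf-based normal CDF (`scipy.special.ndtr`,
|error| < 1e-15) rather than literal quadrature; a quadrature oracle in
the test suite confirms agreement to 1e-8 over t ∈ [−6, 6].  The slope is
bounded below at m = 1e-4 everywhere to keep the curve from degenerating
into a numerical step.  A "simplified" variant of the model that replaces
the probit integral with an exponential of a quadratic in dose exists in
the literature; it is deliberately not implemented — the exact probit is
strictly better behaved and the approximation adds nothing here.

## DVH handling

DVHs are stored internally in differential form: point masses
(dose, volume fraction) with strictly increasing doses and fractions
summing to 1 (tolerance 1e-9).  Cumulative input (volume receiving
≥ dose, starting at 1, non-increasing) is converted by successive
differences, assigning each volume drop to the **higher** dose of the
pair (right-edge convention) and leaving any residual plateau volume at
the last dose.  This is conservative for serial-effect metrics and makes
tests bit-stable.  The differential→cumulative export prepends a
(0 Gy, 1.0) point so the round trip is exact whenever the first bin dose
is positive.  Bin doses are treated as point masses with no within-bin
interpolation: at the 0.01-Gy bin widths typical of planning-system
exports the induced error is negligible.  Volume columns that arrive as
percentages (values > 1.5 summing/starting at ≈100) are divided by 100
with a logged warning.

## Endpoints

Scintigraphy: the salivary excretion factor (SEF) is measured per gland
before and after treatment; the endpoint variable is the follow-up/baseline
flow ratio.  LENT-SOMA bands grade the loss (grade 4: ratio ≤ 0.25,
grade 3: ≤ 0.50, grade 2: ≤ 0.75, grade 1: ≤ 0.95, grade 0 above);
boundary ratios go to the more severe grade, one consistent rule read off
the printed integer-percent bands.  The primary binary event is flow
ratio ≤ 0.45 — reported in the source literature as equivalent to
grade 3+, although the grade-3 band extends to 0.50.  Both predicates are
exposed; they are intentionally not reconciled, and the 45% rule is the
default event definition.

Patient-reported xerostomia: a single 1–4 ordinal item (not at all /
a little / quite a bit / very much) binarized at ≥ 3
(moderate-to-severe).  The exact item-to-event mapping used in the source
study is not published; ≥ 3 is the conventional reading and the cut
level is a function argument.

## Analysis units

The SEF endpoint is analyzed per gland (each patient contributes two
(mean dose, event) pairs); the QoL endpoint per patient at the
spared-gland dose (the lower of the two gland doses), since a
questionnaire score cannot be attributed to one gland.  Both unit
schemes are selectable for either endpoint because the published
analysis is ambiguous about which gland set entered the SEF fit.

## Estimation

Parameters are estimated by Bernoulli maximum likelihood on the
individual (dose, event) units — never on binned proportions, which are
display-only.  The negative log-likelihood is minimized over
(log TD50, log m) with L-BFGS-B inside box bounds TD50 ∈ [5, 100] Gy,
m ∈ [0.01, 1] (rescale the TD50 box when doses are not in Gy), starting
from a fixed 3×3 grid at the 15/50/85% quantiles of the log-scale box so
the fit is deterministic; the best start is kept.  Predicted
probabilities are clamped to [1e-12, 1 − 1e-12] so separated data stay
finite.  Perfect separation (every event dose above every non-event
dose, or m on its lower bound) yields a boundary estimate and a runtime
warning, not a silent result.  Cohorts with a single outcome class or a
single dose level raise a non-identifiability error.

Confidence intervals are profile-likelihood intervals: the values where
the profiled log-likelihood (nuisance parameter re-maximized by bounded
scalar search) drops by χ²₁(level)/2 — 1.921 at 95% — found by bisection
on the log scale to 1e-4 relative tolerance.  If the profile never
crosses the threshold before the box edge the interval is reported open
at that edge with a warning.  Profile intervals were chosen over Wald
because they respect the positivity constraints and behave better at the
small event counts typical of toxicity cohorts; simulation tests verify
93–97% coverage at n = 500.

## Performance metrics

* **Nagelkerke R²** — Cox–Snell R² normalized by its maximum,
  `[1 − exp(2(ll₀ − ll)/n)] / [1 − exp(2·ll₀/n)]`.
* **AUC** — Mann–Whitney concordance with ties counted 0.5
  (`sklearn.metrics.roc_auc_score`; an exhaustive pairwise oracle checks
  it exactly in tests).
* **Hosmer–Lemeshow** — observations sorted by predicted risk into 10
  near-equal groups (group count configurable; the source analyses never
  state theirs, so the conventional deciles are the default), tied
  predictions kept together in the lower bin, χ² = Σ (O−E)²/E over event
  and non-event cells, df = groups − 2, bins with a zero expected count
  merged into a neighbour with a warning.  The df = g − 2 reference
  assumes the predictions were fitted in-sample; the calibration-null
  test therefore refits a model per replicate.
* **Pearson χ²** — two forms: the per-observation goodness-of-fit
  statistic Σ(y − p)²/(p(1−p)) with df = n − #params for a fitted model,
  and the uncorrected 2×2 association test (no Yates correction; the
  uncorrected statistic is the declared convention) used to compare the
  SEF and QoL endpoints on shared patients (spared-gland SEF event vs
  QoL event).
* **Spearman** — `scipy.stats.spearmanr` (average ranks, t-approximation
  p-value), for the dose vs flow-recovery association.

## QUANTEC validation

A treatment plan meets the guideline iff min gland dose ≤ 20 Gy or both
gland doses ≤ 25 Gy ("at the cutoff" counts as meeting it).  Cutoff
classification predicts xerostomia iff dose > cutoff; per-gland doses
are used for per-gland analyses and the spared-gland dose for
per-patient analyses.  PPV and NPV are computed from the
(sensitivity, specificity, prevalence) formulas, which agree exactly
with the confusion-count ratios tp/(tp+fp) and tn/(tn+fn) whenever both
are defined; undefined values (no predicted positives or negatives at a
cutoff) are reported as NaN, never silently as 0 or 100.  The default
cutoff panel is {20, 25, 43.6, 44.1} Gy: the two guideline doses plus
the SEF- and QoL-fitted TD50s.

## Synthetic cohorts

The generator emulates the structure of a 31-patient parotid-sparing
IMRT cohort: per patient, an ipsilateral and contralateral gland with
mean doses from truncated normals — ipsilateral mean 51.7 Gy on
[26.9, 74.8], contralateral 36.7 Gy on [7.6, 57.6], sd defaulting to
range/4 since only means and ranges are reported — and baseline SEF from
Normal(48.1, 18.2) truncated to [19.2, 72.8] (the reported sd).
Truncation pulls the realized means slightly toward the interval centre;
the deviation is under ~1 Gy and is accepted rather than re-solving for
the pre-truncation location.  Ipsi/contra doses are independent by
default (their within-patient correlation is unreported); a
Gaussian-copula correlation parameter is available.

Per-gland events are Bernoulli draws from the SEF dose–response at the
gland's own mean dose; the follow-up SEF is then drawn conditionally —
ratio uniform on (0, 0.45] given an event, on (0.45, 1.1] otherwise — so
the flow-ratio endpoint reproduces the event flag exactly.  This keeps
the generator minimal and self-consistent: the binary endpoint is all
the model consumes, so no continuous dose–flow model is imposed.
Patient-level QoL events are Bernoulli draws from the QoL-fitted curve
(TD50 = 44.1 Gy, m = 0.11 by default) at the spared-gland dose, mapped to
a 1–4 item score (3–4 for events, 1–2 otherwise), so the two-endpoint
comparison path is exercised with realistic concordance.

One caveat follows from the published analysis itself: the printed
(TD50 = 43.6, m = 0.18) describe the response as a function of the
*spared-gland* dose, where the mean dose (≈ 36.7 Gy) sits well below
TD50 and implies the observed ~16% event rate.  Applying the same curve
per gland — as the generator does, because only per-gland generation
lets per-gland fitting recover the parameters — puts the ipsilateral
glands (mean 51.7 Gy) above TD50, so the default synthetic per-gland
prevalence is ≈ 50%, higher than the observed per-gland rate.  The
generator is therefore a parameter-recovery and pipeline-exercise
harness, not a faithful replica of the study's joint dose–outcome
distribution; tests assert self-consistency of the prevalence with the
generative curve, and separately that the spared-dose-evaluated rate
lies near the observed proportion.  Passing tests show the estimator and
metrics behave correctly under the stated generative model — they cannot
show how the model fits any real cohort.

Simulated DVHs draw positive normal bin doses around a target mean with
a chosen spread, Dirichlet volume weights, and a final dose rescaling so
the mean dose hits the target to 1e-6 (zero spread collapses to one
bin).

## Problem sizes

Simulation-based tests use 200 cohorts of 500 glands for median-bias
checks, 300 cohorts for profile-CI coverage, 500 replicates of 100
observations for the calibration null, and 1000 random DVHs for the
EUD/mean-dose identity — sizes at which the checked tolerances (±0.5 Gy
and ±0.01 median bias, 93–97% coverage, KS < 0.1) are comfortably
resolved.

## Known limitations

* Only one follow-up time point is modelled; longitudinal recovery and
  attrition are out of scope (missing follow-up is represented as an
  absent measurement and excluded from fitting with a logged count).
* No alternative NTCP forms (logistic, log-logistic, relative
  seriality) and no Bayesian or bootstrap uncertainty.
* DICOM-RT parsing and DVH computation from dose grids are out of
  scope; DVHs enter as delimited text.
* The per-observation Pearson χ² reference distribution is approximate
  for sparse binary data, as is the Hosmer–Lemeshow χ² at small
  per-group expected counts.
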