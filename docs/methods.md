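# Methods

This note documents the models, numerical choices and defaults behind
`bmdtox`, and what the synthetic-data studies in the test suite do and do
not demonstrate.

## Quantal dose-response models

Nine dichotomous models are implemented. Seven share the
background-multiplied form P(d) = γ + (1 − γ)·F(d) with F(0) = 0
(quantal-linear, multistage, Weibull, gamma, log-logistic, log-probit,
dichotomous Hill); the logistic and probit parameterize P directly. For the
background-multiplied family, extra risk reduces to F(d), so the BMD at
extra-risk level A solves F(d) = A in closed form (inverse CDF or
logit/probit inversion; for the multistage, the smallest positive root of
the dose polynomial). For logistic/probit the BMD follows from inverting
P at the target P(0) + A·(1 − P(0)).

**Constraints.** Under the default *restricted* setting the power/slope
parameters of the log-dose and power-family models are bounded below at 1,
which prevents supralinear (infinite slope at dose zero) behavior; an
unrestricted toggle lowers the bound to ~0. Backgrounds live in [0, 1],
slope-like parameters in [0, 10⁴], powers in [1 (or ~0), 18]. These are the
conventional settings of the benchmark-dose software family; the source
publication for the packaged fixtures names the software it used but not
per-model settings, so the conventional defaults are adopted.

**Fitting.** The binomial log-likelihood is maximized with L-BFGS-B from a
deterministic multi-start schedule: a method-of-moments-style heuristic
start, a scan of the half-maximal-dose guess across the tested dose range
(log-dose models have well-separated local optima in their location
parameter), and Latin-hypercube perturbations from a seeded generator.
Fits are therefore bit-reproducible for a given seed; the default schedule
(seed 0) is what the acceptance script uses, since the MLE is a
deterministic quantity. Non-convergence is flagged on the fit, never
silently returned. The test suite verifies the optimizer dominates a
brute-force grid oracle on ≤3-parameter models to within 10⁻³ nats.

**Parameter counting.** A parameter whose estimate lands on a constraint
boundary is not counted as estimated — for both the AIC penalty and the
Pearson χ² degrees of freedom (df = groups − estimated parameters). This
mirrors the convention of the standard software family and is what makes
the reported goodness-of-fit p-values comparable to published ones.

**BMDL.** One-sided 95% profile likelihood: the smallest BMD for which the
constrained maximum log-likelihood stays within χ²₁(0.90)/2 = 1.35277 nats
of the global maximum. Each model is reparameterized so the BMD is an
explicit parameter (one natural parameter is substituted out; for
logistic/probit the slope is solved from the pinned BMD and the remaining
intercept is optimized on a line). The profile is walked down geometrically
from the MLE with warm-started re-optimization, then the crossing is
bracketed and solved by Brent's method on log-dose. If the profile never
crosses the cutoff down to BMD × 10⁻⁶ the floor is reported with a flag.

**Selection.** Converged fits are screened (χ² p ≥ 0.10 where defined;
|scaled residual| ≤ 2 at the control group and the group nearest the BMD),
then ranked by AIC with ties broken by fewer estimated parameters, then
lower BMDL. The BMD/BMDL ratio is recorded and flagged above 5. The
thresholds are the conventional ones; the source publication lists the
criteria qualitatively.

**Known degeneracy.** Designs with response at a single dose (the packaged
bioassay layout has its only clear response at the top dose) leave
three-parameter log-dose models ridge-degenerate: the likelihood is flat
along a curve in (intercept, slope), and the MLE — hence the BMD — is not
unique along it. The deterministic start schedule makes the reported point
reproducible, and the selection rules generally prefer the identified
lower-parameter fits on such data, but per-model BMDs from ridge-degenerate
fits should be read as one point on an interval. This is a property of the
design, not the optimizer.

## Continuous models

Linear, polynomial, power, Hill and the four nested exponential mean
functions, each with a constant-variance or power-of-mean
(σ² = α·μ^ρ) error model. The likelihood uses the sufficient-statistic
form for group summaries (n, mean, SD), which equals the individual-data
normal likelihood up to a data-independent constant (verified numerically
in the tests). BMRs: one modeled SD (constant-variance σ̂, or the
control-mean σ under power-of-mean) or a relative deviation from the
control mean — the 5% relative-deviation convention is used for
developmental endpoints such as fetal weight. The BMDL profiles the
likelihood with the BMD pinned by an SLSQP equality constraint, bisected
exactly as in the quantal case. Default variance model is constant; the
source publication gives no variance-model detail.

## Bayesian model averaging

Priors are Normal on a transformed scale per parameter kind: logit for
probabilities (background, Hill plateau), log for slopes/powers (lognormal
priors), identity for intercepts. The shipped table
(`src/bmdtox/data/priors_default.yaml`, version 1) uses a diffuse
logistic-normal background N(0, 2), diffuse lognormal slope priors
(σ = 1.5–2) and moderately informative lognormal shape priors with medians
near 1.5–2 and σ = 0.35. The exact priors behind the published
model-average values are not printed anywhere; the scales follow the
Bayesian suite of the standard software family, and the shape-prior width
was calibrated once against the published model-average BMD₁₀/BMDL₁₀ pair
for the packaged liver-lesion fixture, then frozen. All priors are config,
not code.

Posterior model weights come from the Laplace approximation
log m = log p(data, θ_MAP) + (k/2)·ln 2π − ½·ln det H, with H the negative
Hessian (central finite differences) of the log posterior in the
transformed space; a singular Hessian falls back to the pseudo-determinant
and is flagged. The model-averaged BMD posterior is sampled from the
mixture of per-model Gaussians (clipped to the constraint box); draws whose
BMR is unattainable are censored at 100 × the top dose and counted, with
more than 20% censoring an error. Reported: posterior median (BMD_MA) and
5th percentile (BMDL_MA).

The four-parameter dichotomous Hill model is omitted from the *default*
averaging table: with the common four-dose-group design it is saturated,
its Laplace evidence is unreliable, and its inclusion produces a
model-average lower bound dominated by an unidentified plateau parameter.
It can be re-enabled through a custom priors file for richer designs.
Multistage enters the Bayesian table at degree 2.

## Deterministic reference dose

HED = POD × (BW_animal/BW_human)^(1/4) (BW^(3/4) scaling of daily dose).
Animal body weight is a required input with no hidden default — the
packaged pipeline config documents 0.29 kg, back-calculated from the
published HED of 1.6 mg/kg/day for a BMDL of 6.3 mg/kg/day; the bioassay
reports no reference weight. Uncertainty factors take values {1, 3, 10}
and compose in half-log units: each 3 contributes 10^0.5, so
{3, 10, 3} → 10² = 100 (the published total for that set, not the literal
product 90). Reference doses are reported at one significant figure with
the raw value retained (0.016 → 0.02, 0.088 → 0.09).

## Probabilistic reference dose

All uncertain quantities are lognormals stated as (median, P95/P50);
σ_ln = ln(P95/P50)/1.6449. The animal-dose distribution AD_M has median =
BMD and 5th percentile = BMDL. The chain

    HD_M^50% = AD_M / (AF_BW × AF_TK/TD),  HD_M^I = HD_M^50% / AF_H^I

is evaluated both in closed form (quotients of independent lognormals are
lognormal: means subtract, variances add) and by seeded Monte Carlo; the
two must agree within sampling error, and the tests require 1% agreement at
10⁶ draws on the 5th percentile. The pRfD is the 5th percentile of HD_M^I
divided by the deterministic UF_D — applied *after* the percentile, per the
published workflow; UF_D = 3 divides as 3 (at one significant figure the
result is insensitive to the 3-vs-10^0.5 reading, and both are recorded in
the report). A variance budget (per-factor share of ln-variance) is
reported to show which factor drives the spread.

Default adjustment factors (`src/bmdtox/data/aprob_defaults.yaml`,
version 1) follow the approximate probabilistic hazard-characterization
framework: AF_BW median (BW_h/BW_a)^0.3 — the framework's central
allometric dose exponent of 0.7 — with the exponent's sampling SD (0.033)
propagated into a P95/P50 of (BW_h/BW_a)^(1.6449·0.033); AF_TK/TD median 1
with P95/P50 = 3; AF_H^1% median 9.7 with P95/P50 = 4.3. The deterministic
HED uses the BW^(3/4) convention while the probabilistic AF_BW uses the
framework's BW^0.7; the config exposes the exponent, and the 0.7 default
was validated against the published 5th percentile of HD₁₀^1%
(0.040 mg/kg/day), which the shipped defaults reproduce within 6%
(0.0377). Setting the target incidence I to 50% collapses AF_H to a point
mass, recovering the median-human distribution.

## Synthetic data

The generator draws quantal incidences binomially from any suite curve and
continuous summaries from normal individual responses — exactly the noise
models the analyses assume. The `table1_like_design` helper mirrors the
chronic-bioassay layout (doses 0, 0.1, 1, 50 mg/kg/day; n = 70) with truth
anchored at a fixture's control and top-dose proportions; a two-parameter
truth curve is available for studies that need the sparse design to be
fully identifying. What passing tests show: the estimators recover known
truth, the BMDL covers the true BMD at ~95%, and the goodness-of-fit
p-value is calibrated — *under correctly specified binomial/normal
sampling*. What they do not show: robustness to overdispersion (litter
effects), model misspecification, historical-control drift or
non-summary data structure, none of which the generator emulates.

Study sizes used by the test suite were chosen for desk-scale runs:
500 replicates for the coverage study (hence the ≥93% acceptance line at
nominal 95%, allowing ~2σ of Monte Carlo error), 600 replicates for GOF
calibration, n = 10⁴/group for parameter recovery, 10⁶ lognormal draws for
the closed-form/Monte-Carlo cross-check.

## Numerical details

- Probabilities are clipped to [10⁻¹², 1 − 10⁻¹²] inside the likelihood;
  all-zero or all-one incidence therefore fits at the parameter bounds
  rather than failing.
- BMD root-finding tolerance 10⁻⁶ relative; BMDL bisection 10⁻⁴ on
  log-dose.
- The boundary test for parameter counting uses an absolute 10⁻⁶ distance
  (scaled for large bounds); this matters because multistage coefficients
  near zero must count as estimated only when genuinely interior.
- Seeds: every stochastic routine (simulation, mixture sampling, Monte
  Carlo propagation) takes an explicit seed and surfaces it in its result;
  optimizer multi-starts are seeded separately and default to a fixed
  schedule so point estimates are deterministic.

## Limitations

- No nested/litter models, no time-to-event data, no beta-binomial
  overdispersion; summary data only.
- Bayesian machinery is Laplace-based; no MCMC. Evidence for saturated
  models (parameters = dose groups) is unreliable and such models should
  stay out of the averaging set.
- The continuous "hybrid" (tail-probability) BMR is not implemented; 1-SD
  and relative-deviation only.
- Adjustment-factor distributions are treated as independent; correlated
  factors and re-estimation from historical data are out of scope.
- One dose unit (mg/kg/day) throughout; no route-to-route extrapolation or
  cancer slope factors.
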