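# Methods

## The estimation problem

Radionuclide therapy dosimetry needs the time-integrated activity (TIA) of
an organ: the integral of its activity–time curve after injection,
proportional to the absorbed dose through S-values.  Measuring the full
curve takes several imaging sessions per patient.  `stpdosim` implements a
population approach that (i) fits a family of sum-of-exponential (SOE)
curves to the complete time–activity data of a patient cohort with a
nonlinear mixed-effects (NLME) model, (ii) selects the curve
parameterisation most supported by the data via the corrected Akaike
information criterion, and (iii) computes the TIA of a *new* patient from
a single measurement by refitting the population jointly with that one
point, reading the patient's curve off the empirical-Bayes estimate.

## Curve models

Eleven SOE parameterisations with 3, 4 or 5 adjustable parameters are
registered (`f3a`–`f5b`).  All satisfy `f(0) = 0` (no activity in the
organ at injection).  Two fixed rates enter every model: the physical
decay constant of the nuclide (default ¹¹¹In, half-life 67.31 h, i.e.
1.72·10⁻⁴ min⁻¹) and a blood-circulation uptake rate fixed at
ln 2 / 1 min, which cannot be estimated because the first imaging session
happens hours after injection.  Every model is reduced internally to a
plain term list `f(t) = Σ c_k exp(−r_k t)` whose coefficients are balanced
to sum to exactly zero; evaluation and the closed-form integral
`TIA = Σ c_k / r_k` both come from this representation.  `f4a` is defined
with the balancing blood-circulation term `−(A1−A2)·exp(−(λ_bc+λ_phys)t)`,
the only form under which its `f(0) = 0` constraint can hold.

Units: time in minutes internally (hours at the CSV interface), rates in
1/min, activities in % of administered activity.  In `f4d`/`f4e` the
prefactor `A1` is the TIA itself (%·min); in `f3b`/`f3d` the TIA is
`1/A1`.

### Identifiability orderings

Exchange-symmetric forms carry an ordering constraint to remove label
switching.  `f3a`–`f3d` and `f5a` order their rate parameters at the
parameter level (a swapped assignment flips the curve's sign and is
invalid anyway).  `f4d`/`f4e` have a subtler exact symmetry:
`(α, λ1, λ2) → (1−α, λ2, λ1)` leaves the curve unchanged because the
normalising denominator flips sign together with the numerator.  Here the
ordering `λ1 ≤ λ2` is imposed on the population fixed effects only —
individual (random-effect) parameters stay free, because inter-patient
variability can legitimately cross the two rates for single patients.
Heuristic starting values are mapped to the canonical representative
before optimisation.

## Mixed-effects model and objective

Parameter `j` of patient `m` is `P_{j,m} = TVP_j · exp(ETA_{j,m})` with
`ETA_{j,m} ~ N(0, ω_j²)` (diagonal covariance, one variance per
parameter).  Observations follow an exponential error model on the log
scale: `log y = log f(t; P) + ε`, `ε ~ N(0, σ²)`.  The marginal
likelihood integrates the random effects out per patient; the integral is
approximated by Laplace's method at the per-patient posterior mode, with
a Gauss–Newton (first-order conditional style) approximation of the inner
Hessian.  The reported OFV is −2 log of this approximate marginal
likelihood.  The implementation is verified exactly (to 10⁻⁹) against the
closed-form Gaussian marginal of a model that is linear in its random
effect, for which Laplace is exact.

The fraction parameter `α ∈ [0, 1]` defaults to the same multiplicative
log-normal random effect as every other parameter, with proposals pushing
an individual `α` outside `[0, 1]` rejected.  A logit scale
(`alpha_scale="logit"`) is available; on that scale
`logit(1−α) = −logit(α)` makes the mirrored parameterisations `f4d` and
`f4e` *exactly* equivalent as statistical models, which is the setting in
which the OFV-invariance check is exact.  Under the default log-normal
scale the two parameterisations are deliberately distinct models (a
log-normal effect on `α` is not a log-normal effect on `1−α`) and their
maximised OFVs differ by a small but genuine amount — that difference is
the reason for carrying both forms in the candidate set.

### Optimisation

The outer problem optimises `log TVP` (logit for `α` in logit mode),
`log ω²` and `log σ²` with L-BFGS-B.  Every objective evaluation re-solves
all patients' posterior modes by a damped Gauss–Newton iteration that is
batched across patients, finite-difference perturbations and line-search
trials (one vectorised curve evaluation per sweep).  Posterior modes are
warm-started from the previous outer evaluation.  The outer
finite-difference step (10⁻⁵) is set well above the warm-start noise
floor of the inner solves; the relative stopping tolerance (10⁻⁷) sits
just above the same floor.

Starting values come from a pooled log-scale least-squares fit (several
random starts; the few best *distinct* solutions are kept, because the
pooled surface has a confluent `λ1 = λ2` ridge) and from classical
two-stage estimates (per-patient fits; geometric mean → fixed effects,
log-scale variance → random-effect variances).  The default search is a
successive-halving multistart: cheap exploratory L-BFGS-B passes from
every start, full-length polishing of the best two, then up to three
restarts from the winner (a fresh quasi-Newton memory often escapes flat
ridges).  `FitSettings.multistarts` defaults to 10 exploratory starts;
the desk-scale experiments use 3–4 to stay within minutes per cohort.

Fixed-effect uncertainty is computed from the inverse of the
finite-difference Hessian of the profile objective in natural parameters
(fixed effects, variances, residual variance jointly); the fixed-effect
block yields per-parameter coefficients of variation (CV%).  A singular
Hessian reports infinite CV.

### Local (initial-estimates) protocol

`local_fit_settings` reproduces the classical workflow of NLME tools that
require user initial estimates and perform one local maximisation: a
single optimisation started at supplied population values, no multistart,
no restarts.  The parameter-recovery experiment uses this protocol with
the generating values as initial estimates.  The distinction matters: at
the default study size (8 patients × 5 sessions, 21% residual noise) the
marginal likelihood is multimodal, and an unconstrained global search
regularly finds modes far from the generating values that carry a
*better* likelihood — a property of the likelihood at this sample size
and noise level, not of the optimiser.  The local protocol measures
curvature-limited recovery; the global search is the right tool when
nothing is known a priori.

## Model selection

Candidates are ranked by `AICc = OFV + 2K + 2K(K+1)/(N−K−1)` with
`K = 2p + 1` (p fixed effects, p variances, one residual variance) and
`N` the total observation count.  Akaike weights `exp(−Δ/2)`, normalised
after subtracting the minimum AICc, are computed over the models that
pass the goodness-of-fit gate: converged fit and maximum fixed-effect
CV ≤ 50%.  Gated-out models are reported with dashes and excluded from
the weight normalisation.  Ties sort toward smaller `K`, then
lexicographic id.  Stability is assessed by a leave-one-patient-out
jackknife over the models whose full-data weight exceeds 1% (default),
refitting each fold warm-started from the full-data optimum.

## Single-time-point dosimetry

The all-time-point (ATP) reference TIA of each patient integrates the
empirical-Bayes curve of the full-cohort fit over 0–100 000 min by
adaptive quadrature (relative tolerance 10⁻⁶, split at 60 min so the
1-min uptake term is resolved).  For effective decay rates ≥ 10⁻⁴ min⁻¹
the truncation at 100 000 min is below 10⁻³ relative.  The STP TIA of a
target patient keeps the single observation nearest the nominal 22.8 h or
46.7 h session (±3 h tolerance, configurable) and, by default, refits the
complete NLME model on the other patients' full data plus that one point
("refit" mode, the literal joint-fitting protocol).  A "frozen" mode fits
the population on the other patients only and computes the target's
maximum-a-posteriori curve; it agrees with the refit within a few percent
at this cohort size and is faster.  Accuracy is summarised by per-patient
relative deviations `RD = (TIA_STP − TIA_ATP)/TIA_ATP`, their mean and
standard deviation, and `RMSE = sqrt(MeanRD² + SDRD²)`.  The default SD
uses the population convention (divide by n), under which RMSE equals the
literal root mean square of the RDs; the sample convention (n−1) is a
switch.

## Synthetic cohorts

The generator emulates the study design the defaults describe: 8 patients
imaged at five sessions drawn around nominal 2.9, 4.6, 22.8, 46.7 and
70.9 h (SDs 0.6, 0.4, 1.6, 1.7, 1.0 h; truncated above 0.1 h;
independent draws).  Ground truth defaults to the `f4d` population
reported for ¹¹¹In-DOTATATE kidney kinetics: fixed effects
A1 = 129.36 %·min, α = 0.31, λ1 = 1.5·10⁻⁴ min⁻¹ (77.0 h biological
half-life), λ2 = 8.8·10⁻⁴ min⁻¹ (13.1 h); inter-patient variances
(0.08, 0.01, 2.9·10⁻⁴, 1.1); residual log-scale variance 4.4·10⁻²
(treated as a variance, i.e. ≈21% multiplicative noise per measurement).
Random effects are drawn log-normally (the fraction parameter is redrawn
until it stays in `[0, 1]`; a patient whose curve is nonpositive at the
drawn times is redrawn entirely); observations multiply the true curve by
`exp(ε)`.  The generator does not emulate imaging physics — counting
statistics, background, attenuation or organ-overlap corrections — so
passing tests demonstrate statistical behaviour under the assumed error
model, not robustness to real acquisition artefacts.

### What the defaults imply about identifiability

`experiments.design_cv_bound` computes the Fisher-information bound on
the fixed-effect CVs at the nominal design (8 × 5 points, best case with
random effects ignored): for `f4d` roughly 19% (A1), 97% (α), 165% (λ1)
and 257% (λ2).
Consequences worth knowing before interpreting experiment output: on
cohorts simulated from these defaults (i) 4-parameter fits essentially
never pass the 50% CV gate, (ii) the AICc advantage of the generating
4-parameter model over the bi-exponential is usually smaller than its
extra-parameter penalty, so the bi-exponential family tends to rank
first, and (iii) unconstrained maximum likelihood recovers λ1 only to a
few tens of percent.  These are properties of the assumed noise level and
design, not of the estimator (the information bound above caps what any
estimator could do).  The single-time-point
comparison is unaffected in direction — TIAs from the generating
4-parameter model still track the reference better than bi-exponential
STP in most cohorts.

## Experiment protocols and sizes

All experiments live in `stpdosim.experiments`, run in minutes on one
core, and derive every cohort seed from one master seed:

- recovery: 20 cohorts, generating-model fits under the local
  initial-estimates protocol; reported as median relative errors of
  A1, α, λ1.
- selection: 5 cohorts, full 11-model gate-and-weight selection with the
  global multistart (3 starts).
- OFV invariance: one cohort, `f4d` vs `f4e` under the logit fraction
  scale; the two optimisations exchange mirrored optima iteratively until
  neither side improves, so both reach the same basin.
- STP comparison: 11 cohorts, `f4d`- vs `f3d`-based single-point TIAs at
  the 46.7 h session, RD RMSE against the ATP `f4d` reference.
- STP consistency: one cohort, the target keeps all five points; the STP
  TIA must reproduce the ATP TIA within optimiser tolerance.

## Numerical choices and edge cases

- `λ1 = λ2` in forms whose coefficients divide by the rate difference is
  treated as an error, not as the confluent `t·e^{−λt}` limit.
- A zero prefactor in the reciprocal forms (`f3b`, `f3d`) is an error
  (the curve itself is undefined); all-zero prefactors elsewhere give the
  zero function and TIA 0.
- A term with zero total decay rate and nonzero coefficient makes the
  TIA infinite and raises.
- Observation times and activities must be strictly positive (log
  transform); CSV validation reports every offending line.
- Patients with no observations get full shrinkage (`ETA = 0`).
- `PopulationParams` accepts `σ² = 0` so noise-free cohorts can be
  simulated; the fitter always estimates `σ² > 0` (lower bound 10⁻⁸).

## Known limitations

- The Laplace/Gauss–Newton objective is an approximation; at large
  random-effect variances (the λ2 default of 1.1) the inner posterior can
  itself be multimodal and the approximation error is untested against
  exact integration.
- No correlated random effects, no covariates, no stochastic (SAEM/MCMC)
  estimation.
- Model selection quality is limited by optimisation noise of order a few
  tenths of an OFV unit between equivalent parameterisations at the
  default desk-scale settings; raise `multistarts` for sharper tables.
- The CV-based gate inherits the finite-difference Hessian's fragility
  when an estimate sits on a variance bound.
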