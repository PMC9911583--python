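# stpdosim

Population model selection and single-time-point dosimetry for
radionuclide therapy.

## The problem

Internal dosimetry in molecular radiotherapy needs the **time-integrated
activity** (TIA) of an organ — the integral of its activity–time curve —
which classically requires imaging every patient at several times after
injection. A population shortcut is possible: if a cohort has been
characterised once with full time–activity curves, a *new* patient's TIA
can be estimated from a **single** measurement by borrowing strength from
the population through a nonlinear mixed-effects (NLME) model. The
accuracy of that shortcut depends on the fit function, so picking the
function should not be a rule of thumb but a model-selection step.

`stpdosim` implements that workflow for sums of exponentials (SOE):

1. **Fit** — eleven SOE parameterisations `f3a…f5b` with 3–5 adjustable
   parameters, all obeying `f(0) = 0`, are fitted to the cohort by
   maximising a Laplace-approximated marginal likelihood.  Each parameter
   `j` of patient `m` is `P_{j,m} = TVP_j · exp(ETA_{j,m})` with
   `ETA_{j,m} ~ N(0, ω_j²)`, and observations carry a log-scale Gaussian
   residual (`log y = log f + ε`, `ε ~ N(0, σ²)`).
2. **Select** — models are ranked by the small-sample corrected Akaike
   criterion `AICc = OFV + 2K + 2K(K+1)/(N−K−1)` (`K = 2p+1`) and Akaike
   weights `w_j ∝ exp(−Δ_j/2)`, after a goodness-of-fit gate that drops
   fits whose maximum fixed-effect CV exceeds 50%.  A leave-one-patient-out
   jackknife reports the stability of the ranking.
3. **STP dosimetry** — the reference ("all-time-point", ATP) TIA integrates
   each patient's empirical-Bayes curve over 0–100 000 min; the
   single-time-point (STP) TIA refits the population jointly with one
   observation of the target patient (nearest the nominal 22.8 h or 46.7 h
   session) and integrates the target's curve.  Accuracy is summarised by
   relative deviations `RD = (TIA_STP − TIA_ATP)/TIA_ATP` and
   `RMSE = sqrt(MeanRD² + SDRD²)`.

A synthetic-cohort generator reproduces the study design the defaults
describe — eight patients imaged near 2.9, 4.6, 22.8, 46.7 and 70.9 h
post injection, with population kinetics of ¹¹¹In-DOTATATE in kidneys
(`f4d`: A1 = 129.36 %·min, α = 0.31, λ1 = 1.5·10⁻⁴ min⁻¹,
λ2 = 8.8·10⁻⁴ min⁻¹) — so the entire pipeline is testable without
patient data.  See `docs/methods.md` for the model details, estimation
internals and known limitations.

## Worked example

Simulate a cohort, rank two candidate functions, and run the
single-time-point experiment from the shell:

```sh
stpdosim simulate --seed 0 --out cohort.csv
stpdosim select cohort.csv --models f3d,f4d --multistarts 3
stpdosim stp cohort.csv --model f4d --reference-model f4d \
    --time-label T4 --multistarts 3
```

which prints

```
wrote 40 observations for 8 patients to cohort.csv

function     K  weight %  max CV %
f3d          7    100.00      22.6
f4d          9         -      67.0

STP f4d @ T4: mean RD = -4.71%, RMSE = 11.96%
```

Reading the output: the selection table lists each candidate's NLME
parameter count `K`, its Akaike weight among the goodness-of-fit
survivors, and the largest fixed-effect coefficient of variation that the
50% gate checks.  On this cohort the 4-parameter model's fixed effects
are too uncertain (max CV 67%), so the gate excludes it — the dash — and
the bi-exponential `f3d` carries all the weight; `docs/methods.md`
explains why the default noise level makes this the typical outcome on
synthetic cohorts.  The STP line says that, over the eight
leave-one-patient-out folds, TIAs reconstructed from only the ~46.7 h
measurement deviate from the all-time-point reference TIAs by −4.7% on
average, with a root-mean-square error of 12.0%.

The same workflow is available as a library (`simulate_cohort`,
`fit_population`, `select_best`, `jackknife`, `stp_accuracy`) and as one
end-to-end command, `stpdosim run --outdir out/`, which writes the
selection table, per-patient TIA CSV, accuracy JSON and a run log with
the seed and config hash.

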