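# Methods

## Scope

`zolpitox` simulates and estimates the pharmacokinetics of oral zolpidem
with a view to overdose assessment: given a dose (or a multi-dose
regimen), how high do plasma concentrations rise across a population of
patients, and for how long do they stay above the clinically established
toxic (500 ng/mL), comatose (1500 ng/mL) and fatal (4000 ng/mL)
thresholds?  The same machinery runs in reverse as an estimation stack, so
the whole model-building loop — fit, likelihood-ratio testing, bootstrap,
residual diagnostics, visual predictive check — is exercisable end to end
on synthetic data.

## Structural model

A one-compartment model with first-order absorption and elimination and an
absorption lag.  For a dose *D* (mg) at time 0,

    C(t) = 1000 · D·Ka / (V·(Ka − ke)) · (e^{−ke·τ} − e^{−Ka·τ}),
    τ = t − ALAG,  ke = CL/V,  C(t) = 0 for t ≤ ALAG,

with concentration in ng/mL (the factor 1000 converts mg/L).  Parameters
are apparent (CL/F, V/F) because oral bioavailability is not separately
identifiable from oral data alone.  Multiple doses superpose linearly,
each with its own lag-shifted clock.  When |Ka − ke|/ke < 1e−8 the
degenerate limit `C = 1000·(D/V)·ke·τ·e^{−ke·τ}` is used; the branch point
was placed well below any practically reachable parameter configuration
and the two branches agree to ~1e−5 relative at the switch.

The closed form is the primary evaluator (exact and fast enough for
10⁴–10⁵-subject Monte Carlo in milliseconds).  An independent
ordinary-differential-equation integrator (`ode_oracle`, DOP853 at
rtol 1e−10 with bolus-into-depot events) exists purely as a cross-check;
the suite verifies agreement to better than 1e−6 relative over 1000 random
parameter/regimen draws.

Default parameter values (typical adult, immediate-release tablet):
Ka = 5.41 1/h, V/F = 61.7 L, CL/F = 16.9 L/h, ALAG = 0.394 h.  Typical
elimination half-life is ln 2/(CL/V) ≈ 2.5 h; a 24 h horizon therefore
covers > 9 half-lives and truncates < 0.2 % of the AUC.

## Population model

Between-subject variability is lognormal, `P_i = θ · exp(η_i)` with
`η ~ N(0, Ω)` over (Ka, V, CL); the lag time carries no random effect.
Ω has a free Ka variance and a correlated (V, CL) block; the default
correlation is 0.853, reflecting the strong physiological coupling of
clearance and distribution volume.  Residual error is proportional:
`DV = IPRED · (1 + ε)`, `ε ~ N(0, σ²)`, σ = 0.284.

Variability magnitudes are specified as CV percentages (158.91 / 22.10 /
32.60 % for Ka / V / CL).  Two CV→ω² conventions are supported because
reporting practice is ambiguous:

- `exact-lognormal` (default): ω² = ln(1 + CV²) — exact for a lognormal
  variate and the convention under which the simulator reproduces the
  reference dose-escalation percentages most closely;
- `sd-equals-cv`: ω² = (CV/100)², the common shortcut where the reported
  CV% is just 100·√ω².

The two differ by <2 % for the V and CL terms but materially for Ka
(ω² 1.26 vs 2.53), which is why the choice is an explicit argument rather
than buried.

Sampling draws `η = L·z` with `L` the lower-triangular Cholesky factor
(eigendecomposition fallback for singular-PSD Ω), subjects in outer order
and components inner, from numpy's PCG64 generator; a seed therefore pins
the entire cohort.  No truncation or resampling of extreme draws is
applied: the lognormal tails are part of the model, and overdose risk
lives in those tails.

## Monte Carlo simulation and threshold analytics

The default time grid is dense (0.02 h) through the absorption phase
(0–4 h) and sparse (0.25 h) out to 24 h, and always contains the nominal
clinical sampling times.  The dense region exists because duration
summaries bin at 1 h boundaries and need crossing times resolved well
below 0.05 h when a grid fallback is in play.

Percentile bands (default 5/50/95) are pointwise quantiles across subjects
with the linear-interpolation quantile definition.  Note that the
pointwise median band is *not* the typical-subject curve: the median of a
non-monotone function of correlated lognormal effects sits slightly below
it (≈ 9 % at the peak for the default parameters).  Tests assert this
computed behavior rather than the naive identity.

Residual (assay) error is excluded from threshold-duration analytics and
percentile plots by default — the simulator predicts the smooth
individual-level concentration of an unobserved patient, and the duration
of a noisy curve above a threshold is ill-defined.  The VPC machinery,
which emulates *observed* data, always includes it.

Threshold occupancy is computed exactly on the closed-form curve: a single
dose yields a unimodal profile, so the rising and falling crossings of a
level are bracketed and solved by Brent's method (tolerance 1e−9 h; the
cohort path uses an equivalent 60-step vectorized bisection).  Multi-dose
regimens fall back to sign-change scanning on a 0.005 h grid with the same
root polishing.  Durations are tabulated into the bins
NR (never reached) / <1 h / 1–2 h / 2–3 h / >3 h, ties at the boundaries
going to the upper bin (a measure-zero event at Monte Carlo scale).

Two occupancy readings are implemented.  `mode="above"` (default) scores
time above the band's lower edge, so a patient above the fatal threshold
is simultaneously counted in the toxic and comatose rows; this is the
reading under which escalating doses saturate the ">3 h" bin of each row
and is the one used for the severity summary table.  `mode="within"`
scores time strictly inside [lo, hi), which answers a different question
("how long in the comatose *range* specifically") and is exposed because
both readings are defensible summaries of the same curves.

## Non-compartmental analysis

AUC uses the linear-up/log-down trapezoid: linear `(c₁+c₂)/2·Δt` on rising
or flat segments and whenever an endpoint is zero, logarithmic
`(c₁−c₂)·Δt/ln(c₁/c₂)` on declining positive segments.  λz is the negated
slope of a log-linear regression over trailing subsets of ≥ 3 positive
post-peak points (Cmax excluded); the subset maximizing adjusted R² wins,
ties within 1e−4 going to the larger subset — the dominant industry
convention, chosen because the quantity itself does not pin down a
selection rule.  Derived metrics: t½ = ln 2/λz,
AUC∞ = AUC_last + C_last/λz, CL/F = 1000·dose/AUC∞ (mg and ng·h/mL units),
V/F = (CL/F)/λz.  When fewer than three usable terminal points exist, λz
and everything downstream of it are reported as NaN rather than guessed.

## Estimation (FOCE-I)

The marginal likelihood is approximated by first-order conditional
estimation with interaction.  Per subject, the conditional mode η̂
minimizes

    g(η) = Σ_j [ (DV_j − f_j(η))² / var_j + ln var_j ] + ηᵀΩ⁻¹η,
    var_j = σ² f_j(η)²,

solved by a damped, batched Gauss–Newton with analytic ∂f/∂η (chain rule
through the closed form), a ±4 trust region per step and a stagnation exit
once per-iteration improvement falls below 1e−7 (the Gauss–Newton
direction converges linearly near the mode; the residual η error at exit
perturbs the OFV by ≲ 0.01, far below any decision threshold used).  The
objective then linearizes the model about η̂:

    OFV_i = ln det V_i + e_iᵀ V_i⁻¹ e_i,
    V_i = G_i Ω G_iᵀ + diag(σ² f_i(η̂)²),   e_i = DV_i − f_i(η̂) + G_i η̂,

summed over subjects without the n·ln 2π constant, so the usual χ²
likelihood-ratio thresholds (ΔOFV > 3.84 at one added degree of freedom)
apply unchanged.  Residual variance is evaluated at the conditional
prediction — the "interaction".

Predictions below 1e−6 ng/mL are floored inside the likelihood to keep the
proportional-error variance positive.  Relatedly, the synthetic-study
generator flags exact-zero concentrations (pre-dose and pre-lag samples,
truncated negative draws) as MDV = 1: a zero observation is incompatible
with multiplicative error, and including floored zeros was observed to
distort the lag-time likelihood; this mirrors the standard exclusion of
below-quantification records.

The outer problem optimizes log θ, log σ and a log-Cholesky factor of Ω
(positivity and positive-semidefiniteness free by construction) with a
quasi-Newton stage (L-BFGS-B, finite-difference step 1e−4 — large enough
to see through the inner-solver noise floor) followed by a Nelder–Mead
polish.  Standard errors come from the central-difference Hessian of
OFV/2 at the optimum, delta-method-transformed to the natural reporting
scale (θ, ω², ρ, σ); a non-positive-definite Hessian flags SEs as NaN
without discarding the estimates.  RSE% = 100·SE/estimate.

The sex covariate test refits with a multiplicative `exp(β·I(female))`
factor on CL (or V) and compares OFVs; the bootstrap resamples subjects
with replacement, refits each replicate warm-started from the point
estimates with a reduced optimizer budget (validated to move medians and
CI edges by less than the Monte Carlo width it saves), and reports
per-parameter medians with percentile 95 % intervals.  CWRES standardizes
`DV − (f − Gη̂)` by the linearized marginal covariance and is ≈ N(0, 1)
under a correct model; IWRES = (DV − IPRED)/(σ·IPRED).  The VPC bins
observations by nominal sampling time (one bin per distinct time),
simulates replicate datasets at the observed design with residual error,
and envelopes each observed percentile with the 2.5–97.5 % band of its
simulated counterpart.

## Synthetic study generator

`generate_study` emulates a single-dose, rich-sampling healthy-volunteer
study: 10 mg at time zero, samples at 0, 0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4,
6, 8 and 12 h, 23 subjects (12 male / 11 female by default, males first),
full IIV plus proportional residual error, negative draws truncated at
zero.  No sex effect is generated unless the caller builds one in.  What
it deliberately does not emulate: digitization noise of plot-extracted
data, demographic covariates beyond sex, dropout or BQL censoring beyond
the exact-zero rule, and absorption-phase model misspecification.
Consequently, passing recovery tests demonstrate internal consistency of
the estimator under the model's own assumptions — not robustness to the
messiness of real digitized datasets.

## Problem sizes and numerical choices in the test suite

Threshold summaries run at 10,000 subjects (the dose-escalation reference
used 500, so comparisons carry a ±3-binomial-SE-at-n=500 tolerance);
population calibration at 50,000 draws; parameter recovery on one seeded
100-subject study (tolerance 10 % per fixed effect); the lag LRT on ten
seeded 23-subject replicates; the bootstrap at 200 replicates of the
23-subject study.  Intrinsic limits worth knowing: with ω²_Ka = 1.26 the
cohort geometric-mean Ka at n = 100 has ≈ 11 % sampling SD, and both
FOCE-I and the exact marginal MLE shrink Ka downward on unlucky cohorts,
so the Ka recovery margin is genuinely tight — Vd, CL and ALAG recover
within a few percent.

## Known limitations

- Single-compartment, first-order absorption only; no transit/Erlang or
  zero-order variants, no nonlinear elimination.
- No drug–drug interaction, alcohol co-ingestion, or controlled-release
  formulation effects; overdose-scale dissolution slowdown is not modeled,
  so simulated peaks at very large doses are, if anything, pessimistic.
- ALAG carries no between-subject variability; real early-phase spread is
  partly absorbed into the Ka variance.
- Estimation supports one dose record per subject (the design the
  estimation stack is meant for); multi-dose estimation is out of scope,
  though multi-dose *simulation* is fully supported.
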