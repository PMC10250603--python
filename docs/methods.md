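# Methods

## Structural and statistical model

The concentration model is a one-compartment oral-absorption model at
steady state.  All patients are assumed to be at steady state under
once-daily dosing (τ = 24 h); pre-dose samples are treated as the trough
of the steady-state interval, which the closed form makes identical to
t = τ (the profile is periodic, C(0) = C(τ)).  A single-dose profile is
provided for testing; the steady-state form is verified against
superposition of ≥ 50 single doses to 0.01%.  When |Ka − ke| < 10⁻⁶·Ka the
closed form degenerates; the implementation switches to the flip-flop
limit expression with the derivative evaluated at the midpoint rate
(Ka + ke)/2, which makes the branch switch second-order accurate (the
discontinuity at the tolerance boundary is below 10⁻⁶ μg/mL).

Interindividual variability is log-normal with a diagonal Ω on
(CL/F, Vd/F, Ka); the IIV of Vd/F is fixed (not estimated), mirroring the
published model, whose Table of estimates reports it as "3 (FIX)".  The
published IIV entries ("1", "3 (FIX)", "100") carry an ambiguous unit; we
read them as %CV of the log-normal effects, ω = √log(1 + CV²), giving
ω ≈ 0.010, 0.030 and 0.833.  The configuration layer also accepts the SD
scale directly (`omega_scale: sd`) for users who read the table
differently.  Residual error is additive with SD σ (μg/mL); proportional
and combined error models are not implemented because every published
quantity this package reproduces was estimated under the additive model.

Below-quantification-limit values (LLOQ = 2.0 μg/mL) follow the M5
convention: imputed to LLOQ/2 = 1.0 μg/mL, flagged, and treated as
ordinary observations in the likelihood.  A censored-likelihood (M3)
treatment is out of scope.

## FOCE-I estimation

The marginal likelihood is approximated by first-order conditional
estimation with interaction.  Per subject, the conditional mode η̂ of the
penalised objective |y − f(η)|²/σ² + ηᵀΩ⁻¹η is found by a damped
Gauss-Newton iteration run simultaneously for all subjects (analytic
Jacobian of the profile in η; per-subject backtracking line search; an
active set freezes subjects whose gradient, step or improvement falls
below tolerance; at most 40 iterations).  The mode search always starts
from η = 0, so the objective is a pure function of the parameters and the
data — re-evaluating it never depends on earlier calls.  This matters
because the inner problem can be multimodal when ω_Ka is wide (flip-flop
ambiguity); probing additional η_Ka starting points changed the objective
by < 10⁻³ in our experiments and was dropped.

With G the Jacobian at η̂, the subject's objective contribution is

    V = G Ω Gᵀ + σ² I,   r = y − f(η̂) + G η̂,
    OFV_i = log|V| + rᵀ V⁻¹ r,

dropping 2π constants (NONMEM convention), so only OFV *differences* are
meaningful.  For additive error the ε–η interaction term (residual
variance at the conditional prediction) equals σ²I exactly.  On small
toys with informative per-subject data this objective reproduces
−2 log marginal-likelihood differences computed by adaptive quadrature to
within 2% (tested); with a single observation per subject and strongly
conflicting prior/data the FOCE approximation degrades, as expected.

The outer problem minimises the summed OFV with L-BFGS-B over
log-transformed positive parameters (raw scale, bounded, for covariate
effects), after a pooled least-squares pre-fit at η = 0 that refines the
fixed effects and seeds σ — without it the quasi-Newton stage is
sensitive to crude starting values.  An "abnormal line search" termination
from L-BFGS-B at the numerical noise floor of the objective is accepted
as convergence provided the per-subject mode searches succeeded (>99%).
Standard errors come from a central-difference Hessian of the objective
in the transformed parameters (covariance 2H⁻¹, delta method back to the
natural scale); they are reported as %RSE relative to the estimate.
η-shrinkage is 100·(1 − SD(η̂)/ω), clipped to [0, 100] for reporting.

## Covariate machinery and selection

Continuous covariates enter as power functions of the covariate over its
reference (median) value; categorical covariates as 1 + θ·flag
(θ > −1 enforced); allometric size scaling uses fixed exponents 0.75 (CL)
and 1.0 (V) with lean body weight referenced to 48 kg.  The final model
hard-wires only these two allometric terms and the geriatric-DM indicator
(age ≥ 70 AND diabetes; the cutoff is configurable and the derived
indicators for cutoffs 60/65/70 are precomputed for the search).  An
optional helper computes lean body weight from weight/height/sex by the
Janmahasatian equations for datasets that lack it.

Stepwise selection: the first forward step is accepted at ΔOFV ≥ 3.84
(χ²₁, p < 0.05) and subsequent forward steps and all backward steps at
6.63 (p < 0.01), a split made explicit here because the source protocol's
wording mixes both thresholds; both are arguments.  Ties are broken by
candidate order, making the search deterministic.  Under a true null the
per-candidate false-selection rate at 3.84 matches the χ²₁ tail (~5%,
verified by simulation with 200 null replicates).

## Validation machinery

*pcVPC*: observations and simulated replicates of the exact design are
corrected by (bin-median population prediction / own population
prediction) within quantile-based time bins (default 8; empty or
duplicate bins are merged).  Percentiles 5/50/95 are compared with their
across-simulation 95% intervals; the default 1000 simulations have a
desk-scale preset of 100–200 used in the tests.

*Bootstrap*: subjects resampled with replacement to the original n,
refitted per replicate (default 1000; tests use 50); medians and
2.5–97.5 percentile intervals are computed over converged replicates.

*External validation*: MPE = Σ(C_pred − C_obs)/N and
APE = Σ|C_pred − C_obs|/N, with population (η = 0) and individual
(empirical-Bayes) prediction modes reported side by side.  The individual
mode reuses the same sparse observations both to estimate η̂ and to score
the error — an unavoidable circularity with one sample per patient, which
is why both modes are always reported.  Intervals are the 2.5–97.5
percentiles of the per-observation errors, with the min–max range also
carried, since published error intervals of this kind are typically
empirical ranges rather than standard-error CIs.  Comparator models are
supplied by the user through the registry (YAML round-trip); no
third-party parameter sets are hard-coded.

*Forecasting*: MAP η̂ per subject, then AUC₀₋₂₄ = D_norm/CL_i at the
1200 mg normalisation dose and C_max by bounded scalar maximisation of
the individual profile.  Target attainment scores AUC₀₋₂₄ ≥ 363 μg·h/mL
and C_max ≥ 30 μg/mL (inclusive).

## Synthetic cohort generator

The generator defines the study conditions for every simulation-based
test.  Ages are drawn from a Beta(1.3, 1.5) scaled to [19, 96] (median
≈ 54, ~23% aged ≥ 70); lean body weight from sex-specific Beta(3, 2)
distributions scaled to [28, 63.8] kg (men) and [23.1, 55] kg (women),
overall median ≈ 48 kg with two-thirds male; total weight is LBW times a
log-normal ratio (median ≈ 1.27).  Diabetes uses piecewise age rates
(8.5% under 70, 20.9% at ≥ 70) chosen to reproduce the study's four
age-by-DM subgroup proportions directly; a logistic-in-age mechanism
would fit the same margins but adds a parameter the data cannot inform.
Dosing is nominal 25 mg/kg rounded to the nearest marketed tablet
strength {500, 1000, 1200, 1250, 1500, 1600, 2000} mg, capped at
2000 mg.  Sampling follows the study scheme (outpatients: one uniform
draw on (0, 24]; inpatients, 30% of subjects by default: ≥ 2 of the
pre-dose/1/2/5 h points) or a fixed 1/2/5 h design for parameter-recovery
work, which also raises the geriatric-DM fraction to 12% so the covariate
effect is well informed.  Concentrations are the steady-state profile
plus additive Gaussian noise truncated at zero; sub-LLOQ values keep
their raw value with a BLQ flag, imputation being a separate step.

Known infidelities to real data: no adherence failures or dose-history
uncertainty (steady state is exact), no co-medication effects, covariates
other than size/age/DM carry no PK effect (they exist for null testing),
the marketed-tablet rounding produces a flatter dose distribution than
the study's (where 1500 mg dominated at 63%, suggesting prescriber
preference beyond nearest-tablet rounding), and lean body weight is not
age-correlated although the study's elderly were lighter.  Passing
recovery tests therefore demonstrate estimator correctness under the
stated design, not robustness to real-world protocol deviations.

## Problem sizes and numerical defaults

The recovery experiment uses 500 subjects × 3 seeds with samples at
1/2/5 h, the scale at which the sparse design identifies all fixed
effects; smaller cohorts (25–80 subjects) are used for property tests
where effect direction, determinism or distributional shape — not
precision — is being checked.  Inner mode search: tolerance 10⁻⁶,
40 iterations, gradient-freeze 10⁻⁷·(1+obj).  Outer optimiser: L-BFGS-B,
ftol 10⁻¹⁰, forward-difference step 10⁻⁵ on the transformed scale.
Degenerate inputs: zero dose yields zero concentration; a subject with no
observations is rejected by the engine (and given the prior mode η = 0
with a warning by the standalone EBE operation); Ω → 0 reduces the
objective to the pooled fixed-effects −2 log-likelihood (used as a fast
path when all ω < 10⁻³).

## Limitations

Single additive error model; diagonal Ω only; no SAEM/importance-sampling
estimators; no M3 censored likelihood; no multi-compartment or
absorption-delay structures (the source analysis evaluated and rejected
them).  OFV values are comparable only as differences, and between-run
OFV agreement is limited by the mode-search tolerance (~10⁻²).
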