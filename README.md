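# pzapk — population pharmacokinetics of pyrazinamide

Pyrazinamide (PZA) is a first-line antituberculosis drug whose efficacy
tracks steady-state exposure (AUC₀₋₂₄ and C_max), yet routine care measures
at most one or two plasma concentrations per patient at essentially random
times after the last dose.  `pzapk` implements the population-PK machinery
that turns such sparse data into individual exposure estimates: a
nonlinear mixed-effects (NLME) model for adult TB patients on once-daily
oral PZA, its estimation engine, covariate selection, internal/external
validation, and MAP Bayesian forecasting for model-informed precision
dosing.  It is aimed at pharmacometricians and clinical-pharmacology
researchers who want a scriptable, fully testable NONMEM-style pipeline in
Python.

## The model

Structural model: one-compartment disposition with first-order absorption
and elimination at steady state under dose D every τ = 24 h,

    ke = CL/V,
    C(t) = D·Ka / (V·(Ka − ke)) · [ e^(−ke·t)/(1 − e^(−ke·τ))
                                  − e^(−Ka·t)/(1 − e^(−Ka·τ)) ],

with apparent parameters CL/F, Vd/F, Ka (oral bioavailability F is not
separately identifiable).  Individual parameters combine typical values,
multiplicative covariate factors and log-normal random effects η:

    CL_i = θ_CL · (LBW_i/48)^0.75 · (1 + θ_GDM·GDM_i) · e^(η_CL,i)
    V_i  = θ_V  · (LBW_i/48)^1.0  · e^(η_V,i)
    Ka_i = θ_Ka · e^(η_Ka,i)

where LBW is lean body weight (allometric reference 48 kg, fixed exponents
0.75 and 1.0) and GDM is the geriatric-diabetes indicator (age ≥ 70 y AND
diabetes mellitus), which raises clearance by the fraction θ_GDM.
Residual error is additive on the concentration scale; concentrations
below the 2.0 μg/mL assay quantification limit are imputed to 1.0 μg/mL
(Beal's M5 rule) as an explicit preprocessing step.

Estimation is first-order conditional estimation with interaction
(FOCE-I): each subject's conditional η mode is found by penalised
Gauss-Newton, the model is linearised there, and the resulting approximate
−2 log-likelihood (OFV) is minimised over log-transformed population
parameters.  Covariates are selected by likelihood-ratio tests (forward
inclusion at ΔOFV ≥ 3.84, subsequent/backward steps at 6.63); validation
uses prediction-corrected VPCs, nonparametric bootstrap, and MPE/APE
prediction errors on held-out data.

The default parameter values shipped with the package are the published
final-model estimates for adult Korean TB patients: θ_CL = 4.49 L/h,
θ_GDM = 0.32 (so a geriatric diabetic patient has a typical CL/F of
5.9 L/h), θ_V = 44.2 L, θ_Ka = 1.49 h⁻¹, additive residual SD 3.41 μg/mL,
and IIV of 1% / 3% (fixed) / 100% CV on CL, V and Ka.

Because the underlying patient-level study data are not public, the
package includes a first-class synthetic-cohort generator
(`pzapk.cohort`) that emulates the study population: two-thirds male,
median age ~54.5 y (19–96), median lean body weight ~48.1 kg, diabetes
prevalence ~11% enriched above age 70, guideline dosing (25 mg/kg rounded
to marketed tablet strengths, max 2000 mg), and the sparse
outpatient/inpatient sampling scheme with LLOQ censoring.

## Worked example

```python
from pzapk import (PopPKModel, final_model_spec, impute_blq,
                   recovery_design, simulate_dataset, forecast_cohort,
                   PopulationParameters, target_attainment)

# simulate a cohort under the published model, censor, impute, refit
subjects, truth = simulate_dataset(recovery_design(500), seed=1)
fit = PopPKModel(impute_blq(subjects), spec=final_model_spec()).fit(compute_se=False)
print(fit.estimates.round(3))
```

Output (seed 1):

```
theta_cl         4.427
theta_v         46.396
theta_ka         1.525
theta_gdm_cl     0.352
omega_cl         0.000
omega_ka         0.752
sigma            3.451
```

The engine recovers the generating clearance 4.49 L/h within 1.4%, volume
44.2 L within 5%, Ka 1.49 h⁻¹ within 3%, the geriatric-DM fraction 0.32
within 0.04, and the residual SD 3.41 μg/mL within 2% — from three sparse
samples per subject.  Forecasting exposure for the same cohort:

```python
est = forecast_cohort(impute_blq(subjects), PopulationParameters.from_cv_percent())
print(target_attainment(est))   # fractions meeting AUC>=363 ug*h/mL, Cmax>=30 ug/mL
```

A command-line interface mirrors the library
(`pzapk simulate | fit | select-covariates | vpc | bootstrap | validate |
forecast`); every command writes a JSON run report with seeds and versions
so any number can be regenerated exactly.

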