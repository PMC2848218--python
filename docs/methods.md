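# Methods

## Model

The circuit has three populations — PFC (x_p), striatum (x_s), midbrain DA
nuclei (x_d) — plus the striatal DA release y. Each variable relaxes with
its own time constant toward its input: the striatum toward the
glutamatergic cortical drive, the DA nuclei toward a tonic drive minus the
GABAergic striatal input, and DA release toward the dopaminergic output.
Two presynaptic D2 effects multiply transmission by (1 − b·P) on the
cortical terminals and (1 − a·P) on the dopaminergic terminals, with
P = Y/(1+Y) the D2 occupancy by dopamine. The time-domain model optionally
uses a saturating activation f(x) = tanh(x); every parametric result in the
package comes from the linearized (f(x) = x) equilibrium, for which the
normalized fixed point is

    X_s = X_p (1 − bP),  X_d = J_d − X_s,  Y = X_d (1 − aP),  P = Y/(1+Y)

subject to X_s, X_d, Y > 0. Normalization folds all connectivity gains and
time constants into the variables, and measures concentrations in units of
the relevant dissociation constant; absolute K values never enter.

Key assumptions: population-level (mean-field) activities; a single D2
dissociation constant for endogenous dopamine shared by somatic and both
presynaptic receptor pools (only one K_DA is defined); receptor density
unchanged by acute depletion; single-site competitive binding for tracer,
dopamine and antipsychotic (no high/low-affinity D2 states); D2 effect
strength proportional to occupancy, not raw concentration.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| a | autoreceptor suppression of DA release | 0 (0.2 in the "both effects" setting) | study conditions of the parametric analysis |
| b | heteroreceptor depression of corticostriatal input | swept over [0, 1] | the analysis' independent variable |
| J_d | tonic drive to the DA nuclei | 1 | normalization choice; all activities measured relative to it |
| α | residual dopamine fraction after depletion | 0.3 | the 70%-depletion assumption used to interpret AMPT imaging |
| B_max (SZ) | patient D2 density relative to controls | 1.2 | depletion-imaging estimate behind both calibrated models |
| τ_s, τ_d, τ_y, W_* | time constants / gains | 1 | only the normalized combinations matter at equilibrium |

Cross-cohort comparisons scale the D2 coefficients by the cohort's relative
density (a_eff = a·B_max, b_eff = b·B_max): a patient with 1.2× the
receptors experiences 1.2× the presynaptic D2 effect at equal occupancy.
Generic circuit sweeps use the raw coefficients (density 1). The
outcome transformation exposes the scaling behind an explicit
`scale_by_density` flag (moot at its default setting (a, b) = (0, 0)).

Calibrated models: Model 1 takes the one study reporting both cohorts
(occupancies 12% HC / 21% SZ); Model 2 averages the healthy-control studies
(23.6%), extrapolates the patient value by Model 1's SZ/HC ratio (41.3%)
and rounds to 24%/41%. Occupancies convert exactly to dopamine levels via
Y = P/(1−P). The study average is unweighted — the source occupancies carry
no usable precision information.

## Numerical choices

- **Equilibrium.** Damped fixed-point iteration on Y (damping 0.5,
  tolerance 1e−12, ≤10,000 iterations) with a fallback bracketed root
  search (dense sign-scan + Brent) on the scalar residual
  g(Y) = (J_d − X_p(1−bP))(1−aP) − Y. On the physical branch the positive
  solution is unique when it exists; Y < J_d always, which bounds the scan.
  Infeasible parameter points (no positive solution) raise, and sweeps flag
  them per-row rather than dropping them.
- **Modulation clamping.** The factors (1 − a·P) and (1 − b·P) are clamped
  at zero: negative transmission is unphysical, and no analysis setting
  approaches the clamp.
- **Time integration** uses scipy's adaptive Runge–Kutta (rtol 1e−10,
  atol 1e−12) with a divergence event on a configurable state bound; it
  exists to verify the algebraic equilibrium dynamically (terminal
  discrepancy < 1e−6 for stable draws), not to produce results.
- **Depletion inversion.** Y = β/(1 − α(1+β)) is the exact inverse of the
  BP ratio at fixed α; observations with α(1+β) ≥ 1 are rejected as
  inconsistent with the stated depletion rather than truncated.
- **Optimum dose** is closed-form, F/K = Y_SZ·B_max,SZ/(B_max,HC·P_HC) −
  (1+Y_SZ); a negative solution (patient net binding already at or below
  control) raises instead of clamping to zero, except the exactly-degenerate
  identical-cohort case, which yields dose 0.
- **Rounding.** Published-value comparisons use the printed decimals.
  Two printed figures are reproduced only at printed precision of their
  inputs: the drug occupancy 52.3% (exact solution 52.38% = 11/21; the
  printed number follows from substituting the dose rounded to 1.39), and
  the 67% autoreceptor-damped elevation (exact 65.7%; 66.7% from
  DA levels rounded to 0.50/0.30). The striatal activity at
  (a, b) = (0.2, 1) is accepted in [0.46, 0.47] (exact 0.4676 vs printed
  0.46). Tests document these bands explicitly.
- **Regression** is unweighted OLS with the standard two-sided slope test.

## Synthetic data generators

`generate_synthetic_depletion_study` emulates an AMPT-style imaging study:
noiseless binding-theory BPs, B_max/(1+Y) and B_max/(1+αY), each multiplied
by independent unit-mean lognormal noise of a chosen coefficient of
variation (BP is positive and imaging error scales with signal). It does
not emulate between-subject variation in the true dopamine level, scanner
drift between the two sessions (which correlates the two BPs), or
depletion-fraction heterogeneity — so recovery tests show the estimator is
correct and noise-stable, not that α = 0.3 holds in any real cohort.
`generate_synthetic_outcome_records` draws depletion responses uniformly on
[0.02, 0.45], transforms them to PFC activities, and places symptom changes
on a chosen line plus Gaussian noise; it supports exact-recovery and
seeded-noise tests of the transformation/regression pipeline, nothing more.
The per-patient depletion responses behind the published clinical
regression are not tabulated anywhere, so that fit (slope 49.6,
intercept −61.5, R² = 0.56) is documented but not asserted against real
data.

## Design choices where the design was open

- β is the *fractional* BP increase (BP_dep − BP)/BP, which makes the
  depletion inversion dimensionless and consistent with the α = 0.3 usage.
- The glutamatergic efficacy is V_ps = 1 − b_eff·P, the minimal form that
  (i) inverts the equilibrium, giving X_p = (J_d − Y/(1 − a_eff·P))/V_ps,
  and (ii) makes the SZ−HC efficacy difference independent of the
  autoreceptor coefficient, as the cross-cohort analysis requires.
- Missing occupancy cells are represented as absent, never zero; averages
  skip them.
- Percentages are stored as fractions; formatting to "%" happens only in
  the reporting layer (CLI prints percents with one decimal, dopamine
  levels with three).

## Problem sizes

Every reported quantity is a closed form or a one-dimensional fixed point;
sweeps use grids of ~10–100 points, the solver-vs-oracle property uses 100
random parameter draws, Monte-Carlo recovery uses 50–1000 synthetic
subjects, and the synthetic outcome cohorts use n = 14. The full test
suite and the acceptance script each run in a few seconds.

## Known limitations

- Mean-field equilibrium only: no stability/bifurcation analysis, no
  stochastic or spiking dynamics.
- Single-site, single-affinity D2 binding; no D1 or non-D2 pharmacology,
  no radiotracer kinetic modelling.
- Calibration rests on two point parameterizations of a small, variable
  imaging literature; no uncertainty propagation onto model parameters.
- The outcome pipeline predicts group-level tendencies through a chain of
  point transformations; it is not a per-patient clinical predictor.
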