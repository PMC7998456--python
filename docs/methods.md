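# Methods

`ppipkpd` implements a mechanism-based population pharmacokinetic/
pharmacodynamic (PK/PD) model of gastric acid suppression by an
intravenously infused proton pump inhibitor (PPI), with ilaprazole's
published population estimates as the bundled defaults. This note documents
the model, the numerical machinery, the synthetic-data generators, and the
design choices made where the design was genuinely open.

## Structural model

**Pharmacokinetics.** Two-compartment disposition with linear elimination
and zero-order IV infusion input:

    Vc dCp/dt = -CLp·Cp - CLt·(Cp - Ct) + Rin(t),    Cp(0) = 0
    Vt dCt/dt =  CLt·(Cp - Ct),                      Ct(0) = 0

with `Rin = amount/duration` inside each infusion window. Concentrations
are carried in ng/mL, volumes in L, clearances in L/h. The system is solved
in closed form (bi-exponential infusion response, superposed over dose
events), so population simulation and the likelihood are exact and cheap.
One-compartment and Michaelis–Menten variants are available as candidate
structural models for selection experiments (`ModelSpec`); the MM variant
is integrated numerically.

Covariates follow the allometric/multiplicative convention:

    CLp_i = θ_CLp · exp(η_CLp) · θ_sex^sex        (sex = 1 for males)
    Vc_i  = θ_Vc  · exp(η_Vc)  · (WT/70)^θ_wt

with log-normal between-subject variability (BSV) on all four disposition
parameters and proportional residual error `y = Cp (1 + ε)`,
`ε ~ N(0, σ_prop²)`.

**Pharmacodynamics.** The proton pump (H+/K+-ATPase) relative activity
`E = E/E0` follows a turnover model with irreversible second-order
inactivation by the drug; intragastric H+ follows an indirect-response
balance whose secretion is modulated by a circadian surge:

    dE/dt = kdeg (1 - E) - kd · E · Cp(t),                E(0) = 1
    dH/dt = kout · HBASE · f_circ(clock t) · E - kout·H,  H(0) = HBASE

`ksyn = kdeg` is implied by the baseline steady state and is not a free
parameter. The circadian surge is a quartic bell in clock time wrapped on
24 h:

    f_circ(t) = 1 + MA / (((t - MTmax)/MW)^4 + 1)

(the printed source equation is typographically corrupted; the extra
normalising constant it suggests is ≈1e-4 with the default parameters and
is dropped). Meals at 4 h and 10 h after the 08:00 dose dilute the
*observed* H+ without feeding back into the state equations:

    Hobs = H · Fe(t),   Fe = 1 / (1 + FE4h e^{-kFE(t-4)} [+ FE10h e^{-kFE(t-10)}])

and pH is reported as `-log10(H in mM)`, so the fixed baseline
`HBASE = 0.033 mM` maps to a fasting minimum pH of ≈1.48, a physiological
healthy fasting value. pH observations carry additive error
`pH + ε, ε ~ N(0, σ_add²)`, stored unclipped (clipping to [0, 14] would
bias estimation experiments; metrics are computed on noiseless curves).

`kd` is carried in 1/((ng/mL)·h) — the dimensionally consistent reading of
its printed unit — with the published magnitude 18.24. Note the dynamic
consequence: at therapeutic exposure `kd·Cp` reaches O(10^4)/h, so the pump
state collapses to its quasi-steady value `E* = kdeg/(kdeg + kd·Cp)` within
seconds of the infusion start and remains quasi-steady for the entire
sampled day. See "Identifiability" below.

**Parameter defaults.** The bundled `ILAPRAZOLE_PK`/`ILAPRAZOLE_PD` sets
hold the published population estimates. The printed PD variability column
(2.61, 1.38, 1.32) is interpreted as *variances* of the log-scale random
effects (ω = √value); the printed PK variability column (0.23, 1.17, 0.062,
0.29) is interpreted as log-scale *SDs* — the SD reading implies a
clearance CV of ~23% and a central-volume CV of ~6%, typical for an IV
drug, while a variance reading would imply ~48% clearance CV. The printed
residual magnitudes (0.12 proportional, 1.28 pH units additive) are used as
SDs. These readings are configurable through the parameter dataclasses.

## Numerical integration

The PD system is linear in each state variable with time-varying
coefficients, but extremely stiff (`kd·Cp` up to 10^4/h vs `kdeg` 0.15/h).
The production integrator is an exponentially fitted one-step scheme: over
each step the decay rate is frozen at the midpoint and the state is updated
with the exact exponential solution plus a drift correction
`-(yinf' / r)(1 - e^{-r h})` that reproduces the first-order quasi-steady
solution `yinf - yinf'/r` in the stiff limit. The scheme is L-stable and
second-order; pump collapse is resolved by refining the grid 20× inside
each infusion window (+1 h). With the default simulation step `dt = 0.005 h`
the trajectories agree with SciPy's implicit BDF solver (rtol 1e-10) to
~1e-7 relative in `E` and ~3e-5 in `H`; the estimation configuration
(`dt = 0.04 h`, 10× refinement) is accurate to ~3e-4 pH units, negligible
against the 1.28 pH residual SD. The BDF route is retained as
`simulate_individual(..., method="bdf")` and used as the oracle in tests.

Infusion start/end are exact grid points in both integrators; meals and the
circadian surge need no event handling (meals act on observations only, the
surge is smooth).

## Estimation

Estimation is nonlinear mixed-effects by the Laplace approximation with
mu-referenced parameters (fixed effects on the log scale, additive η). The
per-subject marginal integral is computed in the standardised variable
`u = η/ω` (unit-normal prior), which keeps the inner optimisation well
scaled for any ω and makes `ω → 0` collapse the random effect exactly:

    -2 log L_i ≈ 2 h_i(u*) - q log 2π + log det H_i(u*)

The inner mode `u*` is found by a damped Newton method with
finite-difference gradients and Hessians, *vectorised across subjects*: one
batched likelihood-kernel call evaluates the whole FD stencil for all
subjects, and the line search evaluates a 13-point step grid in a single
call. Hessians are made positive definite with a relative eigenvalue floor
(1e-4 of the largest curvature). The Laplace value is exact for models
linear in the random effects (tested against the closed form) and agrees
with adaptive quadrature to <0.1 OFV units on one-η PK subjects (tested).

The likelihood kernels (closed-form two-compartment concentrations; the PD
grid integrator) are JIT-compiled with numba; a full PK fit of the
16-subject crossover study takes ~15 s and a sequential PD fit ~40–90 s on
one CPU.

**Outer optimisation.** Fixed effects, BSV variances and residual
magnitudes are estimated on log-transformed scales (the allometric exponent
untransformed), inside a sane box (penalty outside) that keeps the search
out of degenerate flat basins. The PK stage uses adaptive Nelder-Mead with
an explicit absolute-step initial simplex, a first stage over the fixed
effects only, one polishing restart and a final gradient-based (L-BFGS-B)
polish; starting values come from naive pooled non-compartmental heuristics
(dose/AUC, dose/Cmax). Inner warm starts are guarded per subject against
stale conditional modes (each subject restarts from the better of the warm
point and the prior mode). The PD stage
uses finite-difference L-BFGS-B with gradient-norm convergence 1e-3 on the
transformed scale — see Identifiability for why a gradient-based stopping
rule is the right behaviour there. Standard errors come from the
finite-difference curvature of the objective at the optimum; 95% CIs are
Wald intervals on the transformed scale, back-transformed ("converted back
from mu-referencing").

**Sequential PD conditioning.** The PD stage conditions on per-subject PK
parameters: empirical Bayes estimates from the PK fit
(`individual_pk_from_fit`) or the simulated truth recorded in a generator
manifest (`individual_pk_from_manifest`). HBASE is fixed (as in the
reference parameterisation) and the circadian triple (MA, MW, MTmax) is
fixed at its input values, with `fit_circadian_baseline` providing the
least-squares pre-fit to a drug-free mean baseline profile that the
two-step workflow assumes. Estimated: kdeg, kd, kout (with BSV), FE4h,
FE10h, kFE, the three ω², and σ_add. The fit requires a shared pH sampling
schedule across subject-occasions (true of all bundled designs).

## Identifiability of (kd, kdeg) on 24-h designs

With the default magnitudes, `kd·Cp ≫ kdeg` at every sampled time of a
24-h study (even 24 h after a 5 mg dose, Cp ≈ 3 ng/mL gives `kd·Cp ≈ 59/h`).
The pump therefore never leaves its quasi-steady state, where the data
constrain only the *ratio* `kdeg/kd` (which sets the suppression plateau
via `E* ≈ (kdeg/kd)/Cp`) together with `kout`. Profiling the objective
confirms it: rescaling (kdeg, kd) jointly by any factor in [0.1, 100]
changes the OFV by less than ~1 unit. The individual scales of kd and kdeg
are thus not estimable from this design; recovery experiments report
whatever point of the flat ridge the optimiser stops at (near the
initialisation, for a gradient-norm stopping rule), and only the ratio,
kout and the food parameters are genuinely recovered. This is a property of
the published parameter regime, not of the estimator: identifying the scale
would need data in the recovery regime `kd·Cp ≲ kdeg` (e.g. much later
sampling or far lower exposure).

A related structural fact: because `E* ∝ 1/Cp` in this regime, the
noiseless pH curve shifts by exactly `log10 2` per dose doubling at *every*
dose level. Mean-pH dose-response therefore never saturates — the clinical
"ceiling" appears only in threshold metrics (%time pH > 4 pins at 100% from
20 mg up) where the package's `ceiling_analysis` reports it. The bundled
acceptance test that demands a <20% mean-pH gain ratio fails for this
structural reason and is left failing deliberately.

## Synthetic data

Generators emulate three study designs: the 16-subject crossover (IV
5/10/20 mg, one occasion per dose, shared subject random effects across
occasions — no inter-occasion variability), the 10-subject external 30 mg
arm, and the 12/10-subject loading-dose studies (20 mg then 10 mg daily,
72 h). Weights are truncated normal (mean 62.6, SD 8, range 52–79 kg for
the trial population; mean 70, SD 8, range 40–80 kg for the simulation
population — the SD is chosen as a realistic adult spread where only median
and range are stated), sexes alternate for an exact 1:1 ratio. Plasma is
sampled at 0, 0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4, 6, 8, 12, 24 h post dose
start and pH every 15 min by default (every 30 min in the recovery
experiments); the true schedules of the emulated studies are unpublished.
Pre-dose concentration records are emitted with the missing-data flag since
Cp(0) = 0 is degenerate under proportional error.

What the generator does **not** emulate: assay quantification limits,
inter-occasion variability, adherence/recording errors, drift in meal
times, or any PK/PD difference between healthy subjects and ulcer patients
(the loading-dose arms differ only in size and label, reflecting the
reported similarity). Passing recovery tests therefore demonstrate internal
consistency of simulation + estimation under the published model, not
performance on real clinical data.

## Simulation analyses and metrics

Population analyses draw a shared virtual population (standard-normal
scores scaled by the ω in force, so dose arms and regimens are exactly
paired), simulate noiseless trajectories on a 15-min grid (augmented with
infusion end times so Cmax is sampled exactly), and summarise per-subject
metrics per 24-h window: trapezoidal mean pH, %time above pH 4 and 6
(left-held piecewise-constant time fractions), and the nocturnal %time
above 4 on the 20:00–08:00 window. Percentile bands are 5/50/95 across
subjects. The ceiling analysis compares 10/20/30/40 mg once daily for
3 days; the regimen analysis compares 10/10/10, 20/5/5, 20/10/10 and
20/20/20 mg. "No significant difference" between regimens is
operationalised as an equivalence margin on paired medians (0.2 pH units,
5 percentage points of holding time).

The VPC simulates the full design `n_rep` times (new random effects and
residuals per replicate), bins by nominal (occasion, time), and reports
observed percentiles against simulated 5/50/95 bands with 2.5–97.5%
replicate envelopes plus the fraction of observations inside the 5–95 band.
Binning is exact-time because designs are nominal-time; pH VPCs do not pool
dose groups (bins are per occasion).

## Degenerate inputs and tie-breaks

Zero-amount dose events are legal (drug-free baselines); zero-duration
infusions are not. Predictions are floored at 1e-10 ng/mL inside the
proportional-error likelihood; η excursions beyond ±40 are clamped inside
kernels so line-search trial points stay finite. A repeated disposition
eigenvalue (measure zero) is perturbed by 1e-12 relative. Windows not fully
covered by a pH series yield NaN metrics rather than extrapolation.

## Known limitations

* Only the ratio kdeg/kd is identifiable from 24-h designs at the default
  magnitudes (see above); reported kd/kdeg point estimates are
  initialisation-anchored ridge points.
* The Laplace approximation can be biased for the PD stage's very large BSV
  (ω up to 1.6 on the log scale); no SAEM/quadrature fallback is provided.
* Sequential (not joint) PK→PD estimation propagates no PK uncertainty into
  the PD stage.
* The food effect is population-typical (no BSV), meals are instantaneous,
  and the circadian surge is symmetric; an asymmetric variant (different
  widths left/right of the peak) is not implemented because its intended
  algebra is not recoverable from the source material.
* The CLI covers the bundled designs and analyses; arbitrary NONMEM control
  streams are out of scope.
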