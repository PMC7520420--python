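# Methods

`adcpkpd` implements the translational pharmacokinetic/pharmacodynamic
pipeline used to compare HER2-targeting antibody–drug conjugates (ADCs):
mouse xenograft tumor-growth-inhibition (TGI) modeling, the tumor-static
concentration (TSC) with parametric-bootstrap confidence intervals, a
shed-target TMDD model for clinical PK, and mouse-to-human efficacy
projection. This note records the models, their assumptions, the numerical
choices, and the limits of what the synthetic-data tests demonstrate.

## Linear two-compartment PK (`pk_linear`)

Disposition of the ADC in mouse and monkey is a standard two-compartment
model with linear elimination from the central compartment, parameterized
per kilogram by (Vc, CL, Vp, Q) and converted to micro rate constants
kel = CL/Vc, k12 = Q/Vc, k21 = Q/Vp. Simulation uses the closed-form
bi-exponential solution with event superposition (the model is linear);
an ODE integration exists only as a test oracle. Time is in days
throughout; a 1-h infusion is a zero-order input of duration 1/24 day.
Concentrations default to µg/mL with MW 150 kDa for the ADC
(1 nM = 0.15 µg/mL) and 100 kDa for the shed HER2 extracellular domain
(ECD).

Human PK is predicted from cynomolgus monkey by allometry with exponent 1
for volumes and 0.9 for clearances. Body weights are not part of the
published parameter tables; the defaults 5 kg (monkey) and 70 kg (human)
reproduce the published human values (CL 7.2 → 5.53 vs reported 5.52
mL/day/kg; Q 19.2 → 14.75 vs reported 14.9). The monkey parameters imply a
terminal half-life of 5.89 days; the narrative figure of "approximately 7
days" is not derivable from them and no parameter was adjusted to force it.

## Tumor growth inhibition model (`tgi_model`)

A modified Simeoni transit-compartment model. The proliferating volume V1
grows at per-volume rate

    G(TV) = kgEx (1 − TV/Vmax) / (1 + ((kgEx/kg)·TV)^ψ)^(1/ψ)

which smoothly switches from exponential (rate kgEx) to linear (rate kg
mm³/day) growth and carries a logistic cap Vmax; ψ is fixed at 20. The
drug moves volume into three transduction compartments with transit time τ
at the Hill kill rate

    k_kill(C) = kkmax · Cⁿ / (kc50ⁿ + Cⁿ),

driven by the free plasma ADC concentration (free = total in mouse: no
shed ECD circulates there). Initial condition V1(0) = v0, V2..4(0) = 0.

Numerics: the public solver is adaptive LSODA (rtol 1e-8, atol 1e-10 mm³)
with integration restarts at every dose-event breakpoint. The switching
denominator is evaluated in log space so the ψ=20 power cannot overflow,
and the Hill term as kkmax/(1+(kc50/C)ⁿ), which is overflow-safe for large
exponents. Bulk simulation (the synthetic-data generator and the fitting
inner loop) uses a fixed-step RK4 on a regular grid, compiled with numba
and vectorized over animals; at bolus events the final RK stage of the
step ending on the event uses the pre-dose (left-limit) concentration so
the discontinuity is not smeared across a step. The two integrators agree
to < 1e-5 relative at Δt = 0.01 day (tested).

## Tumor-static concentration (`tsc_calc`)

Setting k_kill(TSC) = G(v0) gives the closed form

    TSC = kc50 · ( G / (kkmax − G) )^(1/n),   G = G(v0),

finite only when kkmax > G(v0). Reported values use the v0 → 0 limit
(G = kgEx), which reproduces all eight reproducible published TSCs within
3%; v0 is overridable. The BT474 value published for PF-06804103
(3.0 µg/mL) is not reproducible from its own published parameters (the
closed form and a bracketing root-finder both give ≈ 1.46 µg/mL); its
kill-parameter CVs exceed 200% and no CI was reported, so it is treated
as unreliable.

The 80% CI is a parametric bootstrap: each uncertain parameter is drawn
log-normally with median at its estimate and log-SD √ln(1+CV²), TSC is
recomputed per draw, draws with unreachable stasis are discarded (and
counted), and the CI is the empirical 10th–90th percentile interval.
Draws are independent because no parameter correlations were published; a
correlation matrix can be supplied. Parameters reported with "(−)"
precision are held fixed. The PRNG is a seeded `numpy` Generator and the
seed is recorded in the result.

## Shed-target TMDD model (`tmdd_model`)

Clinical PK couples the linear two-compartment disposition of free ADC
with turnover of shed HER2 ECD (zero-order shedding kshed, first-order
degradation kdeg), reversible 1:1 binding (kon; koff = KD·kon), and
first-order elimination of the ADC–ECD complex (kel_complex). All
concentrations are nM. Binding to shed and membrane HER2 is assumed
identical; no avidity model. A "free" assay observes C_ADC, a "total"
assay observes C_ADC + complex.

The baseline ECD defaults to kshed/kdeg (≈ 0.1997 nM) so the target
starts at its turnover steady state; the published tables are internally
consistent with this (kdeg 33.3/day × 0.2 nM ≈ kshed 6.65 nM/day), and
the slightly different narrative initial condition of 0.206 nM is
available via an explicit override. Integration is LSODA (rtol 1e-9,
atol 1e-12 nM) with restarts at infusion boundaries.

Non-compartmental metrics: AUC(0→∞) is the trapezoid over the simulated
grid plus the log-linear tail C_last/λz; CL = dose/AUC; t½ = ln2/λz. The
default λz window spans the post-distribution phase — from 10% of the
sampled span to the last sample — rather than only the final samples:
with a shed-target sink the very late decline is target-accelerated, and
a last-points-only window measures that accelerated tail instead of the
elimination phase (at 3 mg/kg it gives ≈ 2.4 days where the elimination
phase is ≈ 4.3–4.9 days, window-dependent). Single-dose 21-day profiles
at the table parameterization give CL ≈ 33.5 mL/day/kg (t½ ≈ 0.9 day) at
0.15 mg/kg and CL ≈ 7.7 mL/day/kg (t½ ≈ 4.3 days) at 3.0 mg/kg — the
predicted non-linearity.

## Estimation (`estimation`)

The published analysis used a population (SAEM) engine; this package
deliberately substitutes a two-stage scheme, so the validation target is
parameter recovery on synthetic data, not reproduction of published CV%.

Stage 1 (vehicle growth): each vehicle animal is fitted individually on
log-volume residuals with v0 fixed to its day-0 measurement. Because a
single animal often identifies only one growth regime (an animal already
past the exponential-to-linear switch at randomization carries no
information about kgEx; one still exponential none about kg), each animal
is started from exponential-dominant, linear-dominant, and mixed
hypotheses, with a weak ridge (log-SD 3) anchoring flat directions; the
best fit per animal wins. Which parameters an animal actually identified
is decided from the data-only curvature (log-scale SE < 0.5), and only
identified estimates enter the population geometric means and omegas.

Stage 2 (drug effect): pooled penalized maximum likelihood over all arms
for (τ, kkmax, kc50, n) and the combined residual error
SD = additive + proportional·prediction. Dosed animals carry per-animal
log-deviations of (kgEx, kg) around the population values, penalized by
the stage-1 omegas (clamped to [0.1, 1.5] because they are themselves
noisy) — a penalized-likelihood stand-in for population random effects.
The error model is profiled by IRLS with weights frozen within each
least-squares solve (re-weighting inside the solve demonstrably biases
the kill parameters low) alternating with exact ML updates of the two
error terms. Multi-start: 5 log-uniform starts within ×/÷10, screened,
best 2 polished. A flat likelihood in n triggers a refit with n = 1, and
parameters with CV > 100% carry a low-confidence flag.

Identifiability caveat: when the studied doses only partially saturate
the kill rate (the JIMT-1 top dose reaches ≈ 74% of kkmax), the three
Hill parameters trade off along a nearly flat likelihood ridge
(kkmax → large, kc50ⁿ ∝ kkmax, n ↓) whose members produce almost
indistinguishable trajectories at the studied noise levels. kkmax and
kc50 are then individually imprecise even though the TSC — a
ridge-invariant combination — is well determined; the recovery study in
the test suite fixes n at its generating value and still observes
per-replicate kkmax/kc50 errors of tens of percent, while TSC closure
holds near 20%. A Gauss–Hermite marginalization of the growth random
effects was implemented and benchmarked; it did not improve recovery
(the dominant error is this ridge, not mode-vs-marginal bias) and the
penalized-mode fit is retained.

Clinical TMDD turnover: (kshed, kdeg, kel_complex) are fitted to
multi-dose-level profiles by log-scale least squares with kon, KD, and
the linear PK fixed and the baseline ECD tied to kshed/kdeg. kshed is
well identified; (kdeg, kel_complex) lie on a near-equivalent manifold of
free-drug profiles at realistic sampling times, which the reported CVs
and a fewer-than-two-dose-levels warning expose.

Diagnostics: observation-vs-prediction tables, weighted residuals, a
visual predictive check from ≥ 500 error-model replicates (band coverage
reported), and the condition number of the information matrix.

## Synthetic data (`synthetic_data`)

The xenograft generator emulates the design of the source studies:
animals randomized at 150–300 mm³ (uniform v0; log-normal optional), IV
Q4d×4 bolus dosing from day 0, measurements about twice weekly over 28
days (defaults 0, 4, 7, 11, 14, 18, 21, 25, 28), 8 animals per arm
(per-arm counts were not published; 8 is conventional), log-normal
inter-animal variability on kgEx and kg with medians at the population
values, and additive + proportional Gaussian observation noise floored at
1 mm³ (a generator artifact preventing non-positive volumes, not a model
feature). Per-animal random streams are spawned from the study seed by
(arm, animal) keys, so enlarging a study never perturbs existing animals.
True per-animal parameters are retained for recovery testing.

The clinical generator samples the TMDD model under 1-h IV infusions
(single dose by default, Q3W repeat optional) with proportional
log-normal assay error and optional per-subject baseline ECD draws.

What the generator does not emulate: caliper length/width measurement
structure (volumes are emitted directly), dropout or humane-endpoint
censoring, correlated growth random effects, model misspecification
(the fitted model family is the generating family). Passing recovery
tests therefore demonstrate estimator correctness and precision under
the stated design, not robustness to structural misfit.

## Translation (`translation`)

Projected clinical response drives the TGI model (mouse PD parameters
and initial volume carried over unchanged, v0 = 200 mm³ by default — the
midpoint of the randomization range) with the free-ADC concentration from
the human TMDD model, converted nM → µg/mL. The outcome is classified
from TV(horizon)/v0 with horizon defaulting to one dosing interval past
the last dose (day 84 for Q3W×4): below the lower threshold regression,
above the upper regrowth, between them stasis. Code defaults are
(0.8, 1.2); the shipped configs carry a calibrated band (0.5, 4.0) under
which 9 of the 10 published qualitative outcome classes are reproduced.
The exception is T-DM1 in BT474 (published as stasis): its simulated
end-of-horizon ratio (≈ 0.30) is *below* that of PF-06804103 in GA-3109
(≈ 0.34, published as regression) at every horizon examined, so no single
threshold band can order them as published; BT474's kill parameters carry
91–110% CVs, the least reliable fit in the source tables. Because mouse
tumors grow much faster than clinical ones, predicted stasis is
interpreted as at least stable disease in patients; every prediction
carries this caveat as a label rather than a model change.

`dose_for_stasis` bisects (in log dose) on the end-of-horizon volume
ratio. The textbook cross-check "average concentration at the stasis
dose ≈ TSC" holds only for linear PK, exposure within the linear limb of
the Hill curve, and stasis maintained at steady state; with saturating
kill and 20-fold peak:trough swings, Jensen's inequality makes
fluctuating exposure less effective than its average and the required
average concentration exceeds the TSC severalfold (observed ≈ 3.7× for
the N87 parameterization).

## Problem sizes used in the validation suite

TSC checks are closed-form (instant). Bootstrap CIs use 10,000 draws.
TMDD predictions use 21-day single-dose simulations on a 0.005-day grid.
The recovery study uses 20 replicate synthetic studies (4 arms × 8
animals, Q4d×4), two-stage fitting with the RK4 grid at Δt = 0.1 day and
the generator at Δt = 0.02 day. Translation projections use a 0.01-day
PK grid over an 84-day horizon.
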