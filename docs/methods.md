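# Methods

`infantpk` implements a complete population-pharmacokinetic workflow for oral
propranolol in infants treated for proliferating infantile hemangioma: the
structural PK models, a FOCE-I nonlinear mixed-effects estimator, allometric
covariate selection, simulation-based qualification, and Monte-Carlo
comparison of dosing regimens, exercised end to end on a synthetic emulation
of a two-group titration study (22 infants, 3 mg/kg/day BID at target dose).

## Structural models and units

The primary disposition model is one-compartment with first-order absorption
and elimination, parameterised as apparent clearance CL/F (L/h), apparent
central volume V/F (L) and absorption rate constant ka (1/h); oral
bioavailability F is not separately identifiable from oral data alone, so it
is absorbed into the apparent parameters. Doses are in mg, times in hours
since the first administration, and concentrations in ng/mL (mg/L × 1000).
Repeated dosing uses superposition of the single-dose solution

    C(t) = Σ_d  D_d·ka / (V·(ka−ke)) · (e^{−ke·Δt_d} − e^{−ka·Δt_d}),  ke = CL/V,

with the analytic limit D·ka·Δt·e^{−ka·Δt}/V applied when |ka−ke| < 1e-8·ka
(the formula's removable singularity). A two-compartment extension
(macro-constant tri-exponential) and a zero-order-absorption variant exist
for model discrimination exercises; all three are validated against an
independent ODE-integration oracle to <1e-6 ng/mL.

Trough and peak (Cmin/Cmax) are extracted by dense-grid search (default step
0.1 h) rather than analytic tmax so the same code handles irregular
multi-dose intervals; halving the grid step changes the day-7 extrema of the
typical subject by <0.1%.

## Mixed-effects model

Between-subject variability is exponential, P_i = TVP·exp(η_i) with
η ~ N(0, ω²) (lognormal parameters); the residual model is proportional,
optionally plus an additive component: y = f·(1+ε₁) + ε₂. The published
final model is

    CL/F = 19.3·(WT/6.3)^0.75·exp(η₁)   ω²₁ = 0.195  (44.2% CV)
    V/F  = 122                            (no random effect)
    ka   = 0.993·exp(η₂)                 ω²₂ = 1.75   (132% CV)
    σ²(proportional) = 0.0953            (30.9% CV)

with 6.3 kg the population median weight. CV% for variance components is
reported as 100·√(variance), the convention that maps the printed variances
to the printed CV%; the lognormal formula 100·√(exp(ω²)−1) is available but
not the default.

## FOCE-I estimation

The objective is the classical first-order conditional estimate with η–ε
interaction. Per subject, the conditional mode η̂ minimises the joint penalty
Σ_j [log g²_j(η) + (y_j−f_j(η))²/g²_j(η)] + η'Ω⁻¹η with
g² = σ²_prop·f² + σ²_add; the model is then linearised at η̂ and the subject
contributes

    log det V_i + e_i' V_i⁻¹ e_i,   V_i = G_i Ω G_i' + diag(g²(η̂)),
    e_i = y_i − f_i(η̂) + G_i η̂,     G_i = ∂f_i/∂η |_{η̂}.

The additive n·log 2π constant is omitted (the convention of the standard
estimation tools in this field); oracle comparisons against exact likelihoods
add it back explicitly. For models linear in η and ε this objective equals
the exact −2 log marginal likelihood, which the test suite asserts to 1e-6 —
the engine's principal correctness oracle. On a deliberately nonlinear
one-subject toy problem the gap to an adaptive-quadrature evaluation of the
exact marginal likelihood is reported (typically a fraction of an OFV unit
per subject).

Numerical choices:

- **Outer problem**: Nelder-Mead on a transformed scale — log for θ and σ²,
  log-Cholesky for Ω (diagonal Ω by default; correlations estimable via
  `omega_corr`). Stopping at simplex OFV spread <0.01 and coordinate spread
  <5e-4; optional seeded jittered multi-start (default 1 start).
- **Inner problem**: damped Newton on η with an analytic Jacobian for the
  one-compartment model (finite differences, central, relative step 1e-4,
  for other structures — the two agree to ~1e-8). The approximate Hessian
  keeps all first-derivative curvature of the interaction terms and falls
  back to the always-positive-definite Gauss-Newton form when indefinite.
  Because that map can contract slowly (or oscillate) along one direction,
  successive near-collinear steps trigger an Aitken-style geometric
  extrapolation to the fixed point, accepted only when it lowers the
  penalty. Step tolerance 1e-5 during outer iterations, 1e-9 for final
  conditional modes. All subjects' inner problems run in lockstep on padded
  arrays (padded Δt entries are 0, where every term of the superposition
  vanishes identically, so padding is exact).
- **Covariance step**: central finite-difference Hessian of the OFV on the
  natural parameter scale at the estimates (relative step 1e-3, capped at
  0.49·estimate for positivity-bounded parameters); Cov = 2·H⁻¹,
  RSE% = 100·SE/|estimate|, CI = estimate ± 1.96·SE with no clipping (a
  variance CI may legitimately include 0, flagging an uninformative random
  effect). A non-positive-definite Hessian yields NaN SEs and a warning,
  never a fabricated interval.
- η-shrinkage is 100·(1 − SD(η̂)/ω) (SD with ddof=1), ε-shrinkage
  100·(1 − SD(IWRES)). CWRES uses the FOCE-I linearisation at η̂
  (Cholesky-decorrelated e_i); PRED is the η=0 prediction.

## Covariate model and selection

Weight enters allometrically, TVP_i = P_pop·(WT_i/WT_med)^θ, evaluated per
occasion with that occasion's recorded weight (weights grow substantially
between D1 and D84). With the closed-form superposition this means the
concentration at an observation uses the parameters implied by that
occasion's weight across the whole dose history — an approximation to
piecewise integration of a time-varying ke that the generator and the
estimator share, so simulation/estimation closure is exact; a baseline-only
switch exists.

Selection is forward inclusion (univariate, ΔOFV ≥ 3.84, inclusive, df=1)
followed by backward deletion (remove when deletion raises OFV by <6.64,
smallest increase first). Free- versus fixed-exponent variants of the same
link (0.75 for clearance, 1 for volume) are compared by AIC = OFV + 2k since
they are not nested; note a fixed-exponent candidate has the same parameter
count as the no-covariate model, so its forward ΔOFV can legitimately be
negative.

**Inclusion power at this design**: with 22 infants whose weights span
roughly 4.4–8.6 kg in two clusters, the weight-on-clearance signal competes
against 44% between-subject variability. Across replicate synthetic studies
the forward ΔOFV for the true weight effect has median ≈8 (range −1 to 20),
giving ~70% inclusion power per replicate — the single-study significance
reported for the real data (ΔOFV 12) is typical-high. The selection test
therefore verifies the mechanics on an informative draw; under a null
(no-covariate) generator the false-inclusion rate of the free-exponent
candidate is consistent with its nominal 5%.

## Synthetic study generator

The generator reproduces the study design: 10 infants aged 50–89 days and 12
aged 95–151 days at inclusion; titration 1 → 2 → 3 mg/kg/day in weekly
steps, split into two equal administrations (≈08:00 and ≈17:00, the evening
dose before the PK day moved to 20:00 so the PK day starts a regular 12-h
interval); trough samples at D7 and D14 and a 6-sample PK profile (predose,
1, 2, 4, 6, 9 h) at D28 (younger group) or D84 (older group) — 8 samples per
infant, 176 in total. Doses are recomputed from the current weight.

Weights follow group median curves (4.8→5.6 kg and 6.2→7.65 kg across
visits, linearly interpolated in time) scaled by a per-subject lognormal
factor with SD(log) 0.13, matching the reported ~13-16% CV per visit and
guaranteeing monotone growth; the older group's published per-visit medians
cross slightly (different n per visit), so a monotone adjusted curve is
used. Exact individual weights and ages are unpublished: the generator
matches summary statistics only, which is the main caveat wherever simulated
medians are compared against the study's printed ones.

Concentrations below the 0.5 ng/mL quantification limit become flagged BLQ
rows carrying no numeric value; cleaning excludes them (as the source
analysis did, rather than a censored-likelihood treatment), can drop
missing-sample/missing-time rows, and applies a configurable ±4 weighted-
residual outlier rule; an optional injector multiplies one PK-day
observation to exercise it. Sampling-time jitter (default off, SD 0.25 h
when enabled) stress-tests estimation. What the generator does *not*
emulate: real weight-age covariance beyond the group structure, dropout,
dosing non-compliance, and assay-specific error structure — so passing
recovery tests demonstrate internal consistency of estimator and design, not
robustness to those real-world features.

## Qualification and regimen simulation

VPCs re-simulate the complete design (same subjects, doses, occasion weights
and sampling times) with fresh η and ε draws, binned by nominal
time-after-dose within visit; percentiles use linear interpolation between
order statistics; percentile defaults are 5/50/95 with an override (both
5/50/95 and 2.5/50/97.5 appear in qualification practice). The
prediction-corrected variant rescales by the bin-median population
prediction, excluding (with a warning) any bin containing a non-positive
prediction. Simulation is at point estimates; parameter uncertainty is not
propagated. Coverage compares each observation with the simulated band at
its own design point; on self-simulated, uncensored data the 5th–95th band
contains ≈90% of observations (±4 points when averaged over a few replicate
studies — single-study coverage varies by ±6 points because observations
within a subject share η). BLQ-censored observed data shifts trough-bin
percentiles upward relative to uncensored simulations; self-consistency
checks therefore disable censoring.

Regimen simulation replicates the virtual population (default: the 22
PK-day weights from the study generator) 1000 times with fresh η per
subject, computes each virtual infant's concentration profile over 7 days of
dosing (ample for steady state at a 4–5 h half-life) and extracts Cmin/Cmax
over the final 24 h on a 0.1 h grid; Cmin is a true window minimum so the
long interval of irregular schedules is captured. Exposure metrics exclude
residual error by default (they are model-predicted quantities; a switch
includes it). The four built-in schedules at 3 mg/kg/day: regular BID
(08:00/20:00), irregular BID (08:00/17:00), TID 08:00/14:00/20:00 and TID
08:00/12:00/20:00.

**Reproducibility caveat for the published regimen table.** Under this
procedure the simulated median Cmax for regular BID lands within ~8% of the
published 61.8 ng/mL and the irregular-BID median-Cmax difference (~9%)
matches the published <10%. Two published values could not be reproduced
from the published model under any variant we examined (exact group-median
weights, paired η draws, percentile-curve-derived extrema, residual-error
inclusion, whole-week minima): the published regular-BID median Cmin
(14.0 ng/mL) sits below the model's own typical-subject steady-state trough
at the study weights (≈16–19 ng/mL), and the model's analytic 15-h/12-h
trough ratio for the typical subject is ≈0.69 — a ~30% drop, versus ~17%
published — while the published Cmax ordering places the 4-h-gap TID
schedule lowest, which superposition of a linear model cannot produce. The
package reports what the stated model and procedure actually yield; the
corresponding comparisons are expected to exceed the published <5%/<20%
bounds for the evenly spaced TID Cmax (~6–7%) and the irregular-BID Cmin
(~27–30%).

## Problem sizes and determinism

Default problem sizes: 1000 replicates for VPC/coverage and regimen
Monte-Carlo; 20 replicate studies for recovery checks; 10 replicate studies
for the null false-inclusion rate. Every stochastic routine takes a seed and
is reproducible bit-for-bit given it; replicate-study seeds are drawn from a
seeded generator and kept below 2³¹.

## Known limitations

- BLQ handling is exclusion, not a censored likelihood (M3); at this
  design's BLQ incidence (a few of 176 samples) the induced bias in θ̂ is
  well inside the recovery tolerances.
- Ω blocks beyond simple correlation structures, SAEM/EM estimators,
  Bayesian estimation, lag-time and transit-compartment absorption are out
  of scope.
- The FOCE-I linearisation error is quantified only on a toy problem; no
  SAEM/importance-sampling reference is available in-package.
- The covariance step assumes an interior optimum; variance components
  estimated at (or collapsing toward) zero are flagged as boundary cases and
  their SEs are unreliable, mirroring the practice of dropping such random
  effects from the model.
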