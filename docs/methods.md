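# Methods

This note records the model the package implements, the choices made where
the design was genuinely open, the numerical machinery, and what the
synthetic-study generator does and does not emulate.

## Structural model

One-compartment disposition with zero-order (infusion) input and a
time-varying total clearance composed of two parallel pathways:

* **Intrinsic clearance** rises logistically from an early value `CL1` to
  a late value `CL2` with midpoint `Tswitch` (h) and slope `k` (1/h).
  This is an empirical description of metabolic recovery in critical
  illness (inflammation-mediated CYP suppression resolving, corticosteroid
  induction, restored hepatic perfusion); the package makes no attempt to
  separate those mechanisms.
* **Sequestration clearance** decays mono-exponentially from `CLseq0` with
  half-life `Thalf_seq`, an apparent first-order loss into the ECMO
  circuit that vanishes as tubing and oxygenator surfaces saturate.

The time origin for both clocks is the first voriconazole dose. A
configurable offset between circuit cannulation and first dose could be
layered on by shifting dose times, but the default and all shipped
analyses use t = 0 at first dose; in the emulated cohort most patients
started drug within a day of cannulation, and the data cannot distinguish
the two clocks.

Units are fixed throughout: hours, mg, litres, mg/L, L/h.

### Concentration solver

`dA/dt = R(t) − CL_total(t)/V · A` is linear, so

`A(t) = ∫ R(s) · exp(−G(s,t)/V) ds`, with `G(s,t)` the clearance
accumulated on `[s,t]`. `G` is closed-form: the logistic pathway
integrates to a softplus (evaluated overflow-safely via `logaddexp`), the
sequestration pathway to an exponential. The convolution is evaluated
per infusion segment by fixed-order Gauss–Legendre quadrature; because
segments never exceed an infusion duration (~2 h), order 20 (the
`model_core` default) and even order 10 (used inside estimation, where
the solver is called millions of times) agree with adaptive stiff ODE
integration to ~1e−9 relative on randomized configurations — the test
suite asserts 1e−5 on 100 such configurations, plus superposition and
mass-balance invariants. Two equivalent evaluation paths exist (a direct
masked source-sum for short observation vectors and a breakpoint
recurrence for dense grids); both keep every exponent non-positive, so
the solver cannot overflow.

## Population model

Log-normal random effects (diagonal omega) on `V`, `CL1`, `CL2`,
`Tswitch`; `k`, `CLseq0`, `Thalf_seq` carry no inter-individual
variability. Omegas are stored as %CV in the parameter file and converted
via `CV% = 100·sqrt(exp(ω²)−1)`. The CYP2C19 covariate multiplies `CL2`
by `exp(β)` for carriers of reduced-function alleles; the reference class
is NM ∪ RM ∪ UM and the shifted class IM ∪ PM. Assigning the single
ultrarapid metabolizer to the reference class is a judgment call — the
cohort contained one UM and one PM, far too few to resolve a five-level
effect. Residual error is combined: `y = f(1+ε_p) + ε_a`; negative draws
are floored at zero and flagged (none occur above the LLOQ in practice).

## Estimation

`LaplaceNLME` maximizes a Laplace-approximated marginal likelihood:

* **Inner problem** (per subject): the joint negative log density over the
  active etas is minimized by Levenberg–Marquardt. The gradient is
  analytic given the Jacobian of predictions with respect to eta (central
  finite differences on the smooth prediction map only — the sharp
  residual-variance terms are differentiated analytically), and the
  curvature is the Fisher/expected-information matrix, positive
  semidefinite by construction. A warm start that is worse than the prior
  mode is discarded, so the returned mode always dominates eta = 0.
  Subjects sharing one design geometry (identical sampling times and dose
  schedules, as in the rich recovery studies) are solved in lockstep with
  fully batched solver calls.
* **Laplace log-determinant**: the expected-information matrix at the
  mode. This is the FOCE-interaction flavour of the approximation; it
  coincides with the exact negative Hessian whenever the prediction is
  linear in eta with additive error, which the test suite exploits as an
  analytic oracle (agreement to 1e−8 with the closed-form marginal
  Gaussian integral).
* **Outer problem**: fixed effects on the log scale (β unconstrained)
  with generous box bounds, optimized by BFGS with an Armijo backtracking
  line search (function-only trials; one-sided finite-difference
  gradients). Empirical-Bayes reference modes are *frozen* during each
  optimizer run and re-anchored between runs; the fit alternates
  anchor/optimize cycles until the anchored −2LL stops improving. Frozen
  references make the objective a deterministic pure function — updating
  them inside the objective lets line-search excursions leave the inner
  solver in secondary modes and corrupts finite-difference gradients (a
  failure mode observed directly during development).
* **Uncertainty**: finite-difference Hessian of −2LL at the optimum
  (relative step 1e−4, one Richardson extrapolation step); covariance
  `2·H⁻¹`; RSEs on the log scale for log-parameterized effects; Wald CIs
  `est·exp(±1.96·RSE/100)`.
* **Model comparison**: `AIC = −2LL + 2p`, `BIC = −2LL + p·ln(n_obs)`;
  the stepwise covariate rule uses ΔOFV ≥ 3.84 forward / ≥ 6.63 backward
  (χ², 1 df).

The original analysis used SAEM in commercial software; this package
deliberately substitutes the deterministic Laplace approach, which is
testable at desk scale. Equivalence is claimed only at the level of
parameter recovery, not algorithm. `k` is always fixed at 0.1/h. The
sequestration parameters `CLseq0` and `Thalf_seq` are estimable but are
fixed at their initial values in the shipped recovery experiments: their
published RSEs exceed 80%, and sparse early sampling leaves them weakly
identified, so freeing them mostly adds optimizer travel without
informing the parameters the experiments assess. Below-LLOQ observations
are excluded from the likelihood with a counted warning.

## Synthetic studies

`simulate_study` emulates the trial design: 31 subjects; weights from a
truncated normal (mean 87 kg, SD 20, bounds 49–134 — the cohort reports
only mean and range, the SD is this package's choice); metabolizer mix
12 NM / 12 IM / 5 RM / 1 PM / 1 UM (exact or multinomial); label dosing
on actual sampled weight (virtual subjects carry no height, so the
adjusted-body-weight rule — implemented and tested for real datasets —
is not triggered); protocol sampling of a near-peak (1–3 h
post-infusion), an elimination sample (5–7 h) and a pre-dose trough
anchored to one dosing interval in days 1–5, plus single troughs in days
6–10 and 11–14; dropout drawn from the cohort's ECMO-duration strata
(32.3 / 25.8 / 12.9 / 29.0% for ≤5 / 6–10 / 11–14 / >14 days) with
uniform placement inside a stratum, truncating both dosing and sampling;
LLOQ 0.01 mg/L with flagged-not-deleted censoring. The "0–5 day"
stratum starts at half a day so every subject retains a samplable
window, matching the cohort where the earliest first sample was drawn
2.6 h after the first dose. Per-subject observation counts land in the
cohort's 1–7 range. True individual parameters and noise-free
concentrations are retained in a truth table.

`simulate_rich_study` is the recovery workhorse: every subject sampled at
the same 12 times (near-peak, mid-interval and trough in four intervals
spanning days 1–14), no dropout, single metabolizer class by default so
the genotype coefficient is inert and the typical `CL2` is the
reference-class value.

What the generator does *not* emulate: circuit changes mid-therapy,
venoarterial vs venovenous differences, inflammatory-marker trajectories,
TDM-triggered dose adjustments, and any correlation between random
effects. Passing tests therefore demonstrate internal consistency of the
machinery under the published model, not fidelity to any new clinical
population.

## Dosing simulation

Virtual patients (weights, genotypes, etas) are dosed per weight-based
presets (`smpc`, `escalate-6`, `escalate-8`; 12-h intervals, 2-h
infusions, whole-mg rounding) and evaluated on an hourly grid.
Probability of target attainment classifies the *model-predicted*
concentration at 48/168/240 h against the closed window [2, 5.5] mg/L —
residual (assay) error is excluded by default because attainment concerns
true exposure; a flag includes it. Doses are scheduled strictly before
the horizon, so an evaluation time that coincides with a dose reads the
pre-dose (trough) concentration. The default population size is 1,000
virtual patients, overridable.

One caution on summaries: with all four log-normal effects active, the
simulated *median* profile is not the typical-subject profile — near the
clearance transition the nonlinear mixture skews the median by up to
about two-fold. The log-normal median property holds (and is tested)
only for a single active effect with a monotone concentration–parameter
relation at the evaluated time.

## Diagnostics

* **pcVPC**: observed and simulated values are multiplied by (bin median
  of typical predictions)/(typical prediction); empirical 5th/50th/95th
  percentiles per bin are compared with 90% prediction intervals of the
  same percentiles over `n_sim` replicate datasets simulated at the
  original design. Default bins follow the protocol windows (0–12,
  12–48, 48–120, 120–240, >240 h).
* **NPDE**: per subject, observed and simulated vectors are decorrelated
  with the simulation mean and Cholesky factor of the simulation
  covariance; ranks map through Φ⁻¹((rank+0.5)/(n_sim+1)); ties are
  jittered within half a rank. Simulation randomness streams per subject
  from the base seed, so results are invariant to subject ordering.
* **IWRES**: `(y − f̂)/sqrt(σ_add² + (σ_prop f̂)²)` at the
  empirical-Bayes etas.

## Problem sizes of the shipped experiments

The recovery experiment uses 5 seeded replicates of a 50-subject,
12-sample rich design (estimates of typical V and CL2 accepted within 15%
of the generating values); the target-attainment experiment uses 1,000
virtual patients; diagnostics calibration uses a 100-subject self-simulated
dataset with 1,000 simulation replicates. These sizes give each check
enough power to be informative while keeping a full run in the tens of
minutes on a single CPU.

## Known limitations

* The Laplace/expected-information approximation shares the usual FOCE
  caveats for very sparse or highly nonlinear subjects; the marginal
  likelihood is approximate, and different inner-mode basins can shift
  −2LL by a few units (the anchored-cycle scheme always keeps the better
  of the warm and prior-mode basins).
* `CLseq0` and `Thalf_seq` are poorly identified by trough-heavy designs;
  estimating them requires dense early sampling.
* The covariate machinery implements the published decision rule only for
  nested single-coefficient steps; the original study's broader covariate
  screen (CRP, ECMO flow, renal replacement, hepatic markers) is out of
  scope.
* Wald intervals reconstructed from estimate and RSE match the published
  volume row to <0.5% but deviate ~2–3% for the high-RSE rows, whose
  exact construction in the original software is unknown; the package
  documents rather than chases that discrepancy.
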