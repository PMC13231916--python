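# voripk

Population pharmacokinetics of intravenous voriconazole in critically ill
adults supported with extracorporeal membrane oxygenation (ECMO).

Voriconazole is the first-line antifungal for invasive aspergillosis, a
frequent and lethal complication of severe viral pneumonitis requiring
ECMO. Its plasma exposure during ECMO is governed by two opposing,
*time-varying* processes: early loss of drug into the circuit's tubing and
oxygenator membranes ("sequestration"), which saturates within hours, and a
delayed several-fold rise of intrinsic (hepatic) clearance as inflammation
resolves and enzyme activity recovers over the first days of support.
Standard fixed mg/kg dosing ignores both, and most patients drift out of
the therapeutic window (2–5.5 mg/L) within a week.

`voripk` implements the published dual-pathway, time-varying clearance
population model as a reusable, tested Python package for pharmacometric
analysis and dosing simulation — estimation, Monte Carlo target-attainment
analysis and model diagnostics, all exercisable end to end on synthetic
studies that emulate the original 31-patient trial design (the raw clinical
concentrations are not public).

## The model

One-compartment disposition with volume *V*, intravenous infusion input
*R(t)* and total clearance

```
CL_intr(t)  = CL1 + (CL2 − CL1) / (1 + exp[−k (t − T_switch)])
CL_seq(t)   = CL_seq0 · exp(−ln 2 · t / T_half,seq)
CL_total(t) = CL_intr(t) + CL_seq(t)

dA/dt = R(t) − CL_total(t)/V · A,      C(t) = A(t)/V
```

with log-normal inter-individual variability on *V*, *CL1*, *CL2* and
*T_switch*, a CYP2C19 covariate on late clearance (intermediate/poor
metabolizers carry CL2·e^β, β = −0.44, a 36% reduction), and combined
additive + proportional residual error. The logistic slope *k* is fixed at
0.1 h⁻¹. The published estimates (V 144.79 L, CL1 6.22 L/h, CL2
22.26 L/h, T_switch 87.96 h, CL_seq0 17.68 L/h, T_half,seq 4.17 h) ship as
the packaged default parameter set.

Because the system is linear with a time-varying coefficient, concentration
profiles are computed from the integrating-factor convolution with a
closed-form cumulative clearance (softplus + exponential terms) and
per-infusion-segment Gauss–Legendre quadrature — exact to ~1e−9 against
stiff ODE integration and fast enough for Monte Carlo and the estimation
inner loop. Population fitting uses Laplace-approximated marginal maximum
likelihood with empirical-Bayes inner optimization (`LaplaceNLME`, a
scikit-learn-style estimator).

## Worked example

```python
import numpy as np
from voripk import (default_population, simulate_study, StudyDesign,
                    fit_population, simulate_population_profiles, pta)

pop = default_population()          # published Table-style estimates

# a synthetic 31-patient study with the trial's sampling design
study = simulate_study(StudyDesign(exact_genotypes=True), pop, "smpc", seed=7)
print(study.n_subjects, len(study.observations()))
# 31 123

# Monte Carlo target attainment under label (SmPC) dosing
profiles = simulate_population_profiles(pop, "smpc", n=1000, horizon=240, seed=1)
result = pta(profiles, eval_times=(48.0, 168.0, 240.0))
print(result.table[["time", "frac_sub", "frac_therapeutic", "frac_supra"]])
#     time  frac_sub  frac_therapeutic  frac_supra
# 0   48.0     0.377             0.522       0.101
# 1  168.0     0.669             0.246       0.085
# 2  240.0     0.728             0.209       0.063
```

At 48 h roughly half of simulated patients are inside the 2–5.5 mg/L
window; by day 7 two-thirds are subtherapeutic — the early sequestration
transient has saturated and intrinsic clearance has risen toward its late
plateau, so troughs fall despite unchanged dosing. That is the clinical
message of the model: dosing needs early and repeated drug monitoring, not
a fixed escalation.

A command-line surface wraps the same functionality:

```bash
voripk synth --n 31 --seed 7 --out out/          # dataset + truth CSVs
voripk fit --data out/dataset.csv --out out/     # Laplace NLME fit
voripk pta --regimen smpc --n 1000 --seed 1 --out out/
voripk vpc --data out/dataset.csv --nsim 1000 --seed 1 --out out/
```

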