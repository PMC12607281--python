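# cbgpk — population pharmacokinetics of cannabigerol in horses

`cbgpk` implements a complete population-pharmacokinetic analysis of
cannabigerol (CBG) and its major metabolite, CBG-glucuronide (CBG-G), in
horses after intravenous (1 mg/kg, 5-minute infusion) and oral (10 mg/kg,
micellar or sesame-oil formulation) administration in a three-occasion
crossover design. It is aimed at pharmacometricians and veterinary
pharmacologists who want a transparent, fully scriptable re-implementation
of the analysis: the structural model, the nonlinear mixed-effects (NLME)
machinery, secondary exposure parameters, Monte Carlo multiple-dose
simulation, and model diagnostics, exercised end to end on synthetic data
that emulates the study design.

## The model

Parent drug: two-compartment disposition with linear elimination; the
metabolite occupies one compartment fed by a fixed fraction of parent
elimination. Amounts A₁ (central), A₂ (peripheral), A₃ (metabolite,
parent-molar equivalents), A₄ (oral depot):

    dA1/dt = r(t) − (Cl/Vc)·A1 − (Q/Vc)·A1 + (Q/Vp)·A2
    dA2/dt = (Q/Vc)·A1 − (Q/Vp)·A2
    dA3/dt = (Cl/Vc)·Fm·A1 − (Clm/Vm)·A3
    A4(t)  = F·D·exp(−(ka·t)^β),   r(t) = −dA4/dt

with C₁ = A₁/Vc and C₃ = A₃/Vm. Oral input follows a Weibull law
(β > 1: sigmoid, delayed-then-fast release; β < 1: fast-then-slow), the
bioavailable fraction F scales the depot load, and the metabolized fraction
is fixed at Fm = 0.75.

Individual parameters are log-normal around the typical values
(logit-normal for F), with between-subject (IIV) and between-oral-occasion
(IOV) random effects, a categorical formulation covariate on ka and β
(micellar reference), and proportional residual error per analyte
(C_obs = C_pred·(1 + b·ε)). Estimation is by SAEM
(Metropolis-within-Gibbs with a closed-form M-step); the marginal
−2·log-likelihood for AIC/BIC and ΔBIC covariate decisions comes from a
Laplace approximation at the empirical Bayes modes. Covariates are retained
when they reduce BIC by ≥ 10.

The solver is analytic-modal: the disposition matrix has a closed-form
spectrum, IV responses are exact, the Weibull input is convolved
mode-by-mode with Gauss–Legendre panels in u = (ka·t)^β, and interval AUCs
are exact functions of the modal state at the interval endpoints.

## Worked example

```python
import numpy as np
from cbgpk import (DoseEvent, StructuralParams, mg_per_kg_to_nmol_per_kg,
                   profile_auc, published_model, terminal_slope,
                   RegimenSpec, monte_carlo_regimen, summarize_metrics)

typ = StructuralParams(F=0.28, ka=0.99, beta=1.59, Cl=1.67, Vc=32.15,
                       Q=154.5, Vp=36.12, Fm=0.75, Clm=0.016, Vm=0.0047)
dose = mg_per_kg_to_nmol_per_kg(10.0)          # 31597.6 nmol/kg
lz, t_half = terminal_slope(typ)               # t_half = 28.4 h
reg = [DoseEvent(0.0, "oral", dose, formulation="micellar")]
profile_auc(typ, reg, 0, np.inf)               # 5297.8 nmol*h/L (= F*D/Cl)
profile_auc(typ, reg, 0, np.inf, "metabolite") # 414718 nmol*h/L (= Fm*F*D/Clm)

pop = published_model()
metrics = monte_carlo_regimen(pop, RegimenSpec(n_subjects=5000, seed=1))
print(summarize_metrics(metrics))
```

The terminal half-life of 28.4 h is the slow eigenvalue of the disposition
matrix — the long tail that governs accumulation under repeated dosing. The
oral AUCs are the linear-system closed forms: 28% of a 10 mg/kg dose cleared
at 1.67 L/h/kg, and 75% of the eliminated parent emerging as glucuronide
cleared at 0.016 L/h/kg (hence the ~78-fold molar exposure of the
metabolite). The Monte Carlo summary for 10 mg/kg every 24 h for 14 days
(micellar, n = 5000) prints, per analyte, the median and CV% of the
first-interval AUC₂₄, the steady-state interval AUC, and the per-subject
accumulation index:

```
parent     auc24        median      2162.04  CV%  32.0
parent     auc_ss       median      5249.06  CV%  34.2
parent     accumulation median         2.37  CV%  33.6
metabolite auc24        median    167451.38  CV%  49.4
metabolite auc_ss       median    408024.59  CV%  39.1
metabolite accumulation median         2.40  CV%  33.7
```

i.e. a ~2.4-fold accumulation from first dose to steady state, reached
around day 4–6 (`time_to_steady_state`), with the metabolite mirroring the
parent because its formation, not its elimination, is rate-limiting.

A command-line pipeline wraps the same functions:

```bash
cbgpk generate --seed 1 --out study.csv        # synthetic crossover study
cbgpk fit      --data study.csv --seed 2 --out fit.yaml
cbgpk nca      --data study.csv --out nca.csv
cbgpk simulate --seed 3 --formulation oil --out regimen.csv
cbgpk vpc      --data study.csv --seed 4 --out vpc.csv --plot vpc.png
cbgpk bootstrap --data study.csv --seed 5 --replicates 200 --out ci.csv
```

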