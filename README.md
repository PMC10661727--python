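# igsim

Population-pharmacokinetic simulation of serum total IgG in patients with
primary immunodeficiency diseases (PIDD) who switch from stable intravenous
immunoglobulin (IVIG) to subcutaneous replacement therapy — either
conventional SCIG at 0.15 g/kg weekly or hyaluronidase-facilitated SCIG
(fSCIG) at 0.6 g/kg every 4 weeks. The package is aimed at pharmacometricians
and clinical-pharmacology analysts who want to explore how body mass index
(BMI) and age shape steady-state IgG exposure under weight-based dosing.

## Model

Serum IgG follows a linear two-compartment disposition model with
first-order subcutaneous absorption and a zero-order endogenous synthesis
into the central compartment:

    dA_d/dt = -ka·A_d
    dA_c/dt =  ka·A_d - (CL/Vc + Q/Vc)·A_c + (Q/Vp)·A_p + k_syn
    dA_p/dt =  (Q/Vc)·A_c - (Q/Vp)·A_p

with each SC dose delivering `F·D` into the depot, where `D = dose_per_kg ×
total body weight`. Clearance-like parameters (CL, Q, k_syn) scale
allometrically with fat-free mass, `CL = CL_ref·(FFM/FFM_ref)^θ_CL`, volumes
with `θ_V`; FFM comes from Janmahasatian's equations. Inter-individual
variability is multiplicative log-normal (`exp(ω·η)`) on CL, Vc, ka and
k_syn. Because the system is linear, multi-dose profiles are computed by
analytic superposition of the tri-exponential unit-dose response plus the
decay of the IgG excess present at the switch (starting trough 7 g/L,
compartments in pseudo-equilibrium).

The core tension the model captures: doses follow **total body weight**
while IgG disposition follows **fat-free mass**. Obese adults receive
proportionally more drug than their lean mass clears, so trough IgG rises
with BMI; young children sit at the other end of the same relationship.

Virtual populations (1000 subjects per stratum) emulate NHANES-like
covariate distributions, stratified either by adult BMI (underweight /
healthy / overweight / obese) or by age band (2–<6, 6–<12, 12–<18, ≥18
years). Steady-state metrics (AUC_ss, C_max,ss, C_min,ss, C_ave,ss) are
taken over the final 28 days of a 20-week horizon, and the share of subjects
maintaining the 7 g/L protective trough is reported per stratum.

## Worked example

```python
from igsim import (PopulationSpec, Regimen, load_default_parameters,
                   run_scenario, sample_population, summarize_groups)

params = load_default_parameters()
pop = sample_population(PopulationSpec("bmi", n_per_group=500, seed=42))
res = run_scenario(pop, Regimen.scig(), params, seed=43)
for s in summarize_groups(res, "bmi", "healthy"):
    print(s.stratum, round(s.cmin_mean, 1), round(s.cmin_ratio, 2),
          s.pct_above_threshold)
```

prints

```
underweight 11.1 0.92 97.4
healthy 12.1 1.0 98.6
overweight 12.8 1.06 98.8
obese 14.5 1.2 99.8
```

i.e. the mean steady-state trough (g/L), its ratio against the healthy-BMI
reference, and the percentage of subjects at or above 7 g/L: troughs climb
roughly 20% from the healthy to the obese stratum, and nearly all simulated
patients stay above the protective threshold. The `examples/` directory has
one short script per capability (population generation, single-subject
profiles, BMI and age scenarios, calibration); a thin CLI (`igsim simulate`,
`igsim calibrate`, `igsim report`) writes the same results as CSV bundles.

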