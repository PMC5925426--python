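# infantpk

Population pharmacokinetics of oral propranolol in infants treated for
proliferating infantile hemangioma (IH). Propranolol is dosed in mg/kg and
titrated to 3 mg/kg/day given twice daily; the pharmacokinetic questions this
package addresses are the ones that drive pediatric dose rationale:

- does body weight explain the between-infant variability in drug exposure
  (so that mg/kg dosing needs no age-based adjustment)?
- are irregular twice-daily or three-times-daily schedules interchangeable
  with strict 12-hour dosing in terms of steady-state peaks and troughs?

It is written for pharmacometricians and methods-minded statisticians who
want a compact, fully tested, pure-Python implementation of this analysis
class — from dataset conventions to estimation, qualification and
simulation — without a commercial estimation engine.

## What is inside

The core model is a one-compartment disposition with first-order absorption
and elimination, lognormal between-subject variability and proportional
residual error:

    C(t)   = Σ_doses D·ka / (V·(ka−ke)) · (e^{−ke·Δt} − e^{−ka·Δt}),  ke = CL/V
    CL/F_i = θ₁ · (WT_i / 6.3 kg)^0.75 · e^{η₁ᵢ},   η₁ ~ N(0, ω₁²)
    V/F_i  = θ₂
    ka_i   = θ₃ · e^{η₂ᵢ},                          η₂ ~ N(0, ω₂²)
    y_ij   = f(t_ij)·(1 + ε_ij),                    ε ~ N(0, σ²)

Modules:

- `infantpk.pk_core` — closed-form one-/two-compartment and zero-order
  absorption models under arbitrary repeated oral dosing; exposure metrics.
- `infantpk.dataset` — NONMEM-convention CSV datasets (EVID/AMT/MDV/BLQ) and
  the study's cleaning rules (BLQ exclusion at 0.5 ng/mL, weighted-residual
  outlier band).
- `infantpk.nlme` — FOCE with η–ε interaction: conditional modes, linearised
  marginal objective, covariance step, likelihood-ratio test, AIC,
  shrinkage, PRED/IPRED/IWRES/CWRES diagnostics.
- `infantpk.covariates` — allometric weight scaling and forward-inclusion /
  backward-deletion covariate selection (ΔOFV ≥ 3.84 / ≥ 6.64, free-vs-fixed
  exponents by AIC); builders for the published base and final models.
- `infantpk.diagnostics` — VPC, prediction-corrected VPC, percentile
  coverage.
- `infantpk.regimens` — Monte-Carlo simulation and comparison of 3 mg/kg/day
  schedules (regular/irregular BID, two TID variants).
- `infantpk.synth` — synthetic study generator reproducing the trial design
  (two age groups of 10 and 12 infants, weekly 1→2→3 mg/kg/day titration,
  the 8-sample sparse sampling schedule, BLQ censoring, outlier injection).
- `infantpk.reporting` — parameter tables, individual-clearance summaries,
  regimen tables.

A thin CLI (`infantpk simulate-study | fit | select-covariates | vpc |
simulate-regimens | report`) wraps these functions.

See `docs/methods.md` for the estimation algorithm, numerical choices, what
the synthetic generator does and does not emulate, and known limitations —
including a documented reproducibility caveat about the published regimen
table.

## Worked example

```python
import infantpk as ip

model = ip.build_final_model()          # published estimates
print(model.theta)                      # {'cl': 19.3, 'v': 122.0, 'ka': 0.993}

# typical clearance of a 7.65 kg infant (older-group median weight)
from infantpk.covariates import allometric
cl = allometric(19.3, 7.65, 6.3, 0.75)
print(round(cl, 1), round(cl / 7.65, 2))   # 22.3 L/h, 2.92 L/h/kg

# simulate a study with the trial design, clean it, and re-fit by FOCE-I
ds = ip.generate_study(model, seed=4)
clean, report = ip.apply_cleaning(ds)
print(len(ds.observations), report.count("blq"))   # planned samples, BLQ drops
res = ip.fit(model, clean, ip.FitOptions(compute_se=False))
print(round(res.ofv, 1))
print({k: round(float(v), 2) for k, v in res.theta.items()})
print({k: round(float(v), 1) for k, v in res.eta_shrinkage.items()})
```

prints

```
{'cl': 19.3, 'v': 122.0, 'ka': 0.993}
22.3 2.92
176 5
881.6
{'cl': 23.17, 'v': 129.57, 'ka': 1.8}
{'cl': -0.4, 'ka': 28.2}
```

i.e. this particular synthetic study fits with a clearance fixed effect of
23.2 L/h (truth 19.3; a single 22-infant study estimates it with ~10-12%
standard error, so replicate-level spread of this size is expected — the
recovery tests quantify it over 20 replicates). Clearance-η shrinkage is
negligible while the absorption rate, weakly identified by the sparse
design, shows moderate shrinkage and a flat likelihood ridge (its estimate
here trades off against its variance at essentially unchanged fit).

Regimen comparison at 3 mg/kg/day over a virtual population:

```python
import numpy as np
from infantpk.regimens import builtin_regimens, simulate_regimen, compare_regimens
from infantpk.synth import StudyDesignConfig, generate_population

pop = generate_population(StudyDesignConfig(), seed=7)
weights = np.array([r[f"WT_D{int(r['PK_DAY'])}"] for _, r in pop.iterrows()])
sums = [simulate_regimen(model, weights, reg, 1000, seed=100 + i)
        for i, reg in enumerate(builtin_regimens())]
print(compare_regimens(sums[0], sums[1:])[
    ["regimen", "cmin_rel_diff_pct", "cmax_rel_diff_pct"]].round(1).to_string(index=False))
```

prints

```
              regimen  cmin_rel_diff_pct  cmax_rel_diff_pct
      BID 08:00/17:00               27.2                8.7
TID 08:00/14:00/20:00                7.3                6.5
TID 08:00/12:00/20:00               14.1                2.8
```

— the median peak concentration moves by under 10% across all alternative
schedules, while the irregular-BID trough drops by ~27% (its overnight
interval is 15 h instead of 12 h).

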