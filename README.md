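# busulfanpk

Population-pharmacokinetic simulation and AUC-method evaluation for
intravenous busulfan in paediatric haematopoietic stem-cell
transplantation.

Busulfan conditioning is dosed to a narrow exposure window — an AUC of
900–1500 uM·min per q6h dose — and paediatric dose individualization
hinges on how that AUC is computed from a handful of blood samples. This
package implements a two-compartment infusion model with body-weight
allometry and a syringe-pump lag-time, and uses it to ask the question a
TDM service actually faces: *given a sampling schedule, is the
label-recommended trapezoidal AUC good enough, or does a model-based
(MAP / empirical-Bayes) AUC do better?*

It is aimed at pharmacometricians and clinical-pharmacology researchers
who want a fast, fully synthetic, reproducible testbed for limited
sampling strategies.

## The model

Disposition: linear two-compartment, zero-order infusion, first-order
elimination, parameters CL, V1, Q, V2 with typical values
(10.7 L/h, 39.5 L, 4.68 L/h, 17.5 L at 70 kg) and fixed-exponent
allometry

    CL_i = CL_t (BW/70)^0.75 · exp(eta_CL + kappa_CL)
    V1_i = V1_t (BW/70)      · exp(eta_V1)
    Q_i  = Q_t  (BW/70)^0.75,   V2_i = V2_t (BW/70)

with correlated lognormal inter-individual variability on CL and V1
(SDs 0.284 / 0.409, correlation 0.679), inter-occasion variability on CL
(SD 0.105) and proportional residual error (SD 0.126). Pump dead volume
delays drug entry by a weight-band lag (40 min in infants down to 7.5 min
above 34 kg), modelled as a pure shift of the infusion start.

Three AUC estimates are compared per virtual patient:

* `AUC_true = dose / CL_true` (simulation truth),
* `AUC_bayes = dose / CL_EBE` with the empirical-Bayes clearance from a
  MAP fit of that patient's noisy samples,
* `AUC_trap`: lag-aware linear-up/log-down trapezoid plus a
  `C_last / lambda_z` tail, lambda_z from the last three samples,

scored by bias `MPE = mean(AUC_true − AUC_calc)` and imprecision
`RMSPE = sqrt(mean((AUC_true − AUC_calc)^2))`.

## Worked example

```python
from busulfanpk import (TypicalParams, allometric_scale, terminal_halflife,
                        auc_model, run_study)

typ = TypicalParams()                 # the published typical values
p = allometric_scale(typ, 15.3)       # a 15.3 kg child, typical individual
print(p.cl, p.v1)                     # 3.42 L/h, 8.63 L
print(terminal_halflife(p))           # 3.38 h
print(auc_model(18.36, p.cl))         # 1308 uM*min for a 1.2 mg/kg dose

res = run_study(typ, n=200, seed=42, schedules=("schedule1",))[0]
print(res.mpe_bayes, res.mpe_trap)    # 37.6 vs 224.0 uM*min
print(res.rmspe_bayes, res.rmspe_trap)  # 109.0 vs 283.5 uM*min
```

Reading the numbers: for a typical 15.3 kg child the 1.2 mg/kg chart dose
lands mid-window (1308 uM·min). Across 200 virtual patients sampled at
2.5/3/4/6 h, the trapezoidal AUC underestimates the true exposure by
224 uM·min on average (about 16%) — because the 3–6 h samples still lie
partly in the distribution phase, so the extrapolation slope is too steep
— while the model-based AUC is nearly unbiased (38 uM·min) and twice as
precise. In TR terms the trapezoid pushed 34.5% of patients below the
window versus 19% for the model-based estimate: the misclassification
that drives unnecessary dose increases.

A command-line interface wraps the same machinery:

```
busulfan-pk simulate --n 50 --schedule schedule1 --seed 1 --out cohort.csv
busulfan-pk fit      --dataset cohort.csv --out fits.csv
busulfan-pk nca      --dataset cohort.csv --out nca.csv
busulfan-pk evaluate --n 1000 --seed 1 --out-dir study/
```

Datasets are NONMEM-style CSV (ID, TIME, AMT, RATE, EVID, MDV, DV, OCC,
BW, LAG). See `docs/methods.md` for model assumptions, numerical choices
and limitations.

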