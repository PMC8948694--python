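# Methods

## The model

Intravenous busulfan disposition in paediatric patients is described by a
linear two-compartment model with zero-order infusion input and first-order
elimination, parameterized as clearance `CL` (L/h), central volume `V1` (L),
intercompartmental clearance `Q` (L/h) and peripheral volume `V2` (L).
Typical values (referenced to a 70 kg body weight) are

| parameter | value | units |
|---|---|---|
| CL | 10.7 | L/h |
| V1 | 39.5 | L |
| Q  | 4.68 | L/h |
| V2 | 17.5 | L |

Body weight enters through fixed-exponent allometry: clearances scale with
`(BW/70)^0.75`, volumes with `(BW/70)^1`. Inter-individual variability is
lognormal on CL (SD 0.284) and V1 (SD 0.409) with correlation 0.679;
inter-occasion variability on CL has SD 0.105; residual error is
proportional with SD 0.126. Because every micro rate constant scales as
`(BW/70)^-0.25`, the terminal half-life obeys the exact scaling law
`t1/2(BW) = t1/2(70 kg) * (BW/70)^0.25` — about 3 h at 10 kg, 4 h at the
cohort mean of 30.6 kg, and 5 h at 70 kg.

Low-volume syringe-pump infusions reach the circulation only after a
dead-volume lag. The lag is a pure time shift of the infusion start
(duration and rate unchanged), taken from the weight-band chart used for
dosing: 40 min below 16 kg, 30 and 20 min in the middle bands, 7.5 min
above 34 kg. Where the chart prints split values (35/25 and 10/5 min)
without defining the sub-band boundary, the band mean is used; a
user-supplied table can override this.

Concentrations are evaluated with the closed-form bi-exponential infusion
solution (during- and post-infusion branches, superposition over doses).
The terminal rate constant beta is computed as `k10*k21 / alpha` rather
than by the subtractive eigenvalue formula, which avoids cancellation when
`k10*k21` is small relative to the squared trace. A piecewise stiff ODE
integration of the same mass-balance system exists in the test suite as an
independent oracle; the closed form matches it to better than 1e-6 relative.

## Synthetic cohorts

No patient data ship with the package. Virtual cohorts emulate the study
demographics: body weight is drawn from a lognormal moment-matched to mean
30.6 kg / SD 21.6 kg and truncated by rejection to the observed 7.38–104 kg
range (truncation lowers the realized mean to ≈30.0 kg, an accepted
consequence of matching the untruncated moments). A resampling mode draws
weights from a user-supplied covariate table instead, mimicking covariates
sampled from a real dataset. Doses follow the SmPC chart (1.0 / 1.2 / 1.1 /
0.95 / 0.8 mg/kg by weight band); band edges are half-open at the interior
boundaries (16 kg receives 1.1 mg/kg) and 34 kg stays in the 0.95 band
because the final band is ">34". Only the first occasion is simulated: the
occasion effect kappa is drawn once and folded into the patient's true
clearance, so `AUC_true = dose / CL_true` is the occasion-specific truth.

Observations carry proportional noise `(1 + eps)`, `eps ~ N(0, 0.126^2)`.
Simulated values at or below a positivity floor (0.001 mg/L) are floored
and flagged, and flagged records are excluded from estimation; with the
schedules used here the floor is essentially never reached. What the
generator does **not** emulate: age-dependent clearance maturation,
covariates other than weight, sampling-time deviations, assay LLOQ
censoring beyond the floor, or multi-day occasion-to-occasion drift — so
passing tests demonstrate correctness of the methods under the stated
model, not robustness to real-world protocol deviations.

## AUC methods compared

* **Model-based (MAP).** Individual random effects `(eta_CL, eta_V1)` are
  the mode of the penalized conditional objective
  `sum_j [(y_j - f_j)^2 / (sigma f_j)^2 + log((sigma f_j)^2)] + eta' Omega^-1 eta`
  (residual variance built from the model prediction, the conditional
  FOCE-with-interaction convention). Minimization is BFGS from `eta = 0`
  with three-point finite-difference gradients, gradient tolerance 1e-8
  and at most 200 iterations; convergence is accepted at a scaled
  first-order norm below 1e-6, and four deterministic jittered restarts
  are attempted otherwise. The occasion effect is not estimated (one
  occasion cannot separate it from eta_CL), so the MAP eta_CL absorbs it —
  which is precisely why `AUC_bayes = dose / CL_EBE` tracks the
  occasion-specific truth. Note a structural property of this objective:
  the `log((sigma f)^2)` term displaces the conditional mode by O(sigma^2)
  even on noise-free data (for a single observation with a flat prior the
  mode satisfies `f = y/(1 + sigma^2)`); at sigma = 0.126 this amounts to
  a few hundredths on the eta scale and vanishes as sigma shrinks. Zero
  omegas pin the corresponding eta at zero.

* **Non-compartmental (trapezoid).** The time axis is re-referenced to the
  effective infusion start (nominal start + lag), a zero anchor placed
  there, and the samples integrated linear-up/log-down (a pure linear mode
  is available for sensitivity analysis). The terminal slope lambda_z is
  the OLS slope of log concentration over the last three samples; the tail
  `C_last / lambda_z` uses the observed last concentration (a
  predicted-C_last variant is a switch). Flat or rising terminal data flag
  the result. Exposure unit: mg·h/L are converted to uM·min with the
  busulfan molar mass 246.30 g/mol (factor 60·1000/246.30 ≈ 243.6), a
  named constant.

## The schedule study

Three sampling designs are compared with 1000 virtual patients each
(master seed plus per-(schedule, patient) substreams, so results are
bit-reproducible and earlier patients are unchanged when the cohort
grows): the original q6h design (2.5, 3, 4, 6 h; 2-h infusion), a reduced
q6h design (2.5, 4, 6 h), and a once-daily design (3, 6, 9, 12 h; 3-h
infusion of a 4x dose, negligible pump lag). Bias is `MPE =
mean(AUC_true - AUC_calc)` (positive = underestimation) and imprecision
`RMSPE = sqrt(mean((AUC_true - AUC_calc)^2))`; both are reported in
uM·min on the per-q6h-dose-equivalent scale (once-daily AUCs divided by
4) so the three schedules share one axis, with relative (%) variants
alongside. Therapeutic-range classification (900–1500 uM·min per q6h
dose, endpoints inclusive) uses the same normalization. Patients with a
non-converged MAP fit or an inestimable slope are excluded per method and
counted.

With the default parameters the study reproduces the qualitative picture
that motivates model-informed dosing: on the 6-h schedules the trapezoid
underestimates exposure severely (the last three samples sit partly in the
distribution phase, so lambda_z overestimates beta and the extrapolated
tail is too small), while the MAP method is close to unbiased; the
once-daily schedule cuts the trapezoid bias to roughly a third, though a
residual underestimation remains from the linear chord across the
infusion rise and the still slightly inflated slope.

## Numerical choices and edge cases

* Degenerate disposition (alpha = beta) cannot occur for Q > 0 and is
  rejected otherwise.
* Predictions inside the MAP objective are floored at 1e-10 mg/L and eta
  is clipped at ±40 so optimizer line-search excursions cannot underflow.
* lambda_z at or below 1e-10 1/h is treated as inestimable.
* Dosing/lag band lookups reject non-positive weights; the band scan is
  exhaustive and mutually exclusive over all positive weights.
* Datasets are NONMEM-style CSV (ID, TIME, AMT, RATE, EVID, MDV, DV, OCC,
  BW, LAG; missing DV as "."); round trips are lossless and missing
  mandatory columns are reported by name.

## Known limitations

* The MAP objective's log-variance term induces a small deterministic
  shift of the EBEs (see above); it is inherent to the conditional
  convention adopted, not removed by richer sampling.
* The trapezoid's infusion-rise chord error persists even for
  one-compartment kinetics; the study isolates the distribution-phase
  component by a Q -> 0 comparison in the tests.
* Only single-occasion, single-dose-interval designs are simulated;
  multi-day TDM and adaptive dosing are out of scope.
* The untruncated-moment matching of the weight distribution slightly
  undershoots the target mean after truncation.

## Problem sizes

The full study runs 1000 patients per schedule (three schedules, one MAP
fit and one NCA per patient) in well under a minute per schedule on a
single CPU; the closed-form evaluator makes per-patient cost microseconds
and the MAP fit a handful of two-parameter BFGS iterations. Statistical
tests in the suite use cohorts of 40–1000 and random-effect samples up to
50,000, sized so that Monte-Carlo error is an order of magnitude below the
asserted tolerances.
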