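# mccrisk

Multi-center competing-risks modelling for epidemiological risk assessment.

Cohort studies that pool many centers (cities, hospitals, regions) often
carry strong between-center heterogeneity that the measured risk factors
cannot explain.  Fitting a separate survival model per center fractures the
covariate effects; ignoring the centers attenuates them.  `mccrisk`
implements the middle road for data with two competing causes of failure:
cause-specific proportional hazards with a fixed per-center log-hazard
offset η_k,

    h_c(t | z, k) = α_c0 · exp(β_cᵀ z + η_k),        c = 1, 2,

where η_k is calibrated from routinely available per-center incidence via
the complementary-log-log contrast

    η_k = ln(−ln(1 − P_k)) − ln(−ln(1 − P)),    α₁₀ = −ln(1 − P),

rather than estimated jointly.  The package provides, for biostatisticians
and epidemiologists evaluating such models:

* the hazard/distribution functions of the stratified (constant-baseline)
  two-cause model, including both the marginal cause-1 sub-CDF and the
  proper cumulative incidence (`mccrisk.model`);
* incidence-based calibration of η and the SDCP heterogeneity statistic,
  with the 0.1 model-choice threshold (`mccrisk.centers`, `recommend_model`);
* a Newton–Raphson Cox partial-likelihood fitter (Breslow ties, fixed
  offsets) for the center-adjusted model (MCCRM) and its unadjusted
  counterpart (CSHM) (`mccrisk.estimate`);
* Gail-type absolute risk over [a, a+τ] under competing mortality, closed
  form plus quadrature oracle, and E/O calibration (`mccrisk.risk`);
* a multi-center cohort simulator (correlated risk factors, exact-SDCP
  center offsets, exponential latent times, Bernoulli cause assignment,
  censoring calibrated to a target ratio) and a Monte-Carlo harness
  reporting bias/SD/RMSE, AUC and E/O grids (`mccrisk.simulate`,
  `mccrisk.evaluate`).

## Worked example

Simulate a 17-center cohort of 5,000 subjects with strong heterogeneity
(SDCP = 1.0, 20% censoring), then fit both models:

```sh
$ mccrisk simulate --n 5000 --q 0.2 --sdcp 1.0 --seed 7 --out example/cohort.csv
wrote example/cohort.csv (realized censor ratio 0.203, b=103.908)

$ mccrisk fit --cohort example/cohort.csv --offsets none --out example/cshm.json
wrote example/cshm.json: tc=0.7933, hdl=-2.4791, sbp=0.0103, diabetes=0.6815, smoking=0.8340

$ mccrisk fit --cohort example/cohort.csv --offsets incidence --horizon 5 --out example/mccrm.json
wrote example/mccrm.json: tc=0.9058, hdl=-2.8449, sbp=0.0123, diabetes=0.8738, smoking=0.9226
```

The generative coefficients are β₁ = (1, −3, 0.01, 1, 1).  The unadjusted
CSHM shrinks every effect toward zero (TC 0.79, HDL −2.48, ...), the
classic attenuation caused by unmodelled center heterogeneity; the MCCRM,
using only per-center incidence by year 5 to build its offsets, recovers
them (TC 0.91, HDL −2.84, ...).  Absolute-risk calibration under the
generative parameters:

```sh
$ mccrisk risk --cohort example/cohort.csv --params example/cohort.params.json \
      --horizon 5 --out example/risks.csv
$ head -3 example/risks.eo.csv
t,expected,observed,ratio
1.0,283.37238517892484,283,1.0013158486887803
2.0,474.858993951058,486,0.97707611924086
```

E ≈ O: the expected cause-1 count from the summed absolute risks matches
the observed count to about 1–2%.  `mccrisk evaluate --config grid.yaml`
runs full replicate studies over an (N, Q, SDCP) grid and
`mccrisk sweep` traces the two models' AUC as heterogeneity grows,
together with the SDCP ≥ 0.1 recommendation to switch to the
center-adjusted model.

See `docs/methods.md` for the model, the simulator's generative
assumptions, and all numerical conventions.

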