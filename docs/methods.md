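# Methods

## Model

`mccrisk` analyses multi-center survival data with two competing causes of
failure (cause 1 = the event of interest, e.g. death from stroke; cause 2 =
death from any other cause).  Within an age/sex stratum, subject *i* of
center *k* with covariate vector `z` has cause-specific hazards

    h1(t | z, k) = α₁₀ · exp(β₁ᵀ z + η_k)
    h2(t | z, k) = α₂₀ · exp(β₂ᵀ z + η_k)

with constant baseline hazards α₁₀, α₂₀ (stratification justifies the
constancy) and a fixed center parameter η_k shared by both causes.  η_k
absorbs latent area-level effects — climate, economy, living habits — that
the measured covariates cannot capture, while the covariate effects β stay
identical across centers.  The all-cause rate λ = h1 + h2 makes the latent
event time exponential given (z, k), and the failing cause is cause 1 with
probability h1/λ, independent of the time.

Two fitted models are compared throughout:

* **CSHM** — the plain cause-specific proportional-hazards (Cox) model,
  ignoring centers;
* **MCCRM** — the same partial likelihood with η_{k(i)} entering as a fixed
  per-subject offset.  η is *plugged in*, never jointly estimated: either
  the known generative values (simulation) or re-estimates from per-center
  incidence.

### Center parameters from incidence

With t = 1 time unit (1 year) and a per-year incidence proportion P at the
baseline level, the marginal cause-1 sub-CDF `1 − e^{−h1·t}` inverts to

    α₁₀ = −ln(1 − P),          η_k = ln(−ln(1 − P_k)) − ln(−ln(1 − P)),

a complementary-log-log contrast of the center incidence P_k against the
overall incidence P.  The overall P is the weight-weighted mean of the P_k
(equal to the pooled incidence when the weights are population sizes),
unweighted when no weights are given.  Incidences of exactly 0 or 1 are
rejected, not clamped; when η is re-estimated from cohort data, centers
with zero events raise an error unless Laplace smoothing
`(events + ½)/(n_k + 1)` is enabled.  The **SDCP** — the sample standard
deviation (n−1 denominator) of η₁..η_K — gauges between-center
heterogeneity; below 0.1 the two models perform alike and the package's
recommendation rule says "either", at or above 0.1 it says "MCCRM".

Note the marginal sub-CDF `1 − e^{−h1 t}` ignores competition; it is kept
because the incidence calibration above is derived from it.  Wherever the
three outcome probabilities must sum to one the package uses the proper
cumulative incidence `(h1/λ)(1 − e^{−λt})` instead.  Both forms are exposed
side by side (`cause1_subcdf`) and coincide as h2 → 0.

### Absolute risk

The Gail-type absolute risk of cause 1 over [a, a+τ],

    P{a, τ | z, k} = ∫_a^{a+τ} h1 e^{−h1(t−a)} · S2(t)/S2(a) dt,

is implemented twice: an adaptive quadrature of the integral (the normative
definition, tolerance 1e−10) and the constant-hazard closed form
`h1/(h1+h2) · (1 − e^{−(h1+h2)τ})` to which it reduces exactly — the
closed form is age-independent because the hazards are age-constant within
the stratum.  The published variants of the simplified formula multiply the
relative risk by e^{η_k} twice and carry unstable sign conventions, so this
package treats the single-`e^{η}` integral as the definition and verifies
the closed form against it (1,000 random parameter triples, 1e−8).

Calibration is summarised by **E/O** over [0, t]: E sums every subject's
model-based absolute risk (subjects censored before t still contribute
their full expected risk), O counts observed cause-1 failures by t.  Under
the generative parameters E/O is consistent up to the censoring-induced
inflation (events censored before t reduce O but not E), which grows slowly
with the horizon — a much milder drift than the double-counted e^{η}
formula would produce.

## Simulator

Per subject: covariates → center offset → latent time → cause → censoring.

* **Covariates** (defaults chosen to mimic Chinese health-check-up
  populations; all config-overridable): TC ~ N(5.0, 1.0²) mmol/L,
  HDL ~ N(1.4, 0.3²) mmol/L, SBP ~ N(130, 15²) mmHg with correlations
  (TC,HDL) = 0.2, (TC,SBP) = 0.2, (HDL,SBP) = −0.1; diabetes ~ Bern(0.08),
  smoking ~ Bern(0.25).  Covariates are centered at their population means
  before entering the linear predictor: with β₁ = (1, −3, 0.01, 1, 1) and
  β₂ = (0.01, −0.01, 0.0001, 0.01, 0.01), uncentered values would produce
  absurd hazards.  Baseline hazards default to α₁₀ = 0.02, α₂₀ = 0.04 per
  year, keeping stratum-level event probabilities plausible.
* **Center offsets**: η_k ~ N(0, SDCP²) i.i.d. for K centers (default
  K = 17), recentered to mean 0 and rescaled so the sample SD equals the
  requested SDCP *exactly*; subjects are allocated to centers in equal
  blocks (counts differ by at most 1).  Offsets are redrawn each
  Monte-Carlo replicate (fresh heterogeneity per run); the per-replicate
  RNG streams are spawned from one master `SeedSequence`, so every result
  is a pure function of the scenario seed.
* **Event mechanism**: T ~ Exp(λ), cause ~ Bernoulli(h1/λ),
  C ~ Uniform(0, b); outcome 0 (censored) iff C < T, observed time
  min(T, C).
* **Censoring calibration**: b is root-found so that the censored fraction
  hits the target Q.  With C ~ U(0, b), P(C < T) = E[min(T, b)]/b, which is
  estimated on a 50,000-subject pilot (per-subject η ~ N(0, SDCP), i.e. the
  marginal offset law) without extra Monte-Carlo noise beyond the pilot
  draw of T, and solved by Brent's method; the achieved fraction must be
  within ±0.005 of Q.  For the homogeneous-rate special case the analytic
  fraction is `(1 − e^{−λb})/(λb)`, which the tests use as the oracle.

What the generator does **not** emulate: real covariate distributions
(the reference covariate parameters were never published, so the defaults
are invented but realistic), informative or administrative censoring,
time-varying hazards or covariates, within-center covariate clustering,
and multiple follow-up visits.  Passing tests therefore demonstrate
correctness of the estimators *under the stated generative model*, not
performance on any particular real registry.

## Estimation

Cause-specific fits treat the other cause and censorings as right-censored.
The Cox partial likelihood with Breslow tie handling is maximised by
Newton–Raphson from β = 0 with step-halving whenever a step would decrease
the log-likelihood; convergence at max|score| < 1e−8 or relative
log-likelihood change < 1e−10, cap 50 iterations; standard errors from the
inverse observed information.  Breslow was chosen because simulated
continuous times are tie-free almost surely (where ties are injected in
tests, Breslow's risk-set convention is verified against an independent
O(n²) evaluation).  Separation is flagged, not raised: because the score
also vanishes under a monotone partial likelihood, a post-convergence guard
marks any fit with |β̂_j|·sd(z_j) > 15 as non-converged with a diagnostic.
Offsets enter the linear predictor additively and are held fixed.

## Evaluation harness

Per replicate: simulate → fit CSHM and MCCRM (cause 1) → record β̂, AUC and
the E/O grid under the generative parameters.  Aggregates: bias =
mean(β̂) − β₁, SD (n−1), RMSE = √(bias² + SD²) (an identity the tests check
to 1e−10 on every emitted cell), mean AUC, mean E/O.  Replicates where a
fit fails to converge are dropped and counted; more than 5% dropped aborts
the scenario.

**AUC labeling.** Scores are the fitted linear predictors (including the
offset for MCCRM).  Positives are cause-1 events; *competing-cause deaths
are excluded* rather than pooled with the censored as negatives.  The
center offset multiplies both cause-specific hazards, so under pooling it
correctly predicts the competing deaths sitting in the negative class and
is penalised for it — measured at SDCP = 2.0, pooling gives
AUC(MCCRM) = 0.742 < AUC(CSHM) = 0.789, inverting the heterogeneity
ordering, while exclusion gives 0.923 vs 0.772.  Exclusion restores the
comparison the offset is meant to win and is applied identically to both
models.  AUC itself is the midrank Mann–Whitney statistic
P(s₊ > s₋) + ½P(s₊ = s₋), verified exactly against O(n²) pair counting.

**Problem sizes.**  The package's default replication scale is N = 2000
with 200 replicates per (N, Q, SDCP) scenario — the full reference design
(N = 5000, 1000 replicates) is a flag away (`--n`, `--reps`) but the
desk-scale runs already pin the Monte-Carlo means to a few thousandths.
The acceptance script uses N = 5000 with 200 replicates for coefficient
means, 50 replicates for E/O, and a single 100,000-subject cohort for the
censoring check.

## Numerical notes and edge cases

* The linear predictor is max-shifted before exponentiation inside the
  partial likelihood, so extreme trial steps cannot overflow.
* `draw_center_offsets` burns the same number of normal draws when
  SDCP = 0, keeping downstream streams aligned across SDCP values.
* A degenerate all-equal offset draw (probability zero) raises rather than
  silently rescaling.
* Incidence-derived η with a center incidence of exactly 1 is rejected.
* E/O with zero observed events raises (`eo_grid` reports NaN for such
  horizons instead, with the valid-replicate count).

## Known limitations

Single stratum per fit (stratified baselines beyond that are out of scope);
exactly two causes; no joint (frailty-likelihood) estimation of η — the
plug-in is the method under study; no confidence intervals for absolute
risk; only baseline covariate values are used, so long-horizon predictions
inherit the usual baseline-only inaccuracy.
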