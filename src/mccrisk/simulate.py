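"""Multi-center competing-risks cohort simulator.

The generative scheme, per subject:

1. covariates: (TC, HDL, SBP) multivariate normal, (diabetes, smoking)
   Bernoulli, all centered at their population means so the linear predictor
   has mean zero;
2. center offsets: eta_k drawn i.i.d. Normal(0, sdcp^2) for K centers, then
   recentered to mean 0 and rescaled so the *sample* SD equals the requested
   SDCP exactly; subjects are allocated to centers in equal blocks;
3. latent event time T ~ Exponential(rate = h1 + h2) with the cause-specific
   hazards of :mod:`mccrisk.model`;
4. cause drawn Bernoulli with P(cause 1) = h1 / (h1 + h2);
5. censoring time C ~ Uniform(0, b); outcome 0 (censored) when C < T, else
   the drawn cause; observed time = min(T, C).

The bound ``b`` controls the censored fraction Q and is calibrated by
root-finding on a Monte-Carlo pilot: with C ~ U(0, b),
P(C < T) = E[min(T, b)] / b, which is smooth, strictly decreasing in b, and
estimated without extra noise from the pilot draws of T alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import (
    COVARIATE_COLUMNS,
    TrueParams,
    default_true_params,
    validate_cohort,
)

_DEF_MEAN = (5.0, 1.4, 130.0)          # TC, HDL (mmol/L), SBP (mmHg)
_DEF_SD = (1.0, 0.3, 15.0)
_DEF_CORR = ((1.0, 0.2, 0.2), (0.2, 1.0, -0.1), (0.2, -0.1, 1.0))


def _default_cov() -> np.ndarray:
    sd = np.asarray(_DEF_SD)
    return np.asarray(_DEF_CORR) * np.outer(sd, sd)


@dataclass
class CovariateModel:
    """Distribution of the five risk-factor covariates.

    Continuous block (TC, HDL, SBP) is multivariate normal; diabetes and
    smoking are Bernoulli.  ``centering`` (length 5) is subtracted from every
    drawn covariate vector; ``None`` means center at the population means,
    which keeps exp(beta . z) near 1 and the simulated hazards plausible.
    """

    mean: np.ndarray = field(default_factory=lambda: np.asarray(_DEF_MEAN, float))
    covariance: np.ndarray = field(default_factory=_default_cov)
    p_diabetes: float = 0.08
    p_smoking: float = 0.25
    centering: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (3,) or self.covariance.shape != (3, 3):
            raise ValueError("mean must be length 3 and covariance 3x3")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.covariance) <= 0):
            raise ValueError("covariance must be positive definite")
        for name, p in (("p_diabetes", self.p_diabetes), ("p_smoking", self.p_smoking)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.centering is not None:
            self.centering = np.asarray(self.centering, dtype=float)
            if self.centering.shape != (5,):
                raise ValueError("centering must have length 5")

    @property
    def centering_vector(self) -> np.ndarray:
        if self.centering is not None:
            return self.centering
        return np.concatenate([self.mean, [self.p_diabetes, self.p_smoking]])


@dataclass
class SimulationConfig:
    """One simulation scenario: (N, Q, SDCP, K) plus generative parameters."""

    n_total: int
    censor_ratio: float = 0.2
    sdcp: float = 0.0
    n_centers: int = 17
    n_reps: int = 1
    seed: int = 0
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    true_params: TrueParams = field(default_factory=default_true_params)
    censor_bound: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.censor_ratio < 1.0:
            raise ValueError("censor ratio must lie in [0, 1)")
        if self.sdcp < 0:
            raise ValueError("sdcp must be nonnegative")
        if self.n_total < self.n_centers:
            raise ValueError("need at least one subject per center")
        if self.censor_bound is not None and self.censor_bound <= 0:
            raise ValueError("censor bound must be positive")


def draw_covariates(n: int, model: CovariateModel, rng: np.random.Generator) -> np.ndarray:
    """Draw an (n, 5) centered covariate matrix (TC, HDL, SBP, diabetes, smoking)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cont = rng.multivariate_normal(model.mean, model.covariance, size=n,
                                   method="cholesky")
    diab = rng.binomial(1, model.p_diabetes, size=n)
    smoke = rng.binomial(1, model.p_smoking, size=n)
    Z = np.column_stack([cont, diab, smoke]).astype(float)
    return Z - model.centering_vector


def draw_center_offsets(
    n_total: int, n_centers: int, sdcp: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw center offsets with *exact* sample SD ``sdcp`` and assign subjects.

    Returns ``(eta, center_index)`` with ``eta`` of length K (mean 0, sample
    SD = sdcp after rescaling) and ``center_index`` in 0..K-1 allocating the
    ``n_total`` subjects to centers in equal blocks (remainder spread over
    the early centers).
    """
    if n_centers < 2 and sdcp > 0:
        raise ValueError("need at least two centers for nonzero sdcp")
    if sdcp == 0.0:
        eta = np.zeros(n_centers)
        rng.standard_normal(n_centers)  # keep the stream layout fixed
    else:
        eta = rng.standard_normal(n_centers)
        eta = eta - eta.mean()
        sd = eta.std(ddof=1)
        if sd == 0.0:  # pathological draw; cannot carry heterogeneity
            raise RuntimeError("degenerate center-offset draw")
        eta = eta * (sdcp / sd)
    base, extra = divmod(n_total, n_centers)
    counts = np.full(n_centers, base)
    counts[:extra] += 1
    center_index = np.repeat(np.arange(n_centers), counts)
    return eta, center_index


def censor_fraction_given_rates(rates, b: float) -> float:
    """Exact censored fraction for exponential times with U(0,b) censoring.

    P(C < T | rate) = (1 - exp(-rate*b)) / (rate*b), averaged over subjects.
    """
    x = np.asarray(rates, dtype=float) * b
    return float(np.mean(-np.expm1(-x) / x))


def _pilot_times(config: SimulationConfig, rng: np.random.Generator, m: int) -> np.ndarray:
    """Latent event times for calibration, marginalised over covariates and
    per-subject center offsets (eta ~ Normal(0, sdcp))."""
    Z = draw_covariates(m, config.covariate_model, rng)
    eta = rng.normal(0.0, config.sdcp, size=m) if config.sdcp > 0 else np.zeros(m)
    p = config.true_params
    rate = (
        p.base_hazard1 * np.exp(Z @ p.beta1 + eta)
        + p.base_hazard2 * np.exp(Z @ p.beta2 + eta)
    )
    return rng.exponential(1.0 / rate)


def calibrate_censor_bound(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_pilot: int = 50_000,
    tol: float = 0.005,
) -> float:
    """Root-find the censoring bound b achieving the target censor ratio Q.

    Uses a pilot sample of latent times and the Rao-Blackwellised estimator
    mean(min(T, b)) / b of P(C < T); deterministic under a fixed rng state.
    """
    Q = config.censor_ratio
    if not 0.0 < Q < 1.0:
        raise ValueError("calibration needs 0 < Q < 1")
    T = _pilot_times(config, rng, n_pilot)

    def frac(b: float) -> float:
        return float(np.mean(np.minimum(T, b))) / b

    lo = 1e-6
    hi = 1.0
    for _ in range(200):
        if frac(hi) < Q:
            break
        hi *= 2.0
    else:
        raise RuntimeError(
            f"censor-bound search failed: fraction at b={hi:.3g} is "
            f"{frac(hi):.4f} > Q={Q}"
        )
    b = brentq(lambda x: frac(x) - Q, lo, hi, xtol=1e-10, rtol=1e-12)
    achieved = frac(b)
    if abs(achieved - Q) > tol:
        raise RuntimeError(
            f"censor-bound calibration off target: achieved {achieved:.4f} "
            f"vs Q={Q}"
        )
    return float(b)


class SimulatedCohort(NamedTuple):
    cohort: pd.DataFrame
    params: TrueParams          # generative parameters with realized eta
    censor_bound: float
    realized_censor_ratio: float


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedCohort:
    """Simulate one multi-center competing-risks cohort.

    Draw order (fixed for reproducibility): covariates, center offsets,
    latent times, causes, censoring times.  The censoring bound is taken
    from ``config.censor_bound`` when set, otherwise calibrated on a pilot
    stream spawned from ``rng`` (so the cohort draws are unaffected by
    whether calibration ran).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.censor_bound is not None:
        b = config.censor_bound
    elif config.censor_ratio == 0.0:
        b = np.inf
    else:
        b = calibrate_censor_bound(config, rng.spawn(1)[0])

    n = config.n_total
    p = config.true_params
    Z = draw_covariates(n, config.covariate_model, rng)
    eta, center_index = draw_center_offsets(n, config.n_centers, config.sdcp, rng)
    eta_i = eta[center_index]
    h1 = p.base_hazard1 * np.exp(Z @ p.beta1 + eta_i)
    h2 = p.base_hazard2 * np.exp(Z @ p.beta2 + eta_i)
    lam = h1 + h2
    T = rng.exponential(1.0 / lam)
    cause = np.where(rng.random(n) < h1 / lam, 1, 2)
    C = rng.uniform(0.0, b, size=n) if np.isfinite(b) else np.full(n, np.inf)
    censored = C < T
    outcome = np.where(censored, 0, cause)
    time = np.minimum(T, C)

    cohort = pd.DataFrame({"center_id": center_index + 1})
    for j, col in enumerate(COVARIATE_COLUMNS):
        cohort[col] = Z[:, j]
    cohort["time"] = time
    cohort["outcome"] = outcome
    cohort["age"] = 0.0
    validate_cohort(cohort)
    return SimulatedCohort(
        cohort=cohort,
        params=p.with_eta(eta),
        censor_bound=float(b),
        realized_censor_ratio=float(censored.mean()),
    )


def outcome_probabilities(h1, h2, b: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact per-subject probabilities of (censored, cause 1, cause 2).

    With T ~ Exp(h1+h2), cause 1 w.p. h1/(h1+h2) independent of T, and
    C ~ U(0, b):  P(censored) = (1 - e^{-lam b})/(lam b) and the event
    probabilities split the remainder proportionally to the hazards.
    """
    h1 = np.asarray(h1, float)
    h2 = np.asarray(h2, float)
    lam = h1 + h2
    x = lam * b
    p0 = -np.expm1(-x) / x
    p_event = 1.0 - p0
    return p0, p_event * h1 / lam, p_event * h2 / lam
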