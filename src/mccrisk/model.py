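"""Cause-specific hazard machinery for the multi-center competing-risks model.

Within an age/sex stratum, subject *i* of center *k* with covariate vector
``z`` fails from cause ``c`` (1 = cause of interest, 2 = competing cause)
with cause-specific hazard

    h_c(t | z, k) = alpha_c0 * exp(beta_c . z + eta_k),

constant in time because the baseline hazards are assumed constant within a
stratum.  ``eta_k`` is a fixed center-level log-hazard offset ("center
parameter") shared by both causes; it absorbs latent area-level effects
(climate, economy, habits, ...) that the measured covariates cannot explain.
The all-cause rate is the sum of the two cause-specific hazards, so the
event-time distribution given (z, k) is exponential.

Two versions of the cause-1 sub-distribution are provided.  The *marginal*
form ``1 - exp(-h1 t)`` treats cause 1 as if no competition existed; it is
the form from which the incidence-based calibration of the baseline hazard
and center parameters is derived (see :mod:`mccrisk.centers`).  The proper
*cumulative incidence* ``h1/(h1+h2) * (1 - exp(-(h1+h2) t))`` is the
probability of actually failing from cause 1 by ``t`` in the presence of the
competing cause; the two cause-specific cumulative incidences sum to the
all-cause CDF.  Use the cumulative-incidence form whenever the three outcome
probabilities must add to one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

#: canonical covariate order: total cholesterol, HDL cholesterol, systolic
#: blood pressure, diabetes (0/1), smoking (0/1)
COVARIATE_COLUMNS: tuple[str, ...] = ("tc", "hdl", "sbp", "diabetes", "smoking")

#: canonical cohort-table columns
COHORT_COLUMNS: tuple[str, ...] = (
    "center_id", *COVARIATE_COLUMNS, "time", "outcome", "age",
)

VALID_OUTCOMES = (0, 1, 2)  # censored / cause of interest / competing cause


@dataclass(frozen=True)
class StratumKey:
    """Age/sex stratum within which baseline hazards are constant.

    ``age_band`` is a half-open interval [lo, hi) in years.
    """

    sex: str | None = None
    age_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.age_band is not None and not self.age_band[0] < self.age_band[1]:
            raise ValueError(f"age band must satisfy lo < hi, got {self.age_band}")


@dataclass
class TrueParams:
    """Generative parameters of the two-cause multi-center model.

    Parameters
    ----------
    beta1, beta2
        Log-hazard-ratio coefficient vectors (length p) for the cause of
        interest and the competing cause.
    base_hazard1, base_hazard2
        Constant baseline hazards alpha_10, alpha_20 (events per year) at
        z = 0, eta = 0.
    eta
        Center offsets eta_1..eta_K, or ``None`` before centers are realized.
    """

    beta1: np.ndarray
    beta2: np.ndarray
    base_hazard1: float
    base_hazard2: float
    eta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        if self.beta1.shape != self.beta2.shape or self.beta1.ndim != 1:
            raise ValueError("beta1 and beta2 must be 1-d vectors of equal length")
        if not (self.base_hazard1 > 0 and self.base_hazard2 > 0):
            raise ValueError("baseline hazards must be strictly positive")
        if self.eta is not None:
            self.eta = np.asarray(self.eta, dtype=float)
            if not np.all(np.isfinite(self.eta)):
                raise ValueError("eta must be finite")

    @property
    def n_covariates(self) -> int:
        return self.beta1.size

    @property
    def n_centers(self) -> int:
        if self.eta is None:
            raise ValueError("center offsets have not been realized")
        return self.eta.size

    def cause(self, c: int) -> tuple[np.ndarray, float]:
        """Return (beta_c, base_hazard_c)."""
        if c == 1:
            return self.beta1, self.base_hazard1
        if c == 2:
            return self.beta2, self.base_hazard2
        raise ValueError(f"cause must be 1 or 2, got {c!r}")

    def with_eta(self, eta: np.ndarray) -> "TrueParams":
        return replace(self, eta=np.asarray(eta, dtype=float))


def default_true_params() -> TrueParams:
    """Default generative parameters for the stroke-mortality scenario.

    Cause-1 coefficients (TC, HDL, SBP, diabetes, smoking) = (1, -3, 0.01,
    1, 1); competing-cause coefficients are near-null, reflecting the usual
    assumption that the measured stroke risk factors barely move mortality
    from other causes.  Baseline hazards 0.02 and 0.04 per year keep the
    within-stratum event probabilities epidemiologically plausible when
    covariates are centered.
    """
    return TrueParams(
        beta1=np.array([1.0, -3.0, 0.01, 1.0, 1.0]),
        beta2=np.array([0.01, -0.01, 0.0001, 0.01, 0.01]),
        base_hazard1=0.02,
        base_hazard2=0.04,
    )


def _check_z(z: np.ndarray, p: int) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != p:
        raise ValueError(
            f"covariate vector length {z.shape[-1]} does not match model p={p}"
        )
    return z


def cause_hazard(z, eta_k, params: TrueParams, cause: int):
    """Cause-specific hazard alpha_c0 * exp(beta_c . z + eta_k).

    ``z`` may be a single length-p vector or an (n, p) matrix; ``eta_k`` a
    scalar or a length-n vector.  Returns a positive rate per year.
    """
    beta, base = params.cause(cause)
    z = _check_z(z, beta.size)
    return base * np.exp(z @ beta + np.asarray(eta_k, dtype=float))


def all_cause_rate(z, eta_k, params: TrueParams):
    """Total hazard lambda = h1 + h2; the exponential event-time rate."""
    return cause_hazard(z, eta_k, params, 1) + cause_hazard(z, eta_k, params, 2)


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return t


def event_time_cdf(t, z, eta_k, params: TrueParams):
    """All-cause failure CDF  F(t | z, k) = 1 - exp(-lambda t)."""
    t = _check_t(t)
    lam = all_cause_rate(z, eta_k, params)
    return -np.expm1(-lam * t)


class Cause1SubCDF(NamedTuple):
    """Both flavours of the cause-1 sub-distribution at time t."""

    marginal: np.ndarray | float          # 1 - exp(-h1 t)
    cumulative_incidence: np.ndarray | float  # h1/(h1+h2) (1 - exp(-(h1+h2) t))


def marginal_subcdf(t, h):
    """Marginal-style sub-CDF 1 - exp(-h t) ignoring competition."""
    return -np.expm1(-np.asarray(h, float) * np.asarray(t, float))


def cumulative_incidence(t, h_cause, h_total):
    """Proper cumulative incidence (h_c/h_tot)(1 - exp(-h_tot t))."""
    h_cause = np.asarray(h_cause, float)
    h_total = np.asarray(h_total, float)
    return h_cause / h_total * -np.expm1(-h_total * np.asarray(t, float))


def cause1_subcdf(t, z, eta_k, params: TrueParams) -> Cause1SubCDF:
    """Cause-1 sub-distribution at ``t`` in both forms.

    Returns a named tuple ``(marginal, cumulative_incidence)``; the marginal
    form feeds the incidence-based calibration, the cumulative-incidence form
    is the probability of observing a cause-1 failure by ``t``.
    """
    t = _check_t(t)
    h1 = cause_hazard(z, eta_k, params, 1)
    h2 = cause_hazard(z, eta_k, params, 2)
    return Cause1SubCDF(
        marginal=marginal_subcdf(t, h1),
        cumulative_incidence=cumulative_incidence(t, h1, h1 + h2),
    )


# ---------------------------------------------------------------------------
# cohort-table I/O

def validate_cohort(df: pd.DataFrame, n_covariates: int | None = None) -> pd.DataFrame:
    """Validate a cohort table in place and return it.

    Requires the canonical columns, outcome codes in {0, 1, 2} and
    nonnegative observed times.  ``age`` is added (0.0) when absent.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "age"]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if "age" not in df.columns:
        df = df.assign(age=0.0)
    if not df["outcome"].isin(VALID_OUTCOMES).all():
        bad = sorted(set(df["outcome"]) - set(VALID_OUTCOMES))
        raise ValueError(f"invalid outcome codes: {bad}")
    if (df["time"] < 0).any():
        raise ValueError("observed times must be nonnegative")
    return df


def read_cohort(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a cohort CSV, optionally renaming columns via ``column_map``
    (file-column -> canonical-name)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False)


def covariate_matrix(
    df: pd.DataFrame, columns: Sequence[str] = COVARIATE_COLUMNS
) -> np.ndarray:
    return df.loc[:, list(columns)].to_numpy(dtype=float)
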