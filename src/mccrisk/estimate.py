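"""Cause-specific Cox partial-likelihood fitting with fixed center offsets.

Two estimators share one fitting routine:

* **CSHM** — plain cause-specific proportional-hazards model: events of the
  other cause and censorings are right-censored at their observed times, no
  center adjustment.
* **MCCRM** — the same partial likelihood with a fixed additive per-subject
  offset eta_{k(i)} in the linear predictor.  The offsets are *plugged in*,
  either known (e.g. the simulator's realized values) or re-estimated from
  per-center incidences via the complementary-log-log transform of
  :func:`mccrisk.centers.center_parameter`; they are never jointly estimated
  with the regression coefficients.

The fitter is Newton-Raphson from beta = 0 with step-halving, Breslow tie
handling, convergence when max|score| < 1e-8 or the relative log-likelihood
change < 1e-10 (max 50 iterations), and standard errors from the inverse
observed information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .centers import center_parameter
from .model import COVARIATE_COLUMNS, covariate_matrix

MAX_ITER = 50
SCORE_TOL = 1e-8
LL_RTOL = 1e-10
_BETA_BOUND = 50.0  # |beta_j| beyond this is treated as separation


@dataclass
class FittedCSModel:
    """Result of one cause-specific partial-likelihood fit."""

    cause: int
    covariates: tuple[str, ...]
    coefficients: np.ndarray
    std_errors: np.ndarray
    offset_mode: str                    # none | known_eta | eta_from_incidence | custom
    eta_used: dict[int, float] | None   # center_id -> eta (None when no offsets)
    log_partial_likelihood: float
    n_events: int
    converged: bool
    n_iter: int
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "cause": self.cause,
            "covariates": list(self.covariates),
            "coefficients": self.coefficients.tolist(),
            "std_errors": self.std_errors.tolist(),
            "offset_mode": self.offset_mode,
            "eta_used": (
                {str(k): v for k, v in self.eta_used.items()}
                if self.eta_used is not None
                else None
            ),
            "log_partial_likelihood": self.log_partial_likelihood,
            "n_events": self.n_events,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "message": self.message,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedCSModel":
        return cls(
            cause=d["cause"],
            covariates=tuple(d["covariates"]),
            coefficients=np.asarray(d["coefficients"], float),
            std_errors=np.asarray(d["std_errors"], float),
            offset_mode=d["offset_mode"],
            eta_used=(
                {int(k): float(v) for k, v in d["eta_used"].items()}
                if d.get("eta_used") is not None
                else None
            ),
            log_partial_likelihood=d["log_partial_likelihood"],
            n_events=d["n_events"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            message=d.get("message", ""),
        )

    @classmethod
    def from_json(cls, path) -> "FittedCSModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def breslow_loglik(
    beta: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    Z: np.ndarray,
    offset: np.ndarray,
) -> float:
    """Breslow partial log-likelihood at ``beta`` (reference evaluation).

    O(n log n); shares no code with the Newton internals' derivative
    assembly beyond the same sufficient statistics.
    """
    state = _PLState(time, event, Z, offset)
    ll, _, _ = state.ll_grad_hess(np.asarray(beta, float), want_derivs=False)
    return ll


class _PLState:
    """Precomputed sort/grouping for repeated partial-likelihood evaluation."""

    def __init__(self, time, event, Z, offset):
        time = np.asarray(time, float)
        event = np.asarray(event, bool)
        Z = np.asarray(Z, float)
        offset = np.asarray(offset, float)
        order = np.argsort(time, kind="mergesort")
        self.t = time[order]
        self.d = event[order]
        self.Z = Z[order]
        self.off = offset[order]
        self.n, self.p = self.Z.shape
        # distinct event times; risk set of an event at tau = all t >= tau,
        # i.e. sorted indices from the first occurrence of tau on (Breslow)
        self.event_times = np.unique(self.t[self.d])
        self.start = np.searchsorted(self.t, self.event_times, side="left")
        grp = np.searchsorted(self.event_times, self.t[self.d])
        G = self.event_times.size
        self.d_count = np.bincount(grp, minlength=G).astype(float)
        self.sumZ_events = np.zeros((G, self.p))
        np.add.at(self.sumZ_events, grp, self.Z[self.d])
        self.grp = grp

    def ll_grad_hess(self, beta, want_derivs=True):
        lp = self.Z @ beta + self.off
        shift = lp.max()  # guard exp overflow for extreme beta during halving
        w = np.exp(lp - shift)
        S0 = np.cumsum(w[::-1])[::-1]
        s0 = S0[self.start]
        ll = (
            float(lp[self.d].sum())
            - float(self.d_count @ (np.log(s0) + shift))
        )
        if not want_derivs:
            return ll, None, None
        wZ = w[:, None] * self.Z
        S1 = np.cumsum(wZ[::-1], axis=0)[::-1]
        s1 = S1[self.start]
        zbar = s1 / s0[:, None]
        S2 = np.cumsum((wZ[:, :, None] * self.Z[:, None, :])[::-1], axis=0)[::-1]
        s2 = S2[self.start]
        grad = self.sumZ_events.sum(axis=0) - self.d_count @ zbar
        info = np.einsum("g,gij->ij", self.d_count, s2 / s0[:, None, None])
        info -= np.einsum("g,gi,gj->ij", self.d_count, zbar, zbar)
        return ll, grad, info  # info = negative Hessian (observed information)


def _newton_cox(time, event, Z, offset):
    state = _PLState(time, event, Z, offset)
    p = state.p
    beta = np.zeros(p)
    ll, grad, info = state.ll_grad_hess(beta)
    n_iter = 0
    converged = False
    message = ""
    for n_iter in range(1, MAX_ITER + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix (possible separation)"
            break
        # step-halving: insist on a non-decreasing log-likelihood
        factor = 1.0
        for _ in range(40):
            cand = beta + factor * step
            ll_new = state.ll_grad_hess(cand, want_derivs=False)[0]
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        else:
            message = "step-halving failed to improve the log-likelihood"
            break
        beta = cand
        ll_prev, ll = ll, ll_new
        _, grad, info = state.ll_grad_hess(beta)
        if np.max(np.abs(beta)) > _BETA_BOUND:
            message = (
                "coefficients diverging (monotone likelihood / separation)"
            )
            break
        if np.max(np.abs(grad)) < SCORE_TOL or (
            abs(ll - ll_prev) < LL_RTOL * (abs(ll_prev) + 1e-300)
        ):
            converged = True
            break
    if not converged and not message:
        message = f"no convergence in {MAX_ITER} iterations"
    if converged:
        # monotone-likelihood guard: the score also vanishes as beta -> inf,
        # so flag coefficients whose contribution spans an absurd lp range
        scale = np.asarray(Z, float).std(axis=0)
        if np.any(np.abs(beta) * np.maximum(scale, 1e-12) > 15.0):
            converged = False
            message = (
                "likelihood converged but a coefficient is diverging "
                "(probable separation / monotone partial likelihood)"
            )
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, ll, converged, n_iter, message


def fit_cause_specific(
    cohort: pd.DataFrame,
    cause: int = 1,
    offsets: np.ndarray | None = None,
    covariate_cols: Sequence[str] = COVARIATE_COLUMNS,
    offset_mode: str | None = None,
    eta_used: dict[int, float] | None = None,
) -> FittedCSModel:
    """Fit the cause-specific proportional-hazards model for one cause.

    Events of the other cause and censorings are treated as right-censored
    at their observed times.  ``offsets``, when given, is a fixed per-subject
    additive term in the linear predictor (the MCCRM center adjustment).
    Non-convergence and separation are flagged on the result, not raised.
    """
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")
    event = (cohort["outcome"].to_numpy() == cause)
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError(f"no events of cause {cause} in the cohort")
    Z = covariate_matrix(cohort, covariate_cols)
    time = cohort["time"].to_numpy(dtype=float)
    if offsets is None:
        off = np.zeros(len(cohort))
        mode = offset_mode or "none"
    else:
        off = np.asarray(offsets, dtype=float)
        if off.shape != (len(cohort),):
            raise ValueError("offsets must be one value per subject")
        mode = offset_mode or "custom"
    beta, se, ll, converged, n_iter, message = _newton_cox(time, event, Z, off)
    return FittedCSModel(
        cause=cause,
        covariates=tuple(covariate_cols),
        coefficients=beta,
        std_errors=se,
        offset_mode=mode,
        eta_used=eta_used if offsets is not None else None,
        log_partial_likelihood=ll,
        n_events=n_events,
        converged=converged,
        n_iter=n_iter,
        message=message,
    )


def mccrm_offsets(
    cohort: pd.DataFrame,
    eta: dict[int, float] | np.ndarray | None = None,
    horizon: float | None = None,
    laplace: bool = False,
) -> tuple[np.ndarray, dict[int, float], str]:
    """Per-subject center offsets for the MCCRM fit.

    Two modes:

    * ``eta`` given (``known_eta``): a dict ``center_id -> eta`` or an array
      indexed by center 1..K; values are mapped onto subjects.
    * ``horizon`` given (``eta_from_incidence``): per-center incidence
      P_k = (cause-1 events by ``horizon``) / n_k, overall incidence pooled
      over all subjects, then the complementary-log-log plug-in.  Centers
      with zero events raise unless ``laplace`` enables the
      (events + 0.5) / (n_k + 1) smoothing.

    Returns ``(offsets, eta_map, mode)``.
    """
    center_ids = cohort["center_id"].to_numpy()
    if (eta is None) == (horizon is None):
        raise ValueError("give exactly one of eta= or horizon=")
    if eta is not None:
        if isinstance(eta, dict):
            eta_map = {int(k): float(v) for k, v in eta.items()}
        else:
            eta = np.asarray(eta, dtype=float)
            eta_map = {k + 1: float(eta[k]) for k in range(eta.size)}
        missing = {int(c) for c in np.unique(center_ids)} - set(eta_map)
        if missing:
            raise ValueError(f"no eta supplied for centers {sorted(missing)}")
        offsets = np.array([eta_map[c] for c in center_ids], dtype=float)
        return offsets, eta_map, "known_eta"

    if horizon <= 0:
        raise ValueError("horizon must be positive")
    is_case = (cohort["outcome"].to_numpy() == 1) & (
        cohort["time"].to_numpy() <= horizon
    )
    df = pd.DataFrame({"center_id": center_ids, "case": is_case})
    grouped = df.groupby("center_id")["case"].agg(["sum", "size"])
    events = grouped["sum"].to_numpy(dtype=float)
    sizes = grouped["size"].to_numpy(dtype=float)
    if laplace:
        P_k = (events + 0.5) / (sizes + 1.0)
    else:
        if np.any(events == 0):
            zero = grouped.index[events == 0].tolist()
            raise ValueError(
                f"centers {zero} have no cause-1 events by t={horizon}; "
                "enable laplace smoothing or extend the horizon"
            )
        P_k = events / sizes
    if np.any(P_k >= 1.0):
        raise ValueError("a center incidence of 1 cannot be calibrated")
    P = float(is_case.sum() + (0.5 * len(grouped) if laplace else 0.0)) / (
        len(cohort) + (1.0 * len(grouped) if laplace else 0.0)
    )
    eta_vals = center_parameter(P_k, P)
    eta_map = {int(c): float(e) for c, e in zip(grouped.index, eta_vals)}
    offsets = np.array([eta_map[c] for c in center_ids], dtype=float)
    return offsets, eta_map, "eta_from_incidence"


def linear_predictor(
    model: FittedCSModel,
    cohort: pd.DataFrame,
    offsets: np.ndarray | None = None,
) -> np.ndarray:
    """Risk score beta_hat . z + offset.

    When ``offsets`` is omitted, offsets are reconstructed from the model's
    stored ``eta_used`` (zero for an offset-free fit).  Used directly as the
    AUC score; adding a constant to all offsets leaves the ranking unchanged.
    """
    Z = covariate_matrix(cohort, model.covariates)
    lp = Z @ model.coefficients
    if offsets is not None:
        return lp + np.asarray(offsets, dtype=float)
    if model.eta_used is not None:
        eta_map = model.eta_used
        try:
            lp = lp + np.array(
                [eta_map[int(c)] for c in cohort["center_id"]], dtype=float
            )
        except KeyError as exc:
            raise ValueError(f"model has no eta for center {exc}") from exc
    return lp
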