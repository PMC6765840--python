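"""Incidence-based calibration of baseline hazard and center parameters.

Under the constant-baseline stratified model the marginal cause-1 sub-CDF is
``1 - exp(-h1 t)``, so with a per-time-unit incidence proportion ``P`` at the
baseline level (z = 0, eta = 0) and t = 1,

    alpha_10 = -ln(1 - P).

The center parameter of center k with incidence ``P_k`` is the plug-in

    eta_k = ln(-ln(1 - P_k)) - ln(-ln(1 - P)),

i.e. the log-ratio of complementary-log-log-transformed incidences; it is
zero when a center's incidence equals the overall incidence.  The standard
deviation of the eta_k across centers (SDCP) gauges between-center
heterogeneity and drives model choice: below 0.1 a plain cause-specific
hazard model and the center-adjusted model behave alike.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd


def _check_proportion(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1)")
    return p


def baseline_hazard_from_incidence(P):
    """Baseline hazard -ln(1 - P) from a per-time-unit incidence proportion."""
    P = _check_proportion(P, "incidence")
    return -np.log1p(-P)


def center_parameter(P_k, P):
    """Center offset eta_k = cloglog(P_k) - cloglog(P).

    Zero iff P_k == P; strictly increasing in P_k.
    """
    P_k = _check_proportion(P_k, "center incidence")
    P = _check_proportion(P, "overall incidence")
    return np.log(-np.log1p(-P_k)) - np.log(-np.log1p(-P))


def sdcp(etas) -> float:
    """Sample standard deviation (n-1 denominator) of the center parameters."""
    etas = np.asarray(etas, dtype=float)
    if etas.size < 2:
        raise ValueError("SDCP needs at least two centers")
    return float(np.std(etas, ddof=1))


class CenterCalibration(NamedTuple):
    center_ids: np.ndarray
    eta: np.ndarray
    overall_incidence: float
    sdcp: float


def centers_from_incidence_table(table: pd.DataFrame) -> CenterCalibration:
    """Calibrate center parameters from a per-center incidence table.

    ``table`` needs columns ``center_id`` plus either ``incidence`` or
    ``events``/``population`` (converted as events/population).  The overall
    incidence is the weighted mean of the center incidences, using
    ``weight`` if present, else ``population``, else equal weights (with
    population weights this equals the pooled incidence).
    """
    if len(table) < 2:
        raise ValueError("need at least two centers")
    if "incidence" in table.columns:
        inc = table["incidence"].to_numpy(dtype=float)
    elif {"events", "population"} <= set(table.columns):
        inc = (
            table["events"].to_numpy(dtype=float)
            / table["population"].to_numpy(dtype=float)
        )
    else:
        raise ValueError(
            "incidence table needs an 'incidence' column or 'events'+'population'"
        )
    inc = _check_proportion(inc, "center incidence")
    if "weight" in table.columns:
        w = table["weight"].to_numpy(dtype=float)
    elif "population" in table.columns:
        w = table["population"].to_numpy(dtype=float)
    else:
        w = np.ones_like(inc)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    overall = float(np.average(inc, weights=w))
    eta = center_parameter(inc, overall)
    return CenterCalibration(
        center_ids=table["center_id"].to_numpy(),
        eta=eta,
        overall_incidence=overall,
        sdcp=sdcp(eta),
    )


def read_incidence_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "center_id" not in df.columns:
        raise ValueError("incidence table must have a center_id column")
    return df
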