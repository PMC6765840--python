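"""Partial-likelihood fitting: oracles, offsets, and center-parameter
re-estimation from incidence."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from mccrisk import (
    SimulationConfig,
    fit_cause_specific,
    linear_predictor,
    mccrm_offsets,
    simulate_cohort,
)
from mccrisk.fixtures import PL_EXAMPLE
from mccrisk.model import COVARIATE_COLUMNS


def brute_partial_loglik(beta, time, event, Z, offset):
    """Independent O(n^2) Breslow partial log-likelihood (test oracle)."""
    beta = np.asarray(beta, float)
    lp = Z @ beta + offset
    ll = 0.0
    for i in np.flatnonzero(event):
        at_risk = time >= time[i]
        ll += lp[i] - np.log(np.exp(lp[at_risk]).sum())
    return ll


def _arrays(cohort, cause=1, cols=COVARIATE_COLUMNS, offset=None):
    time = cohort["time"].to_numpy(float)
    event = cohort["outcome"].to_numpy() == cause
    Z = cohort[list(cols)].to_numpy(float)
    off = np.zeros(len(cohort)) if offset is None else offset
    return time, event, Z, off


class TestNewtonAgainstOracles:
    def test_loglik_matches_brute_force(self, medium_sim):
        from mccrisk.estimate import breslow_loglik

        cohort = medium_sim.cohort.iloc[:300]
        time, event, Z, off = _arrays(cohort)
        rng = np.random.default_rng(5)
        for _ in range(5):
            beta = rng.normal(0, 0.5, 5)
            assert breslow_loglik(beta, time, event, Z, off) == pytest.approx(
                brute_partial_loglik(beta, time, event, Z, off), rel=1e-10
            )

    def test_optimizer_oracle_with_offset(self):
        """The Newton maximiser agrees with direct numerical maximisation of
        the brute-force likelihood, including a nonzero offset."""
        rng = np.random.default_rng(8)
        n = 60
        cohort = pd.DataFrame(
            {
                "center_id": rng.integers(1, 4, n),
                "tc": rng.normal(0, 1, n),
                "hdl": rng.normal(0, 0.5, n),
                "sbp": 0.0,
                "diabetes": 0,
                "smoking": 0,
                "time": rng.exponential(5.0, n),
                "outcome": rng.choice([0, 1, 2], n, p=[0.3, 0.4, 0.3]),
            }
        )
        offset = rng.normal(0, 0.8, n)
        fit = fit_cause_specific(
            cohort, cause=1, offsets=offset, covariate_cols=("tc", "hdl")
        )
        time, event, Z, _ = _arrays(cohort, cols=("tc", "hdl"))
        res = minimize(
            lambda b: -brute_partial_loglik(b, time, event, Z, offset),
            x0=np.zeros(2),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000},
        )
        assert fit.converged
        np.testing.assert_allclose(fit.coefficients, res.x, atol=1e-5)
        assert fit.log_partial_likelihood == pytest.approx(-res.fun, abs=1e-9)

    def test_matches_lifelines(self, medium_sim):
        """Independent implementation check: continuous times have no ties,
        so Breslow and Efron coincide and lifelines must agree."""
        lifelines = pytest.importorskip("lifelines")
        cohort = medium_sim.cohort.iloc[:800].copy()
        fit = fit_cause_specific(cohort, cause=1)
        cohort["event"] = (cohort["outcome"] == 1).astype(int)
        cph = lifelines.CoxPHFitter().fit(
            cohort[[*COVARIATE_COLUMNS, "time", "event"]], "time", "event"
        )
        np.testing.assert_allclose(fit.coefficients, cph.params_.values, atol=5e-4)
        np.testing.assert_allclose(
            fit.std_errors, cph.standard_errors_.values, atol=1e-4
        )

    def test_breslow_handles_ties(self):
        """With tied event times the risk-set sum includes all tied subjects."""
        cohort = PL_EXAMPLE.copy()
        cohort.loc[2, "time"] = cohort.loc[0, "time"]  # two cause-1 events tie
        time, event, Z, off = _arrays(cohort, cols=("tc", "hdl"))
        from mccrisk.estimate import breslow_loglik

        beta = np.array([0.4, -0.7])
        assert breslow_loglik(beta, time, event, Z, off) == pytest.approx(
            brute_partial_loglik(beta, time, event, Z, off), rel=1e-12
        )


class TestFitBehaviour:
    def test_null_covariate_estimates_zero(self, medium_sim):
        cohort = medium_sim.cohort.copy()
        rng = np.random.default_rng(9)
        cohort["tc"] = rng.normal(0, 1, len(cohort))  # break the association
        offs, emap, mode = mccrm_offsets(cohort, eta=medium_sim.params.eta)
        fit = fit_cause_specific(cohort, 1, offsets=offs, offset_mode=mode)
        j = COVARIATE_COLUMNS.index("tc")
        assert abs(fit.coefficients[j]) < 3 * fit.std_errors[j]

    def test_zero_sdcp_offsets_match_plain_fit(self):
        cfg = SimulationConfig(n_total=1500, censor_ratio=0.2, sdcp=0.0, seed=21)
        sim = simulate_cohort(cfg)
        offs, emap, mode = mccrm_offsets(sim.cohort, eta=sim.params.eta)
        fit_off = fit_cause_specific(sim.cohort, 1, offsets=offs, offset_mode=mode)
        fit_plain = fit_cause_specific(sim.cohort, 1)
        np.testing.assert_allclose(
            fit_off.coefficients, fit_plain.coefficients, atol=1e-6
        )

    def test_separation_is_flagged_not_raised(self):
        # event risk strictly ordered by the covariate: monotone likelihood
        n = 8
        cohort = pd.DataFrame(
            {
                "center_id": 1,
                "tc": -np.arange(n, dtype=float),
                "hdl": 0.0,
                "sbp": 0.0,
                "diabetes": 0,
                "smoking": 0,
                "time": np.arange(1.0, n + 1),
                "outcome": 1,
            }
        )
        fit = fit_cause_specific(cohort, 1, covariate_cols=("tc",))
        assert not fit.converged
        assert fit.message != ""

    def test_no_events_raises(self):
        cohort = PL_EXAMPLE.copy()
        cohort["outcome"] = 0
        with pytest.raises(ValueError, match="no events"):
            fit_cause_specific(cohort, 1)

    def test_serialization_roundtrip(self, tmp_path, medium_sim):
        from mccrisk.estimate import FittedCSModel

        offs, emap, mode = mccrm_offsets(
            medium_sim.cohort, eta=medium_sim.params.eta
        )
        fit = fit_cause_specific(
            medium_sim.cohort, 1, offsets=offs, offset_mode=mode, eta_used=emap
        )
        path = tmp_path / "model.json"
        fit.to_json(path)
        back = FittedCSModel.from_json(path)
        np.testing.assert_array_equal(back.coefficients, fit.coefficients)
        assert back.eta_used == fit.eta_used
        assert back.offset_mode == "known_eta"


class TestOffsets:
    def test_known_eta_lookup(self):
        cohort = pd.DataFrame({"center_id": [1, 2, 2, 1]})
        offs, emap, mode = mccrm_offsets(cohort, eta={1: 0.5, 2: -0.5})
        np.testing.assert_array_equal(offs, [0.5, -0.5, -0.5, 0.5])
        assert mode == "known_eta"

    def test_known_eta_array_and_missing_center(self):
        cohort = pd.DataFrame({"center_id": [1, 2, 3]})
        with pytest.raises(ValueError, match="centers \\[3\\]"):
            mccrm_offsets(cohort, eta=np.array([0.1, -0.1]))

    def test_equal_incidence_gives_zero_offsets(self):
        # two centers, identical cause-1 incidence by the horizon
        cohort = pd.DataFrame(
            {
                "center_id": [1] * 10 + [2] * 10,
                "time": [0.5] * 20,
                "outcome": ([1] * 3 + [0] * 7) * 2,
            }
        )
        offs, emap, mode = mccrm_offsets(cohort, horizon=1.0)
        np.testing.assert_allclose(offs, 0.0, atol=1e-14)
        assert mode == "eta_from_incidence"

    def test_zero_event_center_errors_unless_smoothed(self):
        cohort = pd.DataFrame(
            {
                "center_id": [1] * 10 + [2] * 10,
                "time": [0.5] * 20,
                "outcome": [1] * 3 + [0] * 7 + [0] * 10,
            }
        )
        with pytest.raises(ValueError, match="no cause-1 events"):
            mccrm_offsets(cohort, horizon=1.0)
        offs, emap, _ = mccrm_offsets(cohort, horizon=1.0, laplace=True)
        assert emap[2] < 0 < emap[1]

    def test_incidence_mode_recovers_generative_eta(self):
        """Estimated offsets correlate > 0.95 with the generative ones."""
        cfg = SimulationConfig(
            n_total=8500, censor_ratio=0.2, sdcp=1.0, n_centers=17, seed=31
        )
        sim = simulate_cohort(cfg)
        _, emap, _ = mccrm_offsets(sim.cohort, horizon=1.0)
        est = np.array([emap[k] for k in range(1, 18)])
        r = np.corrcoef(est, sim.params.eta)[0, 1]
        assert r > 0.95

    def test_exactly_one_mode(self):
        cohort = pd.DataFrame({"center_id": [1, 2]})
        with pytest.raises(ValueError, match="exactly one"):
            mccrm_offsets(cohort)


class TestLinearPredictor:
    def test_zero_input(self, medium_sim):
        fit = fit_cause_specific(medium_sim.cohort, 1)
        zero = medium_sim.cohort.iloc[:1].copy()
        for c in COVARIATE_COLUMNS:
            zero[c] = 0.0
        assert linear_predictor(fit, zero)[0] == 0.0

    def test_constant_offset_shift(self, medium_sim):
        offs, emap, mode = mccrm_offsets(
            medium_sim.cohort, eta=medium_sim.params.eta
        )
        fit = fit_cause_specific(
            medium_sim.cohort, 1, offsets=offs, offset_mode=mode, eta_used=emap
        )
        lp = linear_predictor(fit, medium_sim.cohort, offs)
        lp_shift = linear_predictor(fit, medium_sim.cohort, offs + 1.7)
        np.testing.assert_allclose(lp_shift - lp, 1.7, rtol=1e-12)

    def test_offsets_reconstructed_from_eta_used(self, medium_sim):
        offs, emap, mode = mccrm_offsets(
            medium_sim.cohort, eta=medium_sim.params.eta
        )
        fit = fit_cause_specific(
            medium_sim.cohort, 1, offsets=offs, offset_mode=mode, eta_used=emap
        )
        np.testing.assert_allclose(
            linear_predictor(fit, medium_sim.cohort),
            linear_predictor(fit, medium_sim.cohort, offs),
            rtol=1e-12,
        )
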