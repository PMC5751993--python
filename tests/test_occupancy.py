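"""Occupancy likelihood, MLE, model enumeration, AICc, and site summaries."""

import itertools
import math

import numpy as np
import pytest

from camtrap.data import ValidationError
from camtrap.io import build_detection_matrix
from camtrap.occupancy import (
    OccModelSpec,
    aicc,
    design_matrices,
    enumerate_model_set,
    fit_occupancy,
    occ_loglik,
    rank_aicc,
    site_psi,
)
from camtrap.simulate import DEFAULT_SPECIES, SimScenario, sim_occupancy_detections, sim_stations

from conftest import make_station


def brute_force_loglik(params, y, Xpsi, Xp):
    """Exhaustive enumeration over the joint latent presence vector."""
    kpsi = Xpsi.shape[1]
    psi = 1 / (1 + np.exp(-(Xpsi @ params[:kpsi])))
    p = 1 / (1 + np.exp(-(Xp @ params[kpsi:])))
    n = y.shape[0]
    total = 0.0
    for zvec in itertools.product([0, 1], repeat=n):
        prob = 1.0
        for s, z in enumerate(zvec):
            prob *= psi[s] if z else (1 - psi[s])
            for o in range(y.shape[1]):
                if math.isnan(y[s, o]):
                    continue
                if z:
                    prob *= p[s] if y[s, o] else (1 - p[s])
                elif y[s, o]:
                    prob *= 0.0
        total += prob
    return math.log(total)


class TestLoglik:
    def test_two_occasion_closed_forms(self):
        X1 = np.ones((1, 1))
        th = np.zeros(2)  # psi = p = 0.5
        ll00 = occ_loglik(th, np.array([[0.0, 0.0]]), X1, X1)
        assert ll00 == pytest.approx(math.log(0.5 * 0.25 + 0.5), abs=1e-12)
        ll10 = occ_loglik(th, np.array([[1.0, 0.0]]), X1, X1)
        assert math.exp(ll10) == pytest.approx(0.125, abs=1e-12)

    def test_matches_enumeration_with_covariates(self, rng):
        for _ in range(30):
            n_s = int(rng.integers(2, 5))
            n_o = int(rng.integers(2, 5))
            Xpsi = np.column_stack([np.ones(n_s), rng.normal(size=n_s)])
            Xp = np.column_stack([np.ones(n_s), rng.normal(size=n_s)])
            params = rng.normal(scale=0.8, size=4)
            y = rng.integers(0, 2, size=(n_s, n_o)).astype(float)
            y[rng.random(size=y.shape) < 0.15] = np.nan
            got = occ_loglik(params, y, Xpsi, Xp)
            want = brute_force_loglik(params, y, Xpsi, Xp)
            assert got == pytest.approx(want, abs=1e-10)

    def test_all_missing_station_contributes_zero(self):
        X1 = np.ones((2, 1))
        y = np.array([[1.0, 0.0], [np.nan, np.nan]])
        with_blank = occ_loglik(np.zeros(2), y, X1, X1)
        alone = occ_loglik(np.zeros(2), y[:1], X1[:1], X1[:1])
        assert with_blank == pytest.approx(alone, abs=1e-12)

    def test_nonfinite_params_rejected(self):
        X1 = np.ones((1, 1))
        with pytest.raises(ValidationError):
            occ_loglik(np.array([np.inf, 0.0]), np.zeros((1, 2)), X1, X1)


class TestFit:
    def test_zero_detections_refused(self, tiny_stations):
        dm = build_detection_matrix([], tiny_stations, "paca", 10)
        with pytest.raises(ValidationError, match="naive zero"):
            fit_occupancy(OccModelSpec("paca"), dm, tiny_stations)

    def test_constant_model_matches_grid_search(self):
        # psi(.)p(.): MLE from the fitter equals a fine grid search
        rng = np.random.default_rng(42)
        n_s, n_o = 60, 6
        z = rng.random(n_s) < 0.6
        y = ((rng.random((n_s, n_o)) < 0.35) & z[:, None]).astype(float)
        stations = [make_station(f"S{i}", x=float(i)) for i in range(n_s)]
        from camtrap.data import DetectionMatrix

        dm = DetectionMatrix("sp", [s.station_id for s in stations], n_o, y,
                             np.ones((n_s, n_o), dtype=int))
        fit = fit_occupancy(OccModelSpec("sp"), dm, stations)
        grid = np.linspace(0.01, 0.99, 197)
        X1 = np.ones((n_s, 1))
        best = -np.inf
        for psi in grid:
            for p in grid:
                th = np.array([np.log(psi / (1 - psi)), np.log(p / (1 - p))])
                ll = occ_loglik(th, y, X1, X1)
                if ll > best:
                    best, best_psi, best_p = ll, psi, p
        assert fit.loglik >= best - 1e-6
        assert fit.psi_hat[0] == pytest.approx(best_psi, abs=0.01)
        assert fit.p_hat[0] == pytest.approx(best_p, abs=0.01)

    def test_recovers_simulated_effects(self, wlp_scenario):
        st = sim_stations(wlp_scenario)
        events = sim_occupancy_detections(wlp_scenario, st)
        dm = build_detection_matrix(events, st, "white-lipped peccary", 10)
        fit = fit_occupancy(
            OccModelSpec("white-lipped peccary", ("ST",), ("DC",)), dm, st
        )
        assert fit.converged
        b = fit.coef("psi_ST")
        se = fit.coef_se("psi_ST")
        assert abs(b - 0.77) < 3 * se

    def test_nesting_never_hurts_loglik(self, wlp_scenario):
        st = sim_stations(wlp_scenario)
        events = sim_occupancy_detections(wlp_scenario, st)
        dm = build_detection_matrix(events, st, "white-lipped peccary", 10)
        f0 = fit_occupancy(OccModelSpec("white-lipped peccary", ("ST",)), dm, st)
        f1 = fit_occupancy(OccModelSpec("white-lipped peccary", ("ST", "H")), dm, st)
        assert f1.loglik >= f0.loglik - 1e-6


class TestModelSet:
    def test_full_enumeration_is_16(self):
        specs = enumerate_model_set("paca")
        assert len(specs) == 16
        assert len(set(specs)) == 16

    def test_strict_15_is_15(self):
        specs = enumerate_model_set("paca", strict_15=True)
        assert len(specs) == 15

    def test_k_counts(self):
        for spec in enumerate_model_set("paca"):
            assert spec.n_params == 2 + len(spec.psi_covariates) + len(spec.p_covariates)


class TestAicc:
    def test_formula(self):
        assert aicc(-10, 2, 100) == pytest.approx(24 + 12 / 97, abs=1e-10)

    def test_limits_to_aic(self):
        assert abs(aicc(-10, 3, 10**9) - (2 * 10 + 2 * 3)) < 1e-6

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            aicc(-10, 5, 6)

    def test_ranking_ties_and_weights(self):
        from camtrap.occupancy import OccupancyFit

        def mkfit(spec, ll):
            k = spec.n_params
            return OccupancyFit(spec, np.zeros(k), np.zeros(k), np.zeros((k, k)),
                                ll, True, np.array([0.5]), np.array([0.5]),
                                ["x"] * k)

        f2 = mkfit(OccModelSpec("sp"), -10.0)
        f3 = mkfit(OccModelSpec("sp", ("ST",)), -10.0)
        table = rank_aicc([f2, f3], n=100)
        assert table["K"].iloc[0] == 2  # smaller K first on equal loglik
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)


class TestSitePsi:
    def test_constant_model_site_means_equal(self, stations):
        sc = SimScenario(seed=77, species=(DEFAULT_SPECIES[6],))  # agouti
        events = sim_occupancy_detections(sc, stations)
        dm = build_detection_matrix(events, stations, DEFAULT_SPECIES[6].name, 10)
        fit = fit_occupancy(OccModelSpec(DEFAULT_SPECIES[6].name), dm, stations)
        table = site_psi(fit, stations)
        assert table["psi"].std() < 1e-12
        assert (table["se"] > 0).all()

    def test_two_station_arithmetic(self):
        # psi-hat 0.2 and 0.6 -> site mean 0.4 (direct average of predictions)
        sts = [make_station("S1", dist_settlement=1.0),
               make_station("S2", dist_settlement=2.0)]
        spec = OccModelSpec("sp", ("ST",))
        Xpsi, _, _ = design_matrices(spec, sts)
        # coefficients chosen to hit psi = 0.2 and 0.6 exactly
        from scipy.special import logit

        b1 = logit(0.6) - logit(0.2)
        b0 = logit(0.2) - b1
        from camtrap.occupancy import OccupancyFit

        fit = OccupancyFit(spec, np.array([b0, b1, 0.0]), np.zeros(3),
                           np.zeros((3, 3)), 0.0, True,
                           np.array([0.2, 0.6]), np.array([0.5, 0.5]),
                           ["psi_intercept", "psi_ST", "p_intercept"])
        table = site_psi(fit, sts)
        assert table["psi"].iloc[0] == pytest.approx(0.4, abs=1e-12)
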