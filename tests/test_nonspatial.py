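"""Jackknife abundance, closure test, MMDM, disk-union ETA, delta-method SE."""

from fractions import Fraction
from math import comb, factorial

import numpy as np
import pytest

from camtrap.data import CaptureRecord, ValidationError
from camtrap.nonspatial import (
    JackknifeResult,
    closure_check,
    density_nonspatial,
    effective_trapping_area,
    jackknife_coefficients,
    jackknife_mh,
    mmdm,
)

from conftest import make_station


def generalized_jackknife(f: np.ndarray, t: int, k: int) -> float:
    """Independent oracle: Gray-Schucany generalized jackknife built from
    exact leave-d-out subset expectations of the observed count (exact
    rational arithmetic)."""
    S = int(f.sum())

    def sbar(d):
        out = Fraction(S)
        for i in range(1, d + 1):
            if f[i - 1]:
                out -= Fraction(int(f[i - 1]) * comb(t - i, t - d), comb(t, t - d))
        return out

    total = Fraction(0)
    for d in range(k + 1):
        total += (-1) ** d * comb(k, d) * Fraction((t - d) ** k) * sbar(d)
    return float(total / factorial(k))


def matrix_from_frequencies(f: np.ndarray, t: int, rng) -> np.ndarray:
    rows = []
    for i, cnt in enumerate(f, start=1):
        for _ in range(int(cnt)):
            row = np.zeros(t, dtype=int)
            row[rng.choice(t, size=i, replace=False)] = 1
            rows.append(row)
    return np.array(rows)


class TestJackknife:
    def test_first_order_closed_form(self, rng):
        f = np.zeros(10, dtype=int)
        f[0], f[1] = 3, 3  # S = 6, f1 = 3, t = 10
        X = matrix_from_frequencies(f, 10, rng)
        res = jackknife_mh(X, fixed_order=1)
        assert res.n_hat == pytest.approx(6 + 3 * 9 / 10, abs=1e-12)  # 8.7

    def test_no_singletons_collapses_to_s(self, rng):
        f = np.zeros(10, dtype=int)
        f[2] = 5  # everyone captured three times
        X = matrix_from_frequencies(f, 10, rng)
        res = jackknife_mh(X, fixed_order=1)
        assert res.n_hat == pytest.approx(5.0, abs=1e-12)

    def test_orders_match_independent_construction(self, rng):
        for _ in range(100):
            t = int(rng.integers(6, 31))
            f = np.zeros(t, dtype=int)
            f[: min(8, t)] = rng.integers(0, 6, size=min(8, t))
            if f.sum() == 0:
                f[0] = 1
            X = matrix_from_frequencies(f, t, rng)
            res = jackknife_mh(X)
            for k, (nk, _) in res.per_order.items():
                want = generalized_jackknife(f, t, k)
                assert nk == pytest.approx(want, abs=1e-9 * max(1.0, abs(want)))

    def test_estimate_never_below_observed(self, rng):
        for _ in range(50):
            t = int(rng.integers(4, 20))
            f = np.zeros(t, dtype=int)
            f[: min(6, t)] = rng.integers(0, 4, size=min(6, t))
            if f.sum() == 0:
                f[1] = 2
            X = matrix_from_frequencies(f, t, rng)
            res = jackknife_mh(X)
            assert res.n_hat >= X.shape[0] - 1e-9

    def test_simulated_heterogeneity_bias_moderate(self):
        # Mh data: individual capture probabilities from a beta distribution
        rng = np.random.default_rng(2)
        N, t = 50, 30
        bias = []
        for _ in range(150):
            p = rng.beta(1.2, 8.0, size=N)
            X = (rng.random((N, t)) < p[:, None]).astype(int)
            X = X[X.sum(axis=1) > 0]
            if X.shape[0] < 5:
                continue
            bias.append(jackknife_mh(X).n_hat / N - 1)
        assert abs(np.mean(bias)) < 0.15

    def test_all_caught_every_occasion(self, rng):
        X = np.ones((4, 6), dtype=int)
        res = jackknife_mh(X)
        assert res.n_hat == pytest.approx(4.0, abs=1e-9)


class TestClosure:
    def test_not_computable_single_capture(self):
        X = np.zeros((1, 30), dtype=int)
        X[0, 4] = 1
        res = closure_check(X)
        assert not res.computable

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        ps = []
        for r in range(200):
            X = (rng.random((12, 30)) < 0.15).astype(int)
            X = X[X.sum(axis=1) > 0]
            if not (X.sum(axis=1) >= 2).any():
                continue
            res = closure_check(X, n_mc=400, seed=r)
            ps.append(res.p_value)
        ps = np.array(ps)
        assert 0.005 < (ps < 0.05).mean() < 0.12
        assert 0.35 < (ps < 0.5).mean() < 0.65

    def test_violation_detected(self):
        # half the individuals only early, half only late -> closure rejected
        rng = np.random.default_rng(4)
        X = np.zeros((20, 30), dtype=int)
        X[:10, :5] = (rng.random((10, 5)) < 0.6).astype(int)
        X[10:, 25:] = (rng.random((10, 5)) < 0.6).astype(int)
        X = X[X.sum(axis=1) >= 2]
        res = closure_check(X, n_mc=1000, seed=0)
        assert res.p_value < 0.01


class TestMmdm:
    def _stations(self):
        return [
            make_station("S1", x=0.0, y=0.0),
            make_station("S2", x=3.0, y=4.0),
            make_station("S3", x=8.0, y=0.0),
        ]

    def test_3_4_5_triangle(self):
        recs = [CaptureRecord("J1", "S1", 1, "A"), CaptureRecord("J1", "S2", 9, "A")]
        mean, se, n = mmdm(recs, self._stations())
        assert mean == pytest.approx(5.0, abs=1e-12)
        assert n == 1 and se == 0.0

    def test_pooled_mean(self):
        recs = [
            CaptureRecord("J1", "S1", 1, "A"), CaptureRecord("J1", "S2", 9, "A"),
            CaptureRecord("J2", "S1", 2, "A"), CaptureRecord("J2", "S3", 5, "A"),
            CaptureRecord("J3", "S1", 2, "A"), CaptureRecord("J3", "S1", 7, "A"),
        ]
        mean, se, n = mmdm(recs, self._stations())
        assert n == 2  # J3 never moved stations
        assert mean == pytest.approx((5.0 + 8.0) / 2, abs=1e-12)

    def test_no_movers_rejected(self):
        recs = [CaptureRecord("J1", "S1", 1, "A")]
        with pytest.raises(ValidationError, match="buffer"):
            mmdm(recs, self._stations())


class TestEta:
    def test_single_disk(self):
        area, se = effective_trapping_area(np.array([[0.0, 0.0]]), 6.08)
        assert area == pytest.approx(np.pi * 6.08**2, rel=2e-4)

    def test_disjoint_disks_additive(self):
        traps = np.array([[0.0, 0.0], [20.0, 0.0]])
        area, _ = effective_trapping_area(traps, 6.08)
        assert area == pytest.approx(2 * np.pi * 6.08**2, rel=2e-4)

    def test_monotone_in_buffer_and_bounded(self, rng):
        traps = rng.uniform(0, 10, size=(8, 2))
        areas = [effective_trapping_area(traps, r)[0] for r in (1.0, 2.0, 4.0)]
        assert areas[0] < areas[1] < areas[2]
        assert areas[2] <= 8 * np.pi * 16 + 1e-6

    def test_coordinate_scaling_quadruples_disjoint_area(self):
        traps = np.array([[0.0, 0.0], [30.0, 0.0]])
        a1, _ = effective_trapping_area(traps, 2.0)
        a2, _ = effective_trapping_area(2 * traps, 4.0)
        assert a2 == pytest.approx(4 * a1, rel=1e-9)

    def test_perturbation_se(self):
        area, se = effective_trapping_area(np.array([[0.0, 0.0]]), 6.0, buffer_se=0.5)
        # d(pi r^2)/dr * se = 2 pi r se
        assert se == pytest.approx(2 * np.pi * 6.0 * 0.5, rel=1e-2)


class TestDensity:
    def test_delta_method_arithmetic(self):
        jk = JackknifeResult(10.0, 2.0, 1.0, {1: (10.0, 2.0)},
                             np.array([3, 3, 0, 0, 0, 0, 0, 0, 0, 0]), 6, {})
        est = density_nonspatial(jk, 458.0, 10.0)
        assert est.d_hat == pytest.approx(10 / 458 * 100, abs=1e-9)
        assert est.se == pytest.approx(
            est.d_hat * np.sqrt((2 / 10) ** 2 + (10 / 458) ** 2), abs=1e-9
        )

    def test_zero_se_degenerate(self):
        jk = JackknifeResult(10.0, 0.0, 1.0, {}, np.zeros(5, dtype=int), 6, {})
        est = density_nonspatial(jk, 100.0, 0.0)
        assert est.se == 0.0

    def test_inverse_scaling_with_eta(self):
        jk = JackknifeResult(12.0, 1.0, 1.0, {}, np.zeros(5, dtype=int), 6, {})
        a = density_nonspatial(jk, 200.0, 0.0)
        b = density_nonspatial(jk, 400.0, 0.0)
        assert a.d_hat == pytest.approx(2 * b.d_hat, abs=1e-12)
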