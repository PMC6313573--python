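"""Ordinary/indicator/residual kriging against hand-solved oracles, and LOOCV."""

import numpy as np
import pytest

from geoexpose.kriging import (
    ObservationSet,
    indicator_krige,
    loocv,
    loocv_residual,
    ordinary_krige,
    residual_krige,
)
from geoexpose.variogram import VariogramModel


@pytest.fixture
def model():
    return VariogramModel("spherical", 0.0, 1.0, 5.0)


@pytest.fixture
def three_points():
    return ObservationSet([0.0, 1.0, 2.0], [0.0, 1.0, 0.0], [1.0, 3.0, 2.0])


def hand_krige(obs, model, x0, y0):
    """Independent oracle: assemble and solve the kriging system directly."""
    n = len(obs)
    xy = np.column_stack([obs.x, obs.y])
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            A[i, j] = model(np.linalg.norm(xy[i] - xy[j]))
    A[n, :n] = A[:n, n] = 1.0
    b = np.append(model(np.linalg.norm(xy - np.array([x0, y0]), axis=1)), 1.0)
    sol = np.linalg.solve(A, b)
    pred = sol[:n] @ obs.values
    var = sol[:n] @ b[:n] + sol[n]
    return pred, max(var, 0.0), sol[:n]


class TestOrdinary:
    def test_exact_at_data_with_zero_nugget(self, three_points, model):
        p, v = ordinary_krige(three_points, model, three_points.x, three_points.y)
        assert np.allclose(p, three_points.values)
        assert np.allclose(v, 0.0, atol=1e-10)

    def test_single_observation_constant_surface(self, model):
        obs = ObservationSet([5.0], [5.0], [2.5])
        p, v = ordinary_krige(obs, model, [0.0, 10.0], [0.0, 3.0])
        assert np.allclose(p, 2.5)

    @pytest.mark.parametrize("target", [(0.5, 0.5), (1.7, 0.2), (5.0, 5.0)])
    def test_matches_hand_solved_system(self, three_points, model, target):
        p, v = ordinary_krige(three_points, model, [target[0]], [target[1]])
        po, vo, w = hand_krige(three_points, model, *target)
        assert p[0] == pytest.approx(po, abs=1e-8)
        assert v[0] == pytest.approx(vo, abs=1e-8)
        assert w.sum() == pytest.approx(1.0, abs=1e-8)

    def test_weights_sum_via_constant_shift(self, three_points, model, rng):
        # adding a constant to data shifts every BLUP by that constant
        tx, ty = rng.uniform(0, 3, 7), rng.uniform(0, 3, 7)
        p1, _ = ordinary_krige(three_points, model, tx, ty)
        shifted = ObservationSet(three_points.x, three_points.y, three_points.values + 10.0)
        p2, _ = ordinary_krige(shifted, model, tx, ty)
        assert np.allclose(p2 - p1, 10.0, atol=1e-8)

    def test_variance_nonnegative_with_nugget(self, rng):
        obs = ObservationSet(rng.uniform(0, 20, 30), rng.uniform(0, 20, 30),
                             rng.normal(0, 1, 30))
        m = VariogramModel("exponential", 0.3, 0.7, 8.0)
        _, v = ordinary_krige(obs, m, rng.uniform(0, 20, 50), rng.uniform(0, 20, 50))
        assert np.all(v >= 0)

    def test_duplicate_coordinates_averaged(self):
        with pytest.warns(UserWarning, match="duplicate"):
            obs = ObservationSet([0, 0, 1], [0, 0, 0], [1.0, 3.0, 5.0])
        assert len(obs) == 2
        assert 2.0 in obs.values


class TestIndicator:
    def test_single_class_constant(self, rng):
        obs = ObservationSet(rng.uniform(0, 10, 8), rng.uniform(0, 10, 8),
                             rng.uniform(1, 2, 8), censored=np.zeros(8, bool))
        with pytest.warns(UserWarning, match="single class"):
            p, _ = indicator_krige(obs, [5.0], [5.0])
        assert p[0] == 1.0

    def test_equals_ordinary_kriging_on_indicators(self, rng):
        n = 10
        x, y = rng.uniform(0, 20, n), rng.uniform(0, 20, n)
        cens = rng.random(n) < 0.4
        obs = ObservationSet(x, y, rng.uniform(0, 3, n), censored=cens)
        m = VariogramModel("spherical", 0.05, 0.2, 8.0)
        tx, ty = rng.uniform(0, 20, 15), rng.uniform(0, 20, 15)
        p, _ = indicator_krige(obs, tx, ty, model=m)
        ind_obs = ObservationSet(x, y, (~cens).astype(float))
        p_ok, _ = ordinary_krige(ind_obs, m, tx, ty)
        assert np.allclose(p, np.clip(p_ok, 0, 1), atol=1e-10)
        assert np.all((p >= 0) & (p <= 1))


class TestResidual:
    def test_constant_trend_matches_ordinary(self, rng):
        n = 25
        obs = ObservationSet(rng.uniform(0, 30, n), rng.uniform(0, 30, n),
                             rng.normal(5, 1, n))
        m = VariogramModel("spherical", 0.1, 0.9, 10.0)
        tx, ty = rng.uniform(0, 30, 9), rng.uniform(0, 30, 9)
        cov = np.ones((n, 1))
        p_rk, _ = residual_krige(obs, cov, np.ones((9, 1)), tx, ty,
                                 trend_fitter="linear", residual_model=m)
        p_ok, _ = ordinary_krige(obs, m, tx, ty)
        assert np.allclose(p_rk, p_ok, atol=1e-6)

    def test_noiseless_linear_field_exact(self, rng):
        n = 30
        x, y = rng.uniform(0, 30, n), rng.uniform(0, 30, n)
        z = 2.0 * x + 0.5 * y + 1.0
        obs = ObservationSet(x, y, z)
        cov = np.column_stack([x, y])
        tx, ty = rng.uniform(0, 30, 10), rng.uniform(0, 30, 10)
        p, _ = residual_krige(obs, cov, np.column_stack([tx, ty]), tx, ty,
                              trend_fitter="linear")
        assert np.allclose(p, 2.0 * tx + 0.5 * ty + 1.0, atol=1e-6)

    def test_nugget_only_residuals_predict_trend(self, rng):
        n = 40
        x, y = rng.uniform(0, 30, n), rng.uniform(0, 30, n)
        z = 3.0 * x + rng.normal(0, 0.5, n)
        obs = ObservationSet(x, y, z)
        nug = VariogramModel("spherical", 0.25, 0.0, 5.0)
        tx, ty = rng.uniform(0, 30, 6), rng.uniform(0, 30, 6)
        p, diag = residual_krige(obs, x[:, None], tx[:, None], tx, ty,
                                 trend_fitter="linear", residual_model=nug)
        trend_at_targets = diag["trend"].predict(tx[:, None])
        # kriged nugget-only residual is the residual mean ~ 0
        assert np.allclose(p, trend_at_targets + diag["residuals"].mean(), atol=1e-8)


class TestLoocv:
    def test_perfect_predictor(self, rng):
        obs = ObservationSet(rng.uniform(0, 10, 6), rng.uniform(0, 10, 6),
                             np.arange(6.0))
        truth = dict(zip(zip(obs.x, obs.y), obs.values))
        out = loocv(obs, lambda tr, _c, x0, y0: truth[(x0[0], y0[0])])
        assert out["me"] == 0.0 and out["rmse"] == 0.0

    def test_error_statistics_sign_conventions(self, rng):
        obs = ObservationSet([0, 5, 10], [0, 0, 0], [1.0, 1.0, 1.0])
        plus_one = loocv(obs, lambda tr, _c, x0, y0: 2.0)
        assert plus_one["me"] == pytest.approx(1.0)
        assert plus_one["rmse"] == pytest.approx(1.0)
        # errors {+2, -2, +2} -> ME 2/3, RMSE 2
        alt = {0.0: 3.0, 5.0: -1.0, 10.0: 3.0}
        mixed = loocv(obs, lambda tr, _c, x0, y0: alt[x0[0]])
        assert mixed["rmse"] == pytest.approx(2.0)

    def test_by_type_breakdown(self, rng):
        obs = ObservationSet([0, 5, 10, 15], [0] * 4, [1.0] * 4,
                             station_type=np.array(["a", "a", "b", "b"]))
        out = loocv(obs, lambda tr, _c, x0, y0: 1.5)
        assert set(out["by_type"]) == {"a", "b"}
        assert out["by_type"]["a"]["me"] == pytest.approx(0.5)

    def test_linear_field_loocv_near_zero(self, rng):
        n = 20
        x, y = rng.uniform(0, 30, n), rng.uniform(0, 30, n)
        obs = ObservationSet(x, y, 2.0 * x + 1.0)
        out = loocv_residual(obs, x[:, None], trend_fitter="linear")
        assert out["rmse"] < 1e-6
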