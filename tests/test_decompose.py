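"""The low-rank + sparse decomposition solver."""

import warnings

import numpy as np
import pytest
from scipy.optimize import least_squares

from shadecorr import (
    ImageStack,
    SolverOptions,
    build_measurement_matrix,
    decompose,
    estimate_shading,
    estimation_score,
)
from shadecorr.decomposition import MeasurementMatrix
from shadecorr.exceptions import DataError, InputSizeError
from shadecorr.synthetic import simulate_collection


def _cosine_flatfield(n):
    """A mean-1, strictly positive field built from low-order cosines only."""
    y = np.cos(np.pi * (np.arange(n) + 0.5) / n)
    field = 1.0 + 0.15 * np.add.outer(y, y) + 0.1 * np.outer(y, y)
    return field / field.mean()


@pytest.fixture(scope="module")
def exact_rank2_matrix():
    """Noise-free matrix B_i * S + D with known smooth truth."""
    n = 32
    S = _cosine_flatfield(n)
    D = 6.0
    B = np.array([40.0, 55.0, 70.0, 90.0, 120.0, 150.0])
    data = S.ravel()[:, None] * B[None, :] + D
    mm = MeasurementMatrix(data, working_height=n, working_width=n)
    return mm, S, D, B


class TestExactRecovery:
    def test_zero_residual_matrix_recovers_truth(self, exact_rank2_matrix):
        mm, S, D, B = exact_rank2_matrix
        res = decompose(mm, SolverOptions(lambda_s=0.0, lambda_d=0.0))
        gamma = estimation_score(res.flatfield_vec.reshape(S.shape), S,
                                 np.ones_like(S))
        assert gamma < 0.01
        assert np.corrcoef(res.baselines, B)[0, 1] > 0.999
        assert res.dark_mean == pytest.approx(D, rel=0.05)

    def test_lowrank_component_has_rank_at_most_two(self, exact_rank2_matrix):
        mm, *_ = exact_rank2_matrix
        res = decompose(mm, SolverOptions(lambda_s=0.0, lambda_d=0.0))
        assert np.linalg.matrix_rank(res.lowrank, tol=1e-8 * res.lowrank.max()) <= 2

    def test_feasibility_identity(self, small_scene):
        mm = build_measurement_matrix(small_scene.measured_images, 64, sort=False)
        res = decompose(mm, SolverOptions())
        gap = (np.linalg.norm(mm.data - res.lowrank - res.residual)
               / np.linalg.norm(mm.data))
        assert gap <= 1e-6
        assert res.final_feasibility_gap <= 1e-6
        # consistency of the reported split
        np.testing.assert_allclose(
            res.darkfield_vec, res.dark_mean + res.dark_residual_vec, atol=1e-9
        )


class TestSmallInstanceOracle:
    def test_agrees_with_brute_force_least_squares(self):
        """3x3-pixel, 4-image, zero-residual problem vs direct optimization."""
        rng = np.random.default_rng(5)
        y = np.cos(np.pi * (np.arange(3) + 0.5) / 3)
        S = 1.0 + 0.2 * np.add.outer(y, y)
        S = S / S.mean()
        B = np.array([20.0, 30.0, 45.0, 60.0])
        dz = 4.0
        data = S.ravel()[:, None] * B[None, :] + dz
        mm = MeasurementMatrix(data, working_height=3, working_width=3)
        res = decompose(mm, SolverOptions(lambda_s=0.0, lambda_d=0.0))

        # independent oracle: direct least squares over the rank-2 structure
        def unpack(theta):
            s = theta[:9]
            s = s / s.mean()
            return s, theta[9:13], theta[13]

        def resid(theta):
            s, b, d = unpack(theta)
            return (s[:, None] * b[None, :] + d - data).ravel()

        theta0 = np.concatenate([
            np.ones(9) + 0.01 * rng.normal(size=9),
            data.mean(axis=0), [0.0],
        ])
        sol = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14)
        s_hat, b_hat, d_hat = unpack(sol.x)
        assert np.abs(resid(sol.x)).max() < 1e-8  # oracle actually solved it

        np.testing.assert_allclose(res.flatfield_vec, s_hat, rtol=1e-4)
        np.testing.assert_allclose(res.baselines, b_hat, rtol=1e-3)
        assert res.dark_mean == pytest.approx(d_hat, abs=0.05)


class TestInvariances:
    def test_scale_equivariance(self, small_scene):
        mm = build_measurement_matrix(small_scene.measured_images, 64, sort=False)
        opts = SolverOptions(lambda_s=1.0, lambda_d=0.2)
        res1 = decompose(mm, opts)
        mm2 = MeasurementMatrix(mm.data * 37.0, 64, 64)
        res2 = decompose(mm2, opts)
        np.testing.assert_allclose(res2.flatfield_vec, res1.flatfield_vec,
                                   rtol=1e-7, atol=1e-9)
        np.testing.assert_allclose(res2.darkfield_vec, 37.0 * res1.darkfield_vec,
                                   rtol=1e-6, atol=1e-6)
        np.testing.assert_allclose(res2.baselines, 37.0 * res1.baselines,
                                   rtol=1e-7)

    def test_image_order_invariance(self, small_scene):
        frames = small_scene.measured_images.frames
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(frames))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = estimate_shading(ImageStack(frames))
            m2 = estimate_shading(ImageStack(frames[perm]))
        np.testing.assert_allclose(m2.flatfield, m1.flatfield, atol=1e-9)
        np.testing.assert_allclose(m2.darkfield, m1.darkfield, atol=1e-7)

    def test_update_size_monotone_after_warmup(self, small_scene):
        mm = build_measurement_matrix(small_scene.measured_images, 64, sort=False)
        res = decompose(mm, SolverOptions(estimate_darkfield=False,
                                          feasibility_tol=0.0,
                                          inner_max_iter=40))
        h = np.asarray(res.gap_history)
        assert len(h) == 40
        assert np.all(np.diff(h[10:]) <= 1e-12 + 1e-6 * h[10:-1])


class TestEdgeCases:
    def test_constant_stack_returns_trivial_model_with_warning(self):
        mm = build_measurement_matrix(
            ImageStack(np.full((4, 16, 16), 7.0)), 16, sort=False)
        with pytest.warns(UserWarning, match="constant"):
            res = decompose(mm, SolverOptions())
        np.testing.assert_allclose(res.flatfield_vec, 1.0)
        np.testing.assert_allclose(res.darkfield_vec, 7.0)

    def test_non_finite_rejected(self):
        data = np.ones((16, 3))
        data[4, 1] = np.inf
        mm = MeasurementMatrix(data, 4, 4)
        with pytest.raises(DataError):
            decompose(mm, SolverOptions())

    def test_single_column_rejected(self):
        mm = MeasurementMatrix(np.ones((16, 1)), 4, 4)
        with pytest.raises(InputSizeError):
            decompose(mm, SolverOptions())
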