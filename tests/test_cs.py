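import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sparsect import (
    CsConfig,
    ImageGrid,
    ProjectionGeometry,
    WaveletOperator,
    alternating_param_search,
    build_system_matrix,
    cost,
    cost_gradient,
    forward_project,
    nlcg_reconstruct,
    param_search,
    rrmse,
    smoothed_abs,
    smoothed_abs_grad,
    tv_gradient,
    tv_norm,
)

from oracles import numerical_gradient

XI = 1e-15


class TestSmoothedAbs:
    def test_at_zero(self):
        assert smoothed_abs(0.0, XI) == pytest.approx(np.sqrt(XI))
        assert smoothed_abs_grad(0.0, XI) == 0.0

    def test_approaches_abs_for_large_arguments(self):
        assert smoothed_abs(3.0, XI) == pytest.approx(3.0, rel=1e-12)
        assert smoothed_abs(-3.0, XI) == pytest.approx(3.0, rel=1e-12)

    def test_derivative_matches_finite_difference(self):
        eps = 1e-7
        fd = (smoothed_abs(1.0 + eps, XI) - smoothed_abs(1.0 - eps, XI)) / (2 * eps)
        assert smoothed_abs_grad(1.0, XI) == pytest.approx(fd, abs=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(hst.floats(min_value=-100, max_value=100, allow_nan=False))
    def test_dominates_abs_and_bounded_by_sqrt_xi(self, x):
        s = smoothed_abs(x, XI)
        assert s >= abs(x)
        assert s <= abs(x) + np.sqrt(XI)


class TestTvNorm:
    def test_constant_image_zero(self):
        assert tv_norm(np.full((5, 5), 2.3), 0.0) == 0.0

    def test_hand_example_two_horizontal_jumps(self):
        assert tv_norm(np.array([[0.0, 1.0], [0.0, 1.0]]), 0.0) == pytest.approx(2.0)

    def test_transpose_symmetry(self, rng):
        img = rng.random((9, 9))
        assert tv_norm(img, 0.0) == pytest.approx(tv_norm(img.T, 0.0), rel=1e-12)

    def test_zero_image_smoothed_value(self):
        # Every pixel contributes sqrt(xi).
        assert tv_norm(np.zeros((4, 4)), XI) == pytest.approx(16 * np.sqrt(XI), rel=1e-9)


class TestTvGradient:
    def test_constant_image_zero_gradient(self):
        g = tv_gradient(np.full((6, 6), 1.7), XI)
        np.testing.assert_array_equal(g, np.zeros((6, 6)))

    def test_matches_numerical_gradient(self, rng):
        img = rng.random((16, 16))
        g = tv_gradient(img, 1e-8)
        num = numerical_gradient(lambda m: tv_norm(m, 1e-8), img, eps=1e-6)
        np.testing.assert_allclose(g, num, rtol=1e-4, atol=1e-4)

    def test_gradient_sums_to_zero(self, rng):
        g = tv_gradient(rng.random((12, 12)), XI)
        assert abs(g.sum()) < 1e-10

    def test_requires_positive_xi(self, rng):
        with pytest.raises(ValueError):
            tv_gradient(rng.random((4, 4)), 0.0)


@pytest.fixture
def cs_instance(rng):
    grid = ImageGrid(rng.random((16, 16)))
    geom = ProjectionGeometry.uniform(10, 16)
    A = build_system_matrix(grid, geom)
    y = forward_project(A, grid)
    return grid, A, y


class TestCost:
    def test_reduces_to_least_squares(self, cs_instance, rng):
        grid, A, y = cs_instance
        mu = rng.random((16, 16))
        cfg = CsConfig(lambda1=0.0, lambda2=0.0)
        r = A.dot(mu.ravel()) - y.ravel()
        assert cost(mu, A, y, cfg) == pytest.approx(r @ r, rel=1e-12)

    def test_zero_image_zero_data(self):
        side = 8
        geom = ProjectionGeometry.uniform(4, side)
        A = build_system_matrix(ImageGrid(np.zeros((side, side))), geom)
        y = forward_project(A, ImageGrid(np.zeros((side, side))))
        cfg = CsConfig(lambda1=0.002, lambda2=0.003, wavelet_levels=2)
        P = side * side
        Q = 8 * 8  # padded coefficient count
        expected = (0.002 * P + 0.003 * Q) * np.sqrt(XI)
        assert cost(np.zeros((side, side)), A, y, cfg) == pytest.approx(expected, rel=1e-9)

    def test_matches_term_by_term_oracle(self, cs_instance, rng):
        grid, A, y = cs_instance
        mu = rng.random((16, 16))
        cfg = CsConfig(lambda1=1e-3, lambda2=2e-3, wavelet_family="haar", wavelet_levels=2)
        w = WaveletOperator(16, "haar", 2)
        r = A.toarray() @ mu.ravel() - y.ravel()
        expected = (
            1e-3 * tv_norm(mu, XI)
            + 2e-3 * np.sum(np.sqrt(w.forward(mu) ** 2 + XI))
            + r @ r
        )
        assert cost(mu, A, y, cfg) == pytest.approx(expected, rel=1e-10)


class TestCostGradient:
    def test_zero_when_consistent_and_unregularized(self, cs_instance):
        grid, A, y = cs_instance
        cfg = CsConfig(lambda1=0.0, lambda2=0.0)
        g = cost_gradient(grid.values, A, y, cfg)
        np.testing.assert_allclose(g, 0.0, atol=1e-9)

    def test_data_term_matches_dense_formula(self, cs_instance, rng):
        grid, A, y = cs_instance
        mu = rng.random((16, 16))
        cfg = CsConfig(lambda1=0.0, lambda2=0.0)
        dense = A.toarray()
        expected = 2 * dense.T @ (dense @ mu.ravel() - y.ravel())
        np.testing.assert_allclose(
            cost_gradient(mu, A, y, cfg).ravel(), expected, rtol=1e-10
        )

    @pytest.mark.parametrize("lambda1", [0.0, 1e-3])
    @pytest.mark.parametrize("lambda2", [0.0, 1e-3])
    def test_matches_numerical_gradient(self, cs_instance, rng, lambda1, lambda2):
        grid, A, y = cs_instance
        mu = rng.random((16, 16))
        cfg = CsConfig(lambda1=lambda1, lambda2=lambda2, wavelet_levels=2)
        g = cost_gradient(mu, A, y, cfg)
        num = numerical_gradient(lambda m: cost(m, A, y, cfg), mu, eps=1e-6)
        scale = np.abs(num).max()
        np.testing.assert_allclose(g, num, atol=1e-4 * scale)


class TestNlcg:
    def test_converges_to_least_squares_solution(self, rng):
        # Direct-solve oracle on a small consistent system.
        grid = ImageGrid(rng.random((8, 8)))
        geom = ProjectionGeometry.uniform(8, 8)
        A = build_system_matrix(grid, geom)
        y = forward_project(A, grid)
        cfg = CsConfig(lambda1=0.0, lambda2=0.0, max_iterations=200, trial_step="quadratic")
        res = nlcg_reconstruct(A, y, cfg)
        rel = np.linalg.norm(A.dot(res.image.values.ravel()) - y.ravel()) / np.linalg.norm(
            y.ravel()
        )
        assert rel < 1e-6

    def test_stationary_start_returns_initial_point(self, cs_instance):
        grid, A, y = cs_instance
        cfg = CsConfig(lambda1=0.0, lambda2=0.0, initial=grid.values)
        res = nlcg_reconstruct(A, y, cfg)
        assert res.iterations_run == 0
        assert res.converged
        np.testing.assert_array_equal(res.image.values, grid.values)

    def test_cost_trace_nonincreasing(self, cs_instance):
        grid, A, y = cs_instance
        cfg = CsConfig(lambda1=1e-3, lambda2=1e-3, max_iterations=60, wavelet_levels=2)
        res = nlcg_reconstruct(A, y, cfg)
        assert np.all(np.diff(res.cost_trace) <= 0.0)

    def test_tv_only_independent_of_wavelet_config(self, cs_instance):
        grid, A, y = cs_instance
        a = nlcg_reconstruct(
            A, y, CsConfig(lambda1=1e-3, lambda2=0.0, max_iterations=30, wavelet_family="haar")
        ).image.values
        b = nlcg_reconstruct(
            A,
            y,
            CsConfig(
                lambda1=1e-3, lambda2=0.0, max_iterations=30, wavelet_family="db4",
                wavelet_levels=2,
            ),
        ).image.values
        np.testing.assert_array_equal(a, b)

    def test_smoothing_perturbation_bound(self, cs_instance, rng):
        grid, A, y = cs_instance
        mu = rng.random((16, 16))
        l1, l2 = 1e-3, 1e-3
        c_big = cost(mu, A, y, CsConfig(lambda1=l1, lambda2=l2, xi=1e-15, wavelet_levels=2))
        c_small = cost(mu, A, y, CsConfig(lambda1=l1, lambda2=l2, xi=1e-20, wavelet_levels=2))
        P, Q = 256, 256
        assert abs(c_big - c_small) <= (l1 * P + l2 * Q) * np.sqrt(1e-15)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CsConfig(xi=0.0)
        with pytest.raises(ValueError):
            CsConfig(lambda1=-1.0)
        with pytest.raises(ValueError):
            CsConfig(trial_step="exact")


class TestParamSearch:
    def test_single_candidate_returned(self, cs_instance):
        grid, A, y = cs_instance
        cfg = CsConfig(max_iterations=5)
        best, surface = param_search(A, y, grid.values, [0.123], cfg)
        assert best == 0.123
        assert set(surface) == {0.123}

    def test_matches_exhaustive_oracle(self, cs_instance):
        grid, A, y = cs_instance
        lams = [1e-4, 1e-3, 1e-2, 1e-1, 1.0]
        cfg = CsConfig(max_iterations=10)
        best, surface = param_search(A, y, grid.values, lams, cfg)
        # Exhaustive re-evaluation with the same protocol.
        errs = {}
        for lam in lams:
            res = nlcg_reconstruct(
                A, y, CsConfig(lambda1=lam, lambda2=0.0, max_iterations=10)
            )
            errs[lam] = rrmse(res.image.values, grid.values)
        assert best == min(errs, key=errs.get)
        for lam in lams:
            assert surface[lam] == pytest.approx(errs[lam], rel=1e-12)

    def test_empty_grid_rejected(self, cs_instance):
        grid, A, y = cs_instance
        with pytest.raises(ValueError):
            param_search(A, y, grid.values, [])

    def test_alternating_search_converges_on_grid(self, cs_instance):
        grid, A, y = cs_instance
        cfg = CsConfig(max_iterations=5, wavelet_levels=2)
        l1, l2, surface = alternating_param_search(
            A, y, grid.values, [1e-3, 1e-2], [1e-3, 1e-2], cfg, lambda2_init=1e-3
        )
        assert l1 in (1e-3, 1e-2) and l2 in (1e-3, 1e-2)
        # The returned pair is no worse than any evaluated alternative.
        assert surface[(l1, l2)] == pytest.approx(min(surface.values()), rel=1e-12)
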