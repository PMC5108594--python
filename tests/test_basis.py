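"""Bases: orthonormality, interpolation exactness, planar reproduction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from divs.basis import (
    history_basis,
    pyramid_basis_2d,
    raw_temporal_functions,
    temporal_basis,
    tent_basis,
)


class TestTemporalBasis:
    @pytest.mark.parametrize("n_funcs", [1, 5, 12, 20])
    def test_gram_matrix_is_identity(self, n_funcs):
        tb = temporal_basis(n_funcs, 200.0, 1.0)
        gram = tb.matrix.T @ tb.matrix
        assert np.abs(gram - np.eye(n_funcs)).max() < 1e-8

    def test_raw_functions_vanish_at_endpoints(self):
        t_max, dt = 200.0, 1.0
        raw = raw_temporal_functions(8, t_max, dt)
        assert np.allclose(raw[0], 0.0)
        # evaluate directly at t = t_max (not a sample of the half-open grid)
        x = 2.0 - 1.0  # 2 t/tF - (t/tF)^2 at t = tF
        assert np.allclose(np.sin(np.pi * np.arange(1, 9) * x), 0.0, atol=1e-12)

    def test_span_unchanged_by_orthonormalization(self):
        raw = raw_temporal_functions(10, 200.0, 1.0)
        tb = temporal_basis(10, 200.0, 1.0)
        stacked = np.concatenate([raw, tb.matrix], axis=1)
        assert np.linalg.matrix_rank(stacked, tol=1e-8) == 10

    def test_project_expand_roundtrip(self):
        tb = temporal_basis(12, 200.0, 1.0)
        coeffs = np.sin(np.arange(12.0))
        assert np.allclose(tb.project(tb.expand(coeffs)), coeffs)

    @pytest.mark.parametrize("bad", [dict(n_funcs=0), dict(t_max=-5.0), dict(dt=0.0)])
    def test_invalid_arguments_raise(self, bad):
        kwargs = dict(n_funcs=5, t_max=200.0, dt=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            temporal_basis(**kwargs)


class TestTentBasis:
    def test_indicator_at_knots(self):
        tb = tent_basis(np.array([-2.0, -0.5, 0.0, 1.0, 3.0]))
        D = tb.design(tb.knots)
        assert np.allclose(D, np.eye(5))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(min_value=-5.0, max_value=5.0))
    def test_partition_of_unity_even_outside_range(self, x):
        tb = tent_basis(np.linspace(-2.0, 2.0, 9))
        assert np.isclose(tb.design(np.array([x])).sum(), 1.0)

    def test_linear_function_reproduced_exactly(self):
        rng = np.random.default_rng(0)
        knots = np.linspace(-3.0, 3.0, 13)
        tb = tent_basis(knots)
        weights = 2.0 * knots + 1.0
        x = rng.uniform(-3.0, 3.0, 100)
        expected = np.interp(x, knots, weights)  # independent interpolation oracle
        assert np.allclose(tb.interp(x, weights), expected)
        assert np.allclose(tb.design(x) @ weights, expected)

    def test_clamped_extrapolation(self):
        knots = np.linspace(0.0, 1.0, 5)
        tb = tent_basis(knots)
        w = knots**2
        assert tb.interp(np.array([-10.0]), w)[0] == w[0]
        assert tb.interp(np.array([10.0]), w)[0] == w[-1]

    def test_derivative_is_piecewise_slope(self):
        knots = np.linspace(-1.0, 1.0, 5)
        tb = tent_basis(knots)
        w = np.array([0.0, 1.0, 1.0, 0.5, 2.0])
        x = np.array([-0.9, -0.2, 0.2, 0.8, -5.0, 5.0])
        expected = np.array([2.0, 0.0, -1.0, 3.0, 0.0, 0.0])
        assert np.allclose(tb.deriv(x, w), expected)

    def test_unsorted_knots_raise(self):
        with pytest.raises(ValueError):
            tent_basis(np.array([0.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            tent_basis(np.array([0.0, 1.0]))


class TestPyramidBasis2D:
    def setup_method(self):
        self.pyr = pyramid_basis_2d(np.linspace(-1, 1, 5), np.linspace(-2, 2, 7))

    def test_indicator_at_vertices(self):
        gx, gy = np.meshgrid(self.pyr.grid_x, self.pyr.grid_y, indexing="ij")
        D = self.pyr.design(gx.ravel(), gy.ravel()).toarray()
        assert np.allclose(D, np.eye(self.pyr.n_funcs))

    def test_partition_of_unity_and_sparsity(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, 200)
        y = rng.uniform(-2, 2, 200)
        D = self.pyr.design(x, y)
        assert np.allclose(np.asarray(D.sum(axis=1)).ravel(), 1.0)
        assert (D.toarray() != 0).sum(axis=1).max() <= 3

    def test_planar_function_reproduced_exactly(self):
        rng = np.random.default_rng(2)
        gx, gy = np.meshgrid(self.pyr.grid_x, self.pyr.grid_y, indexing="ij")
        weights = 3.0 * gx - 2.0 * gy
        x = rng.uniform(-1, 1, 100)
        y = rng.uniform(-2, 2, 100)
        assert np.allclose(self.pyr.interp(x, y, weights), 3.0 * x - 2.0 * y)

    def test_second_differences_vanish_between_knots(self):
        # piecewise-planar: along a line inside one triangle, curvature is 0
        rng = np.random.default_rng(3)
        w = rng.standard_normal(self.pyr.shape)
        x = np.linspace(-0.99, -0.80, 9)  # stays in the lower triangle of the cell
        vals = self.pyr.interp(x, np.full_like(x, -1.7), w)
        assert np.abs(np.diff(vals, 2)).max() < 1e-10

    def test_outside_points_clamped_and_flagged(self):
        inside = self.pyr.contains(np.array([0.0, 5.0]), np.array([0.0, 0.0]))
        assert inside.tolist() == [True, False]
        v_out = self.pyr.interp(np.array([5.0]), np.array([0.0]),
                                np.ones(self.pyr.n_funcs))
        assert np.isclose(v_out[0], 1.0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        w = rng.standard_normal(self.pyr.shape)
        x = np.array([-0.7, 0.13, 0.61])
        y = np.array([-1.1, 0.4, 1.9])
        fx, fy = self.pyr.gradient(x, y, w)
        eps = 1e-7
        fx_num = (self.pyr.interp(x + eps, y, w) - self.pyr.interp(x - eps, y, w)) / (2 * eps)
        fy_num = (self.pyr.interp(x, y + eps, w) - self.pyr.interp(x, y - eps, w)) / (2 * eps)
        assert np.allclose(fx, fx_num, atol=1e-5)
        assert np.allclose(fy, fy_num, atol=1e-5)

    def test_invalid_grids_raise(self):
        with pytest.raises(ValueError):
            pyramid_basis_2d(np.array([0.0, 1.0]), np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            pyramid_basis_2d(np.array([0.0, 1.0, 0.5]), np.linspace(0, 1, 5))


class TestHistoryBasis:
    def test_shape_and_coverage(self):
        hb = history_basis(8, 100.0, 1.0)
        assert hb.shape == (100, 8)
        assert np.all(hb >= 0)
        # every lag in 1..100 ms is covered by at least one bump
        assert hb.max(axis=1).min() > 0.05
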