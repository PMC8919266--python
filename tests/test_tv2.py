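import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

import cstomo as ct
from cstomo.tv2 import (
    GradientOperator,
    HessianOperator,
    hessian_adjoint,
    hessian_apply,
    prox_data_dual,
    prox_l1_dual,
)
from cstomo.projector import operator_norm

from oracles import materialize


def affine_2d(shape, a=2.0, b=-3.0, c=1.0):
    z, x = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    return a * z + b * x + c


class TestHessian:
    def test_affine_annihilated_everywhere_1d_like(self):
        ramp = (3.0 * np.arange(9) + 1.0).reshape(9, 1).repeat(5, axis=1)
        assert np.all(hessian_apply(ramp).components == 0.0)

    @pytest.mark.parametrize("shape", [(8, 8), (5, 9), (4, 5, 6)])
    def test_affine_annihilated_any_shape(self, shape):
        grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
        # dyadic coefficients keep every finite difference exact in float
        f = sum((i + 1.5) * g for i, g in enumerate(grids)) + 0.75
        assert np.all(hessian_apply(f).components == 0.0)

    def test_central_impulse_stencil(self):
        imp = np.zeros((9, 3))
        imp[4, 1] = 1.0
        comp = hessian_apply(imp).components
        xx = comp[0][:, 1]
        assert np.allclose(xx[3:6], [1.0, -2.0, 1.0])
        assert np.abs(xx).sum() == pytest.approx(4.0)

    def test_quadratic_interior_second_difference(self):
        f = (np.arange(9, dtype=float) ** 2).reshape(9, 1).repeat(3, axis=1)
        comp = hessian_apply(f).components
        assert np.allclose(comp[0][1:-1, :], 2.0)

    @pytest.mark.parametrize("shape", [(8, 8), (5, 6, 7)])
    def test_adjoint_is_exact_transpose(self, shape, rng):
        op = HessianOperator(shape, weighted=True)
        for _ in range(20):
            f = rng.standard_normal(shape)
            q = rng.standard_normal((op.n_components,) + shape)
            lhs = np.vdot(op.apply(f), q)
            rhs = np.vdot(f, op.adjoint(q))
            assert abs(lhs - rhs) < 1e-12 * max(abs(lhs), 1.0)

    def test_biharmonic_response_matches_dense(self, rng):
        op = HessianOperator((8, 8), weighted=False)
        dense = materialize(op.apply, (8, 8), op.n_components * 64)
        imp = np.zeros((8, 8))
        imp[4, 4] = 1.0
        direct = op.adjoint(op.apply(imp))
        via_dense = (dense.T @ (dense @ imp.ravel())).reshape(8, 8)
        assert np.allclose(direct, via_dense, atol=1e-12)

    def test_norm_bound_and_dense_svd(self):
        # small grid: power iteration within 1% of dense SVD
        op = HessianOperator((8, 8))
        dense = materialize(op.apply, (8, 8), op.n_components * 64)
        top = np.linalg.svd(dense, compute_uv=False)[0]
        est = operator_norm(
            op.apply, op.adjoint, (8, 8), iterations=200, seed=1
        )
        assert est == pytest.approx(top, rel=0.01)
        # large grid: analytic bound 4*d for the weighted operator
        big = HessianOperator((64, 64))
        est_big = operator_norm(big.apply, big.adjoint, (64, 64), seed=1)
        assert est_big <= 4.0 * 2 + 1e-6


class TestTv2Norm:
    def test_affine_plane_is_zero(self):
        assert ct.tv2_norm(affine_2d((12, 10))) == 0.0

    def test_quadratic_forced_value(self):
        # f(i) = i^2 along one axis of a 9 x 3 grid: each interior xx term
        # is exactly 2; the anisotropic sum counts 7 interior points per row.
        f = (np.arange(9, dtype=float) ** 2).reshape(9, 1).repeat(3, axis=1)
        assert ct.tv2_norm(f, "aniso") == pytest.approx(2.0 * 7 * 3)

    def test_iso_leq_aniso(self, rng):
        f = rng.standard_normal((6, 6))
        assert ct.tv2_norm(f, "iso") <= ct.tv2_norm(f, "aniso") + 1e-12

    def test_nonnegative_and_zero_only_for_affine(self, rng):
        f = rng.standard_normal((8, 8))
        assert ct.tv2_norm(f) > 0.0


class TestFirstOrderTv:
    def test_gradient_adjoint_is_exact_transpose(self, rng):
        op = GradientOperator((7, 9))
        for _ in range(10):
            f = rng.standard_normal((7, 9))
            q = rng.standard_normal((2, 7, 9))
            assert abs(np.vdot(op.apply(f), q) - np.vdot(f, op.adjoint(q))) < 1e-12

    def test_constant_has_zero_tv(self):
        assert ct.tv1_norm(np.full((8, 8), 3.7)) == 0.0


class TestProxOperators:
    def test_l1_dual_interior_unchanged(self):
        q = np.full((1, 4, 4), 0.3)
        assert np.allclose(prox_l1_dual(q, 0.5, "aniso"), 0.3)

    def test_l1_dual_boundary_projection(self):
        lam = 0.7
        q = np.full((1, 4, 4), 2 * lam)
        assert np.allclose(prox_l1_dual(q, lam, "aniso"), lam)
        iso = prox_l1_dual(np.full((3, 4, 4), 2.0), lam, "iso")
        assert np.allclose(np.sqrt((iso**2).sum(axis=0)), lam)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_l1_dual_idempotent(self, seed):
        q = np.random.default_rng(seed).standard_normal((3, 5, 5))
        for grouping in ("iso", "aniso"):
            once = prox_l1_dual(q, 0.8, grouping)
            assert np.allclose(prox_l1_dual(once, 0.8, grouping), once)

    def test_l1_dual_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            prox_l1_dual(np.zeros((1, 4, 4)), -1.0)

    def test_data_dual_closed_forms(self, rng):
        g = rng.standard_normal((3, 8))
        sigma = 0.7
        assert np.allclose(prox_data_dual(sigma * g, g, sigma), 0.0)
        p = rng.standard_normal((3, 8))
        assert np.allclose(prox_data_dual(p, np.zeros_like(p), sigma),
                           p / (1 + sigma))

    def test_data_dual_matches_scalar_optimizer(self, rng):
        """The resolvent minimizes 0.5(y-p)^2 + sigma*(0.5 y^2 + y g)
        elementwise; compare to a numerical scalar optimizer."""
        sigma = 0.7
        for _ in range(10):
            p, g = rng.standard_normal(2)
            got = prox_data_dual(np.array([p]), np.array([g]), sigma)[0]
            ref = minimize_scalar(
                lambda y: 0.5 * (y - p) ** 2 + sigma * (0.5 * y**2 + y * g)
            ).x
            assert got == pytest.approx(ref, abs=1e-6)

    def test_data_dual_sigma_validation(self):
        with pytest.raises(ValueError):
            prox_data_dual(np.zeros(3), np.zeros(3), 0.0)


def test_hessian_field_roundtrip_through_adjoint(rng):
    field = hessian_apply(rng.standard_normal((6, 6)))
    out = hessian_adjoint(field)
    assert out.shape == (6, 6)
    zero = hessian_apply(np.zeros((6, 6)))
    assert np.all(hessian_adjoint(zero) == 0.0)
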