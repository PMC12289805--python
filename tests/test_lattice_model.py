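import numpy as np
import pytest

from pclattice.equilibria import HyperParams, ModelParams, equilibrium_branches
from pclattice.lattice_model import (
    AdaptationParams,
    DiagonalWeights,
    VectorModelParams,
    adaptation_rhs,
    bi_infinite_rhs,
    diagonal_rhs,
    local_map,
    scalar_rhs,
    vector_rhs,
)
from pclattice.nonlinearity import SigmoidParams, sigmoid, sigmoid_deriv
from pclattice.simulate import InputProtocol


def F_p(v, params):
    """Reaction term, coded independently from the printed closed form."""
    sg = params.sigmoid
    return (-v + sigmoid(v, sg)) * (1 - params.p - params.p * sigmoid_deriv(v, sg))


class TestLocalMap:
    def test_equilibrium_zero(self, params_center, branches_center):
        for x in (branches_center.x_d, branches_center.x_m, branches_center.x_u):
            assert local_map(x, x, x, params_center) == pytest.approx(0.0, abs=1e-10)

    def test_diagonal_equals_reaction_term(self, params_center):
        for v0 in (0.1, 0.37, 0.5, 0.82):
            assert local_map(v0, v0, v0, params_center) == pytest.approx(
                F_p(v0, params_center), rel=1e-12
            )

    def test_cooperative_in_neighbors(self, params_center):
        # central differences at 10 random admissible points, fixed seed
        rng = np.random.default_rng(1234)
        h = 1e-6
        for _ in range(10):
            u, v, w = rng.uniform(0.05, 0.95, size=3)
            du = (
                local_map(u + h, v, w, params_center)
                - local_map(u - h, v, w, params_center)
            ) / (2 * h)
            dw = (
                local_map(u, v, w + h, params_center)
                - local_map(u, v, w - h, params_center)
            ) / (2 * h)
            assert du > 0
            assert dw > 0
            assert dw == pytest.approx(
                params_center.q * sigmoid_deriv(w, params_center.sigmoid), rel=1e-4
            )


class TestScalarRhs:
    def test_homogeneous_equilibrium(self, params_center, branches_center):
        x_d = branches_center.x_d
        v = np.full(10, x_d)
        dv = scalar_rhs(v, 0.0, InputProtocol.constant(x_d), params_center)
        assert np.max(np.abs(dv)) < 1e-12

    def test_top_layer_equation(self, params_center):
        # layer J follows the no-feedback equation, coded independently
        rng = np.random.default_rng(7)
        v = rng.uniform(0.1, 0.9, size=6)
        dv = scalar_rhs(v, 0.0, InputProtocol.constant(0.3), params_center)
        sg = params_center.sigmoid
        p, q = params_center.p, params_center.q
        expected = (1 - p - q) * (sigmoid(v[-2], sg) - v[-1]) + p * sigmoid_deriv(
            v[-1], sg
        ) * (v[-2] - sigmoid(v[-1], sg))
        assert dv[-1] == pytest.approx(expected, rel=1e-14)

    def test_interior_delegates_to_local_map(self, params_center):
        v = np.array([0.2, 0.6, 0.8])
        dv = scalar_rhs(v, 0.0, InputProtocol.constant(0.4), params_center)
        assert dv[1] == pytest.approx(
            local_map(v[0], v[1], v[2], params_center), rel=1e-14
        )

    def test_input_layer_uses_protocol(self, params_center):
        v = np.array([0.2, 0.6, 0.8])
        dv = scalar_rhs(v, 0.0, InputProtocol.constant(0.9), params_center)
        assert dv[0] == pytest.approx(
            local_map(0.9, v[0], v[1], params_center), rel=1e-14
        )

    def test_too_few_layers(self, params_center):
        with pytest.raises(ValueError):
            scalar_rhs(np.array([0.5]), 0.0, InputProtocol.constant(0.5), params_center)


class TestBiInfiniteRhs:
    def test_translation_equivariance(self, params_center):
        rng = np.random.default_rng(11)
        v = rng.uniform(0.1, 0.9, size=30)
        dv = bi_infinite_rhs(v, 0.0, params_center, left=v[0], right=v[-1])
        shifted = np.roll(v, 3)
        dvs = bi_infinite_rhs(shifted, 0.0, params_center, left=shifted[0],
                              right=shifted[-1])
        # interior entries away from both boundaries shift identically
        assert np.allclose(dvs[4:-4], np.roll(dv, 3)[4:-4], atol=1e-14)

    def test_clamped_equilibrium(self, params_center, branches_center):
        v = np.full(20, branches_center.x_u)
        dv = bi_infinite_rhs(v, 0.0, params_center, branches_center.x_u,
                             branches_center.x_u)
        assert np.max(np.abs(dv)) < 1e-12


class TestVectorModel:
    def test_reduction_to_scalar(self, branches_center):
        p_tilde, q_tilde = 0.1, 0.5
        hyper = HyperParams(alpha=p_tilde, beta=1 - p_tilde - q_tilde, lambda_=q_tilde)
        sg = SigmoidParams(mu=16.0, theta=0.5)
        vp = VectorModelParams(d=1, W_f=np.eye(1), W_b=np.eye(1), hyper=hyper,
                               sigmoid=sg)
        scalar_params = ModelParams(theta=0.5, mu=16.0, p=p_tilde, q=q_tilde)
        rng = np.random.default_rng(3)
        v = rng.uniform(0.1, 0.9, size=8)
        protocol = InputProtocol.constant(0.4)
        dvec = vector_rhs(v[None, :], 0.0, protocol, vp)
        dsca = scalar_rhs(v, 0.0, protocol, scalar_params)
        assert np.allclose(dvec[0], dsca, atol=1e-14)

    def test_time_scale_factor(self):
        # scaling all gains by a constant scales the RHS by the same constant
        sg = SigmoidParams(mu=16.0, theta=0.5)
        rng = np.random.default_rng(4)
        v = rng.uniform(0.1, 0.9, size=(1, 6))
        protocol = InputProtocol.constant(0.4)
        h1 = HyperParams(alpha=0.1, beta=0.4, lambda_=0.5)
        h3 = HyperParams(alpha=0.3, beta=1.2, lambda_=1.5)
        d1 = vector_rhs(v, 0.0, protocol,
                        VectorModelParams(1, np.eye(1), np.eye(1), h1, sg))
        d3 = vector_rhs(v, 0.0, protocol,
                        VectorModelParams(1, np.eye(1), np.eye(1), h3, sg))
        assert np.allclose(d3, 3 * d1, atol=1e-13)

    def test_diagonal_weights_reduce_termwise(self):
        sg = SigmoidParams(mu=16.0, theta=0.5)
        hyper = HyperParams(alpha=0.2, beta=0.5, lambda_=0.3)
        weights = DiagonalWeights(omega_f=1.3, omega_b=0.7)
        rng = np.random.default_rng(5)
        v = rng.uniform(0.1, 0.9, size=7)
        protocol = InputProtocol.constant(0.4)
        dd = diagonal_rhs(v, 0.0, protocol, hyper, sg, weights)
        vp = VectorModelParams(1, 1.3 * np.eye(1), 0.7 * np.eye(1), hyper, sg)
        dv = vector_rhs(v[None, :], 0.0, protocol, vp)
        assert np.allclose(dv[0], dd, atol=1e-14)

    def test_unit_weights_recover_base(self):
        sg = SigmoidParams(mu=16.0, theta=0.5)
        hyper = HyperParams(alpha=0.1, beta=0.4, lambda_=0.5)
        rng = np.random.default_rng(6)
        v = rng.uniform(0.1, 0.9, size=7)
        protocol = InputProtocol.constant(0.4)
        dd = diagonal_rhs(v, 0.0, protocol, hyper, sg, DiagonalWeights(1.0, 1.0))
        ds = scalar_rhs(v, 0.0, protocol, ModelParams(theta=0.5, mu=16, p=0.1, q=0.5))
        assert np.allclose(dd, ds, atol=1e-14)

    def test_two_population_fixed_point(self):
        sg = SigmoidParams(mu=16.0, theta=0.5)
        hyper = HyperParams(alpha=0.1, beta=0.4, lambda_=0.5)
        vp = VectorModelParams(2, np.eye(2), np.eye(2), hyper, sg)
        bs = equilibrium_branches(0.5, 16.0)
        V = np.full((2, 6), bs.x_u)
        dV = vector_rhs(V, 0.0, InputProtocol.constant(bs.x_u), vp)
        assert np.max(np.abs(dV)) < 1e-12

    def test_shape_mismatch(self):
        sg = SigmoidParams(mu=16.0, theta=0.5)
        hyper = HyperParams(alpha=0.1, beta=0.4, lambda_=0.5)
        vp = VectorModelParams(2, np.eye(2), np.eye(2), hyper, sg)
        with pytest.raises(ValueError):
            vector_rhs(np.zeros((3, 5)), 0.0, InputProtocol.constant(0.4), vp)


class TestAdaptation:
    def test_gamma_zero_reduction(self, params_center):
        rng = np.random.default_rng(8)
        v = rng.uniform(0.1, 0.9, size=9)
        a = rng.uniform(0.1, 0.9, size=9)
        protocol = InputProtocol.constant(0.4)
        dv, da = adaptation_rhs((v, a), 0.0, protocol, params_center,
                                AdaptationParams(gamma=0.0, tau_a=10.0))
        assert np.allclose(dv, scalar_rhs(v, 0.0, protocol, params_center), atol=1e-14)
        assert np.allclose(da, (v - a) / 10.0, atol=1e-14)

    def test_stationary_states_solve_modified_reaction(self, params_center):
        # roots of F_p(v) - gamma v found independently, then checked as
        # stationary points of the full adaptation dynamics
        from scipy.optimize import brentq

        gamma = 0.02
        g = lambda v: F_p(v, params_center) - gamma * v
        grid = np.linspace(1e-6, 0.999, 2001)
        vals = g(grid)
        roots = [
            brentq(g, grid[i], grid[i + 1])
            for i in np.nonzero(vals[:-1] * vals[1:] < 0)[0]
        ]
        assert len(roots) == 3
        for r in roots:
            v = np.full(6, r)
            dv, da = adaptation_rhs((v, v.copy()), 0.0, InputProtocol.constant(r),
                                    params_center,
                                    AdaptationParams(gamma=gamma, tau_a=10.0))
            # layer J follows the no-feedback closure, so only the layers
            # carrying the full coupling map are homogeneous-stationary
            assert np.max(np.abs(dv[:-1])) < 1e-10
            assert np.max(np.abs(da)) < 1e-14

    def test_large_gamma_single_root(self, params_center):
        grid = np.linspace(1e-6, 0.999, 4001)
        for gamma, expected in ((0.02, 3), (1.0, 1)):
            vals = F_p(grid, params_center) - gamma * grid
            n_roots = int(np.sum(vals[:-1] * vals[1:] < 0))
            assert n_roots == expected

    def test_invalid_timescale(self):
        with pytest.raises(ValueError):
            AdaptationParams(gamma=0.5, tau_a=0.0)
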