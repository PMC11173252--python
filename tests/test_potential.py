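"""EPR / HJB / enhanced / weighted-norm losses and the potential network."""

import numpy as np
import pytest

from nessland.potential import (AnalyticModel, MLPPotential, TrainingConfig,
                                enhanced_loss, epr_loss, hjb_loss,
                                hjb_residual, vepr_loss)
from nessland.simulate import SampleSet
from nessland.systems import DynamicalSystem, lorenz_system, make_rotational_toy


def quadratic_model():
    return AnalyticModel(2, lambda x: 0.5 * np.sum(x ** 2, axis=1),
                         gradient=lambda x: np.atleast_2d(x).astype(float),
                         laplacian=lambda x: np.full(len(x), 2.0))


class TestMLPDerivatives:
    @pytest.mark.parametrize("dim", [1, 3, 12])
    def test_gradient_matches_finite_differences(self, dim, rng):
        m = MLPPotential(dim, seed=2)
        x = rng.standard_normal((10, dim))
        h = 1e-5
        g_fd = np.zeros((10, dim))
        for k in range(dim):
            e = np.zeros(dim)
            e[k] = h
            g_fd[:, k] = (m.value(x + e) - m.value(x - e)) / (2 * h)
        denom = np.maximum(np.abs(g_fd), 1e-3)
        assert np.max(np.abs(m.gradient(x) - g_fd) / denom) < 1e-4

    def test_laplacian_matches_hessian_trace(self, rng):
        m = MLPPotential(3, seed=4)
        x = rng.standard_normal((6, 3))
        h = 1e-4
        lap_fd = np.zeros(6)
        v0 = m.value(x)
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            lap_fd += (m.value(x + e) - 2 * v0 + m.value(x - e)) / h ** 2
        denom = np.maximum(np.abs(lap_fd), 1e-3)
        assert np.max(np.abs(m.laplacian(x) - lap_fd) / denom) < 1e-3

    def test_save_load_roundtrip(self, tmp_path, rng):
        m = MLPPotential(4, seed=9)
        m.save(tmp_path / "m.json")
        back = MLPPotential.load(tmp_path / "m.json")
        x = rng.standard_normal((5, 4))
        assert np.array_equal(m.value(x), back.value(x))


class TestEprLoss:
    def test_hand_computed_value(self):
        # V = 0, drift -x, samples {(1,0), (0,2)}: loss = (1 + 4)/2
        sys_ = DynamicalSystem(dim=2, drift=lambda x: -np.atleast_2d(x),
                               drift_divergence=lambda x: -2 * np.ones(len(np.atleast_2d(x))))
        zero = AnalyticModel(2, lambda x: np.zeros(len(x)),
                             gradient=lambda x: np.zeros_like(x))
        samples = SampleSet(states=[[1.0, 0.0], [0.0, 2.0]], noise_strength=0.1,
                            provenance="analytic")
        assert epr_loss(zero, samples, sys_) == pytest.approx(2.5)

    def test_vanishes_at_true_potential_of_gradient_system(self, toy_samples_exact):
        toy0 = make_rotational_toy("quadratic", c=0.0)
        assert epr_loss(quadratic_model(), toy_samples_exact, toy0) < 1e-28

    def test_rotational_toy_residual_is_solenoidal_part(self, toy_c1,
                                                        toy_samples_exact):
        # at V = U0 the residual is exactly c J grad U0, so the loss equals
        # c^2 mean |x|^2, with expectation 2 c^2 D over exact steady samples
        c, D = 1.0, 0.1
        loss = epr_loss(quadratic_model(), toy_samples_exact, toy_c1)
        r2 = np.sum(toy_samples_exact.states ** 2, axis=1)
        assert loss == pytest.approx(c ** 2 * r2.mean(), rel=1e-12)
        se = c ** 2 * r2.std() / np.sqrt(len(r2))
        assert abs(loss - 2 * c ** 2 * D) < 3 * se

    def test_dimension_mismatch_rejected(self, toy_c1, toy_samples_exact):
        with pytest.raises(ValueError, match="dimension"):
            epr_loss(MLPPotential(3), toy_samples_exact, toy_c1)


class TestHjbResidual:
    def test_zero_at_true_potential_for_any_rotation(self, rng):
        for c in (0.0, 1.0, 3.0):
            toy = make_rotational_toy("quadratic", c=c)
            pts = rng.uniform(-2, 2, (100, 2))
            res = hjb_residual(quadratic_model(), pts, toy, D=0.7)
            assert np.max(np.abs(res)) < 1e-12

    def test_zero_model_gives_d_times_divergence(self, rng):
        lo = lorenz_system()
        zero = AnalyticModel(3, lambda x: np.zeros(len(x)),
                             gradient=lambda x: np.zeros_like(x),
                             laplacian=lambda x: np.zeros(len(x)))
        res = hjb_residual(zero, rng.standard_normal((5, 3)), lo, D=1.0)
        assert np.allclose(res, -41.0 / 3.0)

    def test_quadratic_perturbation_scaling(self, toy_c1, rng):
        # V = U0 + eps|x|^2: leading-order residual is linear in eps, so the
        # squared loss scales as eps^2 -> ratio 4 when eps doubles
        D = 0.1
        pts = rng.uniform(-1, 1, (2000, 2))
        samples = SampleSet(states=pts, noise_strength=D, provenance="analytic")

        def perturbed(eps):
            return AnalyticModel(
                2, lambda x: (0.5 + eps) * np.sum(x ** 2, axis=1),
                gradient=lambda x: (1 + 2 * eps) * x,
                laplacian=lambda x: np.full(len(x), 2 * (1 + 2 * eps)))

        l1 = hjb_loss(perturbed(1e-4), samples, toy_c1, D)
        l2 = hjb_loss(perturbed(2e-4), samples, toy_c1, D)
        assert l1 > 0
        assert l2 / l1 == pytest.approx(4.0, rel=0.01)


class TestEnhancedLoss:
    def test_lambda2_zero_reduces_to_weighted_epr(self, toy_c1, toy_samples_exact):
        cfg = TrainingConfig(D=0.1, lambda1=3.0, lambda2=0.0)
        le = enhanced_loss(quadratic_model(), toy_samples_exact, None, toy_c1, cfg)
        assert le == pytest.approx(
            3.0 * epr_loss(quadratic_model(), toy_samples_exact, toy_c1))

    def test_missing_enhanced_set_rejected(self, toy_c1, toy_samples_exact):
        cfg = TrainingConfig(D=0.1, lambda1=1.0, lambda2=1.0)
        with pytest.raises(ValueError, match="enhanced"):
            enhanced_loss(quadratic_model(), toy_samples_exact, None, toy_c1, cfg)

    def test_zero_at_true_potential_of_gradient_system(self, toy_samples_exact):
        toy0 = make_rotational_toy("quadratic", c=0.0)
        cfg = TrainingConfig(D=0.1, lambda1=10.0, lambda2=1.0)
        val = enhanced_loss(quadratic_model(), toy_samples_exact,
                            toy_samples_exact, toy0, cfg)
        assert val < 1e-24

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(lambda1=0.0, lambda2=0.0)


class TestVeprLoss:
    def test_identity_diffusion_is_bitwise_epr(self, toy_c1, toy_samples_exact):
        m = MLPPotential(2, seed=0)
        assert vepr_loss(m, toy_samples_exact, toy_c1, D=0.1) == \
            epr_loss(m, toy_samples_exact, toy_c1)

    def test_explicit_identity_matches_epr(self, toy_samples_exact):
        toy = make_rotational_toy("quadratic", c=1.0)
        toy.diffusion_matrix = lambda x: np.broadcast_to(
            np.eye(2), (len(np.atleast_2d(x)), 2, 2)).copy()
        m = MLPPotential(2, seed=0)
        ref = epr_loss(m, toy_samples_exact, toy)
        assert vepr_loss(m, toy_samples_exact, toy, D=0.1) == \
            pytest.approx(ref, rel=1e-12)

    def test_hand_computed_1d_case(self):
        # a = 2, F = -2x, D arbitrary (a constant so div a = 0), V = x^2/2:
        # residual F^v + a V' = -2x + 2x = 0 at every sample
        sys_ = DynamicalSystem(
            dim=1, drift=lambda x: -2.0 * np.atleast_2d(x),
            drift_divergence=lambda x: -2.0 * np.ones(len(np.atleast_2d(x))),
            diffusion_matrix=lambda x: np.full((len(np.atleast_2d(x)), 1, 1),
                                               np.sqrt(2.0)),
            diffusion_divergence=lambda x: np.zeros((len(np.atleast_2d(x)), 1)))
        v = AnalyticModel(1, lambda x: 0.5 * x[:, 0] ** 2,
                          gradient=lambda x: np.atleast_2d(x).astype(float))
        samples = SampleSet(states=[[1.0]], noise_strength=1.0,
                            provenance="analytic")
        assert vepr_loss(v, samples, sys_, D=1.0) == pytest.approx(0.0, abs=1e-24)

    def test_generalized_detailed_balance_zero_loss(self, rng):
        # 1D state-dependent diffusion a(x) = 1 + x^2, F = -a U0' + D a':
        # the Ito steady flux vanishes at V = U0, so the loss is zero
        D = 0.7

        def a(x):
            return 1.0 + np.atleast_2d(x)[:, 0] ** 2

        sys_ = DynamicalSystem(
            dim=1,
            drift=lambda x: (-(a(x) * np.atleast_2d(x)[:, 0])
                             + D * 2 * np.atleast_2d(x)[:, 0])[:, None],
            drift_divergence=lambda x: (-(1 + 3 * np.atleast_2d(x)[:, 0] ** 2)
                                        + 2 * D),
            diffusion_matrix=lambda x: np.sqrt(a(x))[:, None, None],
            diffusion_divergence=lambda x: (2 * np.atleast_2d(x)[:, 0])[:, None])
        v = AnalyticModel(1, lambda x: 0.5 * x[:, 0] ** 2,
                          gradient=lambda x: np.atleast_2d(x).astype(float))
        samples = SampleSet(states=rng.uniform(-2, 2, (50, 1)),
                            noise_strength=D, provenance="analytic")
        assert vepr_loss(v, samples, sys_, D=D) < 1e-24

    def test_singular_diffusion_reported(self, toy_samples_exact):
        toy = make_rotational_toy("quadratic", c=1.0)
        toy.diffusion_matrix = lambda x: np.zeros((len(np.atleast_2d(x)), 2, 2))
        with pytest.raises(ValueError, match="singular"):
            vepr_loss(MLPPotential(2), toy_samples_exact, toy, D=0.1)


class TestShiftInvariance:
    def test_constant_shift_leaves_losses_unchanged(self, toy_c1,
                                                    toy_samples_exact):
        m = MLPPotential(2, seed=3)
        shifted = MLPPotential(2, seed=3)
        shifted._bs[-1].value = shifted._bs[-1].value + 7.5
        assert epr_loss(m, toy_samples_exact, toy_c1) == \
            epr_loss(shifted, toy_samples_exact, toy_c1)
        assert hjb_loss(m, toy_samples_exact, toy_c1, 0.1) == \
            hjb_loss(shifted, toy_samples_exact, toy_c1, 0.1)


class TestConvexity:
    def test_strict_convexity_on_random_network_pairs(self, toy_c1,
                                                      toy_samples_exact):
        # L_EPR is a positive quadratic in grad V, hence strictly convex
        # along any segment between networks with different gradients
        rng = np.random.default_rng(0)
        sub = SampleSet(states=toy_samples_exact.states[:2000],
                        noise_strength=0.1, provenance="analytic")
        for trial in range(20):
            m0 = MLPPotential(2, seed=2 * trial)
            m1 = MLPPotential(2, seed=2 * trial + 1)
            l0 = epr_loss(m0, sub, toy_c1)
            l1 = epr_loss(m1, sub, toy_c1)
            for w in (0.25, 0.5, 0.75):
                mix = AnalyticModel(
                    2,
                    lambda x, w=w: (1 - w) * m0.value(x) + w * m1.value(x),
                    gradient=lambda x, w=w: ((1 - w) * m0.gradient(x)
                                             + w * m1.gradient(x)))
                lw = epr_loss(mix, sub, toy_c1)
                assert lw < (1 - w) * l0 + w * l1
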