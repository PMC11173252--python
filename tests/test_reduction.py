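"""Projected-force regression, projected losses, and the two reduction routes."""

import numpy as np
import pytest

from nessland.evaluation import rrmse
from nessland.potential import AnalyticModel, MLPPotential, TrainingConfig, hjb_loss
from nessland.reduction import (ExactReducedForce, ReducedSpec,
                                fit_projected_force, marginalize_potential,
                                p_epr_loss, p_hjb_loss,
                                train_reduced_potential)
from nessland.simulate import SampleSet, analytic_sample_set
from nessland.systems import DynamicalSystem


@pytest.fixture(scope="module")
def ou4():
    """4D product Ornstein-Uhlenbeck system (drift -x), separable."""
    return DynamicalSystem(
        dim=4, drift=lambda x: -np.atleast_2d(x).astype(float),
        drift_divergence=lambda x: -4.0 * np.ones(len(np.atleast_2d(x))),
        analytic_potential=lambda x: 0.5 * np.sum(np.atleast_2d(x) ** 2, axis=1),
        analytic_sampler=lambda n, D, rng: np.sqrt(D) * rng.standard_normal((n, 4)),
        name="ou4")


@pytest.fixture(scope="module")
def ou4_samples(ou4):
    return analytic_sample_set(ou4, D=0.5, n=20000, seed=21)


@pytest.fixture(scope="module")
def spec2():
    return ReducedSpec(z_indices=(0, 1), reduced_domain=[[-2, 2], [-2, 2]],
                       grid=41)


def test_spec_validation():
    with pytest.raises(ValueError, match="distinct"):
        ReducedSpec(z_indices=(1, 1), reduced_domain=[[-1, 1], [-1, 1]])
    with pytest.raises(ValueError, match="grid"):
        ReducedSpec(z_indices=(0, 1), reduced_domain=[[-1, 1], [-1, 1]], grid=8)


class TestProjectedForce:
    def test_recovers_z_only_force_exactly(self, ou4, ou4_samples, spec2):
        # F_z = -z depends on z alone: zero-variance regression
        cfg = TrainingConfig(D=0.5, epochs=300, batch_size=512,
                             learning_rate=3e-3, lr_schedule="cosine", seed=0)
        G = fit_projected_force(ou4_samples, ou4, spec2, cfg)
        z = ou4_samples.states[:2000, :2]
        # occupied region: central 95% box of the steady marginal
        box = np.quantile(np.abs(z), 0.95)
        z = z[np.all(np.abs(z) <= box, axis=1)]
        err = np.max(np.abs(G(z) - (-z)))
        assert err < 0.02

    def test_conditional_mean_with_y_noise(self, spec2):
        # F_z(y, z) = -z + y_3 with y_3 centered at 0 under pi: G~ -> -z
        sys_ = DynamicalSystem(
            dim=3,
            drift=lambda x: np.column_stack([
                -np.atleast_2d(x)[:, 0] + np.atleast_2d(x)[:, 2],
                -np.atleast_2d(x)[:, 1],
                -np.atleast_2d(x)[:, 2]]),
            drift_divergence=lambda x: -3.0 * np.ones(len(np.atleast_2d(x))))
        rng = np.random.default_rng(3)
        states = np.sqrt(0.5) * rng.standard_normal((20000, 3))
        samples = SampleSet(states=states, noise_strength=0.5,
                            provenance="analytic")
        cfg = TrainingConfig(D=0.5, epochs=200, batch_size=512,
                             learning_rate=3e-3, lr_schedule="cosine", seed=0)
        G = fit_projected_force(samples, sys_, spec2, cfg)
        z = states[:2000, :2]
        # slope recovered within 5%
        assert np.mean(np.abs(G(z) + z)) < 0.05 * np.mean(np.abs(z))

    def test_loss_floor_is_conditional_variance(self, spec2):
        # projection property: the regression loss cannot fall below the
        # within-slice variance of F_z
        rng = np.random.default_rng(4)
        states = rng.standard_normal((20000, 3))
        sys_ = DynamicalSystem(
            dim=3,
            drift=lambda x: np.column_stack([
                -np.atleast_2d(x)[:, 0] + np.atleast_2d(x)[:, 2],
                -np.atleast_2d(x)[:, 1],
                -np.atleast_2d(x)[:, 2]]),
            drift_divergence=lambda x: -3.0 * np.ones(len(np.atleast_2d(x))))
        samples = SampleSet(states=states, noise_strength=0.5,
                            provenance="analytic")
        spec = ReducedSpec(z_indices=(0, 1), reduced_domain=[[-3, 3], [-3, 3]],
                           grid=41)
        cfg = TrainingConfig(D=0.5, epochs=150, batch_size=512,
                             learning_rate=3e-3, lr_schedule="cosine", seed=0)
        G = fit_projected_force(samples, sys_, spec, cfg)
        Fz = sys_.drift(states)[:, :2]
        loss = np.mean(np.sum((Fz - G(states[:, :2])) ** 2, axis=1))
        # conditional variance of F_z given z is Var(y_3) = 1 (first comp.)
        cond_var = 1.0
        assert loss > cond_var * (1 - 0.05)


class TestProjectedLosses:
    def test_hand_computed_p_epr(self, spec2):
        sys_ = DynamicalSystem(
            dim=4, drift=lambda x: -np.atleast_2d(x).astype(float),
            drift_divergence=lambda x: -4.0 * np.ones(len(np.atleast_2d(x))))
        zero = AnalyticModel(2, lambda z: np.zeros(len(z)),
                             gradient=lambda z: np.zeros_like(z))
        samples = SampleSet(states=[[1.0, 0.0, 0.3, -0.2]], noise_strength=0.5,
                            provenance="analytic")
        assert p_epr_loss(zero, samples, sys_, spec2) == pytest.approx(1.0)

    def test_separable_truth_minimizes_p_epr(self, ou4, ou4_samples, spec2):
        u = AnalyticModel(2, lambda z: 0.5 * np.sum(z ** 2, axis=1),
                          gradient=lambda z: np.atleast_2d(z).astype(float),
                          laplacian=lambda z: np.full(len(z), 2.0))
        assert p_epr_loss(u, ou4_samples, ou4, spec2) < 1e-28

    def test_p_hjb_zero_for_separable_truth(self, ou4, spec2, rng):
        u = AnalyticModel(2, lambda z: 0.5 * np.sum(z ** 2, axis=1),
                          gradient=lambda z: np.atleast_2d(z).astype(float),
                          laplacian=lambda z: np.full(len(z), 2.0))

        class MinusZ:
            def __call__(self, z):
                return -np.atleast_2d(z)

            def divergence(self, z):
                return -2.0 * np.ones(len(np.atleast_2d(z)))

        z = rng.standard_normal((200, 2))
        assert p_hjb_loss(u, MinusZ(), z, D=0.5) < 1e-28

    def test_full_reduction_coincides_with_hjb_loss(self, toy_c1,
                                                    toy_samples_exact):
        # z = all coordinates of a 2D system: the projected HJB residual with
        # the exact force equals the full HJB residual pointwise
        spec = ReducedSpec(z_indices=(0, 1), reduced_domain=[[-2, 2], [-2, 2]])
        model = MLPPotential(2, seed=5)
        exact = ExactReducedForce(toy_c1, spec)
        lhs = p_hjb_loss(model, exact, toy_samples_exact.states, D=0.1)
        rhs = hjb_loss(model, toy_samples_exact, toy_c1, D=0.1)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_p_epr_equals_epr_when_z_is_everything(self, toy_c1,
                                                   toy_samples_exact):
        from nessland.potential import epr_loss
        spec = ReducedSpec(z_indices=(0, 1), reduced_domain=[[-2, 2], [-2, 2]])
        model = MLPPotential(2, seed=6)
        assert p_epr_loss(model, toy_samples_exact, toy_c1, spec) == \
            pytest.approx(epr_loss(model, toy_samples_exact, toy_c1), rel=1e-12)


class TestTwoRoutes:
    def test_route1_recovers_separable_marginal(self, ou4, ou4_samples, spec2):
        D = 0.5
        cfg = TrainingConfig(D=D, lambda1=1.0, lambda2=0.0, epochs=200,
                             batch_size=512, learning_rate=3e-3,
                             lr_schedule="cosine", seed=0)
        model, force, trace = train_reduced_potential(ou4, ou4_samples, spec2,
                                                      cfg)
        u = AnalyticModel(2, lambda z: 0.5 * np.sum(z ** 2, axis=1))
        # compare on the occupied region via exact marginal samples
        z_eval = ou4_samples.states[:4000, :2]
        assert rrmse(model.value, u, D, eval_points=z_eval) < 0.05

    def test_route2_identity_weights_is_kde_of_marginal(self, ou4,
                                                        ou4_samples, spec2):
        D = 0.5
        grid = marginalize_potential(
            AnalyticModel(4, lambda x: 0.5 * np.sum(x ** 2, axis=1)),
            ou4_samples, spec2, D, bandwidth="cv")
        u = AnalyticModel(2, lambda z: 0.5 * np.sum(z ** 2, axis=1))
        pts = grid.grid_points
        vals = grid.values.ravel()
        keep = np.isfinite(vals) & (0.5 * np.sum(pts ** 2, axis=1) <= 20 * D * 0.15)
        ref_vals = u.value(pts[keep])
        v = vals[keep] - vals[keep].min()
        r = ref_vals - ref_vals.min()
        err = np.sqrt(np.sum((v - r) ** 2) / np.sum(r ** 2))
        assert err < 0.05

    def test_masking_of_unoccupied_cells(self, ou4, ou4_samples):
        spec = ReducedSpec(z_indices=(0, 1), reduced_domain=[[-6, 6], [-6, 6]],
                           grid=41)
        grid = marginalize_potential(
            AnalyticModel(4, lambda x: 0.5 * np.sum(x ** 2, axis=1)),
            ou4_samples, spec, D=0.5)
        assert np.isnan(grid.values[0, 0])        # far corner unoccupied
        assert np.isfinite(grid.values[20, 20])   # origin occupied
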