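"""Reduced (2-coordinate) landscapes by projected losses or marginalization.

Two routes to the reduced potential  U~(z) = -D ln p~_ss(z)  over two
prescribed coordinates z = (x_i, x_j):

* Route 1 (projected training): first regress the projected force
  G~(z) ~ E_pi[F_z | z] by least squares over steady samples, then minimize
  lambda1 * L_P-EPR + lambda2 * L_P-HJB for a 2D potential network, where
  the projected losses mirror the full-space EPR / HJB losses with F_z and
  G~ in place of F.
* Route 2 (marginalization): reduce a precomputed high-dimensional potential
  V(x) by a weighted kernel density estimate of the z-marginal of its
  Boltzmann density, then take -D ln on a grid.

The two routes agree on systems with analytic marginals and serve as mutual
consistency checks in high dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .autodiff import Adam, Tensor, sum_axis
from .evaluation import ReferenceSolution
from .potential import (MLPPotential, TrainingConfig, _epr_term_tape,
                        _hjb_term_tape)
from .simulate import SampleSet
from .systems import DynamicalSystem

__all__ = [
    "ReducedSpec", "ReducedForceModel", "ExactReducedForce",
    "fit_projected_force", "p_epr_loss", "p_hjb_loss",
    "train_reduced_potential", "marginalize_potential",
]


@dataclass
class ReducedSpec:
    """Which two coordinates to reduce to, and the evaluation lattice."""

    z_indices: tuple[int, int]
    reduced_domain: np.ndarray            # (2, 2) low/high
    grid: int = 64

    def __post_init__(self):
        i, j = self.z_indices
        if i == j:
            raise ValueError("z_indices must be distinct")
        self.reduced_domain = np.asarray(self.reduced_domain,
                                         dtype=float).reshape(2, 2)
        if self.grid < 32:
            raise ValueError("grid resolution must be >= 32 per axis")

    def project(self, states: np.ndarray) -> np.ndarray:
        return np.atleast_2d(states)[:, list(self.z_indices)]

    def axes(self):
        (l1, h1), (l2, h2) = self.reduced_domain
        return (np.linspace(l1, h1, self.grid), np.linspace(l2, h2, self.grid))


class ReducedForceModel:
    """A learned 2D vector field z -> G~(z), with autodiff divergence."""

    def __init__(self, hidden: Sequence[int] = (20, 20, 20), seed: int = 0,
                 x_shift=None, x_scale=None):
        self.net = MLPPotential(2, hidden=hidden, out_dim=2, seed=seed,
                                x_shift=x_shift, x_scale=x_scale)

    def __call__(self, z) -> np.ndarray:
        return self.net.value(np.atleast_2d(z))

    def divergence(self, z) -> np.ndarray:
        jac = self.net.gradient(np.atleast_2d(z))     # (N, out=2, dim=2)
        return jac[:, 0, 0] + jac[:, 1, 1]


class ExactReducedForce:
    """Adapter exposing the exact z-components of a system drift as a
    'projected force' (correct whenever F_z depends on z only, e.g. when the
    reduction keeps all coordinates)."""

    def __init__(self, system: DynamicalSystem, spec: ReducedSpec):
        self.system, self.spec = system, spec
        if system.dim != 2:
            raise ValueError("ExactReducedForce requires a 2D system")

    def __call__(self, z):
        return self.system.drift(np.atleast_2d(z))[:, list(self.spec.z_indices)]

    def divergence(self, z):
        return self.system.drift_divergence(np.atleast_2d(z))


def fit_projected_force(samples: SampleSet, system: DynamicalSystem,
                        spec: ReducedSpec, config: TrainingConfig,
                        min_samples_per_cell: int = 5,
                        coverage_grid: int = 8) -> ReducedForceModel:
    """Least-squares regression of the drift's z-components onto z.

    The population minimizer of  mean |F_z(y_i, z_i) - G~(z_i)|^2  is the
    conditional expectation E_pi[F_z | z] — the projected force.
    """
    Z = spec.project(samples.states)
    Fz = spec.project(system.drift(samples.states))
    # coverage warning: occupied coarse cells with very few samples
    hist, _, _ = np.histogram2d(Z[:, 0], Z[:, 1], bins=coverage_grid)
    occupied = hist[hist > 0]
    if (occupied < min_samples_per_cell).any():
        warnings.warn("some occupied regions of the reduced plane contain "
                      f"fewer than {min_samples_per_cell} samples; the "
                      "projected force is poorly constrained there")
    model = ReducedForceModel(hidden=config.hidden, seed=config.seed)
    rng = np.random.default_rng(config.seed + 2)
    opt = Adam(model.net.params, lr=config.learning_rate)
    N = len(Z)
    bs = min(config.batch_size, N)
    n_batches = max(1, N // bs)
    for _ in range(config.epochs):
        perm = rng.permutation(N)
        for bi in range(n_batches):
            idx = perm[bi * bs:(bi + 1) * bs]
            opt.zero_grad()
            pred, _, _ = model.net.forward_tape(Z[idx], need_grad=False)
            r = pred - Tensor(Fz[idx])
            loss = sum_axis(r * r, 1).mean()
            loss.backward()
            opt.step()
    return model


def p_epr_loss(reduced_model: MLPPotential, samples: SampleSet,
               system: DynamicalSystem, spec: ReducedSpec) -> float:
    """Projected force-projection loss
    (1/N) sum |F_z(y_i, z_i) + grad_z V~(z_i)|^2; its population minimizer is
    the reduced potential -D ln p~_ss."""
    if reduced_model.in_dim != 2:
        raise ValueError("reduced model must take 2D inputs")
    Z = spec.project(samples.states)
    Fz = spec.project(system.drift(samples.states))
    r = Fz + reduced_model.gradient(Z)
    return float(np.mean(np.sum(r * r, axis=1)))


def p_hjb_loss(reduced_model: MLPPotential, reduced_force,
               enhanced_z_samples: np.ndarray, D: float) -> float:
    """Mean squared projected HJB residual
    -G~ . grad_z V~ + D lap_z V~ - |grad_z V~|^2 + D div_z G~
    over enhanced z-points (the learned G~ standing in for the projected
    force)."""
    Z = np.atleast_2d(np.asarray(enhanced_z_samples, dtype=float))
    g = reduced_model.gradient(Z)
    lap = reduced_model.laplacian(Z)
    G = reduced_force(Z)
    divG = reduced_force.divergence(Z)
    res = (-np.sum(G * g, axis=1) + D * lap - np.sum(g * g, axis=1) + D * divG)
    return float(np.mean(res * res))


def train_reduced_potential(system: DynamicalSystem, samples: SampleSet,
                            spec: ReducedSpec, config: TrainingConfig,
                            enhanced_samples: Optional[SampleSet] = None,
                            reduced_force: Optional[ReducedForceModel] = None,
                            force_config: Optional[TrainingConfig] = None,
                            ):
    """Two-stage route-1 construction of the reduced landscape V~1.

    Stage 1 regresses the projected force G~; stage 2 minimizes
    lambda1 * L_P-EPR + lambda2 * L_P-HJB for a 2D potential network.
    Returns (potential model, reduced force model, trace DataFrame).
    """
    import pandas as pd

    if reduced_force is None:
        reduced_force = fit_projected_force(
            samples, system, spec, force_config or config)
    Z = spec.project(samples.states)
    Fz = spec.project(system.drift(samples.states))
    if config.lambda2 > 0:
        if enhanced_samples is None:
            raise ValueError("lambda2 > 0 requires enhanced samples")
        Ze = (enhanced_samples.states if enhanced_samples.dim == 2
              else spec.project(enhanced_samples.states))
        Ge = reduced_force(Ze)
        divGe = reduced_force.divergence(Ze)
        Ne = len(Ze)

    model = MLPPotential(2, hidden=config.hidden, seed=config.seed)
    rng = np.random.default_rng(config.seed + 3)
    opt = Adam(model.params, lr=config.learning_rate)
    N = len(Z)
    bs = min(config.batch_size, N)
    n_batches = max(1, N // bs)
    trace = []
    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            opt.lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / config.epochs))
        perm = rng.permutation(N)
        if config.lambda2 > 0:
            perme = rng.permutation(Ne)
            bse = min(bs, Ne)
        ep_epr = ep_hjb = 0.0
        for bi in range(n_batches):
            idx = perm[bi * bs:(bi + 1) * bs]
            opt.zero_grad()
            l_epr = _epr_term_tape(model, Z[idx], Fz[idx])
            total = config.lambda1 * l_epr
            l_hjb_val = 0.0
            if config.lambda2 > 0:
                start = (bi * bse) % Ne
                eidx = perme[start:start + bse]
                if len(eidx) < bse:
                    eidx = np.concatenate([eidx, perme[:bse - len(eidx)]])
                l_hjb = _hjb_term_tape(model, Ze[eidx], Ge[eidx],
                                       divGe[eidx], config.D)
                total = total + config.lambda2 * l_hjb
                l_hjb_val = float(l_hjb.value)
            if not np.isfinite(total.value):
                raise RuntimeError(f"non-finite reduced loss at epoch {epoch}")
            total.backward()
            opt.step()
            ep_epr += float(l_epr.value)
            ep_hjb += l_hjb_val
        trace.append({"epoch": epoch, "epr_term": ep_epr / n_batches,
                      "hjb_term": ep_hjb / n_batches})
    return model, reduced_force, pd.DataFrame(trace)


def _cv_bandwidth_factor(Z: np.ndarray, candidates=(0.2, 0.35, 0.5, 0.7, 1.0),
                         max_n: int = 4000, folds: int = 3,
                         seed: int = 0) -> float:
    """Likelihood cross-validation over multiples of the Scott factor.

    The Scott rule uses the global covariance, which badly oversmooths
    multimodal marginals (the covariance is inflated by the inter-well
    separation); held-out log-likelihood picks the factor adaptively.
    """
    rng = np.random.default_rng(seed)
    if len(Z) > max_n:
        Z = Z[rng.choice(len(Z), size=max_n, replace=False)]
    scott = gaussian_kde(Z.T).scotts_factor()
    idx = rng.permutation(len(Z))
    best, best_ll = scott, -np.inf
    for c in candidates:
        ll = 0.0
        for f in range(folds):
            test = idx[f::folds]
            train = np.setdiff1d(idx, test)
            kde = gaussian_kde(Z[train].T, bw_method=c * scott)
            ll += np.mean(np.log(np.maximum(kde(Z[test].T), 1e-300)))
        if ll > best_ll:
            best_ll, best = ll, c * scott
    return best


def marginalize_potential(highdim_model, samples: SampleSet, spec: ReducedSpec,
                          D: float, sampling_density: Optional[np.ndarray] = None,
                          bandwidth=None, min_kernel_count: float = 5.0,
                          bias_correction: bool = True,
                          reflect_domain=None) -> ReferenceSolution:
    """Route-2 reduced potential V~2: weighted kernel estimate of the
    z-marginal of the model's Boltzmann density on the ``spec`` lattice.

    With ``sampling_density`` = p_hat(x_i) (a density estimate of the law the
    samples were drawn from), each sample is importance-reweighted by
    w_i ∝ exp(-V(x_i)/D) / p_hat(x_i), so the estimate targets the model's
    own steady density.  Without it, the samples are taken as already
    Boltzmann-distributed (identity weights) and the estimate reduces to a
    plain kernel density estimate of p~_ss.  Grid cells where the expected
    number of samples within one kernel window falls below
    ``min_kernel_count`` are masked (NaN), not extrapolated — the estimate
    (and especially its logarithm) is pure noise there.  ``bandwidth``
    follows scipy's ``gaussian_kde`` (None = Scott rule) or ``"cv"`` for
    held-out-likelihood selection, which matters for multimodal marginals
    where the global-covariance Scott rule oversmooths.

    ``reflect_domain`` — a (2, 2) low/high box — mirrors the samples about
    each box face before estimation (the standard reflection correction for
    densities with reflecting boundaries, where a plain kernel estimate
    leaks mass outside and biases -D ln p upward near the walls).
    """
    Z = spec.project(samples.states)
    if bandwidth == "cv":
        bandwidth = _cv_bandwidth_factor(Z)
    weights = None
    if sampling_density is not None:
        V = np.asarray(highdim_model(samples.states), dtype=float).reshape(len(Z))
        logw = -(V - V.min()) / D - np.log(np.asarray(sampling_density, float))
        logw -= logw.max()
        weights = np.exp(logw)
        weights /= weights.sum()
    if reflect_domain is not None:
        # mirror only samples within a few kernel widths of each face, so
        # the data covariance (hence the bandwidth) is not distorted
        box = np.asarray(reflect_domain, dtype=float).reshape(2, 2)
        h = gaussian_kde(Z.T, bw_method=bandwidth, weights=weights).factor
        stds = Z.std(axis=0)
        pieces = [Z]
        w_pieces = [weights] if weights is not None else None
        for ax in range(2):
            for side in range(2):
                face = box[ax, side]
                if not np.isfinite(face):
                    continue
                near = np.abs(Z[:, ax] - face) < 5.0 * h * stds[ax]
                if not near.any():
                    continue
                m = Z[near].copy()
                m[:, ax] = 2 * face - m[:, ax]
                pieces.append(m)
                if w_pieces is not None:
                    w_pieces.append(weights[near])
        Z = np.vstack(pieces)
        if weights is not None:
            weights = np.concatenate(w_pieces)
            weights /= weights.sum()
    kde = gaussian_kde(Z.T, bw_method=bandwidth, weights=weights)
    ax1, ax2 = spec.axes()
    X, Y = np.meshgrid(ax1, ax2, indexing="ij")
    pts = np.vstack([X.ravel(), Y.ravel()])
    dens = kde(pts).reshape(X.shape)
    # expected effective sample count within one kernel window per cell
    n_eff = len(Z) if weights is None else 1.0 / np.sum(weights ** 2)
    kernel_area = 2 * np.pi * np.sqrt(np.linalg.det(kde.covariance))
    mask = dens * n_eff * kernel_area < min_kernel_count
    if bias_correction:
        # multiplicative (Jones-Linton-Nielsen) correction p^2 / (K_h * p):
        # K_h * p-hat is a second pass at bandwidth sqrt(2) h, and the ratio
        # cancels the leading O(h^2) smoothing bias of -D ln p-hat
        kde2 = gaussian_kde(Z.T, bw_method=np.sqrt(2.0) * kde.factor,
                            weights=weights)
        dens2 = kde2(pts).reshape(X.shape)
        dens = dens * dens / np.maximum(dens2, 1e-300)
    with np.errstate(divide="ignore"):
        U = -D * np.log(dens)
    U[mask] = np.nan
    return ReferenceSolution(x=ax1, y=ax2, values=U, D=D, source="marginalized",
                             density=dens)
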