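"""Neural potential model and the variational landscape-construction losses.

The scalar field V(x; theta) is a tanh multilayer perceptron (default three
hidden layers of 20 units).  The central objects are:

* the EPR loss  L_EPR = (1/N) sum_i |F(x_i) + grad V(x_i)|^2  over steady
  samples, whose population minimizer is the landscape U = -D ln p_ss and
  whose minimum value is the steady entropy production rate;
* the viscous HJB residual  N_HJB(V) = -F.grad V + D lap V - |grad V|^2
  + D div F, squared and averaged over an *enhanced* (broader) sample set;
* the enhanced loss  lambda1 L_EPR + lambda2 L_HJB, the small-noise workhorse;
* the weighted-norm loss for state-dependent diffusion a(x) = sigma sigma^T:
  L_V-EPR = mean (F^v + a grad V)^T a^-1 (F^v + a grad V),
  F^v = F - D div a.

Training minimizes these by minibatch Adam using the package autodiff core;
spatial first and second derivatives of V are tracked exactly through the
network layers, so parameter gradients of the HJB term are exact as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .autodiff import (Adam, Tensor, affine, einsum, jac_linear, matmul_right,
                       sum_axis)
from .simulate import SampleSet
from .systems import DynamicalSystem

__all__ = [
    "MLPPotential", "TrainingConfig", "epr_loss", "hjb_residual", "hjb_loss",
    "enhanced_loss", "vepr_loss", "train_potential", "estimate_epr",
]


class MLPPotential:
    """Feedforward tanh network x -> V(x), with exact spatial gradient and
    Laplacian, batched.  ``out_dim > 1`` turns it into a vector field (used
    for the projected-force regression)."""

    def __init__(self, in_dim: int, hidden: Sequence[int] = (20, 20, 20),
                 out_dim: int = 1, seed: int = 0,
                 x_shift=None, x_scale=None):
        self.in_dim = int(in_dim)
        self.hidden = tuple(int(h) for h in hidden)
        self.out_dim = int(out_dim)
        # input standardization u = (x - shift) / scale, folded exactly into
        # the spatial-derivative trackers via the chain rule
        self.x_shift = (np.zeros(in_dim) if x_shift is None
                        else np.asarray(x_shift, dtype=np.float64).reshape(in_dim))
        self.x_scale = (np.ones(in_dim) if x_scale is None
                        else np.asarray(x_scale, dtype=np.float64).reshape(in_dim))
        if np.any(self.x_scale <= 0):
            raise ValueError("x_scale must be positive")
        rng = np.random.default_rng(seed)
        sizes = [self.in_dim, *self.hidden, self.out_dim]
        self.params: list[Tensor] = []
        self._Ws, self._bs = [], []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (n_in + n_out))  # Xavier-uniform
            W = Tensor(rng.uniform(-bound, bound, size=(n_out, n_in)),
                       requires_grad=True)
            b = Tensor(np.zeros(n_out), requires_grad=True)
            self._Ws.append(W)
            self._bs.append(b)
            self.params += [W, b]

    # ---- fast numpy evaluation (no tape) --------------------------------

    def _forward_np(self, x, need_grad=False, need_lap=False):
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        h = (x - self.x_shift) / self.x_scale
        G = S = None
        if need_grad or need_lap:
            # d u_i / d x_k = delta_ik / scale_k seeds the Jacobian tracker
            G = np.broadcast_to(np.diag(1.0 / self.x_scale),
                                (len(x), self.in_dim, self.in_dim))
        if need_lap:
            S = np.zeros((len(x), self.in_dim))
        n_layers = len(self._Ws)
        for li, (W, b) in enumerate(zip(self._Ws, self._bs)):
            Wv, bv = W.value, b.value
            a = h @ Wv.T + bv
            if G is not None:
                Ga = np.matmul(G, Wv.T)          # (B, k, o)
            if S is not None:
                Sa = S @ Wv.T
            if li == n_layers - 1:  # linear output layer
                h, G2, S2 = a, (Ga if G is not None else None), (Sa if S is not None else None)
            else:
                h = np.tanh(a)
                t = 1.0 - h * h
                G2 = t[:, None, :] * Ga if G is not None else None
                if S is not None:
                    Qa = (Ga * Ga).sum(axis=1)
                    S2 = (-2.0 * h * t) * Qa + t * Sa
                else:
                    S2 = None
            G, S = G2, S2
        return h, G, S

    def value(self, x) -> np.ndarray:
        v, _, _ = self._forward_np(x)
        return v[:, 0] if self.out_dim == 1 else v

    def __call__(self, x) -> np.ndarray:
        return self.value(x)

    def gradient(self, x) -> np.ndarray:
        _, G, _ = self._forward_np(x, need_grad=True)
        # internal layout is (N, dim, out); expose (N, dim) or (N, out, dim)
        return G[:, :, 0] if self.out_dim == 1 else np.swapaxes(G, 1, 2)

    def laplacian(self, x) -> np.ndarray:
        _, _, S = self._forward_np(x, need_lap=True)
        return S[:, 0] if self.out_dim == 1 else S

    # ---- tape evaluation for training -----------------------------------

    def forward_tape(self, x, need_grad=True, need_lap=False):
        """Return (V, G, S) as autodiff Tensors: value (N,out), spatial
        gradient (N,dim,out), Laplacian (N,out)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        h = Tensor((x - self.x_shift) / self.x_scale)
        G = Tensor(np.broadcast_to(np.diag(1.0 / self.x_scale),
                                   (len(x), self.in_dim, self.in_dim)).copy()) \
            if (need_grad or need_lap) else None
        S = Tensor(np.zeros((len(x), self.in_dim))) if need_lap else None
        n_layers = len(self._Ws)
        for li, (W, b) in enumerate(zip(self._Ws, self._bs)):
            a = affine(h, W, b)
            Ga = jac_linear(G, W) if G is not None else None
            Sa = affine(S, W) if S is not None else None
            if li == n_layers - 1:
                h, G, S = a, Ga, Sa
            else:
                h = a.tanh()
                t = 1.0 - h * h
                if Ga is not None:
                    G = t.reshape(len(x), 1, -1) * Ga
                if Sa is not None:
                    Qa = sum_axis(Ga * Ga, 1)
                    S = (-2.0 * h * t) * Qa + t * Sa
        return h, G, S

    def gradient_tape(self, x) -> Tensor:
        """Spatial gradient of a scalar network as a (N, dim) Tensor, by
        reverse accumulation of vector-Jacobian products.  Cheaper than
        :meth:`forward_tape` when the Laplacian is not needed."""
        if self.out_dim != 1:
            raise ValueError("gradient_tape requires a scalar network")
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        h = Tensor((x - self.x_shift) / self.x_scale)
        ts: list[Tensor] = []
        for W, b in zip(self._Ws[:-1], self._bs[:-1]):
            h = affine(h, W, b).tanh()
            ts.append(1.0 - h * h)
        # dV/da_last-hidden = t_last * (output row of W_out)
        u = ts[-1] * self._Ws[-1]                 # (B,w) * (1,w) broadcast
        for li in range(len(ts) - 2, -1, -1):
            u = ts[li] * matmul_right(u, self._Ws[li + 1])
        # chain rule through the input standardization
        return matmul_right(u, self._Ws[0]) * Tensor(1.0 / self.x_scale)

    # ---- persistence -----------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "in_dim": self.in_dim, "hidden": list(self.hidden),
            "out_dim": self.out_dim,
            "x_shift": self.x_shift.tolist(), "x_scale": self.x_scale.tolist(),
            "weights": [W.value.tolist() for W in self._Ws],
            "biases": [b.value.tolist() for b in self._bs],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.state_dict()))

    @classmethod
    def load(cls, path) -> "MLPPotential":
        d = json.loads(Path(path).read_text())
        model = cls(d["in_dim"], d["hidden"], d["out_dim"],
                    x_shift=d.get("x_shift"), x_scale=d.get("x_scale"))
        for W, w in zip(model._Ws, d["weights"]):
            W.value = np.asarray(w, dtype=np.float64)
        for b, v in zip(model._bs, d["biases"]):
            b.value = np.asarray(v, dtype=np.float64)
        return model


class AnalyticModel:
    """Adapter giving a closed-form scalar field the same batched
    value/gradient/laplacian interface as :class:`MLPPotential`.  Gradient
    and Laplacian default to central finite differences of the value."""

    def __init__(self, in_dim: int, value, gradient=None, laplacian=None,
                 h: float = 1e-5):
        self.in_dim = in_dim
        self.out_dim = 1
        self._value = value
        self._gradient = gradient
        self._laplacian = laplacian
        self._h = h

    def value(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.asarray(self._value(x), dtype=float).reshape(len(x))

    __call__ = value

    def gradient(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self._gradient is not None:
            return np.asarray(self._gradient(x), dtype=float)
        g = np.zeros_like(x)
        for k in range(self.in_dim):
            e = np.zeros(self.in_dim)
            e[k] = self._h
            g[:, k] = (self.value(x + e) - self.value(x - e)) / (2 * self._h)
        return g

    def laplacian(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self._laplacian is not None:
            return np.asarray(self._laplacian(x), dtype=float).reshape(len(x))
        v0 = self.value(x)
        lap = np.zeros(len(x))
        for k in range(self.in_dim):
            e = np.zeros(self.in_dim)
            e[k] = self._h
            lap += (self.value(x + e) - 2 * v0 + self.value(x - e)) / self._h ** 2
        return lap

    def _forward_np(self, x, need_grad=False, need_lap=False):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        G = self.gradient(x)[:, :, None] if (need_grad or need_lap) else None
        S = self.laplacian(x)[:, None] if need_lap else None
        return self.value(x)[:, None], G, S


@dataclass
class TrainingConfig:
    """Hyperparameters of the landscape training loop."""

    D: float = 0.1
    lambda1: float = 1.0
    lambda2: float = 0.0
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    lr_schedule: str = "none"  # "none" | "cosine" (anneal to 0 over epochs)
    batch_size: int = 2048
    epochs: int = 3000
    hidden: Sequence[int] = (20, 20, 20)
    seed: int = 0
    enhancement: Optional[dict] = None  # e.g. {"kind": "larger_noise", "D_prime": ...}
    extra: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0 or self.lambda1 + self.lambda2 <= 0:
            raise ValueError("loss weights must be nonnegative with a positive sum")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.lr_schedule not in ("none", "cosine"):
            raise ValueError("lr_schedule must be 'none' or 'cosine'")


# ---------------------------------------------------------------------------
# losses (public numpy evaluations)
# ---------------------------------------------------------------------------

def _check_dim(model: MLPPotential, system: DynamicalSystem):
    if model.in_dim != system.dim:
        raise ValueError(f"model dimension {model.in_dim} != system dimension {system.dim}")


def epr_loss(model: MLPPotential, samples: SampleSet,
             system: DynamicalSystem) -> float:
    """Empirical force-projection loss (1/N) sum |F(x_i) + grad V(x_i)|^2."""
    _check_dim(model, system)
    x = samples.states
    r = system.drift(x) + model.gradient(x)
    return float(np.mean(np.sum(r * r, axis=1)))


def hjb_residual(model: MLPPotential, points: np.ndarray,
                 system: DynamicalSystem, D: float) -> np.ndarray:
    """Pointwise viscous HJB operator -F.gradV + D lapV - |gradV|^2 + D divF."""
    if system.diffusion_matrix is not None:
        raise ValueError("HJB residual assumes identity diffusion; "
                         "use the weighted-norm (V-EPR) path for sigma(x)")
    x = np.atleast_2d(np.asarray(points, dtype=float))
    _, G, S = model._forward_np(x, need_grad=True, need_lap=True)
    g, lap = G[:, :, 0], S[:, 0]
    F = system.drift(x)
    if system.drift_divergence is None:
        raise ValueError("system lacks drift_divergence; supply an analytic "
                         "divergence or a finite-difference fallback")
    return (-np.sum(F * g, axis=1) + D * lap - np.sum(g * g, axis=1)
            + D * system.drift_divergence(x))


def hjb_loss(model: MLPPotential, enhanced_samples: SampleSet,
             system: DynamicalSystem, D: float) -> float:
    """Mean squared HJB residual over the enhanced sample set."""
    r = hjb_residual(model, enhanced_samples.states, system, D)
    return float(np.mean(r * r))


def enhanced_loss(model: MLPPotential, samples: SampleSet,
                  enhanced_samples: Optional[SampleSet],
                  system: DynamicalSystem, config: TrainingConfig) -> float:
    """lambda1 * L_EPR + lambda2 * L_HJB."""
    total = config.lambda1 * epr_loss(model, samples, system)
    if config.lambda2 > 0:
        if enhanced_samples is None:
            raise ValueError("lambda2 > 0 requires an enhanced sample set")
        total += config.lambda2 * hjb_loss(model, enhanced_samples, system, config.D)
    return float(total)


def _diffusion_fields(system: DynamicalSystem, x: np.ndarray, D: float):
    """a = sigma sigma^T, a^-1 and F^v = F - D div a at the given states."""
    sig = system.diffusion_matrix(x)                       # (N, d, m)
    a = np.einsum("nim,njm->nij", sig, sig)
    # positive definiteness check by Cholesky
    try:
        np.linalg.cholesky(a)
    except np.linalg.LinAlgError:
        bad = next(i for i in range(len(a))
                   if np.any(np.linalg.eigvalsh(a[i]) <= 0))
        raise ValueError(f"diffusion matrix a(x) singular at sample {x[bad]}")
    a_inv = np.linalg.inv(a)
    if system.diffusion_divergence is not None:
        div_a = system.diffusion_divergence(x)             # (N, d)
    else:
        h = 1e-5
        div_a = np.zeros((len(x), system.dim))
        for j in range(system.dim):
            e = np.zeros(system.dim)
            e[j] = h
            sp = system.diffusion_matrix(x + e)
            sm = system.diffusion_matrix(x - e)
            ap = np.einsum("nim,njm->nij", sp, sp)
            am = np.einsum("nim,njm->nij", sm, sm)
            div_a += (ap[:, :, j] - am[:, :, j]) / (2 * h)
    Fv = system.drift(x) - D * div_a
    return a, a_inv, Fv


def vepr_loss(model: MLPPotential, samples: SampleSet,
              system: DynamicalSystem, D: float) -> float:
    """Weighted-norm loss mean (F^v + a gradV)^T a^-1 (F^v + a gradV)
    for state-dependent diffusion; reduces exactly to ``epr_loss`` when the
    diffusion is the identity."""
    _check_dim(model, system)
    if system.diffusion_matrix is None:
        return epr_loss(model, samples, system)
    x = samples.states
    a, a_inv, Fv = _diffusion_fields(system, x, D)
    r = Fv + np.einsum("nij,nj->ni", a, model.gradient(x))
    return float(np.mean(np.einsum("ni,nij,nj->n", r, a_inv, r)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _epr_term_tape(model: MLPPotential, x: np.ndarray, F: np.ndarray) -> Tensor:
    r = model.gradient_tape(x) + Tensor(F)
    return sum_axis(r * r, 1).mean()


def _hjb_term_tape(model: MLPPotential, x: np.ndarray, F: np.ndarray,
                   divF: np.ndarray, D: float) -> Tensor:
    _, G, S = model.forward_tape(x, need_grad=True, need_lap=True)
    g = G.reshape(len(x), model.in_dim)
    lap = S.reshape(len(x))
    res = (-sum_axis(Tensor(F) * g, 1) + D * lap
           - sum_axis(g * g, 1) + Tensor(D * divF))
    return res.square().mean()


def _vepr_term_tape(model: MLPPotential, x: np.ndarray, a: np.ndarray,
                    a_inv: np.ndarray, Fv: np.ndarray) -> Tensor:
    g = model.gradient_tape(x)
    r = einsum("bij,bj->bi", Tensor(a), g) + Tensor(Fv)
    return einsum("bi,bij,bj->b", r, Tensor(a_inv), r).mean()


def train_potential(system: DynamicalSystem, samples: SampleSet,
                    enhanced_samples: Optional[SampleSet],
                    config: TrainingConfig,
                    model: Optional[MLPPotential] = None,
                    ) -> tuple[MLPPotential, "pandas.DataFrame"]:
    """Minimize the (enhanced) loss by minibatch Adam.

    Returns the trained model and a per-epoch trace DataFrame with columns
    (epoch, epr_term, hjb_term, total).  EPR and HJB minibatches are drawn
    independently from their respective sample sets.  Deterministic for a
    fixed seed.
    """
    import pandas as pd

    if config.lambda2 > 0 and enhanced_samples is None:
        raise ValueError("lambda2 > 0 requires enhanced samples")
    if model is None:
        model = MLPPotential(system.dim, hidden=config.hidden, seed=config.seed)
    _check_dim(model, system)
    N = len(samples)
    bs = min(config.batch_size, N)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params, lr=config.learning_rate)

    variable_diffusion = system.diffusion_matrix is not None
    if variable_diffusion and config.lambda2 > 0:
        raise ValueError("the HJB term is defined for identity diffusion only; "
                         "set lambda2 = 0 for state-dependent sigma(x)")

    # precompute drift data once per sample set
    X = samples.states
    if variable_diffusion:
        A_all, Ainv_all, Fv_all = _diffusion_fields(system, X, config.D)
    else:
        F_all = system.drift(X)
    if config.lambda2 > 0:
        Xe = enhanced_samples.states
        Fe_all = system.drift(Xe)
        divFe_all = system.drift_divergence(Xe)
        Ne = len(Xe)
        bse = min(config.batch_size, Ne)

    trace = []
    n_batches = max(1, N // bs)
    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            opt.lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / config.epochs))
        perm = rng.permutation(N)
        if config.lambda2 > 0:
            perme = rng.permutation(Ne)
        ep_epr = ep_hjb = 0.0
        for bi in range(n_batches):
            idx = perm[bi * bs:(bi + 1) * bs]
            opt.zero_grad()
            if variable_diffusion:
                l_epr = _vepr_term_tape(model, X[idx], A_all[idx],
                                        Ainv_all[idx], Fv_all[idx])
            else:
                l_epr = _epr_term_tape(model, X[idx], F_all[idx])
            total = config.lambda1 * l_epr
            l_hjb_val = 0.0
            if config.lambda2 > 0:
                eidx = perme[(bi * bse) % Ne:(bi * bse) % Ne + bse]
                if len(eidx) < bse:  # wrap around
                    eidx = np.concatenate([eidx, perme[:bse - len(eidx)]])
                l_hjb = _hjb_term_tape(model, Xe[eidx], Fe_all[eidx],
                                       divFe_all[eidx], config.D)
                total = total + config.lambda2 * l_hjb
                l_hjb_val = float(l_hjb.value)
            if not np.isfinite(total.value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bi} "
                    f"(epr={float(l_epr.value)}, hjb={l_hjb_val})")
            total.backward()
            opt.step()
            ep_epr += float(l_epr.value)
            ep_hjb += l_hjb_val
        trace.append({"epoch": epoch, "epr_term": ep_epr / n_batches,
                      "hjb_term": ep_hjb / n_batches,
                      "total": (config.lambda1 * ep_epr
                                + config.lambda2 * ep_hjb) / n_batches})
    return model, pd.DataFrame(trace)


def estimate_epr(model: MLPPotential, samples: SampleSet,
                 system: DynamicalSystem) -> float:
    """Steady entropy-production-rate estimate: the EPR loss at the trained
    model, whose population value at the true landscape is e_p^ss."""
    return epr_loss(model, samples, system)
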