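"""SDE system definitions: drift fields, domains, and analytic ground truth.

A :class:`DynamicalSystem` bundles everything downstream code needs about the
Langevin dynamics

    dx/dt = F(x) + sqrt(2 D) dw/dt,

namely the drift ``F``, its divergence (needed by the Hamilton-Jacobi-Bellman
residual), the domain (unbounded or a hyperrectangle with reflecting walls),
an optional state-dependent diffusion matrix, and — for benchmark fixtures —
the analytic potential U0 = -D ln p_ss and an exact steady-state sampler.

All maps are batched: states are (N, dim) arrays, drifts are (N, dim),
scalars are (N,).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "DynamicalSystem",
    "make_rotational_toy",
    "lorenz_system",
    "gmm_system",
    "twelve_dim_gmm",
    "gene_network_system",
    "system_from_config",
    "finite_difference_divergence",
]


@dataclass
class DynamicalSystem:
    """A stochastic dynamical system dx = F(x) dt + sqrt(2D) sigma(x) dw."""

    dim: int
    drift: Callable[[np.ndarray], np.ndarray]
    drift_divergence: Callable[[np.ndarray], np.ndarray]
    domain: Optional[np.ndarray] = None  # (dim, 2) low/high, or None = R^d
    diffusion_matrix: Optional[Callable[[np.ndarray], np.ndarray]] = None
    diffusion_divergence: Optional[Callable[[np.ndarray], np.ndarray]] = None
    analytic_potential: Optional[Callable[[np.ndarray], np.ndarray]] = None
    analytic_sampler: Optional[Callable[[int, float, np.random.Generator], np.ndarray]] = None
    name: str = "system"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dim <= 0:
            raise ValueError("dim must be a positive integer")
        if self.domain is not None:
            self.domain = np.asarray(self.domain, dtype=float).reshape(self.dim, 2)
            if not np.all(self.domain[:, 0] < self.domain[:, 1]):
                raise ValueError("domain bounds must satisfy low < high per coordinate")

    # convenience ---------------------------------------------------------

    def contains(self, x: np.ndarray) -> np.ndarray:
        """Boolean mask of states inside the (closed) domain."""
        x = np.atleast_2d(x)
        if self.domain is None:
            return np.ones(len(x), dtype=bool)
        lo, hi = self.domain[:, 0], self.domain[:, 1]
        return np.all((x >= lo) & (x <= hi), axis=1)

    def sample_interior(self, n: int, rng: np.random.Generator,
                        center: Optional[np.ndarray] = None, scale: float = 1.0) -> np.ndarray:
        """Initial states: uniform on a bounded domain, Gaussian otherwise."""
        if self.domain is not None:
            lo, hi = self.domain[:, 0], self.domain[:, 1]
            return rng.uniform(lo, hi, size=(n, self.dim))
        c = np.zeros(self.dim) if center is None else np.asarray(center, float)
        return c + scale * rng.standard_normal((n, self.dim))


def finite_difference_divergence(drift: Callable[[np.ndarray], np.ndarray],
                                 x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference estimate of div F at each row of ``x``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    div = np.zeros(len(x))
    for k in range(x.shape[1]):
        e = np.zeros(x.shape[1])
        e[k] = h
        div += (drift(x + e)[:, k] - drift(x - e)[:, k]) / (2 * h)
    return div


def _fd_gradient(f: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
                 h: float = 1e-6) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    g = np.zeros_like(x)
    for k in range(x.shape[1]):
        e = np.zeros(x.shape[1])
        e[k] = h
        g[:, k] = (f(x + e) - f(x - e)) / (2 * h)
    return g


# ---------------------------------------------------------------------------
# rotational toy: gradient-plus-solenoidal field with exact steady state
# ---------------------------------------------------------------------------

_J = np.array([[0.0, -1.0], [1.0, 0.0]])  # 90-degree rotation


def _quadratic_u0():
    value = lambda x: 0.5 * np.sum(np.atleast_2d(x) ** 2, axis=1)
    grad = lambda x: np.atleast_2d(x).astype(float)
    lap = lambda x: np.full(len(np.atleast_2d(x)), 2.0)
    return value, grad, lap


def _ring_u0(a: float = 1.0):
    def value(x):
        r2 = np.sum(np.atleast_2d(x) ** 2, axis=1)
        return a * (r2 - 1.0) ** 2

    def grad(x):
        x = np.atleast_2d(x).astype(float)
        r2 = np.sum(x ** 2, axis=1, keepdims=True)
        return 4.0 * a * (r2 - 1.0) * x

    def lap(x):
        x = np.atleast_2d(x)
        r2 = np.sum(x ** 2, axis=1)
        return 4.0 * a * 2 * (r2 - 1.0) + 8.0 * a * r2

    return value, grad, lap


def make_rotational_toy(u0_spec="quadratic", c: float = 1.0,
                        domain: Optional[Sequence] = None,
                        name: str = "rotational_toy") -> DynamicalSystem:
    """Two-dimensional system F = -grad(U0) + c J grad(U0).

    Because the solenoidal part c J grad(U0) is divergence-free along the level
    sets of U0, the steady density is exactly exp(-U0/D)/Z for every noise
    strength D, while the probability flux (hence the entropy production) grows
    with the rotation strength c.  ``u0_spec`` is ``"quadratic"``, ``"ring"``,
    or a dict with callables ``{"value", "grad", "lap"}``.
    """
    if isinstance(u0_spec, str):
        if u0_spec == "quadratic":
            value, grad, lap = _quadratic_u0()
        elif u0_spec == "ring":
            value, grad, lap = _ring_u0()
        else:
            raise ValueError(f"unknown confining potential {u0_spec!r}")
    else:
        value, grad = u0_spec["value"], u0_spec["grad"]
        lap = u0_spec.get("lap")
        if lap is None:
            lap = lambda x: finite_difference_divergence(grad, x)

    # smoothness check: analytic gradient must be consistent with finite
    # differences of the value at a few probe points
    rng = np.random.default_rng(0)
    probes = rng.uniform(-1.2, 1.2, size=(16, 2))
    # include near-axis probes: kinks at coordinate zeros (e.g. |x|) make
    # finite differences step-size dependent there
    probes = np.vstack([probes,
                        [[5e-7, 0.8], [0.8, -5e-7], [5e-7, -5e-7]]])
    g_fd = _fd_gradient(value, probes)
    g_an = grad(probes)
    denom = np.maximum(np.abs(g_fd), 1.0)
    if not np.all(np.abs(g_fd - g_an) / denom < 1e-3):
        raise ValueError(
            "u0_spec rejected: analytic gradient disagrees with finite "
            "differences of the value; the confining potential must be smooth"
        )

    def drift(x):
        g = grad(np.atleast_2d(x))
        return -g + c * g @ _J.T

    def divergence(x):
        # div(-grad U0) = -lap U0; the rotational part is divergence-free
        return -np.asarray(lap(np.atleast_2d(x)), dtype=float)

    sampler = None
    if isinstance(u0_spec, str) and u0_spec == "quadratic":
        def sampler(n, D, rng):
            return np.sqrt(D) * rng.standard_normal((n, 2))
    elif isinstance(u0_spec, str) and u0_spec == "ring":
        def sampler(n, D, rng):
            # radial inverse-CDF on a fine grid; angle uniform
            r = np.linspace(0.0, 3.5, 4001)
            w = r * np.exp(-(1.0 * (r ** 2 - 1.0) ** 2) / D)
            cdf = np.cumsum(w)
            cdf /= cdf[-1]
            rr = np.interp(rng.uniform(size=n), cdf, r)
            th = rng.uniform(0, 2 * np.pi, size=n)
            return np.column_stack([rr * np.cos(th), rr * np.sin(th)])

    return DynamicalSystem(
        dim=2, drift=drift, drift_divergence=divergence,
        domain=None if domain is None else np.asarray(domain, float),
        analytic_potential=lambda x: np.asarray(value(np.atleast_2d(x)), float),
        analytic_sampler=sampler, name=name, meta={"c": c, "u0": u0_spec},
    )


# ---------------------------------------------------------------------------
# Lorenz system
# ---------------------------------------------------------------------------

def lorenz_system(beta1: float = 10.0, beta2: float = 28.0,
                  beta3: float = 8.0 / 3.0) -> DynamicalSystem:
    """The chaotic Lorenz drift (beta1(y-x), x(beta2-z)-y, xy-beta3 z)."""
    if min(beta1, beta2, beta3) <= 0:
        raise ValueError("Lorenz parameters must be positive")

    def drift(s):
        s = np.atleast_2d(s)
        x, y, z = s[:, 0], s[:, 1], s[:, 2]
        return np.column_stack([beta1 * (y - x), x * (beta2 - z) - y, x * y - beta3 * z])

    div_const = -beta1 - 1.0 - beta3

    return DynamicalSystem(
        dim=3, drift=drift,
        drift_divergence=lambda s: np.full(len(np.atleast_2d(s)), div_const),
        name="lorenz", meta={"beta": (beta1, beta2, beta3)},
    )


# ---------------------------------------------------------------------------
# Gaussian mixture gradient system
# ---------------------------------------------------------------------------

def gmm_system(weights, means, covariances, D: float,
               name: str = "gmm") -> DynamicalSystem:
    """Gradient system whose steady density at noise strength D is exactly
    the given Gaussian mixture.

    U0(x) = -D ln p0(x) with p0 the normalized mixture; F = -grad(U0)
    = D grad(ln p0).  Covariances may be full matrices or scalars (isotropic).
    """
    w = np.asarray(weights, dtype=float)
    mu = np.atleast_2d(np.asarray(means, dtype=float))
    K, d = mu.shape
    if w.shape != (K,):
        raise ValueError("weights and means have mismatched component counts")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    covs = []
    for c in covariances:
        c = np.asarray(c, dtype=float)
        covs.append(c * np.eye(d) if c.ndim == 0 else c)
    if len(covs) != K or any(c.shape != (d, d) for c in covs):
        raise ValueError("covariances mismatch weights/means dimensions")
    prec = np.array([np.linalg.inv(c) for c in covs])          # (K,d,d)
    _, logdets = zip(*[np.linalg.slogdet(c) for c in covs])
    log_norm = -0.5 * (d * np.log(2 * np.pi) + np.array(logdets))
    chols = np.array([np.linalg.cholesky(c) for c in covs])
    # isotropic fast path (the common benchmark case)
    iso = all(np.allclose(c, c[0, 0] * np.eye(d)) for c in covs)
    inv_var = np.array([1.0 / c[0, 0] for c in covs]) if iso else None

    def _log_terms(x):
        x = np.atleast_2d(x)
        diff = x[:, None, :] - mu[None, :, :]                  # (N,K,d)
        if iso:
            quad = np.sum(diff * diff, axis=2) * inv_var
        else:
            quad = np.einsum("nki,kij,nkj->nk", diff, prec, diff,
                             optimize=True)
        return np.log(w) + log_norm - 0.5 * quad, diff

    def log_density(x):
        lt, _ = _log_terms(x)
        return logsumexp(lt, axis=1)

    def _resp_and_g(x):
        lt, diff = _log_terms(x)
        lse = logsumexp(lt, axis=1, keepdims=True)
        r = np.exp(lt - lse)                                   # (N,K)
        if iso:
            g_comp = -diff * inv_var[None, :, None]            # grad ln p_k
        else:
            g_comp = -np.einsum("kij,nkj->nki", prec, diff, optimize=True)
        return r, g_comp

    def drift(x):
        r, g_comp = _resp_and_g(x)
        return D * np.einsum("nk,nki->ni", r, g_comp)

    trace_prec = np.einsum("kii->k", prec)

    def divergence(x):
        # div F = D * lap(ln p0)
        r, g_comp = _resp_and_g(x)
        g = np.einsum("nk,nki->ni", r, g_comp)
        lap_k = -trace_prec[None, :] + np.einsum("nki,nki->nk", g_comp, g_comp)
        return D * (np.einsum("nk,nk->n", r, lap_k) - np.einsum("ni,ni->n", g, g))

    def sampler(n, D_req, rng):
        if not np.isclose(D_req, D):
            raise ValueError("mixture is the steady state only at the construction D")
        comp = rng.choice(K, size=n, p=w)
        z = rng.standard_normal((n, d))
        return mu[comp] + np.einsum("nij,nj->ni", chols[comp], z)

    return DynamicalSystem(
        dim=d, drift=drift, drift_divergence=divergence,
        analytic_potential=lambda x: -D * log_density(x),
        analytic_sampler=sampler, name=name,
        meta={"weights": w, "means": mu, "covariances": covs, "D": D,
              "log_density": log_density, "prec": prec, "log_norm": log_norm},
    )


# the bundled 12-dimensional two-component benchmark mixture
_MU1 = np.array([1.2, 2.0, 0.6, 1.5, 0.9, 1.5, 1.5, 0.9, 1.2, 1.2, 0.5, 1.8])
_MU2 = np.array([1.8, 1.4, 0.8, 0.9, 0.9, 1.5, 2.0, 1.0, 1.6, 1.0, 0.7, 1.4])


def twelve_dim_gmm(D: float = 0.1) -> DynamicalSystem:
    """12D bistable benchmark: two-component isotropic Gaussian mixture with
    weights (0.6, 0.4) and covariances (0.04 I, 0.02 I)."""
    return gmm_system([0.6, 0.4], [_MU1, _MU2], [0.04, 0.02], D=D, name="gmm12")


# ---------------------------------------------------------------------------
# Hill-kinetics gene regulatory network family
# ---------------------------------------------------------------------------

def gene_network_system(activators: Sequence[Sequence[int]],
                        repressors: Sequence[Sequence[int]],
                        a: float = 0.37, b: float = 0.5, k: float = 1.0,
                        S: float = 0.5, n: float = 3.0,
                        domain_high: float = 3.0,
                        name: str = "gene_network") -> DynamicalSystem:
    """Gene regulatory network with Hill activation/repression kinetics:

        F_i(x) = -k x_i + sum_{j in A_i} a x_j^n/(S^n + x_j^n)
                        + sum_{j in R_i} b S^n/(S^n + x_j^n).

    ``activators[i]`` / ``repressors[i]`` list the regulator indices of node i.
    Default domain is the hyperrectangle [0, domain_high]^d with reflection.
    """
    if min(a, b, k, S) <= 0 or n < 1:
        raise ValueError("require a, b, k, S > 0 and n >= 1")
    d = len(activators)
    if len(repressors) != d:
        raise ValueError("activators and repressors must have equal length")
    A = np.zeros((d, d))
    R = np.zeros((d, d))
    for i, js in enumerate(activators):
        for j in js:
            if not (0 <= j < d):
                raise ValueError(f"activator index {j} out of range for node {i}")
            A[i, j] = 1.0
    for i, js in enumerate(repressors):
        for j in js:
            if not (0 <= j < d):
                raise ValueError(f"repressor index {j} out of range for node {i}")
            R[i, j] = 1.0
    Sn = S ** n
    integer_n = float(n).is_integer()

    def _check(x):
        if not integer_n and np.any(x < 0):
            raise ValueError("negative state with non-integer Hill exponent")

    def drift(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        _check(x)
        xn = x ** n
        act = a * xn / (Sn + xn)
        rep = b * Sn / (Sn + xn)
        return -k * x + act @ A.T + rep @ R.T

    diagA, diagR = np.diag(A), np.diag(R)

    def divergence(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        _check(x)
        xn = x ** n
        dxn = n * x ** (n - 1)
        dact = a * Sn * dxn / (Sn + xn) ** 2
        drep = -b * Sn * dxn / (Sn + xn) ** 2
        return -k * d + dact @ diagA + drep @ diagR

    return DynamicalSystem(
        dim=d, drift=drift, drift_divergence=divergence,
        domain=np.column_stack([np.zeros(d), np.full(d, domain_high)]),
        name=name, meta={"a": a, "b": b, "k": k, "S": S, "n": n},
    )


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

def system_from_config(cfg) -> DynamicalSystem:
    """Build a system from a dict or a YAML/JSON file path.

    Recognized ``kind`` values: rotational_toy, lorenz, gmm, gene_network,
    expression (a list of sympy drift expressions in x1..xd, differentiated
    symbolically for the divergence).
    """
    if isinstance(cfg, (str, Path)):
        text = Path(cfg).read_text()
        if str(cfg).endswith((".yaml", ".yml")):
            import yaml
            cfg = yaml.safe_load(text)
        else:
            cfg = json.loads(text)
    cfg = dict(cfg)
    kind = cfg.pop("kind")
    if kind == "rotational_toy":
        return make_rotational_toy(**cfg)
    if kind == "lorenz":
        return lorenz_system(**cfg)
    if kind == "gmm":
        return gmm_system(**cfg)
    if kind == "gmm12":
        return twelve_dim_gmm(**cfg)
    if kind == "gene_network":
        return gene_network_system(**cfg)
    if kind == "expression":
        return _expression_system(**cfg)
    raise ValueError(f"unknown system kind {kind!r}")


def _expression_system(drift: Sequence[str], domain=None,
                       name: str = "custom") -> DynamicalSystem:
    import sympy as sp

    d = len(drift)
    syms = sp.symbols(f"x1:{d + 1}")
    exprs = [sp.sympify(e) for e in drift]
    div_expr = sum(sp.diff(exprs[i], syms[i]) for i in range(d))
    f_fns = [sp.lambdify(syms, e, "numpy") for e in exprs]
    div_fn = sp.lambdify(syms, div_expr, "numpy")

    def F(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        cols = [np.broadcast_to(f(*x.T), (len(x),)).astype(float) for f in f_fns]
        return np.column_stack(cols)

    def div(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.broadcast_to(div_fn(*x.T), (len(x),)).astype(float)

    return DynamicalSystem(dim=d, drift=F, drift_divergence=div,
                           domain=domain, name=name)
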