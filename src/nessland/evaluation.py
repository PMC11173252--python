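"""Ground-truth references and accuracy metrics for learned landscapes.

Provides a piecewise-bilinear finite-element solver of the steady
Fokker-Planck equation on 2D rectangles (with reflecting, i.e. zero normal
flux, boundary conditions), relative error metrics restricted to the
low-energy region {U0 <= 20 D}, barrier-height extraction along a transition
line, gradient / non-gradient force decomposition, the conditional-expectation
error map for Gaussian-mixture fixtures, and a quadrature oracle for the
steady entropy production rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator
from scipy.special import logsumexp

from .systems import DynamicalSystem

__all__ = [
    "ReferenceSolution", "solve_fpe_reference_2d", "rrmse", "rmae",
    "conditional_error_map", "barrier_heights_on_line", "force_decomposition",
    "epr_quadrature_oracle", "analytic_reference_2d",
]


@dataclass
class ReferenceSolution:
    """A gridded 2D reference potential with bilinear interpolation."""

    x: np.ndarray          # (nx,)
    y: np.ndarray          # (ny,)
    values: np.ndarray     # (nx, ny) potential U0 on the grid
    D: float
    source: str = "analytic"        # "analytic" | "fpe_fem"
    density: Optional[np.ndarray] = None  # p_ss on the grid, if available

    def __post_init__(self):
        self._interp = RegularGridInterpolator(
            (self.x, self.y), self.values, method="linear",
            bounds_error=False, fill_value=None)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return self._interp(np.atleast_2d(pts))

    @property
    def grid_points(self) -> np.ndarray:
        X, Y = np.meshgrid(self.x, self.y, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])


def analytic_reference_2d(system: DynamicalSystem, D: float,
                          domain, resolution: int = 201) -> ReferenceSolution:
    """Tabulate the system's analytic potential on a grid."""
    if system.analytic_potential is None:
        raise ValueError("system has no analytic potential")
    lo_hi = np.asarray(domain, dtype=float).reshape(2, 2)
    x = np.linspace(lo_hi[0, 0], lo_hi[0, 1], resolution)
    y = np.linspace(lo_hi[1, 0], lo_hi[1, 1], resolution)
    X, Y = np.meshgrid(x, y, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    U = system.analytic_potential(pts).reshape(resolution, resolution)
    return ReferenceSolution(x=x, y=y, values=U, D=D, source="analytic")


# ---------------------------------------------------------------------------
# bilinear FEM solver for the steady Fokker-Planck equation
# ---------------------------------------------------------------------------

# 2x2 Gauss points/weights on [-1, 1]
_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_GW = np.array([1.0, 1.0])


def solve_fpe_reference_2d(system: DynamicalSystem, D: float,
                           grid_resolution: int = 201,
                           domain=None, p_floor_rel: float = 1e-12,
                           ) -> ReferenceSolution:
    """Steady Fokker-Planck reference on a rectangle by piecewise-bilinear
    finite elements.

    Weak form with reflecting (zero normal flux) boundary: for all test
    functions phi,  int (p F . grad phi - D grad p . grad phi) dx = 0.
    The singular sparse system is closed with the normalization row
    int p = 1 and solved in the least-squares (normal-equation) sense.
    The potential is U0 = -D ln max(p, floor).
    """
    if system.dim != 2:
        raise ValueError("the FEM reference is 2D only")
    if domain is None:
        if system.domain is None:
            raise ValueError("specify a bounded domain for the FEM reference")
        domain = system.domain
    lo_hi = np.asarray(domain, dtype=float).reshape(2, 2)
    n = int(grid_resolution)
    xs = np.linspace(lo_hi[0, 0], lo_hi[0, 1], n)
    ys = np.linspace(lo_hi[1, 0], lo_hi[1, 1], n)
    hx = xs[1] - xs[0]
    hy = ys[1] - ys[0]

    # element corner node indices, vectorized over all (n-1)^2 elements
    ex, ey = np.meshgrid(np.arange(n - 1), np.arange(n - 1), indexing="ij")
    ex, ey = ex.ravel(), ey.ravel()
    n_el = len(ex)
    # local node order: (0,0), (1,0), (0,1), (1,1) in (x, y) offsets
    loc_dx = np.array([0, 1, 0, 1])
    loc_dy = np.array([0, 0, 1, 1])
    nodes = (ex[:, None] + loc_dx) * n + (ey[:, None] + loc_dy)   # (n_el, 4)

    rows, cols, vals = [], [], []
    for gx, wx in zip(_GP, _GW):
        for gy, wy in zip(_GP, _GW):
            # shape functions and derivatives at the Gauss point
            sx = np.array([(1 - gx) / 2, (1 + gx) / 2])
            sy = np.array([(1 - gy) / 2, (1 + gy) / 2])
            dsx = np.array([-0.5, 0.5]) * (2.0 / hx)
            dsy = np.array([-0.5, 0.5]) * (2.0 / hy)
            phi = (sx[loc_dx] * sy[loc_dy])                  # (4,)
            dphix = dsx[loc_dx] * sy[loc_dy]
            dphiy = sx[loc_dx] * dsy[loc_dy]
            # physical coordinates of the Gauss point per element
            px = xs[ex] + (gx + 1) / 2 * hx
            py = ys[ey] + (gy + 1) / 2 * hy
            F = system.drift(np.column_stack([px, py]))      # (n_el, 2)
            w = wx * wy * (hx * hy / 4.0)
            # local matrix: K[j, i] = w * (phi_i F . grad phi_j
            #                              - D grad phi_i . grad phi_j)
            conv = F[:, 0:1, None] * (dphix[None, :, None] * phi[None, None, :]) \
                 + F[:, 1:2, None] * (dphiy[None, :, None] * phi[None, None, :])
            diff = (np.outer(dphix, dphix) + np.outer(dphiy, dphiy))[None, :, :]
            K = w * (conv - D * diff)                        # (n_el, 4j, 4i)
            rows.append(np.repeat(nodes, 4, axis=1).ravel())         # j index
            cols.append(np.tile(nodes, (1, 4)).ravel())              # i index
            vals.append(K.ravel())

    N = n * n
    A = sp.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))), shape=(N, N)).tocsr()

    # normalization row: trapezoid weights (= bilinear lumped mass).  The
    # weak-form rows sum to zero (test functions form a partition of unity),
    # so one row is redundant and is replaced by the normalization condition.
    wq = np.ones(n)
    wq[0] = wq[-1] = 0.5
    mass = (hx * hy) * np.outer(wq, wq).ravel()
    scale = abs(A).sum() / A.nnz
    A = A.tolil()
    A[0] = mass * scale
    rhs = np.zeros(N)
    rhs[0] = 1.0 * scale
    p = spla.spsolve(A.tocsc(), rhs)

    total = float(mass @ p)
    if total <= 0:
        raise RuntimeError("FEM solution has nonpositive mass; refine the grid")
    p = p / total
    neg_mass = float(mass @ np.clip(p, None, 0.0))
    if neg_mass < -1e-3:
        raise RuntimeError(
            f"FEM density has negative mass {neg_mass:.2e}; grid too coarse")
    floor = p_floor_rel * p.max()
    U = -D * np.log(np.maximum(p, floor))
    return ReferenceSolution(x=xs, y=ys, values=U.reshape(n, n), D=D,
                             source="fpe_fem", density=p.reshape(n, n))


# ---------------------------------------------------------------------------
# error metrics on the low-energy region {U0 <= 20 D}
# ---------------------------------------------------------------------------

def _eval_candidate(model_or_grid, pts: np.ndarray) -> np.ndarray:
    if callable(model_or_grid):
        return np.asarray(model_or_grid(pts), dtype=float).reshape(len(pts))
    raise TypeError("candidate must be callable on (N, 2) points")

def _metric_arrays(model_or_grid, reference, D, threshold_mult=20.0,
                   eval_points=None):
    """Min-shifted (V, U0, weights) restricted to the comparison region."""
    if eval_points is not None:
        pts = np.atleast_2d(np.asarray(eval_points, dtype=float))
        U0 = np.asarray(reference(pts), dtype=float).reshape(len(pts))
        w = np.ones(len(pts))
    else:
        pts = reference.grid_points
        U0 = reference.values.ravel()
        wx = np.ones(len(reference.x)); wx[0] = wx[-1] = 0.5
        wy = np.ones(len(reference.y)); wy[0] = wy[-1] = 0.5
        w = np.outer(wx, wy).ravel()
    U0 = U0 - U0.min()
    mask = U0 <= threshold_mult * D
    U0m = U0[mask] - U0[mask].min()
    if not mask.any() or np.sum(w[mask] * U0m ** 2) == 0.0:
        raise ValueError("comparison region {U0 <= threshold * D} is empty "
                         "or degenerate; threshold too small")
    V = _eval_candidate(model_or_grid, pts)
    V = V - V[mask].min()
    return V[mask], U0m, w[mask]


def rrmse(model_or_grid, reference, D: float, threshold_mult: float = 20.0,
          eval_points=None) -> float:
    """Relative root-mean-square error of the min-shifted candidate versus the
    min-shifted reference over {U0 <= threshold_mult * D}.  ``eval_points``
    switches from grid quadrature to a Monte-Carlo sample average (the high-
    dimensional mode)."""
    V, U0, w = _metric_arrays(model_or_grid, reference, D, threshold_mult,
                              eval_points)
    return float(np.sqrt(np.sum(w * (V - U0) ** 2) / np.sum(w * U0 ** 2)))


def rmae(model_or_grid, reference, D: float, threshold_mult: float = 20.0,
         eval_points=None) -> float:
    """Relative mean absolute (L1) error; same conventions as :func:`rrmse`."""
    V, U0, w = _metric_arrays(model_or_grid, reference, D, threshold_mult,
                              eval_points)
    return float(np.sum(w * np.abs(V - U0)) / np.sum(w * np.abs(U0)))


# ---------------------------------------------------------------------------
# Gaussian-mixture conditional error map
# ---------------------------------------------------------------------------

def conditional_error_map(model, gmm_system: DynamicalSystem, z_grid,
                          n_cond_samples: int = 200, seed: int = 0,
                          density_floor: float = 1e-12):
    """Mean absolute error E[|U0 - V| | x1, x2] on a grid of the first two
    coordinates, averaging over the closed-form conditional mixture of the
    remaining coordinates.  Both potentials are globally aligned by their
    minimum over the drawn conditional samples.  Nodes where the 2D marginal
    density underflows are masked (NaN)."""
    meta = gmm_system.meta
    w, mu, covs = meta["weights"], meta["means"], meta["covariances"]
    K, d = mu.shape
    rng = np.random.default_rng(seed)
    z1, z2 = np.asarray(z_grid[0]), np.asarray(z_grid[1])
    out = np.full((len(z1), len(z2)), np.nan)

    # component blocks: z = first two coords, y = rest
    mu_z, mu_y = mu[:, :2], mu[:, 2:]
    cov_zz = np.array([c[:2, :2] for c in covs])
    cov_yy = np.array([c[2:, 2:] for c in covs])
    cov_yz = np.array([c[2:, :2] for c in covs])
    # conditional pieces (valid for general covariances)
    inv_zz = np.array([np.linalg.inv(c) for c in cov_zz])
    cond_cov = np.array([cov_yy[k] - cov_yz[k] @ inv_zz[k] @ cov_yz[k].T
                         for k in range(K)])
    cond_chol = np.array([np.linalg.cholesky(c) for c in cond_cov])
    _, ld = zip(*[np.linalg.slogdet(c) for c in cov_zz])
    log_norm_z = -0.5 * (2 * np.log(2 * np.pi) + np.array(ld))

    U0_all, V_all, node_index = [], [], []
    for i1, a in enumerate(z1):
        for i2, b in enumerate(z2):
            z = np.array([a, b])
            dz = z[None, :] - mu_z
            logpz = (np.log(w) + log_norm_z
                     - 0.5 * np.einsum("ki,kij,kj->k", dz, inv_zz, dz))
            tot = logsumexp(logpz)
            if np.exp(tot) < density_floor:
                continue
            r = np.exp(logpz - tot)
            comp = rng.choice(K, size=n_cond_samples, p=r)
            eps = rng.standard_normal((n_cond_samples, d - 2))
            mu_cond = mu_y[comp] + np.einsum(
                "nij,nj->ni", cov_yz[comp] @ inv_zz[comp], dz[comp])
            y = mu_cond + np.einsum("nij,nj->ni", cond_chol[comp], eps)
            x = np.column_stack([np.tile(z, (n_cond_samples, 1)), y])
            U0_all.append(gmm_system.analytic_potential(x))
            V_all.append(np.asarray(model(x), dtype=float).reshape(len(x)))
            node_index.append((i1, i2))

    if not U0_all:  # every node masked
        return out
    # global alignment: subtract each field's minimum over all drawn samples
    u_min = np.concatenate(U0_all).min()
    v_min = np.concatenate(V_all).min()
    for (i1, i2), U0v, Vv in zip(node_index, U0_all, V_all):
        out[i1, i2] = np.mean(np.abs((Vv - v_min) - (U0v - u_min)))
    return out


# ---------------------------------------------------------------------------
# barrier heights along a transition line
# ---------------------------------------------------------------------------

def _profile_barriers(vals: np.ndarray):
    """(BH1, BH2) from a 1D profile: interior maximum between the two
    outermost minima; None when the profile is monotone."""
    interior = vals[1:-1]
    if len(interior) == 0:
        return None
    # candidate saddle: the largest interior local maximum
    is_locmax = (interior >= vals[:-2]) & (interior >= vals[2:])
    idx = np.nonzero(is_locmax)[0] + 1
    best = None
    for i in idx:
        left_min = vals[:i].min()
        right_min = vals[i + 1:].min() if i + 1 < len(vals) else np.inf
        if vals[i] > left_min and vals[i] > right_min:
            h = min(vals[i] - left_min, vals[i] - right_min)
            if best is None or h > best[0]:
                best = (h, vals[i] - left_min, vals[i] - right_min)
    if best is None:
        return None
    return best[1], best[2]


def barrier_heights_on_line(model, reference, p1, p2, n_points: int = 1001):
    """Barrier heights of model and reference along the segment p1 -> p2.

    Returns a dict with BH1/BH2 for both potentials, or None entries when a
    profile is monotone (single well).  BH_i is saddle minus the basin-i
    minimum, basins taken on either side of the interior maximum.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    pts = p1[None, :] + t * (p2 - p1)[None, :]
    vm = np.asarray(model(pts), dtype=float).reshape(n_points)
    vr = np.asarray(reference(pts), dtype=float).reshape(n_points)
    bm = _profile_barriers(vm)
    br = _profile_barriers(vr)
    return {
        "model": {"BH1": None if bm is None else bm[0],
                  "BH2": None if bm is None else bm[1]},
        "reference": {"BH1": None if br is None else br[0],
                      "BH2": None if br is None else br[1]},
    }


# ---------------------------------------------------------------------------
# force decomposition and EPR quadrature
# ---------------------------------------------------------------------------

def force_decomposition(model, system: DynamicalSystem, grid_points: np.ndarray):
    """Split F into the learned gradient part -grad V and the remainder
    F + grad V on the given points; the parts sum to F exactly."""
    pts = np.atleast_2d(np.asarray(grid_points, dtype=float))
    g = model.gradient(pts)
    F = system.drift(pts)
    return -g, F + g


def epr_quadrature_oracle(system: DynamicalSystem, D: float,
                          quadrature_resolution: int = 201,
                          half_width: Optional[float] = None,
                          tail_tol: float = 1e-6) -> float:
    """Steady entropy production rate int |F + grad U0|^2 p_ss dx by
    tensor-grid trapezoid quadrature (1D/2D analytic fixtures only)."""
    if system.analytic_potential is None:
        raise ValueError("quadrature oracle needs an analytic potential")
    if system.dim > 2:
        raise ValueError("quadrature oracle is 1D/2D only")
    if system.domain is not None:
        lo, hi = system.domain[:, 0], system.domain[:, 1]
    else:
        hw = 6.0 * np.sqrt(D) + 2.0 if half_width is None else half_width
        lo, hi = -hw * np.ones(system.dim), hw * np.ones(system.dim)
    axes = [np.linspace(lo[k], hi[k], quadrature_resolution)
            for k in range(system.dim)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    U0 = system.analytic_potential(pts)
    p = np.exp(-(U0 - U0.min()) / D)
    # unnormalized; normalize on the grid
    h = 1e-6
    gU = np.zeros_like(pts)
    for k in range(system.dim):
        e = np.zeros(system.dim)
        e[k] = h
        gU[:, k] = (system.analytic_potential(pts + e)
                    - system.analytic_potential(pts - e)) / (2 * h)
    r = system.drift(pts) + gU
    integ = np.sum(r * r, axis=1) * p
    wts = [np.ones(quadrature_resolution) for _ in range(system.dim)]
    for w in wts:
        w[0] = w[-1] = 0.5
    W = wts[0] if system.dim == 1 else np.outer(wts[0], wts[1]).ravel()
    vol = np.prod([(a[1] - a[0]) for a in axes])
    Z = np.sum(W * p) * vol
    # tail check: boundary mass must be negligible
    if system.domain is None:
        edge = np.any(np.abs(pts - (lo + hi) / 2) >
                      0.98 * (hi - lo) / 2, axis=1)
        if np.sum(W[edge] * p[edge]) / np.sum(W * p) > tail_tol:
            raise ValueError("steady density has non-negligible tail mass; "
                             "enlarge the quadrature box")
    return float(np.sum(W * integ) * vol / Z)
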