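"""Euler-Maruyama ensemble simulation and sample-set handling.

Steady-state samples are the end states of N independent trajectories of

    dx = F(x) dt + sqrt(2 D) sigma(x) dw,

integrated with the Ito Euler-Maruyama scheme.  Hyperrectangle domains are
enforced by coordinate-wise reflection at the faces, the numerical counterpart
of the zero-normal-flux boundary condition.  Enhanced sample sets — broader
distributions used to evaluate the HJB residual in low-probability regions —
come either from re-simulation at a larger noise D' or from Gaussian
perturbation of existing samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .systems import DynamicalSystem

__all__ = [
    "SampleSet",
    "simulate_ensemble",
    "enhance_by_larger_noise",
    "enhance_by_perturbation",
    "enhance_by_bridging",
    "concat_sample_sets",
    "analytic_sample_set",
]

PROVENANCES = ("steady_ensemble", "long_trajectory", "larger_noise",
               "gaussian_perturbed", "bridge", "analytic")


@dataclass
class SampleSet:
    """An ensemble of states approximating the steady (or an enhanced) law."""

    states: np.ndarray                    # (N, dim)
    noise_strength: float
    provenance: str
    seed: Optional[int] = None
    burn_in_time: float = 0.0
    dt: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.states = np.atleast_2d(np.asarray(self.states, dtype=np.float64))
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if len(self.states) == 0:
            raise ValueError("sample set must be nonempty")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("sample set contains non-finite states")

    def __len__(self):
        return len(self.states)

    @property
    def dim(self) -> int:
        return self.states.shape[1]

    # persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Binary array container plus a JSON metadata sidecar."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.states)
        sidecar = {
            "noise_strength": self.noise_strength, "provenance": self.provenance,
            "seed": self.seed, "burn_in_time": self.burn_in_time, "dt": self.dt,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "SampleSet":
        path = Path(path)
        states = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(states=states, **meta)

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.states, columns=[f"x{i+1}" for i in range(self.dim)])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, noise_strength: float,
                 provenance: str = "steady_ensemble", **kw) -> "SampleSet":
        import pandas as pd
        return cls(states=pd.read_csv(path).to_numpy(dtype=float),
                   noise_strength=noise_strength, provenance=provenance, **kw)


def _reflect(x: np.ndarray, domain: Optional[np.ndarray]) -> np.ndarray:
    """Fold states back into the hyperrectangle by mirror reflection."""
    if domain is None:
        return x
    lo, hi = domain[:, 0], domain[:, 1]
    for _ in range(10):
        below, above = x < lo, x > hi
        if not (below.any() or above.any()):
            break
        x = np.where(below, 2 * lo - x, x)
        x = np.where(above, 2 * hi - x, x)
    return np.clip(x, lo, hi)


def simulate_ensemble(system: DynamicalSystem, D: float, n_traj: int,
                      t_final: float, dt: float, init=None,
                      seed: int = 0, provenance: str = "steady_ensemble",
                      max_resample_frac: float = 0.1) -> SampleSet:
    """End states of ``n_traj`` independent Euler-Maruyama trajectories.

    ``init`` is one of None (uniform on a bounded domain, standard Gaussian
    otherwise), an (n_traj, dim) array, a callable ``(n, rng) -> states``, or
    a dict ``{"center": ..., "scale": ...}`` for a Gaussian cloud.  Trajectories
    that blow up to non-finite states are reset to a fresh initial state and
    counted; more than ``max_resample_frac`` resets raises (dt too large).
    Deterministic for fixed arguments and seed.
    """
    if dt <= 0 or t_final < 0:
        raise ValueError("require dt > 0 and t_final >= 0")
    if D < 0:
        raise ValueError("noise strength D must be nonnegative")
    rng = np.random.default_rng(seed)

    def draw_init(n):
        if init is None:
            return system.sample_interior(n, rng)
        if callable(init):
            return np.atleast_2d(init(n, rng))
        if isinstance(init, dict):
            c = np.asarray(init.get("center", np.zeros(system.dim)), float)
            s = float(init.get("scale", 1.0))
            return c + s * rng.standard_normal((n, system.dim))
        arr = np.atleast_2d(np.asarray(init, dtype=float))
        if len(arr) != n:
            raise ValueError("init array length must equal n_traj")
        return arr.copy()

    x = _reflect(draw_init(n_traj), system.domain)
    n_steps = int(round(t_final / dt))
    sqdt = np.sqrt(2.0 * D * dt)
    resampled: set[int] = set()
    use_sigma = system.diffusion_matrix is not None

    for _ in range(n_steps):
        f = system.drift(x)
        if D > 0:
            if use_sigma:
                sig = system.diffusion_matrix(x)          # (N, d, m)
                xi = rng.standard_normal((len(x), sig.shape[2]))
                noise = sqdt * np.einsum("nim,nm->ni", sig, xi)
            else:
                noise = sqdt * rng.standard_normal(x.shape)
        else:
            noise = 0.0
        x = _reflect(x + f * dt + noise, system.domain)
        bad = ~np.all(np.isfinite(x), axis=1)
        if bad.any():
            idx = np.nonzero(bad)[0]
            resampled.update(idx.tolist())
            if len(resampled) > max_resample_frac * n_traj:
                raise RuntimeError(
                    f"{len(resampled)} of {n_traj} trajectories diverged; "
                    "the time step dt is too large for this system")
            x[idx] = _reflect(draw_init(len(idx)), system.domain)

    return SampleSet(states=x, noise_strength=D, provenance=provenance,
                     seed=seed, burn_in_time=t_final, dt=dt,
                     meta={"n_resampled": len(resampled)})


def enhance_by_larger_noise(system: DynamicalSystem, D_prime: float,
                            n_traj: int, t_final: float, dt: float,
                            init=None, seed: int = 0, D: Optional[float] = None,
                            ) -> SampleSet:
    """Broader ensemble from re-simulation at noise strength D' (> D)."""
    if D_prime <= 0:
        raise ValueError("D_prime must be positive")
    if D is not None and D_prime <= D:
        warnings.warn("D_prime <= D: enhanced set is no broader than the base set")
    return simulate_ensemble(system, D_prime, n_traj, t_final, dt,
                             init=init, seed=seed, provenance="larger_noise")


def enhance_by_perturbation(samples: SampleSet, sigma: float, seed: int = 0,
                            system: Optional[DynamicalSystem] = None) -> SampleSet:
    """Add isotropic Gaussian jitter of standard deviation ``sigma`` to each
    state; re-reflect into the domain when ``system`` is bounded."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    states = samples.states + sigma * rng.standard_normal(samples.states.shape)
    if system is not None:
        states = _reflect(states, system.domain)
    return SampleSet(states=states, noise_strength=samples.noise_strength,
                     provenance="gaussian_perturbed", seed=seed,
                     burn_in_time=samples.burn_in_time, dt=samples.dt,
                     meta={"sigma": sigma})


def enhance_by_bridging(samples: SampleSet, n_bridge: int, sigma: float = 0.0,
                        seed: int = 0,
                        system: Optional[DynamicalSystem] = None) -> SampleSet:
    """Transition-region enhancement: random convex combinations of sample
    pairs, optionally jittered by isotropic Gaussian noise of s.d. ``sigma``.

    In multistable systems steady samples concentrate in the wells and leave
    the transition (saddle) region empty — severely so in high dimension,
    where no feasible re-simulation at larger noise populates a specific
    saddle.  Segments between samples from different basins pass through
    that region, giving the HJB residual the support it needs there.
    """
    if n_bridge <= 0:
        raise ValueError("n_bridge must be positive")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, len(samples), size=n_bridge)
    j = rng.integers(0, len(samples), size=n_bridge)
    t = rng.uniform(size=(n_bridge, 1))
    states = (1 - t) * samples.states[i] + t * samples.states[j]
    if sigma > 0:
        states = states + sigma * rng.standard_normal(states.shape)
    if system is not None:
        states = _reflect(states, system.domain)
    return SampleSet(states=states, noise_strength=samples.noise_strength,
                     provenance="bridge", seed=seed,
                     burn_in_time=samples.burn_in_time, dt=samples.dt,
                     meta={"sigma": sigma})


def concat_sample_sets(*sets: SampleSet) -> SampleSet:
    """Pool several enhanced sample sets into one (mixture of their laws)."""
    if not sets:
        raise ValueError("need at least one sample set")
    return SampleSet(states=np.vstack([s.states for s in sets]),
                     noise_strength=sets[0].noise_strength,
                     provenance=sets[0].provenance, seed=sets[0].seed,
                     meta={"pooled": [s.provenance for s in sets]})


def analytic_sample_set(system: DynamicalSystem, D: float, n: int,
                        seed: int = 0) -> SampleSet:
    """Exact steady-state samples via the system's analytic sampler."""
    if system.analytic_sampler is None:
        raise ValueError(f"system {system.name!r} has no analytic sampler")
    rng = np.random.default_rng(seed)
    return SampleSet(states=system.analytic_sampler(n, D, rng),
                     noise_strength=D, provenance="analytic", seed=seed)
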