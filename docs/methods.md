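# Methods

## Model

`nessland` constructs the potential landscape of a non-equilibrium steady
state (NESS).  The dynamics is the overdamped Langevin SDE

    dx/dt = F(x) + sqrt(2 D) sigma(x) w'(t),      x in Omega ⊆ R^d,

with smooth drift `F`, noise strength `D > 0`, and (by default) identity
diffusion.  `Omega` is either all of `R^d` (vanishing density at infinity) or
a hyperrectangle with reflecting (zero normal flux) walls.  The landscape is
defined at finite noise as

    U(x) = -D ln p_ss(x),

where `p_ss` is the steady density.  `U` is characterized variationally:
under the steady-state-weighted inner product `(f, g)_pi = ∫ f g p_ss dx`,
`-grad U` is the orthogonal projection of `F` onto the space of gradient
fields.  Hence `U` is the unique minimizer (up to an additive constant) of
the force-projection loss

    L_EPR(V) = ∫ |F + grad V|^2 dpi,

which is strictly convex in `V` (up to constants), and its minimum value is
the steady entropy production rate  e_p^ss = ∫ |J_ss|^2 / p_ss dx  with
`J_ss = p_ss F - D grad p_ss`.  The package therefore returns both the
landscape and an entropy-production estimate from one optimization.

In practice the ensemble average is replaced by an empirical average over
the end states of N independent trajectories (Euler-Maruyama), and `V` is a
small tanh multilayer perceptron (default three hidden layers of 20 units).

### Small noise: the enhanced loss

Substituting `p_ss = exp(-U/D)` into the steady Fokker-Planck equation gives
the viscous Hamilton-Jacobi-Bellman (HJB) equation

    N_HJB(U) = -F . grad U + D lap U - |grad U|^2 + D div F = 0.

When `D` is small, steady samples concentrate in the wells and leave the
low-probability regions (barriers, outskirts) unconstrained.  The enhanced
loss adds the squared HJB residual evaluated on a *broader* sample set:

    L_enh = lambda1 * L_EPR + lambda2 * L_HJB,
    L_HJB = mean over enhanced samples of N_HJB(V)^2.

Enhanced sets supported:

* `larger_noise` — re-simulate at `D' > D`; covers the energy band up to
  roughly `U ~ 10 D'`.
* `perturbation` — add isotropic Gaussian jitter of s.d. `sigma` to steady
  samples.
* `bridge` — random convex combinations of steady-sample pairs plus small
  jitter.  In high dimension no feasible re-simulation or isotropic jitter
  places points near a specific saddle (sample mass concentrates on shells);
  segments between samples from different basins pass through the transition
  region and give the HJB residual support exactly where barrier heights are
  decided.  This is the package's targeted variant of "more samples in the
  transition region".

The HJB term is a physics-informed (non-convex) residual; the convex EPR
term anchors the solution on the data and empirically prevents the HJB term
from selecting spurious residual-zero branches inside the sampled region.
Outside the enhanced coverage the network extrapolates essentially linearly,
so error metrics should only be trusted on regions the enhanced set covers.

### State-dependent diffusion

For `a(x) = sigma sigma^T` uniformly positive definite, the landscape
minimizes the weighted-norm loss

    L_V-EPR(V) = ∫ (F^v + a grad V)^T a^{-1} (F^v + a grad V) dpi,
    F^v = F - D div a,   (div a)_i = sum_j d_j a_ij,

which reduces exactly (same code path, bit-identical) to `L_EPR` for
identity diffusion.  Training with this loss is supported; the HJB
enhancement is restricted to identity diffusion.

## Training

Minibatch Adam (default learning rate 1e-3, batch 2048) on the package's own
numpy reverse-mode autodiff core (`autodiff.py`).  Spatial first derivatives
of `V` enter the EPR term through exact vector-Jacobian products; the HJB
term tracks the full per-layer Jacobian and Laplacian forward (exact trace
of the Hessian, not a stochastic estimate), and parameter gradients of both
terms are exact.  Everything is double precision and seed-deterministic on
fixed hardware.  EPR and HJB minibatches are drawn independently from their
respective sample sets.  `lambda1 : lambda2` should balance the two terms'
magnitudes; 10 : 1 is the package default for the benchmark systems
(sensitivity to `lambda1` over a decade is mild — see the test suite), and
longer training mainly improves the barrier region, where only the HJB term
has data.

## Dimensionality reduction

For two prescribed coordinates `z = (x_i, x_j)` the reduced landscape is
`U~(z) = -D ln p~_ss(z)` with `p~_ss` the steady z-marginal.  Two routes:

1. **Projected training.**  `U~` minimizes the projected EPR loss
   `∫ |F_z + grad_z V~(z)|^2 dpi(y, z)` (`F_z` = z-components of the drift).
   For the projected HJB enhancement, the projected force
   `F~(z) = E_pi[F_z | z]` is first learned by least-squares regression
   (`fit_projected_force`; the population minimizer of the regression loss
   *is* the conditional expectation), then the projected HJB residual
   `-F~ . grad_z V~ + D lap_z V~ - |grad_z V~|^2 + D div_z F~` is penalized
   on enhanced z-points.
2. **Marginalization.**  A precomputed high-dimensional potential `V` is
   reduced by a weighted kernel density estimate of its Boltzmann z-marginal:
   weights `w_i ∝ exp(-V(x_i)/D) / p_hat(x_i)` when a sampling-density
   estimate `p_hat` is supplied, identity weights when the samples are taken
   as already Boltzmann-distributed (then the route is plain KDE of the
   marginal).  Three estimator refinements matter in practice: bandwidth by
   held-out likelihood (`"cv"`) rather than the Scott rule, which
   oversmooths multimodal marginals; the multiplicative
   (Jones-Linton-Nielsen) bias correction `p^2 / (K_h * p)`, which cancels
   the leading O(h^2) smoothing bias of `-D ln p_hat`; and mirror reflection
   of near-wall samples for reflecting domains.  Cells where the expected
   kernel-effective sample count falls below a floor (default 5) are
   masked, never extrapolated.

When `z` exhausts the coordinates, both projected losses coincide with the
full-space losses to machine precision (tested).

## Reference solutions and metrics

* 2D steady Fokker-Planck reference: piecewise-bilinear finite elements on a
  rectangular grid, weak form `∫ (p F - D grad p) . grad phi dx = 0` (the
  reflecting boundary is natural in this form), 2x2 Gauss quadrature.  The
  weak-form rows sum to zero over the test-function partition of unity, so
  one redundant row is replaced by the normalization `∫ p = 1` and the
  system is solved directly.  `U0 = -D ln max(p, floor)` with a relative
  density floor.  Verified against analytic steady states (relative RMS
  error < 1e-2 at 201^2; error falls at second order in the mesh width).
* Error metrics: relative RMSE and relative MAE of the min-shifted candidate
  against the min-shifted reference over the low-energy region
  `{U0 - min U0 <= 20 D}` — grid trapezoid quadrature in 2D, Monte-Carlo
  over supplied evaluation samples in high dimension.  Min-shift alignment
  is computed over the compared region.
* Barrier heights: along the segment through two basin centers, the saddle
  is the interior local maximum separating the two basin minima; `BH_i` =
  saddle minus basin-i minimum; monotone profiles report "undefined".
* Entropy-production oracle: `∫ |F + grad U0|^2 p_ss dx` by tensor-grid
  quadrature for 1D/2D analytic fixtures (e.g. `2 c^2 D` for the rotational
  toy below).
* Conditional error maps for Gaussian-mixture fixtures: at each (x1, x2)
  node, the mean of `|U0 - V|` over exact draws from the closed-form
  conditional mixture of the remaining coordinates, after global min-shift
  alignment of both fields.

## Fixtures and the synthetic-data generator

All benchmark inputs are generated by the package itself:

* **Rotational toy** (`make_rotational_toy`): `F = -grad U0 + c J grad U0`
  with `J` the 90° rotation.  Because the solenoidal part is tangent to the
  level sets of `U0`, the steady density is exactly `exp(-U0/D)/Z` for every
  `c` and `D`, while `e_p^ss = 2 c^2 D` for the quadratic `U0` — an exactly
  solvable NESS used throughout the tests.
* **Lorenz system** (beta1 = 10, beta2 = 28, beta3 = 8/3), constant drift
  divergence -41/3.
* **12D two-component Gaussian mixture** (`twelve_dim_gmm`): weights
  (0.6, 0.4), covariances (0.04 I, 0.02 I), fixed printed means; the drift
  is `-grad U0`, so the mixture is the exact steady law.  Study conditions
  chosen once for the benchmark: D = 0.1 (not fixed by the construction —
  the mixture is steady at the construction D for any choice; 0.1 makes the
  landscape scale O(1)); N = N' = 10000 end states, t_final = 100, dt = 0.01
  from an overdispersed Gaussian cloud over both basins.  Inter-well
  occupancy does not equilibrate to the 0.6/0.4 weights on this horizon
  (barrier crossing times are ~e^{9} steps); this is harmless for the EPR
  term — the zero-residual minimizer V = U0 is independent of the sampling
  weights — while the inter-well offset is fixed by the HJB term, whose
  enhanced set (larger-noise D' = 2D pooled with 500 bridge points, jitter
  0.02) covers the barrier energy band.  A caution specific to high
  dimension: a much larger D' concentrates the enhanced cloud on a
  high-energy shell that misses the saddle entirely, and a large fraction
  of bridge points concentrates on the mixture's soft-min crease (width
  ~ sigma^2 / well separation), whose curvature a small smooth network
  cannot match early in training — both choices degrade convergence.
* **Hill-kinetics gene networks** (`gene_network_system`): activation /
  repression Hill terms with a = 0.37, b = 0.5, k = 1, S = 0.5, n = 3 on
  `[0, 3]^d`; the regulation topology is always supplied via config.  The
  52-node topology used in the tests is a synthetic two-module stand-in
  (two mutually repressing hub genes, each sustained by its module) that
  reproduces the double-well structure over the two hub genes.

What the generator does **not** emulate: measurement noise, non-Gaussian or
correlated driving noise, unresolved fast variables, and model mismatch
between the drift used for training and the drift that produced the data —
with real data F is estimated, here it is exact.  Passing tests therefore
demonstrate correctness of the estimator under its own assumptions, not
robustness to misspecification.

## Numerical choices

* Integrator: Euler-Maruyama with coordinate-wise mirror reflection at
  hyperrectangle faces; trajectories reaching non-finite states are reset to
  fresh initial conditions and counted; more than 10% resets aborts (dt too
  large).  Per-fixture steps: toy/OU dt = 1e-3, 12D mixture dt = 0.01, gene
  networks dt = 0.005-0.01.
* Divergence of the drift: analytic for every built-in system (symbolic for
  config-defined expression drifts); a central-difference helper is provided
  for plug-in drifts.
* Training problem sizes used by the test suite and acceptance script are
  scaled so that each end-to-end experiment completes in minutes on one CPU
  core: the 12D benchmark uses N = 10000, 600 epochs, batch 512 with cosine
  learning-rate annealing (small batches give more optimizer steps per epoch
  at equal per-sample cost, and annealing suppresses the end-of-training
  oscillation of constant-rate Adam); the `TrainingConfig` defaults
  (3000 epochs, batch 2048) correspond to the fully converged reference
  setting.
* Probability floors before logarithms; masked cells excluded from metrics;
  degenerate (single-point or zero-denominator) comparison regions raise.
* Tie-break in barrier extraction: the interior local maximum with the
  largest minimum drop to either side.

## Known limitations

* Sharp landscape features — e.g. the soft-min crease of a Gaussian mixture
  with small covariances, on which its saddle point lies — are resolved by
  the default 3x20 tanh network only after very long training.  At the
  desk-scale training lengths used here the global error metrics converge
  well before the barrier height does, so barrier heights carry a
  substantially larger relative error than the rRMSE suggests.

* Accuracy outside the region covered by the (enhanced) samples is
  uncontrolled — the network extrapolates smoothly but arbitrarily; the
  20 D metric region convention makes this visible rather than hiding it.
* The HJB term is non-convex; with poor coverage it can settle on spurious
  residual-zero branches (documented in the test suite via the small-noise
  fixtures).  The convex EPR term mitigates but does not eliminate this.
* The FEM reference is 2D only; 3D systems are validated against analytic
  fixtures and moment checks instead.
* `estimate_epr` inherits the Monte-Carlo error of the sample set and the
  optimization gap of training; it is validated against the quadrature
  oracle on the rotational toy at three standard errors.
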