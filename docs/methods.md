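# Methods

## Model class

`cmemor` works with stochastic reaction networks described by the chemical
master equation (CME).  A network has species `X_1 … X_n` and irreversible
reactions `sum_i sigma_ij X_i -> sum_i phi_ij X_i`, `j = 1…m`, with net
change vectors `v_j = phi_.j - sigma_.j` (two reactions never share a net
change vector).  The state is the vector of copy numbers `x in N_0^n`; the
CME propagates the probabilities `p(t, x)`:

    d/dt p(t,x) = sum_j [ nu_j(x - v_j, theta) p(t, x - v_j) - nu_j(x, theta) p(t, x) ].

Propensities `nu_j` are mass-action monomials `theta_j * prod_i x_i^sigma_ij`
(plain powers — a modelling convention, not falling factorials) or general
expressions such as Hill terms.

## Finite state projection (FSP)

The CME is truncated to a rectangular lattice `Omega = {x^(i)}, i = 1…d`
with per-species bounds, giving the linear ODE `dP/dt = A(theta) P`,
`P(0) = P0`.  States are ordered lexicographically with the first species
varying fastest, copy numbers starting at the lower bound; the index map is
a strides-based bijection.

`A` is assembled per propensity term: the diagonal entry of state `i` is
minus the term's propensity at `x^(i)` — counted even when the reaction
target `x^(i) + v_j` leaves the rectangle, so probability leaks at the
boundary (sink-type truncation; a reflecting variant is deliberately not
offered).  The inflow entry `(i, j)` is the propensity at `x^(j)` exactly
when `x^(i) = x^(j) + v_j` with both states inside.  Consequently all
off-diagonals are nonnegative, all diagonals nonpositive, and every column
sums to at most zero — exactly zero for states whose reaction targets all
stay inside.  Total probability mass is therefore non-increasing; the gap
to 1 measures the truncation leak.

Outputs are linear, `y(t) = C P(t)`: expectation rows (`C_j = x_i^(j)`)
and region-probability rows (0/1 indicators, e.g. `Prob(x2 > 100)`).

## Parameter-separable decomposition

For parametric work the operator is kept in separated form
`A(theta) = sum_q vartheta_q(theta) A_q` with parameter-free sparse
components `A_q` (compressed column storage, vectorized assembly) and
scalar coefficient functions.  The decomposition is per *term*, not per
reaction: one reaction's propensity may split into several terms (the
oscillator's production of X2 contributes `k4*s` and the autocatalytic Hill
term separately), and a coefficient may be a parameter product (the
switch's production of X1 carries `u1*k1` and `u1*V1`).  Parameters inside
denominators (Hill constants `M1`, `M2`, the oscillator's `s`, `k2`, `k6`)
cannot be separated; they are baked into the components at their nominal
values and are not tunable online — consistent with which parameters the
studies actually vary.

Coefficient and state factors are plain expression strings compiled once
with sympy; every identifier is treated as a symbol (never a sympy
built-in), which keeps model files declarative and makes reduced models
serializable without code.

## Full-order time integration

`solve_full` integrates `dP/dt = A P` with an adaptive BDF multistep method
(scipy's implementation) using the sparse operator itself as the analytic
Jacobian.  A subclass swaps the SuperLU column ordering to `MMD_AT_PLUS_A`,
which roughly halves the factorization cost on these lattice-banded
generators.  Defaults: `rtol = 1e-8`, `atol = 1e-12`, both configurable.
Two further modes exist:

* `method="expm"` — action of the matrix exponential; exact up to
  round-off but impractical when `||A|| * T` is very large (the switch
  horizon is `T = 1e7` min).
* `method="euler"` — fixed-step backward Euler marching exactly through
  the output grid, one sparse LU per distinct increment.  First-order
  accurate only, but L-stable and extremely fast on a coarse grid (the
  entire 81-trajectory switch training set solves in about half a minute).
  This is the discrete-evolution convention of the offline studies (next
  section).

Tiny negative entries from floating point are kept in the stored state and
clipped only in reported outputs.

## Snapshot grids and quadrature

Time integrals (POD correlation, projection errors, least-squares costs)
use trapezoidal weights on the trajectory's output grid; the weights sum to
`T`.  Two grid families are provided:

* `TimeGrid.uniform(T, K)` — K equally spaced points including 0 and T
  (default `K = 100`).
* `TimeGrid.logarithmic(T, K, t_min)` — 0 followed by K−1 log-spaced points.

The choice matters and is a genuine free parameter of the offline phase,
because the switch model relaxes from its initial distribution on the time
scale of minutes (`1/u ≈ 100` min) while the horizon is `1e7` min.  Three
coherent conventions are supported, and basis sizes are only comparable
within one convention:

1. **Accurate solves on a uniform grid** (BDF + `TimeGrid.uniform`): the
   100-point grid never samples the initial relaxation, so the snapshots
   span only the slow transition manifold (the full 81-parameter training
   set collapses into ~19 dimensions at machine precision).  The
   Galerkin-reduced dynamics must still integrate *through* the unsampled
   fast transient, and the resulting error does not decay: the reduced
   output can be off by the full signal scale even though the snapshot
   projection error is at machine zero.  Suitable for studying the greedy
   loop, **not** for building usable reduced models.
2. **Accurate solves on a logarithmic grid** (BDF + `TimeGrid.logarithmic`
   with `t_min` of order of the fastest relaxation time): every decade is
   resolved, the basis absorbs the transient (at the price of many extra
   modes — order 100 for the switch at tight tolerances), and reduced
   outputs are accurate to ~1e-3 on a signal of order 70.  The convention
   of choice when the reduced model must reproduce the *continuous-time*
   solution.
3. **Discrete evolution** (backward Euler on the uniform output grid for
   *both* the full training trajectories and the reduced solves): the
   L-stable first step lands directly on the slow manifold, the snapshot
   set contains a handful of algebraically decaying discrete-transient
   modes on top of the slow manifold, and — because full and reduced
   models share the stepping scheme — the reduced recursion is consistent
   with the full one whenever the snapshots are in span.  Reduction error
   is then the only discrepancy (a few 1e-4 on the switch output), while
   the offline phase costs seconds per trajectory.  This is the convention
   of the shipped full-scale studies: it yields 32 basis vectors for the
   switch (81 training parameters) and 107 for the oscillator (30 training
   parameters) at `eps_tol = 1e-12`.  Its trade-off is first-order time
   accuracy with respect to the continuous CME solution, which cancels in
   analyses where measurement and model share the scheme and is
   acceptable wherever ~percent-level time-discretization bias is.

## POD and POD-Greedy

`pod_first_mode` computes the dominant mode of the time-weighted snapshot
correlation `C = sum_k w_k P_k P_k^T` by the method of snapshots: the
`K x K` Gram matrix of `diag(sqrt(w)) S` is diagonalized and the top
eigenvector lifted back — the `d x d` correlation matrix is never formed
(their equivalence is a tested property).  The sign is fixed by making the
largest-magnitude entry positive.

`pod_greedy` grows an orthonormal basis `V` from `V_init` (the initial
distribution, normalized — normalization is required for orthonormality):

1. find the training parameter maximizing the projection error
   `Delta(theta, V) = int ||P(t) - V V^T P(t)||^2 dt` (ties: smallest
   training index under the documented lexicographic training order);
2. orthogonalize that trajectory against `V`, take the weighted POD mode of
   the residual;
3. re-orthonormalize it against `V` (Gram–Schmidt, applied twice); a
   residual norm below `1e-10` terminates with a `stagnated` status;
4. append and repeat until `max Delta <= eps_tol` or a hard size cap
   (default 200) is reached.

Each training parameter is simulated exactly once; trajectories can be
cached on disk keyed by (model, theta, grid).  Per-snapshot residual norms
are maintained incrementally — appending an orthonormal `v` lowers
`||P_k - V V^T P_k||^2` by exactly `(v^T P_k)^2` — and the current argmax
candidates are recomputed exactly each iteration, so the termination
decision near `eps_tol` never rests on accumulated down-dates.  The error
sequence `eps_N` is non-increasing by construction; on the switch training
runs its logarithm decays essentially linearly in `N` (exponential decay),
and the selected parameters concentrate on the boundary of the parameter
domain.

## Reduced models

With `W := V` (biorthogonal by construction), each component is projected
once offline: `A_r_q = V^T A_q V` (dense `r x r`), `C_r = C V`,
`P_r0 = V^T P0`.  Online, `A_r(theta) = sum_q vartheta_q(theta) A_r_q` is
assembled and the reduced linear system is propagated *exactly* (to
round-off) with matrix exponentials of the grid increments — for a constant
`r x r` generator this is both faster and tighter than adaptive
integration; equal increments share one exponential.  Approximate full
states are reconstructed as `P_hat = V P_r` on demand; no `d`-dimensional
object is touched online except for that optional reconstruction.

## Parametric analyses

* **Measurements** — `y_meas(t_k) = y(t_k)(1 + level * n_k)` with i.i.d.
  standard normal `n_k` from a recorded seed; the study level is 5%.  The
  estimation study samples the output on a 500-point uniform grid — denser
  than the default simulation grid, since population-average measurements
  are cheap to sample and a denser series averages the multiplicative
  noise down (the estimator's standard error scales like `K^(-1/2)`).
* **Cost** — `J(theta) = int (y_meas - y_hat(theta))^2 dt`, trapezoidal on
  the measurement grid (which must coincide with the simulation grid).
* **Estimation** — the cost along a parameter line is multimodal: a narrow
  valley through the data-generating parameter flanked by broad side
  basins.  A local solver started blindly (e.g. at the box midpoint)
  regularly converges into the wrong basin, so `estimate` first scans a
  coarse per-axis grid (9 points, log-spaced for positive boxes), then
  refines the best node with L-BFGS-B on box-normalized variables and a
  start-normalized objective.  Non-convergence is a reported status, not an
  exception; the estimate always lies in the search box.
* **Landscapes** — `J` tabulated over a tensor grid (all nodes
  domain-checked up front), returned as a tidy table.
* **Sweeps** — one output (typically a region probability) evaluated at
  `t_eval` while a single parameter sweeps a value list.  Values outside
  the trained parameter range are evaluated with a logged warning:
  extrapolation of the reduced model is explicitly permitted, and validated
  against full-order recomputation in the tests.

## Packaged study models

* **Follicle switch** (rates per minute): Hill-activated mutual activation,
  truncation `{0..150}^2` (d = 22801), `T = 1e7`, initial mass uniform on
  the triangle `x1 + x2 <= 20` (231 states; a `<= 19` variant with exactly
  210 states is available), varied `(u1, u2) in [0.005, 0.02]^2`, output
  `E[x1]`.  Nominal values: `k1 = 4`, `V1 = V2 = 75`, `M1 = M2 = 25`,
  `u1 = u2 = 0.01`.
* **Genetic oscillator** (rates per second): negative feedback with
  positive autoregulation, system-size parameter `s` mapping dimensionless
  concentrations to copy numbers.  Truncation `{0..30s}^2` (d = 90601 at
  the nominal `s = 10`), `T = 6`, uniform initial mass on `{0..5s}^2`,
  varied `k4 in [10, 100]`, output `Prob(x2 > 10s)` — the
  oscillation-amplitude proxy.  Nominal values: `k1 = 15`, `k2 = 0.2`,
  `k3 = 1`, `k4 = 10`, `k5 = 100`, `k6 = 6.5`, `k7 = 100`.  Passing a
  smaller `s` yields a consistently scaled-down variant (smaller lattice,
  more intrinsic noise) used for fast validation studies.
* **Birth–death** oracle: constant birth `k`, linear death `gamma * x`,
  closed-form Poisson solution `lambda(t) = (k/gamma)(1 - e^(-gamma t))`
  attached for integrator validation.

## Problem sizes used in the shipped tests

The suite mixes scale levels so that every code path runs in minutes:

* greedy-behaviour study: switch on `{0..80}^2`, T = 1e6 min, 3x3 training
  grid, `eps_tol = 1e-8`, accurate BDF trajectories on a logarithmic grid
  (convention 2 above);
* full-scale offline phases: the complete 81-parameter switch run and
  30-parameter oscillator run under the discrete-evolution convention
  (convention 3), asserting the 32/107-vector basis sizes;
* estimation study: full `{0..150}^2` switch lattice (the truncation bound
  cannot be lowered much — at a bound of 100 the long-horizon boundary
  leak visibly drains the on-state and the output signal collapses) with a
  3x3 training grid and the 500-point measurement grid;
* oscillator sweep: the full-scale reduced model, 200 sweep points on
  `k4 in [12, 40]`, with full-order validation at two untrained values.

`scripts/acceptance.py` reruns the full-scale phases end to end;
`scripts/train_full.py` exposes them individually, including the
adaptive-integrator variant whose oscillator run takes hours.

## Known limitations

* No a-posteriori error estimators for the reduced outputs: validation is
  by full-order recomputation at selected parameters.
* No FSP truncation-error bound and no adaptive/moving truncation; bounds
  are user-chosen and the mass leak is the diagnostic.
* Non-separable parameters (in denominators) are frozen at nominal values;
  no empirical interpolation is provided.
* The greedy adds one POD mode per iteration; multi-mode extensions and
  training-set adaptation are out of scope.
* Stochastic simulation (Gillespie/SSA) is out of scope; the CME is always
  solved as a linear ODE.
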