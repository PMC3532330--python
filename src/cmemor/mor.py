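"""Parametric model order reduction: POD-Greedy bases and reduced models.

Offline, an orthonormal basis ``V`` (d x r, r << d) is grown by the
POD-Greedy algorithm: repeatedly pick the training parameter whose full
trajectory is worst approximated by the current subspace (projection error
``Delta(theta, V) = int ||P(t) - V V^T P(t)||^2 dt``), orthogonalize that
trajectory against ``V``, and append the dominant POD mode of the residual.
With ``W := V`` the Petrov-Galerkin pair is biorthogonal by construction.

Each separable component is then projected once, ``A_r_q = V^T A_q V``
(r x r, dense), so that online assembly and simulation for any new theta
touch only r-dimensional objects.

POD is computed by the method of snapshots: the K x K Gram matrix of
time-weighted snapshots, never the d x d correlation matrix; the two
eigenproblems are equivalent and the equivalence is a tested property.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.linalg

from .network import DomainError, InitialDistribution, OutputMap, ParametricOperator
from .simulate import FullTrajectory, TimeGrid, solve_full

logger = logging.getLogger("cmemor")

__all__ = [
    "ReducedBasis",
    "ReducedModel",
    "ReducedTrajectory",
    "GreedyReport",
    "TrajectoryCache",
    "pod_first_mode",
    "projection_error",
    "pod_greedy",
    "reduce",
    "solve_reduced",
    "reconstruct",
]

_ORTHO_TOL = 1e-8
_STAGNATION_NORM = 1e-10


# ---------------------------------------------------------------------------
# POD and projection errors


def pod_first_mode(states: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Dominant mode of the time-weighted snapshot correlation.

    Solves the eigenproblem of ``C = sum_k w_k P_k P_k^T`` through the small
    Gram matrix ``G = B B^T`` with ``B = diag(sqrt(w)) S``; returns the unit
    eigenvector for the largest eigenvalue, sign fixed so its
    largest-magnitude entry is positive.
    """
    S = np.atleast_2d(np.asarray(states, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.shape != (S.shape[0],):
        raise ValueError("one quadrature weight per snapshot required")
    if (w < 0).any():
        raise ValueError("negative quadrature weight")
    B = np.sqrt(w)[:, None] * S
    G = B @ B.T
    lam, vecs = scipy.linalg.eigh(G)
    if lam[-1] <= 0 or not np.isfinite(lam[-1]):
        raise ValueError("all-zero (or invalid) trajectory has no POD mode")
    v = B.T @ vecs[:, -1]
    v /= np.linalg.norm(v)
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v


def _check_orthonormal(V: np.ndarray) -> None:
    r = V.shape[1]
    defect = np.abs(V.T @ V - np.eye(r)).max() if r else 0.0
    if defect > _ORTHO_TOL:
        raise ValueError(f"basis is not orthonormal (defect {defect:.2e})")


def projection_error(
    states: np.ndarray, V: np.ndarray, weights: np.ndarray
) -> float:
    """Quadrature approximation of ``int ||P(t) - V V^T P(t)||^2 dt``."""
    S = np.atleast_2d(np.asarray(states, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    w = np.asarray(weights, dtype=float)
    _check_orthonormal(V)
    R = S - (S @ V) @ V.T
    return float(w @ (R * R).sum(axis=1))


# ---------------------------------------------------------------------------
# trajectory cache


class TrajectoryCache:
    """Compute-once store of full trajectories keyed by (model, theta, grid).

    With a ``directory`` the snapshots are persisted as ``.npz`` files so a
    restarted offline phase never re-simulates a training parameter.
    """

    def __init__(self, model_key: str = "", directory=None):
        self.model_key = model_key
        self.directory = Path(directory) if directory else None
        if self.directory:
            self.directory.mkdir(parents=True, exist_ok=True)
        self._memory: dict[str, FullTrajectory] = {}

    def _key(self, theta: Mapping[str, float], grid: TimeGrid) -> str:
        h = hashlib.sha256()
        h.update(self.model_key.encode())
        for name in sorted(theta):
            h.update(f"{name}={theta[name]!r};".encode())
        h.update(grid.times.tobytes())
        return h.hexdigest()[:24]

    def get_or_solve(
        self,
        theta: Mapping[str, float],
        grid: TimeGrid,
        solver: Callable[[Mapping[str, float], TimeGrid], FullTrajectory],
    ) -> FullTrajectory:
        key = self._key(theta, grid)
        if key in self._memory:
            return self._memory[key]
        if self.directory:
            path = self.directory / f"{key}.npz"
            if path.exists():
                data = np.load(path)
                traj = FullTrajectory(TimeGrid(data["times"]), data["states"], theta=dict(theta))
                self._memory[key] = traj
                return traj
        traj = solver(theta, grid)
        self._memory[key] = traj
        if self.directory:
            np.savez_compressed(
                self.directory / f"{key}.npz", times=grid.times, states=traj.states
            )
        return traj


# ---------------------------------------------------------------------------
# POD-Greedy


@dataclass
class GreedyReport:
    """Provenance of one POD-Greedy run."""

    eps_sequence: list[float]
    selected: list[dict]
    training_set: list[dict]
    eps_tol: float
    status: str  # converged | max_size | stagnated
    wall_time: float
    n_initial: int = 1


@dataclass
class ReducedBasis:
    """Orthonormal global basis V (d x r) with its greedy provenance."""

    V: np.ndarray
    report: GreedyReport | None = None

    def __post_init__(self):
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        _check_orthonormal(self.V)

    @property
    def r(self) -> int:
        return self.V.shape[1]


def _orthonormalize_against(v: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, float]:
    """Twice-repeated Gram-Schmidt of v against the columns of V."""
    for _ in range(2):
        v = v - V @ (V.T @ v)
    norm = float(np.linalg.norm(v))
    return (v / norm if norm > 0 else v), norm


def pod_greedy(
    trajectories: Sequence[FullTrajectory]
    | Callable[[Mapping[str, float], TimeGrid], FullTrajectory],
    training_set: Sequence[Mapping[str, float]],
    grid: TimeGrid | None = None,
    V_init: np.ndarray | None = None,
    eps_tol: float = 1e-12,
    max_size: int = 200,
    cache: TrajectoryCache | None = None,
) -> tuple[ReducedBasis, GreedyReport]:
    """Grow a reduced basis until ``max_theta Delta(theta, V) <= eps_tol``.

    ``trajectories`` is either a pre-computed sequence aligned with
    ``training_set`` or a solver callable ``(theta, grid) -> FullTrajectory``
    (each training parameter is then simulated exactly once, through
    ``cache`` when given).  ``V_init`` may be a single vector (it is
    normalized) or an orthonormal d x N0 matrix.

    Bookkeeping: the per-snapshot squared residual norms are maintained
    incrementally (appending an orthonormal vector v lowers
    ``||P_k - V V^T P_k||^2`` by exactly ``(v^T P_k)^2``); the selected
    parameter's residual is recomputed exactly each iteration so that the
    termination decision near ``eps_tol`` does not rest on accumulated
    down-dates.
    """
    training_set = [dict(t) for t in training_set]
    if not training_set:
        raise ValueError("empty training set")

    t_start = time.perf_counter()
    if callable(trajectories):
        if grid is None:
            raise ValueError("a time grid is required when a solver is passed")
        cache = cache or TrajectoryCache()
        trajs = [cache.get_or_solve(th, grid, trajectories) for th in training_set]
    else:
        trajs = list(trajectories)
        if len(trajs) != len(training_set):
            raise ValueError("one trajectory per training parameter required")
        grid = trajs[0].grid
    w = grid.weights
    snaps = [t.states for t in trajs]
    d = snaps[0].shape[1]

    if V_init is None:
        raise ValueError("V_init required (e.g. the normalized initial distribution)")
    V = np.atleast_2d(np.asarray(V_init, dtype=float))
    if V.shape == (1, d):  # a single row vector
        V = V.T
    if V.shape[0] != d:
        raise ValueError("V_init dimension does not match the trajectories")
    if V.shape[1] == 1:
        V = V / np.linalg.norm(V)
    _check_orthonormal(V)
    n_initial = V.shape[1]

    # exact per-snapshot residual norms at start
    residual_sq = []
    for S in snaps:
        R = S - (S @ V) @ V.T
        residual_sq.append((R * R).sum(axis=1))
    errors = np.array([w @ r2 for r2 in residual_sq])

    eps_sequence: list[float] = []
    selected: list[dict] = []
    status = "converged"

    while True:
        # refresh candidate errors exactly before trusting the argmax
        refreshed: set[int] = set()
        while True:
            i_star = int(np.argmax(errors))  # ties: smallest training index
            if i_star in refreshed:
                break
            S = snaps[i_star]
            R = S - (S @ V) @ V.T
            residual_sq[i_star] = (R * R).sum(axis=1)
            errors[i_star] = w @ residual_sq[i_star]
            refreshed.add(i_star)
        eps = float(errors.max())
        i_star = int(np.argmax(errors))
        eps_sequence.append(eps)
        if eps <= eps_tol:
            break
        if V.shape[1] >= max_size:
            status = "max_size"
            logger.warning("POD-Greedy stopped at the size cap %d (eps=%.3e)", max_size, eps)
            break
        theta_star = training_set[i_star]
        E = snaps[i_star] - (snaps[i_star] @ V) @ V.T  # error trajectory, orthogonal to span(V)
        v = pod_first_mode(E, w)
        v, norm = _orthonormalize_against(v, V)
        if norm < _STAGNATION_NORM:
            status = "stagnated"
            logger.warning(
                "POD-Greedy stagnated: appended mode has residual norm %.2e", norm
            )
            break
        V = np.column_stack([V, v])
        selected.append(dict(theta_star))
        # down-date all residuals by the new component
        for i, Si in enumerate(snaps):
            t = Si @ v
            residual_sq[i] = np.maximum(residual_sq[i] - t * t, 0.0)
            errors[i] = w @ residual_sq[i]
        logger.info(
            "POD-Greedy N=%d theta*=%s eps=%.6e", V.shape[1], theta_star, eps
        )

    report = GreedyReport(
        eps_sequence=eps_sequence,
        selected=selected,
        training_set=training_set,
        eps_tol=eps_tol,
        status=status,
        wall_time=time.perf_counter() - t_start,
        n_initial=n_initial,
    )
    return ReducedBasis(V, report), report


# ---------------------------------------------------------------------------
# reduced model


@dataclass
class ReducedComponent:
    matrix: np.ndarray  # r x r, dense
    coefficient: Callable[[Mapping[str, float]], float]
    label: str = ""
    expression: str = ""


@dataclass
class ReducedModel:
    """Projected parametric model; online cost independent of d."""

    components: list[ReducedComponent]
    output_matrix: np.ndarray  # p x r
    output_labels: list[str]
    initial: np.ndarray  # r
    basis: ReducedBasis | None = None
    nominal: dict = field(default_factory=dict)
    domain: dict = field(default_factory=dict)
    trained_range: dict = field(default_factory=dict)

    @property
    def r(self) -> int:
        return self.initial.size

    @property
    def n_components(self) -> int:
        return len(self.components)

    def check_domain(self, theta: Mapping[str, float]) -> None:
        for name, (lo, hi) in self.domain.items():
            value = theta.get(name, self.nominal.get(name))
            if value is None or not lo <= value <= hi:
                raise DomainError(
                    f"parameter {name}={value} outside admissible range [{lo}, {hi}]"
                )

    def warn_extrapolation(self, theta: Mapping[str, float]) -> None:
        for name, (lo, hi) in self.trained_range.items():
            value = theta.get(name)
            if value is not None and not lo <= value <= hi:
                logger.warning(
                    "parameter %s=%g outside the trained range [%g, %g]; "
                    "extrapolating the reduced model",
                    name,
                    value,
                    lo,
                    hi,
                )

    def assemble(self, theta: Mapping[str, float] | None = None) -> np.ndarray:
        params = dict(self.nominal)
        if theta:
            self.check_domain(theta)
            params.update(theta)
        Ar = np.zeros((self.r, self.r))
        for comp in self.components:
            Ar += comp.coefficient(params) * comp.matrix
        return Ar


@dataclass
class ReducedTrajectory:
    grid: TimeGrid
    states: np.ndarray  # K x r
    outputs: np.ndarray  # p x K
    theta: dict = field(default_factory=dict)


def reduce(
    operator: ParametricOperator,
    output_map: OutputMap,
    initial: InitialDistribution | np.ndarray,
    basis: ReducedBasis | np.ndarray,
    trained_range: Mapping[str, tuple[float, float]] | None = None,
) -> ReducedModel:
    """Project operator components, output map and initial condition onto V."""
    if not isinstance(basis, ReducedBasis):
        basis = ReducedBasis(np.asarray(basis))
    V = basis.V
    if V.shape[0] != operator.state_space.dimension:
        raise ValueError("basis dimension does not match the operator")
    P0 = initial.vector if isinstance(initial, InitialDistribution) else np.asarray(initial, float)
    comps = [
        ReducedComponent(V.T @ (c.matrix @ V), c.coefficient, c.label, c.expression)
        for c in operator.components
    ]
    Cr = np.asarray(output_map.matrix @ V)
    if trained_range is None and basis.report is not None:
        trained_range = {
            name: (
                min(t[name] for t in basis.report.training_set),
                max(t[name] for t in basis.report.training_set),
            )
            for name in (basis.report.training_set[0] if basis.report.training_set else {})
        }
    return ReducedModel(
        components=comps,
        output_matrix=Cr,
        output_labels=list(output_map.labels),
        initial=V.T @ P0,
        basis=basis,
        nominal=dict(operator.nominal),
        domain=dict(operator.domain),
        trained_range=dict(trained_range or {}),
    )


def solve_reduced(
    model: ReducedModel,
    theta: Mapping[str, float] | None,
    grid: TimeGrid,
    warn_extrapolation: bool = True,
    method: str = "expm",
) -> ReducedTrajectory:
    """Integrate the r-dimensional reduced system and evaluate its outputs.

    With ``method="expm"`` (default) the constant reduced generator is
    propagated exactly (to round-off) with matrix exponentials of the grid
    increments; equal increments share one factor.  With ``method="euler"``
    the system is stepped with backward Euler, matching the
    discrete-evolution convention of a full model solved the same way (so
    that reduction error is the only discrepancy between the two).
    """
    if theta and warn_extrapolation:
        model.warn_extrapolation(theta)
    Ar = model.assemble(theta)
    K = grid.times.size
    Pr = np.empty((K, model.r))
    Pr[0] = model.initial
    dts = np.diff(grid.times)
    if method == "expm":
        cache: dict[float, np.ndarray] = {}
        for k, dt in enumerate(dts):
            Phi = cache.get(dt)
            if Phi is None:
                Phi = scipy.linalg.expm(Ar * dt)
                cache[dt] = Phi
            Pr[k + 1] = Phi @ Pr[k]
    elif method == "euler":
        lu_cache: dict[float, tuple] = {}
        I = np.eye(model.r)
        for k, dt in enumerate(dts):
            lu = lu_cache.get(dt)
            if lu is None:
                lu = scipy.linalg.lu_factor(I - dt * Ar)
                lu_cache[dt] = lu
            Pr[k + 1] = scipy.linalg.lu_solve(lu, Pr[k])
    else:
        raise ValueError(f"unknown method {method!r}")
    outputs = model.output_matrix @ Pr.T
    return ReducedTrajectory(grid, Pr, np.asarray(outputs), theta=dict(theta or {}))


def reconstruct(
    basis: ReducedBasis | np.ndarray, reduced: ReducedTrajectory | np.ndarray
) -> np.ndarray:
    """Approximate full states P_hat(t) = V P_r(t); shape (K, d) or (d,)."""
    V = basis.V if isinstance(basis, ReducedBasis) else np.asarray(basis)
    Pr = reduced.states if isinstance(reduced, ReducedTrajectory) else np.asarray(reduced)
    if Pr.ndim == 1:
        if Pr.size != V.shape[1]:
            raise ValueError("reduced state length does not match the basis")
        return V @ Pr
    if Pr.shape[1] != V.shape[1]:
        raise ValueError("reduced state length does not match the basis")
    return Pr @ V.T
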