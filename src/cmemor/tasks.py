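"""Parametric analyses on reduced models: estimation, landscapes, sweeps.

These are the "online" applications the reduction exists for: every
evaluation below is a reduced solve of dimension r, so hundreds of
parameter queries cost seconds instead of hours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .mor import ReducedModel, solve_reduced
from .simulate import TimeGrid

logger = logging.getLogger("cmemor")

__all__ = [
    "Measurement",
    "EstimationResult",
    "add_noise",
    "cost",
    "estimate",
    "cost_landscape",
    "sensitivity_sweep",
]


@dataclass
class Measurement:
    """A (possibly noisy) scalar output series on a time grid."""

    grid: TimeGrid
    values: np.ndarray
    noise_level: float = 0.0
    seed: int | None = None
    theta_ref: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.times.size:
            raise ValueError("one measured value per grid time required")


def add_noise(
    y: np.ndarray,
    grid: TimeGrid,
    level: float,
    seed: int,
    theta_ref: Mapping[str, float] | None = None,
) -> Measurement:
    """Multiplicative white noise: y_meas(t_k) = y(t_k) (1 + level * n_k).

    ``n_k`` are i.i.d. standard normal draws from the seeded generator; the
    seed is recorded on the measurement for reproducibility.
    """
    if level < 0:
        raise ValueError("noise level must be nonnegative")
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(y.size)
    return Measurement(
        grid, y * (1.0 + level * noise), noise_level=level, seed=seed,
        theta_ref=dict(theta_ref or {}),
    )


def cost(
    model: ReducedModel,
    theta: Mapping[str, float],
    measurement: Measurement,
    output_index: int = 0,
    method: str = "expm",
) -> float:
    """Least-squares misfit J(theta) = int (y_meas - y_hat(theta))^2 dt.

    Trapezoidal quadrature on the measurement grid, which must coincide with
    the simulation grid.
    """
    traj = solve_reduced(
        model, theta, measurement.grid, warn_extrapolation=False, method=method
    )
    residual = measurement.values - traj.outputs[output_index]
    return float(measurement.grid.weights @ (residual * residual))


@dataclass
class EstimationResult:
    theta_est: dict
    cost_est: float
    cost_ref: float | None
    n_evaluations: int
    status: str
    message: str = ""


def estimate(
    model: ReducedModel,
    measurement: Measurement,
    search: Mapping[str, tuple[float, float]],
    fixed: Mapping[str, float] | None = None,
    start: Mapping[str, float] | None = None,
    output_index: int = 0,
    n_scan: int = 9,
    method: str = "expm",
) -> EstimationResult:
    """Bound-constrained least-squares fit of the reduced model.

    ``search`` maps the free parameter names to their box bounds (a single
    entry gives the 1-D restricted problem); ``fixed`` pins the remaining
    varied parameters.  The cost along a parameter line is typically
    multimodal (a narrow valley through the data-generating parameter plus
    shallow side basins), so a local solver started blindly can converge to
    the wrong basin: unless ``start`` is given, a coarse ``n_scan``-point
    per-axis scan (log-spaced for positive boxes) first locates the best
    node, then a bound-constrained quasi-Newton refinement (L-BFGS-B on
    box-normalized variables, objective normalized by its start value) polishes
    it.  Reduced solves make the scan cheap.  Non-convergence is reported in
    ``status``, not raised.
    """
    names = list(search)
    lower = np.array([search[n][0] for n in names])
    upper = np.array([search[n][1] for n in names])
    fixed = dict(fixed or {})

    def theta_of(x: np.ndarray) -> dict:
        theta = dict(fixed)
        theta.update({n: float(v) for n, v in zip(names, x)})
        return theta

    counter = {"n": 0}

    def objective(x: np.ndarray) -> float:
        counter["n"] += 1
        return cost(model, theta_of(x), measurement, output_index, method=method)

    if start is not None:
        x0 = np.array([start[n] for n in names], dtype=float)
    else:
        axes = [
            np.geomspace(lo, hi, n_scan) if lo > 0 else np.linspace(lo, hi, n_scan)
            for lo, hi in zip(lower, upper)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        nodes = np.stack([m.ravel() for m in mesh], axis=1)
        scan_costs = [objective(x) for x in nodes]
        x0 = nodes[int(np.argmin(scan_costs))]

    span = upper - lower
    f0 = objective(x0) or 1.0

    def normalized(z: np.ndarray) -> float:
        return objective(lower + z * span) / f0

    result = minimize(
        normalized,
        (x0 - lower) / span,
        method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * len(names),
        options={"ftol": 1e-11, "gtol": 1e-10},
    )
    result.fun = result.fun * f0
    theta_est = theta_of(lower + result.x * span)
    cost_ref = None
    if measurement.theta_ref:
        theta_ref = dict(fixed)
        theta_ref.update(measurement.theta_ref)
        cost_ref = cost(model, theta_ref, measurement, output_index, method=method)
    status = "converged" if result.success else "not-converged"
    if not result.success:
        logger.warning("estimation did not converge: %s", result.message)
    return EstimationResult(
        theta_est=theta_est,
        cost_est=float(result.fun),
        cost_ref=cost_ref,
        n_evaluations=counter["n"],
        status=status,
        message=str(result.message),
    )


def cost_landscape(
    model: ReducedModel,
    measurement: Measurement,
    grid_spec: Mapping[str, Sequence[float]],
    output_index: int = 0,
    method: str = "expm",
) -> pd.DataFrame:
    """Evaluate J on a tensor grid of parameter values.

    Returns a tidy table with one row per node (parameter columns plus
    ``cost``); every node is domain-checked up front.
    """
    names = list(grid_spec)
    axes = [np.asarray(grid_spec[n], dtype=float) for n in names]
    mesh = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([m.ravel() for m in mesh], axis=1)
    for row in nodes:
        model.check_domain({n: float(v) for n, v in zip(names, row)})
    records = []
    for row in nodes:
        theta = {n: float(v) for n, v in zip(names, row)}
        records.append(
            {**theta, "cost": cost(model, theta, measurement, output_index, method=method)}
        )
    return pd.DataFrame.from_records(records)


def sensitivity_sweep(
    model: ReducedModel,
    parameter: str,
    values: Sequence[float],
    grid: TimeGrid,
    t_eval: float | None = None,
    output_index: int = 0,
    method: str = "expm",
) -> pd.DataFrame:
    """Evaluate one output at ``t_eval`` while sweeping a single parameter.

    For each value the reduced model is solved on ``grid`` and the output
    row ``output_index`` (typically a region probability) is read off at the
    grid time closest to ``t_eval`` (default: the final time).  Values
    outside the trained parameter range are flagged with a warning but
    evaluated — extrapolation of the reduced model is permitted.
    """
    values = np.asarray(values, dtype=float)
    t_eval = grid.final_time if t_eval is None else float(t_eval)
    if t_eval > grid.final_time:
        raise ValueError("t_eval beyond the simulation horizon")
    k_eval = int(np.argmin(np.abs(grid.times - t_eval)))
    curve = np.empty(values.size)
    for i, value in enumerate(values):
        traj = solve_reduced(model, {parameter: float(value)}, grid, method=method)
        curve[i] = traj.outputs[output_index, k_eval]
    return pd.DataFrame({parameter: values, "output": curve})
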