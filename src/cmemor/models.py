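"""Packaged model fixtures: follicle switch, genetic oscillator, test oracles.

Both study models are two-species gene-regulation networks whose CME is
truncated to a square lattice:

* **Follicle switch** — two mutually activating gene products with Hill-type
  production; a bistable system whose probability mass migrates from the
  off-state near (0, 0) to the on-state near (V1, V2) over T = 1e7 minutes.
  Varied parameters: the turnover rates (u1, u2) in [0.005, 0.02]^2.
* **Genetic oscillator** — a negative feedback loop with positive
  autoregulation showing noise-induced oscillations.  The system-size
  parameter ``s`` maps dimensionless concentrations to copy numbers; the
  production rate ``k4`` in [10, 100] is varied and the default output is
  the probability that x2 exceeds 10*s (the oscillation-amplitude proxy).

The birth-death fixture is a one-species oracle with the closed-form
Poisson solution used to validate the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import sympy
import yaml

from .network import (
    InitialDistribution,
    OutputMap,
    ParametricOperator,
    ReactionNetwork,
    StateSpace,
    enumerate_states,
    expectation_output,
    initial_uniform,
    region_output,
)
from .simulate import TimeGrid

__all__ = ["ModelFixture", "build_switch", "build_oscillator", "build_birth_death"]


def _compile_predicate(expr_str: str, species_names) -> Callable[[np.ndarray], np.ndarray]:
    """Compile a boolean expression over species names into a vectorized mask."""
    from .network import parse_expression

    expr = parse_expression(expr_str)
    syms = [sympy.Symbol(name) for name in species_names]
    unknown = expr.free_symbols - set(syms)
    if unknown:
        raise KeyError(f"predicate {expr_str!r} references unknown names {unknown}")
    func = sympy.lambdify(syms, expr, modules="numpy")

    def predicate(states: np.ndarray) -> np.ndarray:
        cols = [states[:, k] for k in range(len(species_names))]
        return np.broadcast_to(np.asarray(func(*cols), dtype=bool), (states.shape[0],))

    return predicate


@dataclass
class ModelFixture:
    """A reaction network bundled with its study conditions.

    Carries everything a run needs: nominal parameter values, the admissible
    domain of the varied parameters, the truncation rectangle, the initial
    distribution predicate, the horizon T and named output maps.
    """

    name: str
    network: ReactionNetwork
    nominal: dict
    varied: dict  # name -> (low, high)
    bounds: list  # per-species (low, high)
    initial_expr: str
    final_time: float
    outputs: dict = field(default_factory=dict)  # label -> output spec dict
    default_output: str = ""
    units: str = ""

    def __post_init__(self):
        for name in self.varied:
            if name not in self.nominal:
                raise ValueError(f"varied parameter {name!r} has no nominal value")
        lo_hi = np.asarray([list(b) for b in self.bounds])
        if not np.isfinite(lo_hi).all():
            raise ValueError("truncation bounds must be finite")

    # -- lazy builders ----------------------------------------------------
    def state_space(self) -> StateSpace:
        if not hasattr(self, "_space"):
            self._space = enumerate_states(self.bounds)
        return self._space

    def operator(self) -> ParametricOperator:
        if not hasattr(self, "_operator"):
            self._operator = ParametricOperator.from_network(
                self.network, self.state_space(), self.nominal, self.varied
            )
        return self._operator

    def initial(self) -> InitialDistribution:
        predicate = _compile_predicate(self.initial_expr, self.network.species_names)
        return initial_uniform(self.state_space(), predicate, description=self.initial_expr)

    def output(self, label: str | None = None) -> OutputMap:
        label = label or self.default_output
        spec = self.outputs[label]
        space = self.state_space()
        if spec["kind"] == "expectation":
            out = expectation_output(space, spec["species"], self.network.species_names)
        elif spec["kind"] == "region_probability":
            predicate = _compile_predicate(spec["predicate"], self.network.species_names)
            out = region_output(space, predicate, label=label)
        else:
            raise ValueError(f"unknown output kind {spec['kind']!r}")
        out.labels = [label]
        return out

    def grid(self, n_points: int = 100) -> TimeGrid:
        return TimeGrid.uniform(self.final_time, n_points)

    def theta_nominal(self) -> dict:
        return {name: self.nominal[name] for name in self.varied}

    @property
    def model_key(self) -> str:
        bounds = ",".join(f"{lo}-{hi}" for lo, hi in self.bounds)
        params = ",".join(f"{k}={self.nominal[k]!r}" for k in sorted(self.nominal))
        return f"{self.name}|{bounds}|{params}|T={self.final_time!r}|{self.initial_expr}"

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "parameters": dict(self.nominal),
            "varied": {k: list(v) for k, v in self.varied.items()},
            "bounds": {
                name: list(b) for name, b in zip(self.network.species_names, self.bounds)
            },
            "initial": self.initial_expr,
            "final_time": self.final_time,
            "outputs": self.outputs,
            "default_output": self.default_output,
            "units": self.units,
            **self.network.to_dict(),
        }

    @classmethod
    def from_dict(cls, spec: Mapping) -> "ModelFixture":
        network = ReactionNetwork.from_dict(spec)
        bounds = [tuple(spec["bounds"][name]) for name in network.species_names]
        return cls(
            name=spec.get("name", "model"),
            network=network,
            nominal=dict(spec["parameters"]),
            varied={k: tuple(v) for k, v in spec.get("varied", {}).items()},
            bounds=bounds,
            initial_expr=spec["initial"],
            final_time=float(spec["final_time"]),
            outputs=dict(spec.get("outputs", {})),
            default_output=spec.get("default_output", ""),
            units=spec.get("units", ""),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelFixture":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# fixtures


def build_switch(
    bound: int = 150,
    final_time: float = 1e7,
    initial: str = "x1 + x2 <= 20",
) -> ModelFixture:
    """Bistable follicle switch (rates per minute).

    Five separable components with coefficients (u1*k1, u1*V1, u1, u2*V2,
    u2): the Hill constants M1, M2 sit in denominators and are baked in at
    their nominal value 25.  ``bound`` and ``final_time`` allow scaled-down
    variants for fast studies; the study conditions are the defaults.
    The printed initial condition spreads uniform mass over x1+x2 <= 20
    (231 states); pass ``initial="x1 + x2 <= 19"`` for the 210-state
    variant whose mass is exactly 1/210.
    """
    spec = {
        "name": "switch",
        "species": ["x1", "x2"],
        "reactions": [
            {
                "products": {"x1": 1},
                "terms": [
                    {"coefficient": "u1*k1", "state": "1", "label": "basal production of X1"},
                    {
                        "coefficient": "u1*V1",
                        "state": "x2**3/(M1**3 + x2**3)",
                        "label": "activated production of X1",
                    },
                ],
            },
            {
                "reactants": {"x1": 1},
                "terms": [{"coefficient": "u1", "state": "x1", "label": "degradation of X1"}],
            },
            {
                "products": {"x2": 1},
                "terms": [
                    {
                        "coefficient": "u2*V2",
                        "state": "x1**3/(M2**3 + x1**3)",
                        "label": "activated production of X2",
                    }
                ],
            },
            {
                "reactants": {"x2": 1},
                "terms": [{"coefficient": "u2", "state": "x2", "label": "degradation of X2"}],
            },
        ],
        "parameters": {
            "k1": 4.0,
            "V1": 75.0,
            "M1": 25.0,
            "u1": 0.01,
            "V2": 75.0,
            "M2": 25.0,
            "u2": 0.01,
        },
        "varied": {"u1": [0.005, 0.02], "u2": [0.005, 0.02]},
        "bounds": {"x1": [0, bound], "x2": [0, bound]},
        "initial": initial,
        "final_time": final_time,
        "outputs": {
            "E[x1]": {"kind": "expectation", "species": "x1"},
            "E[x2]": {"kind": "expectation", "species": "x2"},
        },
        "default_output": "E[x1]",
        "units": "time in minutes, rates per minute",
    }
    return ModelFixture.from_dict(spec)


def build_oscillator(
    s: float = 10.0,
    bound: int | None = None,
    initial_bound: int | None = None,
    final_time: float = 6.0,
) -> ModelFixture:
    """Stochastic genetic oscillator (rates per second).

    Five separable components with coefficients (k1, k3, k4, k5, k7); the
    production of X2 contributes two terms sharing one stoichiometry.  The
    parameters s, k2, k6 appear in denominators and are baked in.  The
    default truncation is {0..30s}^2 with uniform initial mass on {0..5s}^2
    and the amplitude output Prob(x2 > 10s); at the nominal s = 10 these are
    the study conditions {0..300}^2, {0..50}^2 and Prob(x2 > 100).
    """
    bound = int(round(30 * s)) if bound is None else bound
    initial_bound = int(round(5 * s)) if initial_bound is None else initial_bound
    amp_threshold = int(round(10 * s))
    spec = {
        "name": "oscillator",
        "species": ["x1", "x2"],
        "reactions": [
            {
                "products": {"x1": 1},
                "terms": [
                    {
                        "coefficient": "k1",
                        "state": f"s**2/(k2*s + x2)",
                        "label": "production of X1",
                    }
                ],
            },
            {
                "reactants": {"x1": 1},
                "terms": [{"coefficient": "k3", "state": "x1", "label": "degradation of X1"}],
            },
            {
                "products": {"x2": 1},
                "terms": [
                    {"coefficient": "k4", "state": "s", "label": "basal production of X2"},
                    {
                        "coefficient": "k5",
                        "state": "x2**2*x1/(k6*s**2 + x2**2)",
                        "label": "autocatalytic production of X2",
                    },
                ],
            },
            {
                "reactants": {"x2": 1},
                "terms": [{"coefficient": "k7", "state": "x2", "label": "degradation of X2"}],
            },
        ],
        "parameters": {
            "k1": 15.0,
            "k2": 0.2,
            "k3": 1.0,
            "k4": 10.0,
            "k5": 100.0,
            "k6": 6.5,
            "k7": 100.0,
            "s": float(s),
        },
        "varied": {"k4": [10.0, 100.0]},
        "bounds": {"x1": [0, bound], "x2": [0, bound]},
        "initial": f"(x1 <= {initial_bound}) & (x2 <= {initial_bound})",
        "final_time": final_time,
        "outputs": {
            f"P[x2>{amp_threshold}]": {
                "kind": "region_probability",
                "predicate": f"x2 > {amp_threshold}",
            },
            "E[x2]": {"kind": "expectation", "species": "x2"},
        },
        "default_output": f"P[x2>{amp_threshold}]",
        "units": "time in seconds, rates per second",
    }
    return ModelFixture.from_dict(spec)


def build_birth_death(k: float = 10.0, gamma: float = 1.0, bound: int = 60) -> ModelFixture:
    """One-species birth-death oracle with closed-form Poisson solution.

    Starting empty, the copy-number distribution at time t is Poisson with
    mean ``lambda(t) = (k/gamma) (1 - exp(-gamma t))`` (or ``k t`` for
    gamma = 0).  Used to validate the FSP integrator.
    """
    if k < 0 or gamma < 0:
        raise ValueError("rates must be nonnegative")
    spec = {
        "name": "birth_death",
        "species": ["x"],
        "reactions": [
            {"products": {"x": 1}, "terms": [{"coefficient": "k", "state": "1", "label": "birth"}]},
            {
                "reactants": {"x": 1},
                "terms": [{"coefficient": "gamma", "state": "x", "label": "death"}],
            },
        ],
        "parameters": {"k": float(k), "gamma": float(gamma)},
        "varied": {},
        "bounds": {"x": [0, bound]},
        "initial": "x <= 0",
        "final_time": 5.0 / gamma if gamma > 0 else 1.0,
        "outputs": {"E[x]": {"kind": "expectation", "species": "x"}},
        "default_output": "E[x]",
        "units": "dimensionless time",
    }
    fixture = ModelFixture.from_dict(spec)

    def poisson_mean(t):
        t = np.asarray(t, dtype=float)
        return k * t if gamma == 0 else (k / gamma) * (1.0 - np.exp(-gamma * t))

    fixture.poisson_mean = poisson_mean  # analytic oracle attached to the fixture
    return fixture
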