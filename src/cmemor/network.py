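"""Reaction networks, truncated state spaces and sparse parametric FSP operators.

The chemical master equation (CME) of a reaction network is an (in general
infinite) linear ODE for the probabilities of all molecular copy-number
states.  The finite state projection (FSP) truncates it to a rectangular
lattice ``Omega`` and yields ``dP/dt = A(theta) P`` with a sparse generator
``A``.  For the parametric reduction downstream, ``A`` is kept in
parameter-separable form::

    A(theta) = sum_q  vartheta_q(theta) * A_q

with parameter-free sparse components ``A_q`` and scalar coefficient
functions ``vartheta_q``.  Each component carries the state-dependent part
``g_q(x)`` of one propensity term; the coefficient carries the parameter
dependence (a rate constant, or a product such as ``u1*V1``).

Propensity expressions are plain strings over species and parameter names,
compiled once with sympy.  Mass-action terms use the monomial
``prod_i x_i**sigma_ij`` (plain powers, a modelling convention kept
throughout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import sympy

logger = logging.getLogger("cmemor")

__all__ = [
    "DomainError",
    "ReactionNetwork",
    "Reaction",
    "PropensityTerm",
    "StateSpace",
    "ParametricOperator",
    "OutputMap",
    "InitialDistribution",
    "enumerate_states",
    "evaluate_propensity",
    "assemble_component",
    "assemble_operator",
    "expectation_output",
    "region_output",
    "output_matrix",
    "initial_uniform",
    "initial_point_mass",
    "export_components_mtx",
    "export_states_csv",
]


class DomainError(ValueError):
    """Parameter vector outside the admissible domain P."""


# ---------------------------------------------------------------------------
# expression compilation


_ALLOWED_FUNCS = {
    "exp": sympy.exp,
    "log": sympy.log,
    "sqrt": sympy.sqrt,
    "sin": sympy.sin,
    "cos": sympy.cos,
    "tanh": sympy.tanh,
    "Abs": sympy.Abs,
    "Min": sympy.Min,
    "Max": sympy.Max,
}


def parse_expression(expr_str: str) -> sympy.Expr:
    """Parse an expression treating every identifier as a plain symbol.

    Bare names never resolve to sympy built-ins (``gamma``, ``beta``, ...);
    only the explicit function names in ``_ALLOWED_FUNCS`` are callable.
    """
    import re

    identifiers = set(re.findall(r"[A-Za-z_][A-Za-z_0-9]*", str(expr_str)))
    local = {name: sympy.Symbol(name) for name in identifiers if name not in _ALLOWED_FUNCS}
    local.update(_ALLOWED_FUNCS)
    return sympy.parse_expr(str(expr_str), local_dict=local)


def _compile_expression(expr_str: str):
    """Compile a scalar expression string into ``(callable, arg_names)``.

    The callable takes keyword arguments named after the free symbols and
    broadcasts over numpy arrays.
    """
    expr = parse_expression(expr_str)
    syms = sorted(expr.free_symbols, key=str)
    names = [str(s) for s in syms]
    func = sympy.lambdify(syms, expr, modules="numpy")
    return func, names


class _Expression:
    """A compiled scalar expression over species and/or parameter names."""

    def __init__(self, expr_str: str):
        self.text = str(expr_str)
        self._func, self.arg_names = _compile_expression(self.text)

    def __call__(self, env: Mapping[str, object]) -> object:
        try:
            args = [env[name] for name in self.arg_names]
        except KeyError as exc:
            raise KeyError(
                f"expression {self.text!r} references unknown name {exc.args[0]!r}"
            ) from None
        return self._func(*args)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"_Expression({self.text!r})"


# ---------------------------------------------------------------------------
# network types


@dataclass
class Reaction:
    """One irreversible reaction with reactant/product stoichiometries."""

    reactant_stoich: np.ndarray
    product_stoich: np.ndarray

    def __post_init__(self):
        self.reactant_stoich = np.asarray(self.reactant_stoich, dtype=int)
        self.product_stoich = np.asarray(self.product_stoich, dtype=int)
        if self.reactant_stoich.shape != self.product_stoich.shape:
            raise ValueError("reactant and product stoichiometries differ in length")
        if (self.reactant_stoich < 0).any() or (self.product_stoich < 0).any():
            raise ValueError("stoichiometric coefficients must be nonnegative")

    @property
    def net_change(self) -> np.ndarray:
        """Stoichiometric reaction vector v_j = products - reactants."""
        return self.product_stoich - self.reactant_stoich


@dataclass
class PropensityTerm:
    """One separable term of a reaction propensity.

    ``coefficient`` is an expression over parameter names only (the
    vartheta_q(theta) of the separable decomposition); ``state`` is an
    expression over species names and *fixed* parameter names giving the
    nonnegative state factor g_q(x).
    """

    reaction_index: int
    coefficient: str
    state: str
    label: str = ""

    def __post_init__(self):
        self._coeff = _Expression(self.coefficient)
        self._state = _Expression(self.state)
        if not self.label:
            self.label = self.coefficient

    @classmethod
    def mass_action(
        cls, reaction_index: int, rate: str, network: "ReactionNetwork", label: str = ""
    ) -> "PropensityTerm":
        """Mass-action term: g(x) = prod_i x_i**sigma_ij (plain powers)."""
        sigma = network.reactions[reaction_index].reactant_stoich
        factors = [
            f"{name}**{int(s)}" if s > 1 else name
            for name, s in zip(network.species_names, sigma)
            if s > 0
        ]
        return cls(reaction_index, rate, "*".join(factors) or "1", label=label)

    def coefficient_value(self, params: Mapping[str, float]) -> float:
        value = float(self._coeff(params))
        if value < 0:
            raise ValueError(
                f"coefficient {self.coefficient!r} is negative ({value}) "
                f"for the given parameters"
            )
        return value

    def state_values(
        self, states: np.ndarray, species_names: Sequence[str], params: Mapping[str, float]
    ) -> np.ndarray:
        """Evaluate g_q over an (m, n) array of lattice states."""
        states = np.atleast_2d(np.asarray(states, dtype=float))
        env: dict[str, object] = dict(params)
        for k, name in enumerate(species_names):
            env[name] = states[:, k]
        values = np.broadcast_to(
            np.asarray(self._state(env), dtype=float), (states.shape[0],)
        ).copy()
        if (values < 0).any():
            raise ValueError(
                f"state function {self.state!r} is negative on the lattice "
                "(malformed propensity)"
            )
        return values


@dataclass
class ReactionNetwork:
    """Species, reactions and separable propensity terms of a network."""

    species_names: list[str]
    reactions: list[Reaction]
    propensity_terms: list[PropensityTerm] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.species_names)
        for j, r in enumerate(self.reactions):
            if len(r.reactant_stoich) != n:
                raise ValueError(f"reaction {j}: stoichiometry length != {n} species")
        changes = [tuple(r.net_change) for r in self.reactions]
        if len(set(changes)) != len(changes):
            raise ValueError("two reactions share the same net change vector")
        for term in self.propensity_terms:
            if not 0 <= term.reaction_index < len(self.reactions):
                raise ValueError(
                    f"propensity term {term.label!r} references missing reaction "
                    f"{term.reaction_index}"
                )

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    @classmethod
    def from_dict(cls, spec: Mapping) -> "ReactionNetwork":
        """Build a network from the YAML/dict schema (see docs/methods.md)."""
        species = list(spec["species"])
        n = len(species)

        def stoich(d: Mapping[str, int]) -> np.ndarray:
            v = np.zeros(n, dtype=int)
            for name, count in (d or {}).items():
                v[species.index(name)] = int(count)
            return v

        reactions, terms = [], []
        for j, rspec in enumerate(spec["reactions"]):
            reactions.append(Reaction(stoich(rspec.get("reactants")), stoich(rspec.get("products"))))
            for tspec in rspec["terms"]:
                terms.append(
                    PropensityTerm(
                        j,
                        str(tspec["coefficient"]),
                        str(tspec.get("state", "1")),
                        label=str(tspec.get("label", "")),
                    )
                )
        net = cls(species, reactions)
        net.propensity_terms = terms
        net.__post_init__()
        return net

    def to_dict(self) -> dict:
        out: dict = {"species": list(self.species_names), "reactions": []}
        for j, r in enumerate(self.reactions):
            rspec = {
                "reactants": {
                    name: int(s)
                    for name, s in zip(self.species_names, r.reactant_stoich)
                    if s
                },
                "products": {
                    name: int(s)
                    for name, s in zip(self.species_names, r.product_stoich)
                    if s
                },
                "terms": [
                    {"coefficient": t.coefficient, "state": t.state, "label": t.label}
                    for t in self.propensity_terms
                    if t.reaction_index == j
                ],
            }
            out["reactions"].append(rspec)
        return out


# ---------------------------------------------------------------------------
# state space


@dataclass
class StateSpace:
    """Rectangular FSP lattice with a deterministic lexicographic order.

    States are ordered with the first species varying fastest; copy numbers
    run from ``lower`` to ``upper`` inclusive.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=int)
        self.upper = np.asarray(self.upper, dtype=int)
        if self.lower.ndim != 1 or self.lower.size == 0:
            raise ValueError("bounds must be a nonempty 1-D list of (lower, upper)")
        if (self.lower < 0).any():
            raise ValueError("copy numbers cannot be negative")
        if (self.upper < self.lower).any():
            raise ValueError("upper bound below lower bound")
        self.shape = tuple((self.upper - self.lower + 1).tolist())
        self.dimension = int(np.prod(self.shape))
        # strides for the index map; species 0 varies fastest
        self.strides = np.concatenate([[1], np.cumprod(self.shape[:-1])]).astype(np.int64)

    @property
    def n_species(self) -> int:
        return self.lower.size

    @property
    def states(self) -> np.ndarray:
        """(d, n) integer array of lattice points in storage order."""
        grids = np.meshgrid(
            *[np.arange(lo, hi + 1) for lo, hi in zip(self.lower, self.upper)],
            indexing="ij",
        )
        return np.stack([g.ravel(order="F") for g in grids], axis=1)

    def index_of(self, states: np.ndarray) -> np.ndarray:
        """Map lattice points to linear indices (vectorized bijection)."""
        states = np.atleast_2d(np.asarray(states, dtype=np.int64))
        if states.shape[1] != self.n_species:
            raise ValueError("state dimension mismatch")
        if ((states < self.lower).any()) or ((states > self.upper).any()):
            raise ValueError("state outside the truncation rectangle")
        return (states - self.lower) @ self.strides

    def contains(self, states: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=np.int64))
        return ((states >= self.lower) & (states <= self.upper)).all(axis=1)


def enumerate_states(bounds: Sequence[tuple[int, int]]) -> StateSpace:
    """Enumerate the rectangular lattice Omega given per-species bounds."""
    bounds = list(bounds)
    if not bounds:
        raise ValueError("bounds must be nonempty")
    lower = np.array([b[0] for b in bounds], dtype=int)
    upper = np.array([b[1] for b in bounds], dtype=int)
    return StateSpace(lower, upper)


def evaluate_propensity(
    term: PropensityTerm,
    x: np.ndarray,
    species_names: Sequence[str],
    params: Mapping[str, float] | None = None,
) -> float:
    """Evaluate one term's state factor g_q at a single lattice state."""
    return float(term.state_values(np.atleast_2d(x), species_names, params or {})[0])


# ---------------------------------------------------------------------------
# operator assembly


def assemble_component(
    state_space: StateSpace,
    net_change: np.ndarray,
    g: np.ndarray | Callable[[np.ndarray], np.ndarray],
) -> sp.csc_matrix:
    """Assemble one parameter-free FSP component A_q.

    The diagonal entry of state ``i`` is ``-g(x_i)`` (outflow is counted even
    when ``x_i + v`` leaves the rectangle: sink-type truncation, probability
    leaks at the boundary).  Off-diagonal inflow ``(i, j)`` is ``g(x_j)``
    exactly when ``x_i = x_j + v`` with both states inside.
    """
    v = np.asarray(net_change, dtype=int)
    if v.shape != (state_space.n_species,):
        raise ValueError("net change vector length does not match the state space")
    states = state_space.states
    g_vals = np.asarray(g(states) if callable(g) else g, dtype=float)
    if g_vals.shape != (state_space.dimension,):
        raise ValueError("state factor g has wrong length")
    targets = states + v
    inside = state_space.contains(targets)
    rows = state_space.index_of(targets[inside])
    cols = np.flatnonzero(inside)
    d = state_space.dimension
    diag = sp.diags(-g_vals, format="csc")
    flow = sp.csc_matrix((g_vals[inside], (rows, cols)), shape=(d, d))
    return (diag + flow).tocsc()


@dataclass
class OperatorComponent:
    matrix: sp.csc_matrix
    coefficient: Callable[[Mapping[str, float]], float]
    label: str = ""
    expression: str = ""  # coefficient expression text, kept for persistence


@dataclass
class ParametricOperator:
    """Parameter-separable FSP operator A(theta) = sum_q vartheta_q(theta) A_q."""

    state_space: StateSpace
    components: list[OperatorComponent]
    nominal: dict = field(default_factory=dict)
    domain: dict = field(default_factory=dict)  # varied name -> (low, high)

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
        for name in theta:
            if name not in self.nominal and name not in self.domain:
                raise DomainError(f"unknown parameter {name!r}")

    def parameters(self, theta: Mapping[str, float] | None = None) -> dict:
        merged = dict(self.nominal)
        if theta:
            merged.update(theta)
        return merged

    def coefficients(self, theta: Mapping[str, float] | None = None) -> np.ndarray:
        if theta is not None:
            self.check_domain(theta)
        params = self.parameters(theta)
        return np.array([c.coefficient(params) for c in self.components])

    def assemble(self, theta: Mapping[str, float] | None = None) -> sp.csc_matrix:
        """Online assembly of A(theta) from the stored components."""
        coeffs = self.coefficients(theta)
        d = self.state_space.dimension
        acc = sp.csc_matrix((d, d))
        for c, comp in zip(coeffs, self.components):
            if c != 0.0:
                acc = acc + c * comp.matrix
        return acc.tocsc()

    @classmethod
    def from_network(
        cls,
        network: ReactionNetwork,
        state_space: StateSpace,
        nominal: Mapping[str, float],
        domain: Mapping[str, tuple[float, float]] | None = None,
    ) -> "ParametricOperator":
        """Assemble all separable components of a network on a lattice.

        Fixed parameters appearing inside state expressions (e.g. Hill
        constants) are baked into the components at their nominal values;
        only the coefficient functions remain parameter-dependent online.
        """
        comps = []
        for term in network.propensity_terms:
            v = network.reactions[term.reaction_index].net_change
            g_vals = term.state_values(state_space.states, network.species_names, nominal)
            comps.append(
                OperatorComponent(
                    assemble_component(state_space, v, g_vals),
                    term.coefficient_value,
                    label=term.label,
                    expression=term.coefficient,
                )
            )
        return cls(state_space, comps, nominal=dict(nominal), domain=dict(domain or {}))


def assemble_operator(
    operator: ParametricOperator, theta: Mapping[str, float] | None = None
) -> sp.csc_matrix:
    """Functional alias for :meth:`ParametricOperator.assemble`."""
    return operator.assemble(theta)


# ---------------------------------------------------------------------------
# outputs and initial distributions


@dataclass
class OutputMap:
    """Sparse output matrix C with one labelled row per output quantity."""

    matrix: sp.csr_matrix
    labels: list[str]
    kind: str = "custom"  # expectation | region_probability | custom

    def __post_init__(self):
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("one label per output row required")

    @property
    def n_outputs(self) -> int:
        return self.matrix.shape[0]

    def stack(self, other: "OutputMap") -> "OutputMap":
        return OutputMap(
            sp.vstack([self.matrix, other.matrix]).tocsr(),
            self.labels + other.labels,
            kind="custom" if self.kind != other.kind else self.kind,
        )


def expectation_output(
    state_space: StateSpace, species: int | str, species_names: Sequence[str] | None = None
) -> OutputMap:
    """Row C with C_j = x_i^(j): y(t) = E[x_i] under P(t)."""
    if isinstance(species, str):
        if species_names is None or species not in species_names:
            raise KeyError(f"unknown species {species!r}")
        index = list(species_names).index(species)
        label = f"E[{species}]"
    else:
        index = int(species)
        label = f"E[x{index + 1}]"
    if not 0 <= index < state_space.n_species:
        raise KeyError(f"species index {index} out of range")
    row = sp.csr_matrix(state_space.states[:, index].astype(float)[None, :])
    return OutputMap(row, [label], kind="expectation")


def region_output(
    state_space: StateSpace,
    predicate: Callable[[np.ndarray], np.ndarray],
    label: str = "P[region]",
) -> OutputMap:
    """0/1 row summing probability over a state-space region."""
    mask = np.asarray(predicate(state_space.states), dtype=bool)
    if mask.shape != (state_space.dimension,):
        raise ValueError("predicate must return one boolean per state")
    row = sp.csr_matrix(mask.astype(float)[None, :])
    return OutputMap(row, [label], kind="region_probability")


def output_matrix(state_space: StateSpace, spec, species_names=None) -> OutputMap:
    """Build an output map from a ('expectation', species) or
    ('region', predicate[, label]) tuple."""
    kind = spec[0]
    if kind == "expectation":
        return expectation_output(state_space, spec[1], species_names)
    if kind == "region":
        return region_output(state_space, spec[1], *spec[2:])
    raise ValueError(f"unknown output kind {kind!r}")


@dataclass
class InitialDistribution:
    """Dense probability vector over the lattice."""

    vector: np.ndarray
    description: str = ""

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if (self.vector < 0).any():
            raise ValueError("negative probability in initial distribution")
        total = self.vector.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"initial distribution sums to {total}, not 1")


def initial_uniform(
    state_space: StateSpace,
    predicate: Callable[[np.ndarray], np.ndarray],
    description: str = "",
) -> InitialDistribution:
    """Uniform probability over the states selected by ``predicate``."""
    mask = np.asarray(predicate(state_space.states), dtype=bool)
    support = int(mask.sum())
    if support == 0:
        raise ValueError("initial predicate selects no state")
    vec = np.zeros(state_space.dimension)
    vec[mask] = 1.0 / support
    return InitialDistribution(vec, description or f"uniform over {support} states")


def initial_point_mass(state_space: StateSpace, state: Sequence[int]) -> InitialDistribution:
    vec = np.zeros(state_space.dimension)
    vec[int(state_space.index_of(np.asarray(state))[0])] = 1.0
    return InitialDistribution(vec, f"point mass at {tuple(state)}")


# ---------------------------------------------------------------------------
# exports


def export_components_mtx(operator: ParametricOperator, directory, prefix: str = "A") -> list:
    """Write each sparse component to Matrix Market files; returns the paths."""
    from pathlib import Path

    import scipy.io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for q, comp in enumerate(operator.components, start=1):
        path = directory / f"{prefix}_{q}.mtx"
        scipy.io.mmwrite(path, comp.matrix)
        paths.append(path)
    return paths


def export_states_csv(state_space: StateSpace, path, species_names=None) -> None:
    """Write the state table (index, x_1..x_n) to CSV."""
    import pandas as pd

    names = list(species_names or [f"x{i + 1}" for i in range(state_space.n_species)])
    df = pd.DataFrame(state_space.states, columns=names)
    df.insert(0, "index", np.arange(state_space.dimension))
    df.to_csv(path, index=False)
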