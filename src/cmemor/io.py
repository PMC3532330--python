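"""Run configuration, training-set construction and HDF5 persistence.

Artifacts (bases, reduced models, trajectories, greedy reports) are stored
in schema-versioned HDF5 groups; a reduced model reloads without the full
operator because coefficient functions travel as expression strings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import yaml

from .mor import GreedyReport, ReducedBasis, ReducedComponent, ReducedModel
from .network import _Expression
from .simulate import FullTrajectory, TimeGrid

logger = logging.getLogger("cmemor")

SCHEMA_VERSION = 1

__all__ = [
    "SchemaError",
    "RunConfig",
    "make_training_set",
    "save_basis",
    "load_basis",
    "save_reduced_model",
    "load_reduced_model",
    "save_trajectory",
    "load_trajectory",
    "write_manifest",
]


class SchemaError(RuntimeError):
    """Artifact file is missing, corrupt, or has an incompatible schema."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Serializable description of one pipeline run.

    ``model`` is a fixture name (``switch``, ``oscillator``, ``birth_death``)
    or a path to a model YAML file.  Every stochastic step carries an
    explicit seed.
    """

    model: str = "switch"
    grid_points: int = 100
    solver_method: str = "bdf"  # bdf | expm | euler
    rtol: float = 1e-8
    atol: float = 1e-12
    training_counts: dict = field(default_factory=dict)  # parameter -> count
    training_spacing: str = "log"
    eps_tol: float = 1e-12
    max_basis_size: int = 200
    seed: int = 0
    noise_level: float = 0.05
    cache_dir: str | None = None
    output_dir: str = "results"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def make_training_set(
    ranges: Mapping[str, tuple[float, float]],
    counts: Mapping[str, int] | int,
    spacing: str = "log",
) -> list[dict]:
    """Tensor grid of parameter vectors in deterministic lexicographic order.

    Per-axis values are logarithmically (default) or linearly equidistant
    with both endpoints included; a count of 1 degenerates to the lower
    bound.  The first parameter varies slowest, so ties in later argmax
    selections resolve to the smallest index under this documented order.
    """
    names = list(ranges)
    axes = []
    for name in names:
        lo, hi = ranges[name]
        count = counts if isinstance(counts, int) else counts[name]
        if count < 1:
            raise ValueError("counts must be >= 1")
        if count == 1:
            axes.append(np.array([lo], dtype=float))
        elif spacing == "log":
            if lo <= 0 or hi <= 0:
                raise ValueError("log spacing requires positive bounds")
            axes.append(np.geomspace(lo, hi, count))
        elif spacing == "linear":
            axes.append(np.linspace(lo, hi, count))
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
    mesh = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([m.ravel() for m in mesh], axis=1)
    return [{n: float(v) for n, v in zip(names, row)} for row in nodes]


# ---------------------------------------------------------------------------
# HDF5 artifacts


def _open(path, mode="r"):
    try:
        return h5py.File(path, mode)
    except (OSError, ValueError) as exc:
        raise SchemaError(f"cannot open artifact file {path}: {exc}") from exc


def _check_schema(group, kind: str) -> None:
    found_kind = group.attrs.get("kind")
    version = group.attrs.get("schema_version")
    if found_kind != kind:
        raise SchemaError(f"expected a {kind!r} artifact, found {found_kind!r}")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"schema version mismatch: file has {version}, expected {SCHEMA_VERSION}"
        )


def _write_report(group, report: GreedyReport) -> None:
    g = group.create_group("report")
    g.create_dataset("eps_sequence", data=np.asarray(report.eps_sequence))
    g.attrs["selected"] = json.dumps(report.selected)
    g.attrs["training_set"] = json.dumps(report.training_set)
    g.attrs["eps_tol"] = report.eps_tol
    g.attrs["status"] = report.status
    g.attrs["wall_time"] = report.wall_time
    g.attrs["n_initial"] = report.n_initial


def _read_report(group) -> GreedyReport:
    g = group["report"]
    return GreedyReport(
        eps_sequence=[float(e) for e in g["eps_sequence"][()]],
        selected=json.loads(g.attrs["selected"]),
        training_set=json.loads(g.attrs["training_set"]),
        eps_tol=float(g.attrs["eps_tol"]),
        status=str(g.attrs["status"]),
        wall_time=float(g.attrs["wall_time"]),
        n_initial=int(g.attrs["n_initial"]),
    )


def save_basis(path, basis: ReducedBasis) -> None:
    with _open(path, "w") as fh:
        g = fh.create_group("basis")
        g.attrs["kind"] = "basis"
        g.attrs["schema_version"] = SCHEMA_VERSION
        g.create_dataset("V", data=basis.V)
        if basis.report is not None:
            _write_report(g, basis.report)


def load_basis(path) -> ReducedBasis:
    with _open(path) as fh:
        if "basis" not in fh:
            raise SchemaError(f"{path} holds no basis group")
        g = fh["basis"]
        _check_schema(g, "basis")
        report = _read_report(g) if "report" in g else None
        return ReducedBasis(g["V"][()], report=report)


def save_reduced_model(path, model: ReducedModel, include_basis: bool = False) -> None:
    with _open(path, "w") as fh:
        g = fh.create_group("reduced_model")
        g.attrs["kind"] = "reduced_model"
        g.attrs["schema_version"] = SCHEMA_VERSION
        comps = g.create_group("components")
        for q, comp in enumerate(model.components):
            ds = comps.create_dataset(f"A_{q}", data=comp.matrix)
            ds.attrs["expression"] = comp.expression or comp.label
            ds.attrs["label"] = comp.label
        g.create_dataset("output_matrix", data=model.output_matrix)
        g.attrs["output_labels"] = json.dumps(model.output_labels)
        g.create_dataset("initial", data=model.initial)
        g.attrs["nominal"] = json.dumps(model.nominal)
        g.attrs["domain"] = json.dumps(model.domain)
        g.attrs["trained_range"] = json.dumps(model.trained_range)
        if include_basis and model.basis is not None:
            b = g.create_group("basis")
            b.attrs["kind"] = "basis"
            b.attrs["schema_version"] = SCHEMA_VERSION
            b.create_dataset("V", data=model.basis.V)
            if model.basis.report is not None:
                _write_report(b, model.basis.report)


def _coefficient_from_expression(expr_str: str):
    expr = _Expression(expr_str)

    def coefficient(params: Mapping[str, float]) -> float:
        return float(expr(params))

    return coefficient


def load_reduced_model(path) -> ReducedModel:
    with _open(path) as fh:
        if "reduced_model" not in fh:
            raise SchemaError(f"{path} holds no reduced_model group")
        g = fh["reduced_model"]
        _check_schema(g, "reduced_model")
        comps = []
        cg = g["components"]
        for q in range(len(cg)):
            ds = cg[f"A_{q}"]
            expr = str(ds.attrs["expression"])
            comps.append(
                ReducedComponent(
                    ds[()], _coefficient_from_expression(expr),
                    label=str(ds.attrs["label"]), expression=expr,
                )
            )
        basis = None
        if "basis" in g:
            report = _read_report(g["basis"]) if "report" in g["basis"] else None
            basis = ReducedBasis(g["basis"]["V"][()], report=report)
        return ReducedModel(
            components=comps,
            output_matrix=g["output_matrix"][()],
            output_labels=json.loads(g.attrs["output_labels"]),
            initial=g["initial"][()],
            basis=basis,
            nominal=json.loads(g.attrs["nominal"]),
            domain={k: tuple(v) for k, v in json.loads(g.attrs["domain"]).items()},
            trained_range={
                k: tuple(v) for k, v in json.loads(g.attrs["trained_range"]).items()
            },
        )


def save_trajectory(path, trajectory: FullTrajectory) -> None:
    with _open(path, "w") as fh:
        g = fh.create_group("trajectory")
        g.attrs["kind"] = "trajectory"
        g.attrs["schema_version"] = SCHEMA_VERSION
        g.create_dataset("times", data=trajectory.grid.times)
        g.create_dataset("states", data=trajectory.states)
        g.attrs["theta"] = json.dumps(trajectory.theta)


def load_trajectory(path) -> FullTrajectory:
    with _open(path) as fh:
        if "trajectory" not in fh:
            raise SchemaError(f"{path} holds no trajectory group")
        g = fh["trajectory"]
        _check_schema(g, "trajectory")
        return FullTrajectory(
            TimeGrid(g["times"][()]), g["states"][()], theta=json.loads(g.attrs["theta"])
        )


def write_manifest(path, config: RunConfig, extra: Mapping | None = None) -> None:
    """Record config hash, seeds and library versions for reproducibility."""
    import scipy

    from . import __version__

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest,
        "seed": config.seed,
        "versions": {
            "cmemor": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "h5py": h5py.__version__,
        },
    }
    if extra:
        manifest["extra"] = dict(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
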