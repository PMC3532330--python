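#!/usr/bin/env python
"""Full-scale offline POD-Greedy runs for the packaged study models.

These reproduce the complete basis-generation experiments:

  switch      81 log-equidistant training parameters on [0.005, 0.02]^2,
              eps_tol 1e-12
  oscillator  30 log-equidistant k4 values on [10, 100], eps_tol 1e-12

The default stepping scheme is the studies' discrete-evolution convention
(fixed-step backward Euler on the output grid; minutes per model).  With
``--method bdf`` the trajectories are instead solved to rtol 1e-8 with the
adaptive stiff integrator — hours for the oscillator, whose full-order
solves take minutes each.  Trajectories are cached on disk, so an
interrupted run resumes without re-simulating.  Usage:

    python scripts/train_full.py --model switch --out results/
    python scripts/train_full.py --model oscillator --out results/
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import cmemor as cm  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--model", choices=["switch", "oscillator"], required=True)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--eps-tol", type=float, default=1e-12)
    parser.add_argument("--grid-points", type=int, default=100)
    parser.add_argument("--method", choices=["euler", "bdf"], default="euler")
    parser.add_argument("--cache-dir", type=Path, default=Path("scratch/cache"))
    args = parser.parse_args()

    import logging

    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

    if args.model == "switch":
        fixture = cm.build_switch()
        counts = 9
    else:
        fixture = cm.build_oscillator()
        counts = {"k4": 30}

    op = fixture.operator()
    init = fixture.initial()
    grid = fixture.grid(args.grid_points)
    training = cm.make_training_set(fixture.varied, counts, "log")
    cache = cm.TrajectoryCache(fixture.model_key, args.cache_dir)

    def solver(theta, g):
        return cm.solve_full(op, theta, init, g, method=args.method)

    basis, report = cm.pod_greedy(
        solver, training, grid=grid, V_init=init.vector,
        eps_tol=args.eps_tol, cache=cache,
    )
    args.out.mkdir(parents=True, exist_ok=True)
    cm.save_basis(args.out / f"{fixture.name}_basis.h5", basis)
    model = cm.reduce(op, fixture.output(), init, basis)
    cm.save_reduced_model(args.out / f"{fixture.name}_reduced.h5", model, include_basis=True)
    print(
        f"{fixture.name}: basis size {basis.r} ({report.status}), "
        f"final eps {report.eps_sequence[-1]:.3e}, {report.wall_time / 3600:.2f} h"
    )


if __name__ == "__main__":
    main()
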