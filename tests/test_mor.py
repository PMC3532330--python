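"""POD, projection errors, POD-Greedy and reduced-model algebra."""

import numpy as np
import pytest
import scipy.linalg

import cmemor as cm
from cmemor.mor import TrajectoryCache, _orthonormalize_against


def _trajectory(states, T=1.0):
    states = np.asarray(states, dtype=float)
    return cm.FullTrajectory(cm.TimeGrid.uniform(T, states.shape[0]), states)


class TestPodFirstMode:
    def test_constant_trajectory_returns_normalized_state(self):
        p = np.array([3.0, 0.0, 4.0])
        S = np.tile(p, (6, 1))
        v = cm.pod_first_mode(S, np.full(6, 1 / 6))
        assert np.allclose(v, p / 5.0)

    def test_dominant_snapshot_wins(self):
        """Snapshots {10 e1, 0.1 e2} with equal weights: the correlation's
        top eigenvector is e1."""
        S = np.array([[10.0, 0.0], [0.0, 0.1]])
        v = cm.pod_first_mode(S, np.array([0.5, 0.5]))
        assert np.allclose(v, [1.0, 0.0], atol=1e-12)

    def test_matches_dense_correlation_eigenproblem(self, rng):
        """Method of snapshots == eigen-decomposition of the explicitly
        formed d x d correlation matrix."""
        S = rng.standard_normal((7, 5))
        w = rng.random(7) + 0.1
        v = cm.pod_first_mode(S, w)
        C = sum(wk * np.outer(sk, sk) for wk, sk in zip(w, S))
        lam, vecs = scipy.linalg.eigh(C)
        v_dense = vecs[:, -1]
        if v_dense[np.argmax(np.abs(v_dense))] < 0:
            v_dense = -v_dense
        assert np.abs(v - v_dense).max() < 1e-10

    def test_zero_trajectory_rejected(self):
        with pytest.raises(ValueError):
            cm.pod_first_mode(np.zeros((4, 3)), np.full(4, 0.25))


class TestProjectionError:
    def test_zero_when_v_spans_snapshots(self, rng):
        S = rng.standard_normal((6, 10))
        V, _ = np.linalg.qr(S.T)
        err = cm.projection_error(S, V[:, :6], np.full(6, 1 / 6))
        assert err <= 1e-20

    def test_empty_basis_gives_weighted_norms(self, rng):
        S = rng.standard_normal((5, 8))
        w = rng.random(5)
        err = cm.projection_error(S, np.zeros((8, 0)), w)
        assert np.isclose(err, w @ (S * S).sum(axis=1))

    def test_matches_direct_dense_computation(self, rng):
        S = rng.standard_normal((9, 6))
        V, _ = np.linalg.qr(rng.standard_normal((6, 2)))
        w = rng.random(9)
        direct = sum(
            wk * np.linalg.norm(sk - V @ (V.T @ sk)) ** 2 for wk, sk in zip(w, S)
        )
        assert np.isclose(cm.projection_error(S, V, w), direct, rtol=1e-12)

    def test_non_orthonormal_basis_rejected(self, rng):
        S = rng.standard_normal((4, 5))
        with pytest.raises(ValueError, match="orthonormal"):
            cm.projection_error(S, np.ones((5, 2)), np.full(4, 0.25))


class TestPodGreedy:
    def _low_rank_training(self, rng, d=40, k=4, n_theta=3, K=20):
        U, _ = np.linalg.qr(rng.standard_normal((d, k)))
        trajs = []
        for _ in range(n_theta):
            coeffs = rng.standard_normal((K, k))
            trajs.append(_trajectory(coeffs @ U.T))
        return U, trajs

    def test_exact_recovery_of_low_rank_training_set(self, rng):
        """Trajectories inside a k-dim subspace: at most k + N0 columns and
        final error at machine zero."""
        k = 4
        U, trajs = self._low_rank_training(rng, k=k)
        v0 = trajs[0].states[0]
        basis, report = cm.pod_greedy(
            trajs, [{"t": i} for i in range(len(trajs))],
            V_init=v0 / np.linalg.norm(v0), eps_tol=1e-20,
        )
        assert basis.r <= k + 1
        assert report.status == "converged"
        assert report.eps_sequence[-1] <= 1e-20

    def test_error_sequence_non_increasing(self, rng):
        _, trajs = self._low_rank_training(rng, d=30, k=6, n_theta=4)
        v0 = trajs[0].states[0]
        _, report = cm.pod_greedy(
            trajs, [{"t": i} for i in range(len(trajs))],
            V_init=v0 / np.linalg.norm(v0), eps_tol=1e-30, max_size=5,
        )
        eps = np.array(report.eps_sequence)
        assert (np.diff(eps) <= 1e-9 * eps[:-1]).all()

    def test_size_cap_reported(self, rng):
        _, trajs = self._low_rank_training(rng, d=30, k=8, n_theta=4)
        v0 = trajs[0].states[0]
        basis, report = cm.pod_greedy(
            trajs, [{"t": i} for i in range(len(trajs))],
            V_init=v0 / np.linalg.norm(v0), eps_tol=1e-30, max_size=3,
        )
        assert basis.r == 3
        assert report.status == "max_size"

    def test_solver_called_once_per_parameter(self, small_switch):
        calls = []
        op = small_switch.operator()
        init = small_switch.initial()
        grid = small_switch.grid(15)

        def solver(theta, g):
            calls.append(dict(theta))
            return cm.solve_full(op, theta, init, g)

        training = cm.make_training_set(small_switch.varied, 2, "log")
        cache = TrajectoryCache(small_switch.model_key)
        cm.pod_greedy(
            solver, training, grid=grid, V_init=init.vector,
            eps_tol=1e-6, cache=cache,
        )
        assert len(calls) == len(training)

    def test_disk_cache_round_trip(self, small_switch, tmp_path):
        op = small_switch.operator()
        init = small_switch.initial()
        grid = small_switch.grid(8)
        theta = {"u1": 0.01, "u2": 0.01}
        calls = []

        def solver(th, g):
            calls.append(1)
            return cm.solve_full(op, th, init, g)

        cache = TrajectoryCache(small_switch.model_key, tmp_path)
        first = cache.get_or_solve(theta, grid, solver)
        reloaded = TrajectoryCache(small_switch.model_key, tmp_path)
        second = reloaded.get_or_solve(theta, grid, solver)
        assert len(calls) == 1
        assert np.array_equal(first.states, second.states)

    def test_orthonormality_maintained(self, rng):
        _, trajs = self._low_rank_training(rng, d=50, k=10, n_theta=5)
        v0 = trajs[0].states[0]
        basis, _ = cm.pod_greedy(
            trajs, [{"t": i} for i in range(len(trajs))],
            V_init=v0 / np.linalg.norm(v0), eps_tol=1e-18,
        )
        defect = np.abs(basis.V.T @ basis.V - np.eye(basis.r)).max()
        assert defect < 1e-10


class TestReduce:
    def test_identity_basis_preserves_components(self, birth_death):
        op = birth_death.operator()
        d = op.state_space.dimension
        model = cm.reduce(op, birth_death.output(), birth_death.initial(), np.eye(d))
        for comp, full in zip(model.components, op.components):
            assert np.abs(comp.matrix - full.matrix.toarray()).max() < 1e-14

    def test_reduced_shapes(self, birth_death, rng):
        op = birth_death.operator()
        d = op.state_space.dimension
        V, _ = np.linalg.qr(rng.standard_normal((d, 3)))
        model = cm.reduce(op, birth_death.output(), birth_death.initial(), V)
        assert all(c.matrix.shape == (3, 3) for c in model.components)
        assert model.output_matrix.shape == (1, 3)
        assert model.initial.shape == (3,)

    def test_triple_products_match_dense_oracle(self, birth_death, rng):
        op = birth_death.operator()
        d = op.state_space.dimension
        V, _ = np.linalg.qr(rng.standard_normal((d, 4)))
        model = cm.reduce(op, birth_death.output(), birth_death.initial(), V)
        for comp, full in zip(model.components, op.components):
            dense = V.T @ full.matrix.toarray() @ V
            assert np.abs(comp.matrix - dense).max() < 1e-12


class TestSolveReducedAndReconstruct:
    def test_identity_basis_reproduces_full_output(self, birth_death):
        grid = birth_death.grid(15)
        op = birth_death.operator()
        d = op.state_space.dimension
        model = cm.reduce(op, birth_death.output(), birth_death.initial(), np.eye(d))
        reduced = cm.solve_reduced(model, None, grid)
        full = cm.solve_full(op, None, birth_death.initial(), grid)
        y_full = cm.observe(full, birth_death.output())
        assert np.abs(reduced.outputs - y_full).max() < 1e-6

    def test_identity_basis_euler_solve_is_discrete_consistent(self, birth_death):
        """With V = I, the backward-Euler reduced recursion reproduces the
        backward-Euler full recursion to round-off: discrete consistency."""
        grid = birth_death.grid(12)
        op = birth_death.operator()
        d = op.state_space.dimension
        model = cm.reduce(op, birth_death.output(), birth_death.initial(), np.eye(d))
        reduced = cm.solve_reduced(model, None, grid, method="euler")
        full = cm.solve_full(op, None, birth_death.initial(), grid, method="euler")
        assert np.abs(reduced.states - full.states).max() < 1e-11

    def test_zero_generator_keeps_reduced_state_constant(self):
        model = cm.ReducedModel(
            components=[],
            output_matrix=np.eye(2),
            output_labels=["a", "b"],
            initial=np.array([0.3, 0.7]),
        )
        traj = cm.solve_reduced(model, None, cm.TimeGrid.uniform(4.0, 9))
        assert np.allclose(traj.states, [0.3, 0.7])

    def test_reconstruct_identity_and_zero(self, rng):
        V, _ = np.linalg.qr(rng.standard_normal((8, 3)))
        Pr = rng.standard_normal((5, 3))
        assert np.allclose(cm.reconstruct(V, Pr), Pr @ V.T)
        assert not cm.reconstruct(V, np.zeros(3)).any()

    def test_reconstruct_training_snapshot(self, small_switch):
        """Reduce-then-solve at a training parameter, reconstruct the final
        state: entrywise close to the cached full snapshot (full and reduced
        share the backward-Euler stepping, so only reduction error remains)."""
        grid = small_switch.grid(20)
        op = small_switch.operator()
        init = small_switch.initial()
        training = cm.make_training_set(small_switch.varied, 2, "log")
        solver = lambda th, g: cm.solve_full(op, th, init, g, method="euler")
        basis, _ = cm.pod_greedy(
            solver, training, grid=grid, V_init=init.vector, eps_tol=1e-14
        )
        model = cm.reduce(op, small_switch.output(), init, basis)
        theta = training[0]
        reduced = cm.solve_reduced(model, theta, grid, method="euler")
        full = cm.solve_full(op, theta, init, grid, method="euler")
        # final-time snapshot reconstructed from the reduced state
        recon = cm.reconstruct(basis, reduced.states[-1])
        assert np.abs(recon - full.states[-1]).max() < 1e-4

    def test_dimension_mismatch_rejected(self, rng):
        V, _ = np.linalg.qr(rng.standard_normal((8, 3)))
        with pytest.raises(ValueError):
            cm.reconstruct(V, np.zeros(5))


def test_double_gram_schmidt_orthogonalizes(rng):
    V, _ = np.linalg.qr(rng.standard_normal((20, 6)))
    v_raw = rng.standard_normal(20)
    v, norm = _orthonormalize_against(v_raw, V)
    assert norm > 0
    assert np.abs(V.T @ v).max() < 1e-12
    assert np.isclose(np.linalg.norm(v), 1.0)
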