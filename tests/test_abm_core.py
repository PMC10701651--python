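"""Dynamics of the threshold diffusion model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from peerdiffusion.abm_core import (
    AgentState,
    InfluenceMatrix,
    ModelParams,
    Population,
    build_influence_matrix,
    detect_steady_state,
    run_simulation,
    run_to_steady,
    step,
)
from peerdiffusion.network_builder import ClassNetwork

import networkx as nx


def _population(pals, fas=None, class_ids=None):
    n = len(pals)
    return Population(
        ids=np.arange(n),
        class_ids=np.ones(n, dtype=int) if class_ids is None else class_ids,
        pal=np.asarray(pals, dtype=float),
        fas=np.full(n, 9.0) if fas is None else np.asarray(fas, dtype=float),
        influential=np.zeros(n, dtype=bool),
    )


def _net(edges, n, source="web", class_id=1):
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return ClassNetwork(class_id=class_id, graph=g, source=source)


def _mutual_pair(w=1.0):
    """Two agents influencing each other with full weight."""
    return InfluenceMatrix(
        w=np.array([[0.0, 1.0], [1.0, 0.0]]) * 1.0,
        isolated=np.zeros(2, dtype=bool),
    )


class TestInfluenceMatrix:
    def test_single_influencer_row_normalizes_to_one(self):
        pop = _population([1.0, 1.0])
        # web edge 1 -> 0 (sender 1, receiver 0): 1 influences 0
        net = _net([(1, 0, 0.4)], 2)
        W = build_influence_matrix(net, pop, ModelParams(0.1, 0.01))
        assert W.w[0, 1] == 1.0
        assert W.isolated.tolist() == [False, True]

    def test_weights_proportional(self):
        pop = _population([1.0] * 3)
        net = _net([(1, 0, 0.2), (2, 0, 0.6)], 3)
        W = build_influence_matrix(net, pop, ModelParams(0.1, 0.01))
        assert W.w[0, 1] == pytest.approx(0.25)
        assert W.w[0, 2] == pytest.approx(0.75)

    def test_nomination_orientation_reversed(self):
        """A nominated alter influences the nominating ego by default."""
        pop = _population([1.0, 1.0])
        net = _net([(0, 1, 0.5)], 2, source="nomination")  # ego 0 names alter 1
        W = build_influence_matrix(net, pop, ModelParams(0.1, 0.01))
        assert W.w[0, 1] == 1.0  # 1 influences 0
        net_web = _net([(0, 1, 0.5)], 2, source="web")  # 0 sends to 1
        W2 = build_influence_matrix(net_web, pop, ModelParams(0.1, 0.01))
        assert W2.w[1, 0] == 1.0

    def test_sent_orientation_flips(self):
        pop = _population([1.0, 1.0])
        net = _net([(0, 1, 0.5)], 2, source="web")
        W = build_influence_matrix(net, pop, ModelParams(0.1, 0.01, influence_orientation="sent"))
        assert W.w[0, 1] == 1.0


class TestStep:
    def test_threshold_exceeded_steps_up(self):
        pop = _population([1.0, 1.5])
        params = ModelParams(t_pal=0.1, i_pal=0.05, lambda_env=0.0)
        new = step(pop, _mutual_pair(), params)
        assert new.pal[0] == pytest.approx(1.05)

    def test_below_threshold_unchanged(self):
        pop = _population([1.0, 1.05])
        params = ModelParams(t_pal=0.1, i_pal=0.05, lambda_env=0.0)
        new = step(pop, _mutual_pair(), params)
        assert new.pal[0] == 1.0

    def test_downward_step_multiplicative(self):
        pop = _population([1.5, 1.0])
        params = ModelParams(t_pal=0.1, i_pal=0.05, lambda_env=0.0)
        new = step(pop, _mutual_pair(), params)
        assert new.pal[0] == pytest.approx(1.425)

    def test_isolate_follows_environment_only(self):
        pop = _population([1.0], fas=[12.0])
        W = InfluenceMatrix(w=np.zeros((1, 1)), isolated=np.ones(1, dtype=bool))
        params = ModelParams(t_pal=0.0, i_pal=0.05, lambda_env=0.2)
        env = np.array([1.5])
        new = step(pop, W, params, env=env)
        assert new.pal[0] == pytest.approx(1.05)  # pulled toward env target

    @given(
        st.lists(st.floats(0.1, 2.0), min_size=2, max_size=6),
        st.floats(0.0, 0.5),
        st.floats(0.0, 0.2),
        st.floats(0.0, 1.0),
    )
    def test_pal_stays_within_bounds(self, pals, t_pal, i_pal, lam):
        pop = _population(pals, fas=np.linspace(1, 12, len(pals)))
        rng = np.random.default_rng(0)
        w = rng.random((len(pals), len(pals)))
        np.fill_diagonal(w, 0.0)
        w /= w.sum(axis=1, keepdims=True)
        W = InfluenceMatrix(w=w, isolated=np.zeros(len(pals), dtype=bool))
        params = ModelParams(t_pal=t_pal, i_pal=i_pal, lambda_env=lam)
        traj_pop = pop
        for _ in range(5):
            traj_pop = step(traj_pop, W, params)
            assert (traj_pop.pal >= params.pal_bounds[0]).all()
            assert (traj_pop.pal <= params.pal_bounds[1]).all()

    @given(st.floats(0.0, 0.3), st.floats(0.0, 0.2))
    def test_homogeneous_fixed_point(self, t_pal, i_pal):
        pop = _population([0.9] * 4)
        w = (np.ones((4, 4)) - np.eye(4)) / 3
        W = InfluenceMatrix(w=w, isolated=np.zeros(4, dtype=bool))
        new = step(pop, W, ModelParams(t_pal=t_pal, i_pal=i_pal, lambda_env=0.0))
        assert new.pal.tolist() == [0.9] * 4

    def test_freezing_at_large_threshold(self):
        rng = np.random.default_rng(1)
        pop = _population(rng.uniform(0.2, 1.8, size=8), fas=rng.integers(2, 13, size=8))
        w = rng.random((8, 8))
        np.fill_diagonal(w, 0)
        w /= w.sum(axis=1, keepdims=True)
        W = InfluenceMatrix(w=w, isolated=np.zeros(8, dtype=bool))
        params = ModelParams(t_pal=5.0, i_pal=0.1)  # larger than any possible gap
        traj = run_simulation(pop, W, params, 20)
        assert np.array_equal(traj.class_means[0], traj.class_means[-1])

    def test_larger_i_pal_never_smaller_step(self):
        pop = _population([1.0, 1.5])
        params_small = ModelParams(t_pal=0.1, i_pal=0.02, lambda_env=0.0)
        params_big = ModelParams(t_pal=0.1, i_pal=0.08, lambda_env=0.0)
        d_small = abs(step(pop, _mutual_pair(), params_small).pal[0] - 1.0)
        d_big = abs(step(pop, _mutual_pair(), params_big).pal[0] - 1.0)
        assert d_big >= d_small

    def test_agent_order_irrelevant(self):
        """Synchronous update: permuting agents permutes outputs identically."""
        rng = np.random.default_rng(5)
        n = 10
        pals = rng.uniform(0.3, 1.8, n)
        fas = rng.integers(2, 13, n).astype(float)
        w = rng.random((n, n))
        np.fill_diagonal(w, 0)
        w /= w.sum(axis=1, keepdims=True)
        params = ModelParams(t_pal=0.05, i_pal=0.03)
        perm = rng.permutation(n)
        out = step(_population(pals, fas),
                   InfluenceMatrix(w, np.zeros(n, bool)), params)
        out_p = step(_population(pals[perm], fas[perm]),
                     InfluenceMatrix(w[np.ix_(perm, perm)], np.zeros(n, bool)), params)
        assert out.pal[perm] == pytest.approx(out_p.pal)


class TestRunSimulation:
    def test_constant_when_homogeneous(self):
        pop = _population([1.1, 1.1])
        traj = run_simulation(pop, _mutual_pair(), ModelParams(0.0, 0.05, lambda_env=0.0), 30)
        assert np.all(traj.class_means == 1.1)

    def test_zero_days_returns_snapshot(self):
        pop = _population([0.8, 1.2])
        traj = run_simulation(pop, _mutual_pair(), ModelParams(0.1, 0.01), 0)
        assert traj.class_means.shape[0] == 1
        assert traj.cohort_mean[0] == pytest.approx(1.0)

    def test_two_agent_convergence_matches_scalar_recursion(self):
        """Mutually influencing pair approaches each other monotonically.

        The vectorized engine is checked against an independent scalar
        implementation of the same recursion.
        """
        params = ModelParams(t_pal=0.0, i_pal=0.02, lambda_env=0.0)
        pop = _population([0.8, 1.2])
        traj = run_simulation(pop, _mutual_pair(), params, 9, record_agents=True)

        p, q = 0.8, 1.2
        for d in range(1, 10):
            # scalar oracle: each agent moves toward the other by 2% if apart
            p_new = p * (1 + 0.02 * np.sign(q - p)) if q != p else p
            q_new = q * (1 + 0.02 * np.sign(p - q)) if p != q else q
            p, q = min(p_new, 2.0), min(q_new, 2.0)
            assert traj.snapshots[d] == pytest.approx([p, q])
        gaps = np.abs(traj.snapshots[:, 1] - traj.snapshots[:, 0])
        assert (np.diff(gaps) < 0).all()


class TestSteadyState:
    def test_constant_trajectory_day_zero(self):
        pop = _population([1.0, 1.0])
        traj = run_simulation(pop, _mutual_pair(), ModelParams(0.0, 0.05, lambda_env=0.0), 15)
        assert detect_steady_state(traj, tol=1e-6, window=10) == 0

    def test_oscillation_never_steady(self):
        means = np.array([[1.0], [1.2]] * 10)
        from peerdiffusion.abm_core import Trajectory
        traj = Trajectory(np.array([1]), means, means[:, 0])
        assert detect_steady_state(traj, tol=0.1, window=5) is None

    def test_convergence_day_within_analytic_bound(self):
        """Two-agent contraction settles within the linear-rate bound.

        The gap shrinks by at least i_pal*(p+q) >= i_pal*2*p_min each day
        until it falls below t_pal, after which nothing moves.
        """
        t_pal, i_pal = 0.05, 0.02
        params = ModelParams(t_pal=t_pal, i_pal=i_pal, lambda_env=0.0)
        pop = _population([0.8, 1.2])
        final, days, converged = run_to_steady(
            pop, _mutual_pair(), params, tol=1e-9, window=5, max_days=200
        )
        assert converged
        bound = int(np.ceil((0.4 - t_pal) / (i_pal * 2 * 0.8))) + 5  # + window
        assert days <= bound
        assert abs(final.pal[1] - final.pal[0]) <= t_pal + 1e-12


class TestAgentStateRoundtrip:
    def test_population_from_agents(self):
        agents = [AgentState(3, 1, 0.9, 8), AgentState(5, 1, 1.1, 10, True)]
        pop = Population.from_agents(agents)
        assert pop.agents() == agents
        assert pop.index_of(5) == 1


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(t_pal=-0.1, i_pal=0.0),
        dict(t_pal=0.1, i_pal=1.0),
        dict(t_pal=0.1, i_pal=0.01, lambda_env=1.5),
        dict(t_pal=0.1, i_pal=0.01, pal_bounds=(2.0, 0.1)),
        dict(t_pal=0.1, i_pal=0.01, influence_orientation="sideways"),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
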