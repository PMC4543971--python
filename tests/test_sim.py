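"""Stochastic network simulation: graph generation, event semantics,
registry bookkeeping, and exact small-graph distributions."""

import numpy as np
import pytest

from hetsis import sim
from hetsis.params import ModelParams

from .oracles import infected_count_distribution


def make_net(edges, types, states):
    n = len(types)
    return sim.NetworkState(
        node_type=np.array(types, dtype=np.uint8),
        node_state=np.array(states, dtype=np.uint8),
        edge_u=np.array([e[0] for e in edges], dtype=np.int64),
        edge_v=np.array([e[1] for e in edges], dtype=np.int64),
    )


def small_params(beta=0.8, psi_a=0.9, psi_b=0.3, mu=0.5, omega=0.7,
                 n_nodes=4, n_links=3, p_a=0.5):
    return ModelParams(beta=beta, psi_a=psi_a, psi_b=psi_b, p_a=p_a,
                       mu=mu, omega=omega, n_nodes=n_nodes, n_links=n_links)


class TestErGeneration:
    def test_three_nodes_three_links_is_the_triangle(self):
        for seed in (0, 1, 99):
            net = sim.generate_er_network(3, 3, seed)
            assert net.edge_set() == {(0, 1), (0, 2), (1, 2)}

    def test_exact_link_count_and_simplicity(self):
        net = sim.generate_er_network(500, 3000, seed=5)
        net.check_consistency()
        assert net.n_links == 3000

    def test_poissonian_degree_statistics(self):
        """G(N, K) degrees are asymptotically Poisson: variance ~ mean."""
        means, varis = [], []
        for seed in range(10):
            net = sim.generate_er_network(10000, 100000, seed=seed)
            deg = np.bincount(
                np.concatenate([net.edge_u, net.edge_v]), minlength=10000
            )
            means.append(deg.mean())
            varis.append(deg.var())
        assert np.mean(means) == pytest.approx(20.0, abs=1e-12)
        assert np.mean(varis) == pytest.approx(20.0, rel=0.05)

    def test_too_many_links_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_er_network(5, 11, seed=0)

    def test_dense_graph_supported(self):
        net = sim.generate_er_network(6, 14, seed=3)
        net.check_consistency()
        assert net.n_links == 14


class TestInitialCondition:
    def test_exact_type_and_infected_counts(self):
        net = sim.generate_er_network(100, 500, seed=0)
        net = sim.assign_initial_condition(net, 0.75, 0.2, seed=1)
        assert int(np.sum(net.node_type == 0)) == 75
        assert net.n_infected() == 20

    def test_zero_prevalence_start_is_frozen(self):
        net = sim.generate_er_network(50, 100, seed=0)
        net = sim.assign_initial_condition(net, 0.5, 0.0, seed=1)
        p = small_params(n_nodes=50, n_links=100)
        ts = sim.gillespie_run(net, p, t_max=10.0, seed=2)
        assert ts.n_events == 0
        assert ts.extinct

    def test_type_and_state_assignments_independent(self):
        """Infected fraction among type A equals that among type B within
        binomial error, pooled over seeds."""
        n, reps = 1000, 200
        base = sim.generate_er_network(n, 5000, seed=0)
        diff = []
        for seed in range(reps):
            net = sim.assign_initial_condition(base, 0.5, 0.3, seed=seed)
            inf_a = np.mean(net.node_state[net.node_type == 0])
            inf_b = np.mean(net.node_state[net.node_type == 1])
            diff.append(inf_a - inf_b)
        se = np.std(diff) / np.sqrt(reps)
        assert abs(np.mean(diff)) < 3 * se + 1e-12


class TestRewireEvent:
    def test_two_node_graph_has_no_target(self):
        net = make_net([(0, 1)], [0, 0], [0, 1])
        before = net.edge_set()
        sim.rewire_event(net, (0, 1), np.random.default_rng(0))
        assert net.edge_set() == before

    def test_saturated_neighbourhood_is_noop(self):
        # S hub 0 connected to every other susceptible and one infected leaf
        net = make_net([(0, 1), (0, 2), (0, 3)], [0, 0, 0, 0], [0, 0, 0, 1])
        before = net.edge_set()
        sim.rewire_event(net, (0, 3), np.random.default_rng(0))
        assert net.edge_set() == before

    def test_star_rewiring_moves_one_link_to_an_isolated_node(self):
        # S center 0, infected leaf 1, isolated susceptibles 2..6
        net = make_net([(0, 1)], [0] * 7, [0, 1, 0, 0, 0, 0, 0])
        sim.rewire_event(net, (0, 1), np.random.default_rng(1))
        deg = np.bincount(
            np.concatenate([net.edge_u, net.edge_v]), minlength=7
        )
        assert deg[0] == 1  # S center keeps its degree
        assert deg[1] == 0  # infected leaf lost the link
        assert np.sum(deg[2:] == 1) == 1  # exactly one isolated S gained it

    def test_non_si_link_raises(self):
        net = make_net([(0, 1)], [0, 0], [1, 1])
        with pytest.raises(AssertionError, match="S-I"):
            sim.rewire_event(net, (0, 1), np.random.default_rng(0))


class TestGillespieRun:
    def test_single_exponential_clock(self):
        """One infected node, beta=omega=0: extinction time is Exp(mu)."""
        net = make_net([(0, 1)], [0, 0], [1, 0])
        p = small_params(beta=0.0, omega=0.0, mu=0.5, n_nodes=2, n_links=1)
        times = []
        rng = np.random.default_rng(7)
        for _ in range(10000):
            ts = sim.gillespie_run(
                net, p, t_max=1e3, seed=int(rng.integers(2**31 - 1))
            )
            times.append(ts.t_end)
        mean = np.mean(times)
        se = np.std(times) / np.sqrt(len(times))
        assert abs(mean - 1 / p.mu) < 3 * se

    def test_pure_death_harmonic_extinction_time(self):
        """beta=0: extinction of I0 infected is a pure-death process with
        expected absorption time sum_i 1/(i mu)."""
        n, i0, mu = 40, 10, 1.0
        net = sim.generate_er_network(n, 80, seed=0)
        net = sim.assign_initial_condition(net, 0.5, i0 / n, seed=1)
        p = small_params(beta=0.0, omega=0.0, mu=mu, n_nodes=n, n_links=80)
        times = []
        rng = np.random.default_rng(8)
        for _ in range(4000):
            ts = sim.gillespie_run(
                net, p, t_max=1e3, seed=int(rng.integers(2**31 - 1))
            )
            times.append(ts.t_end)
        expected = sum(1.0 / (i * mu) for i in range(1, i0 + 1))
        se = np.std(times) / np.sqrt(len(times))
        assert abs(np.mean(times) - expected) < 3 * se

    def test_competing_transmission_odds_on_path(self):
        """S-I-S path, mu=omega=0: the left S is infected first with
        probability psi_left/(psi_left+psi_right) = 0.65/0.70."""
        net = make_net([(0, 1), (1, 2)], [0, 0, 1], [0, 1, 0])
        p = ModelParams(beta=1.0, psi_a=0.65, psi_b=0.05, p_a=0.5,
                        mu=1e-12, omega=0.0, n_nodes=3, n_links=2)
        wins = 0
        reps = 10000
        rng = np.random.default_rng(9)
        for _ in range(reps):
            ts = sim.gillespie_run(
                net, p, t_max=1e6, stop_above_ninf=2,
                seed=int(rng.integers(2**31 - 1)), in_place=False,
            )
            assert ts.established
            # which S became infected: i_a counts type-a infected; node 0 is
            # type a, node 2 type b, node 1 (type a) started infected
            if ts.i_a[-1] * 3 == pytest.approx(2):
                wins += 1
        p_left = 0.65 / 0.70
        se = np.sqrt(p_left * (1 - p_left) / reps)
        assert abs(wins / reps - p_left) < 3 * se

    def test_extinction_is_absorbing(self):
        net = make_net([(0, 1), (1, 2)], [0, 1, 0], [1, 0, 0])
        p = small_params(n_nodes=3, n_links=2)
        ts = sim.gillespie_run(net, p, t_max=1e3, stop_on_extinction=False,
                               seed=4)
        assert ts.prevalence[-1] == 0.0
        # after extinction no further events fire: the time series is flat
        ext_idx = np.argmax(ts.prevalence == 0)
        assert np.all(ts.prevalence[ext_idx:] == 0)

    def test_si_registry_matches_recomputation(self, main_params):
        """The incrementally maintained S-I counts agree with a from-scratch
        recomputation on the final network."""
        net = sim.generate_er_network(2000, 20000, seed=10)
        net = sim.assign_initial_condition(net, 0.75, 0.3, seed=11)
        p = main_params.replace(n_nodes=2000, n_links=20000)
        work = net.copy()
        ts = sim.gillespie_run(work, p, t_max=50.0, sample_interval=50.0,
                               seed=12, in_place=True)
        si = work.si_links()
        si_a = sum(1 for s, i in si if work.node_type[s] == 0)
        si_b = len(si) - si_a
        assert ts.si_a[-1] * 2000 == si_a
        assert ts.si_b[-1] * 2000 == si_b
        work.check_consistency()

    def test_conserved_quantities(self, main_params):
        net = sim.generate_er_network(1000, 10000, seed=13)
        net = sim.assign_initial_condition(net, 0.75, 0.4, seed=14)
        p = main_params.replace(n_nodes=1000, n_links=10000)
        work = net.copy()
        sim.gillespie_run(work, p, t_max=200.0, seed=15, in_place=True)
        assert work.n_links == net.n_links
        np.testing.assert_array_equal(work.node_type, net.node_type)
        work.check_consistency()

    def test_complete_graph_distribution_matches_master_equation(self):
        """On a complete graph (where rewiring is always a no-op) the
        empirical infected-count distribution at a fixed time matches the
        exact 16-state master equation."""
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        types, states = [0, 0, 1, 1], [1, 0, 0, 0]
        beta, psi, mu, omega, T = 0.8, (0.9, 0.3), 0.5, 0.7, 1.5
        exact = infected_count_distribution(
            4, edges, types, states, beta, psi, mu, omega, T
        )
        net = make_net(edges, types, states)
        p = small_params(beta=beta, psi_a=psi[0], psi_b=psi[1], mu=mu,
                         omega=omega, n_nodes=4, n_links=6)
        reps = 10000
        counts = np.zeros(5)
        rng = np.random.default_rng(16)
        for _ in range(reps):
            ts = sim.gillespie_run(
                net, p, t_max=T, stop_on_extinction=False,
                sample_interval=T, seed=int(rng.integers(2**31 - 1)),
            )
            counts[int(round(ts.prevalence[-1] * 4))] += 1
        emp = counts / reps
        se = np.sqrt(exact * (1 - exact) / reps)
        assert np.all(np.abs(emp - exact) <= 3 * se + 1e-9)

    def test_path_graph_distribution_exercises_rewiring(self):
        """On a path graph rewiring changes the topology; the joint chain
        over (graph, states) is enumerated exactly and compared."""
        edges = [(0, 1), (1, 2), (2, 3)]
        types, states = [0, 1, 0, 1], [1, 0, 0, 0]
        beta, psi, mu, omega, T = 0.8, (0.9, 0.3), 0.5, 0.7, 2.0
        exact = infected_count_distribution(
            4, edges, types, states, beta, psi, mu, omega, T
        )
        net = make_net(edges, types, states)
        p = small_params(beta=beta, psi_a=psi[0], psi_b=psi[1], mu=mu,
                         omega=omega, n_nodes=4, n_links=3)
        reps = 10000
        counts = np.zeros(5)
        rng = np.random.default_rng(17)
        for _ in range(reps):
            ts = sim.gillespie_run(
                net, p, t_max=T, stop_on_extinction=False,
                sample_interval=T, seed=int(rng.integers(2**31 - 1)),
            )
            counts[int(round(ts.prevalence[-1] * 4))] += 1
        emp = counts / reps
        se = np.sqrt(exact * (1 - exact) / reps)
        assert np.all(np.abs(emp - exact) <= 3 * se + 1e-9)


class TestProtocols:
    def test_adapted_restart_preserves_topology_and_types(self):
        net = sim.generate_er_network(200, 1000, seed=20)
        net = sim.assign_initial_condition(net, 0.75, 0.5, seed=21)
        restart = sim.adapted_restart_state(net, n_infected=20, seed=22)
        assert restart.edge_set() == net.edge_set()
        np.testing.assert_array_equal(restart.node_type, net.node_type)
        assert restart.n_infected() == 20
        other = sim.adapted_restart_state(net, n_infected=20, seed=23)
        assert other.edge_set() == restart.edge_set()
        assert not np.array_equal(other.node_state, restart.node_state)

    def test_restart_count_validated(self):
        net = sim.generate_er_network(10, 20, seed=0)
        with pytest.raises(ValueError):
            sim.adapted_restart_state(net, n_infected=11, seed=0)

    def test_degree_stats_identities(self):
        net = sim.generate_er_network(1000, 10000, seed=24)
        net = sim.assign_initial_condition(net, 0.75, 0.0, seed=25)
        ds = sim.degree_stats(net)
        assert 0.75 * ds.k_a + 0.25 * ds.k_b == pytest.approx(20.0)
        # fresh ER network: types independent of degree
        assert ds.degree_ratio == pytest.approx(1.0, abs=0.1)

    def test_degree_stats_regular_triangle(self):
        net = make_net([(0, 1), (0, 2), (1, 2)], [0, 0, 1], [0, 0, 0])
        ds = sim.degree_stats(net)
        assert ds.k_a == 2.0 and ds.k_b == 2.0
        assert ds.degree_ratio == 1.0

    def test_degree_stats_missing_type(self):
        net = make_net([(0, 1)], [0, 0], [0, 0])
        ds = sim.degree_stats(net)
        assert ds.k_b is None and ds.degree_ratio is None

    def test_run_to_stationarity_flags_extinction_below_threshold(
        self, main_params
    ):
        p = main_params.replace(beta=0.004, n_nodes=1000, n_links=10000)
        net = sim.generate_er_network(1000, 10000, seed=26)
        net = sim.assign_initial_condition(net, 0.75, 0.01, seed=27)
        _, summary = sim.run_to_stationarity(net, p, seed=28, t_cap=5e4)
        assert summary.extinct
        assert summary.prevalence == 0.0

    def test_run_to_stationarity_endemic_at_high_beta(self, main_params):
        p = main_params.replace(n_nodes=1000, n_links=10000)
        net = sim.generate_er_network(1000, 10000, seed=29)
        net = sim.assign_initial_condition(net, 0.75, 0.5, seed=30)
        adapted, summary = sim.run_to_stationarity(
            net, p, seed=31, window=2000.0, t_cap=4e4,
        )
        assert not summary.extinct
        assert summary.prevalence > 0.5
        assert adapted.n_links == net.n_links


class TestInvasionScan:
    def test_limiting_regimes_and_monotonicity(self):
        """Extinction probability ~1 far below threshold, ~0 far above, and
        non-increasing along the grid within binomial error."""
        n, k = 500, 2500
        p = ModelParams(beta=0.1, psi_a=0.5, psi_b=0.5, p_a=0.5, mu=0.05,
                        omega=0.1, n_nodes=n, n_links=k)
        base = sim.generate_er_network(n, k, seed=40)
        base = sim.assign_initial_condition(base, 0.5, 0.0, seed=41)

        def factory(seed):
            return sim.adapted_restart_state(base, n_infected=5, seed=seed)

        from hetsis.sim import _extinction_probability

        rng = np.random.default_rng(42)
        # homogeneous threshold ~ (mu+omega)/(psi <k>) = 0.03
        betas = [0.006, 0.03, 0.15, 0.75]
        probs = [
            _extinction_probability(factory, p, b, 60, rng, 0.1, 2e3)
            for b in betas
        ]
        assert probs[0] > 0.9
        assert probs[-1] < 0.35
        noise = 3 * np.sqrt(0.25 / 60)
        assert all(
            probs[j + 1] <= probs[j] + noise for j in range(len(probs) - 1)
        )

    def test_threshold_bracketing_error(self):
        n, k = 200, 1000
        p = ModelParams(beta=0.1, psi_a=0.5, psi_b=0.5, p_a=0.5, mu=0.05,
                        omega=0.1, n_nodes=n, n_links=k)
        base = sim.generate_er_network(n, k, seed=43)
        base = sim.assign_initial_condition(base, 0.5, 0.0, seed=44)

        def factory(seed):
            return sim.adapted_restart_state(base, n_infected=5, seed=seed)

        with pytest.raises(ValueError, match="outside scanned range"):
            sim.estimate_invasion_threshold_sim(
                factory, p, [1e-4, 2e-4], n_runs=20, seed=45, t_max=500.0
            )
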