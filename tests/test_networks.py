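"""Tests of graph generators, percolation analytics, mean field and the agent model."""

import math

import networkx as nx
import numpy as np
import pytest

from behaviordyn.networks import (
    DegreeMoments,
    ImmunityConfig,
    MeanFieldSISParams,
    config_supercritical_margin,
    connectivity_regime,
    degree_moments,
    estimate_percolation_threshold,
    generate_ba_graph,
    generate_configuration_graph,
    generate_poisson_graph,
    giant_component_fraction,
    meanfield_degree_based,
    meanfield_homogeneous,
    outbreak_coupling,
    remove_immune,
    solve_outbreak_fraction,
    simulate_network_contagion,
)


class TestGenerators:
    def test_poisson_extremes(self):
        assert generate_poisson_graph(10, 0.0, seed=1).number_of_edges() == 0
        assert generate_poisson_graph(10, 1.0, seed=1).number_of_edges() == 45

    def test_poisson_p_out_of_range(self):
        with pytest.raises(ValueError):
            generate_poisson_graph(10, 1.5)

    def test_poisson_mean_degree(self):
        """Mean degree over 30 seeds within 3 standard errors of (n-1)p."""
        n, p = 1000, 0.01
        means = [
            2 * generate_poisson_graph(n, p, seed=s).number_of_edges() / n
            for s in range(30)
        ]
        expected = (n - 1) * p
        se = math.sqrt(2 * p * (1 - p) * (n - 1) / n) / math.sqrt(30)
        assert abs(np.mean(means) - expected) <= 3 * se

    def test_poisson_reproducible(self):
        a = generate_poisson_graph(200, 0.02, seed=7)
        b = generate_poisson_graph(200, 0.02, seed=7)
        assert set(a.edges()) == set(b.edges())

    def test_ba_is_tree(self):
        g = generate_ba_graph(500, seed=3)
        assert g.number_of_edges() == 499
        assert nx.is_connected(g)
        assert sum(d for _, d in g.degree()) == 2 * 499

    def test_ba_rejects_tiny(self):
        with pytest.raises(ValueError):
            generate_ba_graph(1)

    def test_ba_powerlaw_exponent(self):
        """Hill/Clauset-style MLE of the degree-tail exponent lies in the
        scale-free band (>= 2; the ideal preferential-attachment value is 3)."""
        exponents = []
        for s in range(20):
            degs = np.array([d for _, d in generate_ba_graph(5000, seed=s).degree()])
            tail = degs[degs >= 2]  # leaves of the tree sit below the power-law tail
            exponents.append(1.0 + tail.size / np.sum(np.log(tail / 1.5)))
        assert np.mean(exponents) >= 2.0

    def test_configuration_trivial(self):
        assert generate_configuration_graph([0, 0, 0]).number_of_edges() == 0
        g = generate_configuration_graph([1, 1], seed=2)
        assert set(g.edges()) == {(0, 1)}

    def test_configuration_regular_mean_degree(self):
        g = generate_configuration_graph([3] * 2000, seed=5)
        assert degree_moments(g).mean_deg == pytest.approx(3.0, rel=0.02)

    def test_configuration_odd_sum_rejected(self):
        with pytest.raises(ValueError):
            generate_configuration_graph([1, 1, 1])


class TestImmunityAndComponents:
    def test_removal_extremes(self):
        g = generate_poisson_graph(50, 0.1, seed=1)
        same, kept = remove_immune(g, ImmunityConfig(0.0, seed=1))
        assert same.number_of_nodes() == 50 and kept.size == 50
        empty, kept = remove_immune(g, ImmunityConfig(1.0, seed=1))
        assert empty.number_of_nodes() == 0 and kept.size == 0

    def test_removal_binomial_count(self):
        g = nx.empty_graph(10_000)
        survivors = [
            remove_immune(g, ImmunityConfig(0.3, seed=s))[0].number_of_nodes()
            for s in range(30)
        ]
        se = math.sqrt(10_000 * 0.3 * 0.7) / math.sqrt(30)
        assert abs(np.mean(survivors) - 7000) <= 3 * se

    def test_giant_fraction_trivial(self):
        assert giant_component_fraction(nx.complete_graph(8)) == 1.0
        g = nx.disjoint_union(nx.path_graph(7), nx.path_graph(3))
        assert giant_component_fraction(g) == 0.7
        assert giant_component_fraction(nx.Graph()) == 0.0

    def test_giant_fraction_against_union_find_oracle(self, rng):
        """Independent union-find largest-component size on 100 small graphs."""

        def uf_largest(n, edges):
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for u, v in edges:
                parent[find(u)] = find(v)
            from collections import Counter

            return max(Counter(find(x) for x in range(n)).values()) if n else 0

        for _ in range(100):
            n = int(rng.integers(1, 51))
            g = generate_poisson_graph(n, float(rng.uniform(0, 0.2)), seed=int(rng.integers(2**31)))
            assert giant_component_fraction(g) == uf_largest(n, list(g.edges())) / n

    def test_er_giant_component_matches_fixed_point(self):
        """Mean degree 2: giant fraction solves r = 1 - exp(-2r)."""
        g = generate_poisson_graph(10_000, 2.0 / 9999, seed=11)
        assert giant_component_fraction(g) == pytest.approx(
            solve_outbreak_fraction(2.0), abs=0.02
        )


class TestOutbreakEquation:
    def test_subcritical_root_is_zero(self):
        assert solve_outbreak_fraction(1.0) == 0.0
        assert solve_outbreak_fraction(0.3) == 0.0

    def test_known_value_at_c2(self):
        # Frozen from bisection on the monotone map r -> 1 - exp(-2r).
        assert solve_outbreak_fraction(2.0) == pytest.approx(0.7968121300, abs=1e-9)

    def test_saturates_for_large_c(self):
        assert solve_outbreak_fraction(50.0) >= 1 - 1e-15

    def test_negative_coupling_rejected(self):
        with pytest.raises(ValueError):
            solve_outbreak_fraction(-0.1)

    def test_monotone_and_continuous_in_c(self):
        grid = np.linspace(0.5, 8.0, 200)
        step = grid[1] - grid[0]
        vals = np.array([solve_outbreak_fraction(c) for c in grid])
        assert np.all(np.diff(vals) >= 0)
        # the slope of r(c) is bounded by 2 just above criticality
        assert np.max(np.abs(np.diff(vals))) < 2.5 * step

    def test_coupling_inverts_outbreak_fraction(self):
        for c in (1.5, 2.0, 4.0):
            assert outbreak_coupling(solve_outbreak_fraction(c)) == pytest.approx(c, rel=1e-9)


class TestThresholdAndRegimes:
    def test_percolation_threshold_small_sweep(self):
        coupling = np.arange(0.5, 1.65, 0.1)
        res = estimate_percolation_threshold(
            1000, 0.0, coupling / 1000, reps=10, seed=21
        )
        assert 0.7 <= res.coupling_at_crossing <= 1.3

    def test_grid_above_threshold_warns(self):
        with pytest.warns(RuntimeWarning):
            res = estimate_percolation_threshold(
                500, 0.0, np.array([3.0, 4.0]) / 500, reps=5, seed=2
            )
        assert res.crossed_at_first_point

    def test_grid_below_threshold_signals(self):
        with pytest.raises(RuntimeError, match="no threshold"):
            estimate_percolation_threshold(
                500, 0.0, np.array([0.1, 0.2]) / 500, reps=5, seed=2
            )

    def test_connectivity_regimes(self):
        assert connectivity_regime(1000, 0.0, 0.0005) == "subcritical"
        assert connectivity_regime(1000, 0.0, 0.05) == "connected-regime"
        # 1/n = 0.001 < 0.005 < ln(1000)/1000 ~ 0.0069
        assert connectivity_regime(1000, 0.0, 0.005) == "supercritical"

    def test_connectivity_degenerate(self):
        with pytest.raises(ValueError):
            connectivity_regime(10, 0.9, 0.5)

    @pytest.mark.parametrize(
        "mean, second, sign",
        [(1.0, 1.0, -1), (2.0, 4.0, 0), (3.0, 9.0, 1)],
    )
    def test_configuration_margin(self, mean, second, sign):
        margin = config_supercritical_margin(DegreeMoments(mean, second))
        assert np.sign(margin) == sign


class TestMeanField:
    def test_homogeneous_absorbing_states(self):
        t = np.linspace(0, 10, 11)
        assert np.all(meanfield_homogeneous(0.1, 4, 0.0, t) == 0.0)
        assert np.all(meanfield_homogeneous(0.0, 4, 0.3, t) == 0.3)

    def test_homogeneous_matches_ode_oracle(self):
        from scipy.integrate import solve_ivp

        lam, k, i0 = 0.1, 4.0, 0.01
        t = np.linspace(0, 20, 50)
        sol = solve_ivp(lambda _t, y: lam * k * y * (1 - y), (0, 20), [i0],
                        t_eval=t, rtol=1e-12, atol=1e-14)
        assert np.max(np.abs(meanfield_homogeneous(lam, k, i0, t) - sol.y[0])) <= 1e-8

    def _params(self):
        # degrees {2, 6} with equal mass: <k> = 4, <k^2> = 20
        return MeanFieldSISParams(
            lam=0.1, i0=0.01, degrees=np.array([2.0, 6.0]), pk=np.array([0.5, 0.5])
        )

    def test_time_scales_from_moments(self):
        p = self._params()
        assert p.tau == pytest.approx(20 / (0.1 * 16))           # printed form: 12.5
        assert p.tau_consistent == pytest.approx(4 / (0.1 * 16))  # 2.5

    def test_initial_condition(self):
        res = meanfield_degree_based(self._params(), np.array([0.0]))
        assert np.all(res.i_k_closed[:, 0] == 0.01)
        assert np.all(res.i_k_ode[:, 0] == pytest.approx(0.01))

    def test_closed_form_with_consistent_tau_matches_ode_early(self):
        """The exponential early-time solution tracks the density equations
        when its time constant is the self-consistent <k>-numerator form."""
        p = self._params()
        t = np.linspace(0.0, 0.25 * p.tau_consistent, 30)
        res = meanfield_degree_based(p, t, tau=p.tau_consistent)
        rel = np.abs(res.i_k_closed - res.i_k_ode) / res.i_k_ode
        assert rel.max() <= 0.05

    def test_closed_form_capped_at_one(self):
        p = self._params()
        res = meanfield_degree_based(p, np.array([0.0, 100.0]))
        assert np.all(res.i_k_closed <= 1.0)

    def test_requires_heterogeneous_moments(self):
        with pytest.raises(ValueError):
            MeanFieldSISParams(0.1, 0.01, np.array([1.0]), np.array([1.0]))


class TestAgentContagion:
    def test_silent_without_seeds_or_spontaneous(self):
        g = generate_poisson_graph(100, 0.05, seed=1)
        out = simulate_network_contagion(g, 0.5, 0.0, [], 20, seed=2, reps=3)
        assert np.all(out == 0)

    def test_complete_graph_instant_spread(self):
        g = nx.complete_graph(30)
        out = simulate_network_contagion(g, 1.0, 0.0, [0], 5, seed=3, immune_set=[1, 2])
        assert out[0, 1] == 28  # everyone but the two immune nodes

    def test_counts_monotone_and_immune_respected(self):
        g = generate_poisson_graph(300, 0.02, seed=4)
        immune = list(range(0, 300, 3))
        seeds = [1]
        out = simulate_network_contagion(
            g, 0.4, 0.01, seeds, 40, seed=5, reps=5, immune_set=immune
        )
        assert np.all(np.diff(out, axis=1) >= 0)
        assert np.all(out <= 300 - len(immune))

    def test_immune_seed_rejected(self):
        g = nx.path_graph(5)
        with pytest.raises(ValueError):
            simulate_network_contagion(g, 0.5, 0.0, [0], 5, immune_set=[0])

    def test_zero_behavioral_degree_never_spreads(self):
        g = nx.complete_graph(10)
        out = simulate_network_contagion(
            g, 1.0, 0.0, [0], 5, seed=1, behavioral_degree=np.zeros(10)
        )
        assert np.all(out == 1)

    def test_deterministic_under_seed(self):
        g = generate_poisson_graph(200, 0.03, seed=6)
        a = simulate_network_contagion(g, 0.3, 0.001, [0], 30, seed=9, reps=4)
        b = simulate_network_contagion(g, 0.3, 0.001, [0], 30, seed=9, reps=4)
        assert np.array_equal(a, b)

    def test_denser_network_spreads_no_slower(self):
        """Median time to 50% adoption does not increase with density."""

        def median_t50(p, seed):
            g = generate_poisson_graph(400, p, seed=seed)
            out = simulate_network_contagion(g, 0.5, 0.0, [0], 60, seed=seed, reps=11)
            times = []
            for row in out:
                hit = np.nonzero(row >= 200)[0]
                times.append(hit[0] if hit.size else np.inf)
            return np.median(times)

        assert median_t50(0.02, seed=31) >= median_t50(0.08, seed=31)

    def test_mc_outbreak_matches_analytic_fraction(self):
        """Deterministic transmission on an ER graph with coupling 2: the
        conditional final fraction approaches the outbreak-equation root."""
        n = 3000
        g = generate_poisson_graph(n, 2.0 / n, seed=13)
        rng = np.random.default_rng(14)
        finals = []
        for s in rng.integers(0, n, size=60):
            out = simulate_network_contagion(g, 1.0, 0.0, [int(s)], 50, seed=int(s), reps=1)
            finals.append(out[0, -1] / n)
        outbreaks = [f for f in finals if f > 0.01]
        assert np.mean(outbreaks) == pytest.approx(solve_outbreak_fraction(2.0), abs=0.05)
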