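"""Pair-approximation dynamics: closure, conservation, equilibria, correlations."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sisa import (
    ContactNetwork,
    CorrelationSet,
    NetworkSummary,
    PairwiseState,
    SISaParams,
    closed_form_steady_state,
    closure_triples,
    correlations_from_pairs,
    empirical_pair_counts,
    integrate_pairwise,
    pairwise_rhs,
    random_mixing_pairs,
    steady_state_pairwise,
    steady_state_wellmixed,
)


def census_triples(graph: nx.Graph, states: dict, x: str, y: str, z: str) -> int:
    """Brute-force ordered triple count: X adjacent to Y adjacent to Z."""
    count = 0
    for centre in graph.nodes():
        if states[centre] != y:
            continue
        for left, right in itertools.permutations(graph.neighbors(centre), 2):
            if states[left] == x and states[right] == z:
                count += 1
    return count


class TestClosure:
    def test_no_triples_through_empty_class(self):
        net = NetworkSummary(N=10, k=3.0, phi=0.0)
        all_infected = PairwiseState(S=0, I=10, SS=0, SI=0, II=30)
        assert closure_triples(all_infected, net, "S", "S", "I") == 0.0
        assert closure_triples(all_infected, net, "I", "S", "I") == 0.0

    def test_mean_field_substitution_identity(self):
        """At phi=0 with uncorrelated pairs the closure reduces to the
        mean-field triple density ((k-1)/k) * k^2 * x*y*z * N exactly."""
        N, k = 100.0, 4.0
        net = NetworkSummary(N=N, k=k, phi=0.0)
        i = 0.3
        pairs = random_mixing_pairs(i, net)
        x, y, z = 1 - i, 1 - i, i  # S, S, I fractions
        expected = (k - 1.0) / k * k * k * x * y * z * N
        assert closure_triples(pairs, net, "S", "S", "I") == pytest.approx(expected, rel=1e-12)

    def test_closure_against_exact_census_on_small_graph(self):
        # Two triangles sharing an edge plus a pendant path; mixed states.
        # The closure assumes an n-regular neighbourhood, so on this small
        # irregular graph it is only accurate to a multiplicative factor;
        # the census values below bound it within a factor of two.
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (1, 3), (2, 3), (3, 4), (4, 5)])
        states = {0: "I", 1: "S", 2: "I", 3: "S", 4: "S", 5: "I"}
        net = ContactNetwork.from_edges(g.nodes(), g.edges(), directed=False)
        pairs = empirical_pair_counts(net, states)
        summary = NetworkSummary(N=6, k=2 * g.number_of_edges() / 6, phi=nx.transitivity(g))
        for xyz in [("I", "S", "I"), ("I", "S", "S"), ("S", "I", "S"), ("S", "S", "I")]:
            exact = census_triples(g, states, *xyz)
            approx = closure_triples(pairs, summary, *xyz)
            assert exact / 2.0 <= approx <= exact * 2.0


class TestRhs:
    def test_unstructured_no_transmission_equilibrium(self):
        p = SISaParams(a=0.02, g=0.04, beta=0.0)
        net = NetworkSummary(N=1000, k=3.0, phi=0.3)
        state = random_mixing_pairs(p.a / (p.a + p.g), net)
        derivs = pairwise_rhs(state, p, net)
        for value in derivs.values():
            assert value == pytest.approx(0.0, abs=1e-9)

    def test_absorbing_disease_free_state(self):
        p = SISaParams(a=0.0, g=0.04, beta=0.01)
        net = NetworkSummary(N=100, k=3.0, phi=0.0)
        state = random_mixing_pairs(0.0, net)
        assert all(v == 0.0 for v in pairwise_rhs(state, p, net).values())

    @settings(max_examples=50, derandomize=True)
    @given(
        i=st.floats(0.01, 0.99),
        c_si=st.floats(0.1, 1.0),
        a=st.floats(0.0, 0.5),
        g=st.floats(0.0, 0.5),
        beta=st.floats(0.0, 0.5),
        phi=st.floats(0.0, 1.0),
    )
    def test_conservation_of_nodes_and_edges(self, i, c_si, a, g, beta, phi):
        """d(SS)/dt + 2 d(SI)/dt + d(II)/dt = 0 and dS/dt = -dI/dt for any
        valid state, including clustered (c_si < 1) configurations."""
        net = NetworkSummary(N=500, k=4.0, phi=phi)
        base = random_mixing_pairs(i, net)
        si = base.SI * c_si
        # keep edge total fixed: surplus split between SS and II
        surplus = base.SI - si
        state = PairwiseState(S=base.S, I=base.I, SS=base.SS + surplus, SI=si, II=base.II + surplus)
        d = pairwise_rhs(state, SISaParams(a=a, g=g, beta=beta), net)
        assert d["SS"] + 2 * d["SI"] + d["II"] == pytest.approx(0.0, abs=1e-8)
        assert d["S"] == pytest.approx(-d["I"], abs=1e-12)

    def test_inconsistent_state_rejected(self):
        net = NetworkSummary(N=100, k=3.0, phi=0.0)
        bad = PairwiseState(S=50, I=50, SS=100, SI=10, II=10)  # pairs != 2E
        with pytest.raises(ValueError):
            pairwise_rhs(bad, SISaParams(a=0.1, g=0.1, beta=0.1), net)


class TestIntegrate:
    def test_conservation_along_trajectory(self, obesity_params):
        net = NetworkSummary(N=1000, k=3.0, phi=0.64)
        traj = integrate_pairwise(obesity_params, net, 0.14, 200.0, n_points=200)
        for s in traj.states[:: 20]:
            assert s.N == pytest.approx(net.N, abs=1e-8 * net.N)
            assert s.two_E == pytest.approx(2 * net.E, abs=1e-6 * net.E)

    def test_no_correlations_without_transmission(self):
        p = SISaParams(a=0.02, g=0.04, beta=0.0)
        net = NetworkSummary(N=1000, k=3.0, phi=0.5)
        traj = integrate_pairwise(p, net, 0.14, 150.0, n_points=100)
        for c in traj.correlations[1:]:
            assert c.c_si == pytest.approx(1.0, abs=1e-6)
            assert c.c_ii == pytest.approx(1.0, abs=1e-6)

    def test_invalid_inputs_rejected(self, obesity_params):
        net = NetworkSummary(N=100, k=3.0, phi=0.0)
        with pytest.raises(ValueError):
            integrate_pairwise(obesity_params, net, 1.5, 10.0)
        with pytest.raises(ValueError):
            integrate_pairwise(obesity_params, net, 0.5, 0.0)


class TestSteadyState:
    def test_no_transmission_gives_unstructured_equilibrium(self):
        p = SISaParams(a=0.02, g=0.04, beta=0.0)
        i_star, corr = steady_state_pairwise(p, NetworkSummary(N=100, k=3.0, phi=0.2))
        assert i_star == pytest.approx(1.0 / 3.0)
        assert corr == CorrelationSet(1.0, 1.0, 1.0)

    @pytest.mark.parametrize("beta,g,k", [(0.05, 0.04, 3.0), (0.1, 0.08, 4.0), (0.3, 0.2, 5.0)])
    def test_closed_form_matches_numerical_root(self, beta, g, k):
        """For a = 0 and phi = 0 the analytically derived equilibrium must
        agree with the numerical root of the full reduced system."""
        p = SISaParams(a=0.0, g=g, beta=beta)
        net = NetworkSummary(N=1000, k=k, phi=0.0)
        i_closed, c_si_closed = closed_form_steady_state(p, net)
        i_num, corr = steady_state_pairwise(p, net)
        assert i_num == pytest.approx(i_closed, abs=1e-8)
        assert corr.c_si == pytest.approx(c_si_closed, abs=1e-6)

    def test_closed_form_threshold(self):
        # below the pair-approximation threshold beta*(k-1) = g the only
        # equilibrium without spontaneous infection is disease-free
        p = SISaParams(a=0.0, g=0.1, beta=0.04)
        i_star, _ = closed_form_steady_state(p, NetworkSummary(N=1, k=2.0, phi=0.0))
        assert i_star == 0.0

    def test_transmission_clusters_infecteds(self):
        """Raising beta from 0 increases prevalence and pushes C_SI below 1
        (the S-I correlation decline is monotone in the weak-transmission
        regime; at larger beta rising prevalence partially restores it)."""
        net = NetworkSummary(N=1000, k=3.0, phi=0.0)
        prev_i, prev_csi = 0.0, np.inf
        for beta in (0.0, 0.002, 0.005, 0.01):
            i_star, corr = steady_state_pairwise(SISaParams(a=0.01, g=0.05, beta=beta), net)
            assert i_star > prev_i - 1e-12
            assert corr.c_si < prev_csi + 1e-12
            prev_i, prev_csi = i_star, corr.c_si
        assert prev_csi < 1.0
        # and C_SI stays below 1 even at strong transmission
        assert steady_state_pairwise(SISaParams(a=0.01, g=0.05, beta=0.06), net)[1].c_si < 1.0

    def test_effective_transmission_self_consistency(self, obesity_params):
        """At equilibrium, I* solves the well-mixed balance with beta
        replaced by beta * C_SI* (the network lowers the effective
        transmission rate by the S-I correlation factor)."""
        for phi in (0.0, 0.64):
            net = NetworkSummary(N=1.0, k=3.0, phi=phi)
            i_star, corr = steady_state_pairwise(obesity_params, net)
            a, g, b = obesity_params.a, obesity_params.g, obesity_params.beta
            balance = a * (1 - i_star) + b * corr.c_si * net.k * i_star * (1 - i_star) - g * i_star
            assert balance == pytest.approx(0.0, abs=1e-6)

    def test_wellmixed_limit(self, obesity_params):
        """phi = 0 with k -> N-1 recovers the well-mixed equilibrium."""
        n = 2000.0
        i_pw, _ = steady_state_pairwise(obesity_params, NetworkSummary(N=n, k=n - 1, phi=0.0))
        i_wm = steady_state_wellmixed(obesity_params, n - 1)
        assert i_pw == pytest.approx(i_wm, abs=1e-4)

    def test_phi_insensitive_for_obesity_rates(self, obesity_params):
        """With spontaneous infection dominating, transitivity barely
        moves the equilibrium (< 1 percentage point across phi in [0,1])."""
        values = [
            steady_state_pairwise(obesity_params, NetworkSummary(N=1.0, k=3.0, phi=phi))[0]
            for phi in np.linspace(0.0, 1.0, 6)
        ]
        assert (max(values) - min(values)) * 100 < 1.0

    def test_phi_decreases_prevalence_at_large_beta(self):
        """For strongly transmissive spread, transitivity slightly
        suppresses prevalence by clustering infecteds."""
        p = SISaParams(a=0.002, g=0.04, beta=0.1)
        net0 = NetworkSummary(N=1.0, k=3.0, phi=0.0)
        net8 = NetworkSummary(N=1.0, k=3.0, phi=0.8)
        assert steady_state_pairwise(p, net8)[0] < steady_state_pairwise(p, net0)[0]


class TestCorrelations:
    def test_random_mixing_is_uncorrelated(self):
        net = NetworkSummary(N=100, k=4.0, phi=0.0)
        corr = correlations_from_pairs(random_mixing_pairs(0.3, net), net)
        assert corr.c_ss == pytest.approx(1.0)
        assert corr.c_si == pytest.approx(1.0)
        assert corr.c_ii == pytest.approx(1.0)

    def test_all_infected_population(self):
        net = NetworkSummary(N=10, k=3.0, phi=0.0)
        pairs = PairwiseState(S=0, I=10, SS=0, SI=0, II=30)
        corr = correlations_from_pairs(pairs, net)
        assert corr.c_ii == pytest.approx(1.0)
        assert np.isnan(corr.c_ss) and np.isnan(corr.c_si)  # undefined, not 0

    def test_two_clique_segregation_census(self):
        """Two 5-cliques, one fully infected: C_II doubles the random
        expectation and C_SI vanishes (hand-countable)."""
        cliques = [list(range(5)), list(range(5, 10))]
        edges = [
            (u, v) for grp in cliques for i, u in enumerate(grp) for v in grp[i + 1 :]
        ]
        net = ContactNetwork.from_edges(range(10), edges, directed=False)
        states = {v: ("I" if v < 5 else "S") for v in range(10)}
        pairs = empirical_pair_counts(net, states)
        summary = NetworkSummary(N=10, k=4.0, phi=1.0)
        corr = correlations_from_pairs(pairs, summary)
        # E = 20, [II] = 20 ordered, C_II = 100*20/(40*25) = 2
        assert corr.c_ii == pytest.approx(2.0)
        assert corr.c_si == pytest.approx(0.0)
        assert corr.c_ss == pytest.approx(2.0)
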