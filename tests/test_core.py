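"""Unit and property tests of the neighborhood-enrichment statistic."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surrogene.core import (
    NullCache,
    SurrogateGeneSet,
    call_surrogates,
    calls_to_table,
    count_altered_neighbors,
    exact_tail_pvalue,
    expand_seed_set,
    neighbor_frequency,
    permutation_pvalue,
)
from surrogene.genomic import AlterationProfile
from surrogene.network import PPINetwork


def brute_force_tail(N: int, k: int, M: int, x_obs: int) -> float:
    """Oracle: enumerate every M-subset of range(N), count hits among first k."""
    if x_obs <= 0:
        return 1.0
    hits = sum(
        1
        for subset in itertools.combinations(range(N), M)
        if sum(1 for i in subset if i < k) >= x_obs
    )
    return hits / math.comb(N, M)


class TestExpandSeedSet:
    @pytest.fixture
    def net(self):
        # C adjacent to both seeds, D adjacent to A only
        return PPINetwork.from_edges(
            [("A", "C"), ("B", "C"), ("A", "D"), ("A", "B")]
        )

    def test_two_connection_threshold(self, net):
        out = expand_seed_set(net, {"A", "B"}, min_connections=2)
        assert out.expanded == {"A", "B", "C"}
        assert out.seeds == {"A", "B"}

    def test_single_connection_threshold(self, net):
        out = expand_seed_set(net, {"A", "B"}, min_connections=1)
        assert out.expanded == {"A", "B", "C", "D"}

    def test_no_qualifying_neighbors(self, net):
        out = expand_seed_set(net, {"D"}, min_connections=2)
        assert out.expanded == {"D"}

    def test_unknown_seeds_dropped_all_unknown_raises(self, net):
        with pytest.raises(ValueError):
            expand_seed_set(net, {"ZZZ"}, min_connections=2)
        out = expand_seed_set(net, {"A", "B", "ZZZ"}, min_connections=2)
        assert out.seeds == {"A", "B"}


class TestCountAlteredNeighbors:
    def test_star_center_excludes_self(self, star_graph):
        prof = AlterationProfile("S1", mutated={"L1", "L3", "X"})
        x, contributing, self_altered = count_altered_neighbors(star_graph, "X", prof)
        assert x == 2
        assert [g for g, _ in contributing] == ["L1", "L3"]
        assert self_altered

    def test_no_altered_neighbors(self, star_graph):
        prof = AlterationProfile("S1", mutated={"X"})
        x, contributing, _ = count_altered_neighbors(star_graph, "X", prof)
        assert x == 0 and contributing == []

    def test_fully_altered_neighborhood(self, star_graph):
        prof = AlterationProfile("S1", mutated={"L1", "L2"}, gained={"L3", "L4"})
        x, contributing, self_altered = count_altered_neighbors(star_graph, "X", prof)
        assert x == star_graph.degree("X")
        assert not self_altered
        assert dict(contributing)["L3"] == ("gain",)


class TestExactTail:
    def test_zero_observation_is_one(self):
        assert exact_tail_pvalue(10, 4, 5, 0) == 1.0

    def test_above_support_is_zero(self):
        assert exact_tail_pvalue(10, 4, 5, 5) == 0.0

    def test_frozen_example(self):
        # N=10, k=4, M=5, x=3: (C(4,3)C(6,2) + C(4,4)C(6,1)) / C(10,5) = 66/252
        assert exact_tail_pvalue(10, 4, 5, 3) == pytest.approx(66 / 252, abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        for N in (5, 8, 10):
            for k in range(N + 1):
                for M in range(N + 1):
                    for x in range(min(k, M) + 2):
                        assert exact_tail_pvalue(N, k, M, x) == pytest.approx(
                            brute_force_tail(N, k, M, x), abs=1e-12
                        ), (N, k, M, x)

    def test_infeasible_parameters_raise(self):
        with pytest.raises(ValueError):
            exact_tail_pvalue(10, 11, 5, 1)
        with pytest.raises(ValueError):
            exact_tail_pvalue(10, 4, 11, 1)
        with pytest.raises(ValueError):
            exact_tail_pvalue(10, 4, 5, -1)


@settings(deadline=None, max_examples=200)
@given(st.data())
def test_exact_tail_properties(data):
    """p in [0,1]; non-increasing in x_obs; non-decreasing in M for x_obs > 0."""
    N = data.draw(st.integers(2, 60))
    k = data.draw(st.integers(0, N))
    M = data.draw(st.integers(0, N))
    x = data.draw(st.integers(0, min(k, M) + 1))
    p = exact_tail_pvalue(N, k, M, x)
    assert 0.0 <= p <= 1.0
    assert exact_tail_pvalue(N, k, M, x + 1) <= p
    if x > 0 and M < N:
        assert exact_tail_pvalue(N, k, M + 1, x) >= p


@pytest.fixture(scope="module")
def small_net():
    """11-node graph: 10-cycle plus a degree-4 hub."""
    edges = [(f"N{i}", f"N{(i + 1) % 10}") for i in range(10)]
    edges += [("HUB", f"N{i}") for i in range(4)]
    return PPINetwork.from_edges(edges)


class TestPermutation:
    def test_zero_observation_is_one(self, small_net):
        assert permutation_pvalue(small_net, "HUB", 0, 5, n_perm=100, rng_seed=0) == 1.0

    def test_saturated_network(self, small_net):
        # M = N: every permutation alters every gene, so count == k always
        N = small_net.n_nodes
        k = small_net.degree("HUB")
        assert permutation_pvalue(small_net, "HUB", k, N, n_perm=100, rng_seed=0) == 1.0

    def test_matches_exact_within_monte_carlo_error(self, small_net):
        # HUB has degree 4 in an 11-node network
        N, k, M, x = small_net.n_nodes, 4, 5, 3
        exact = exact_tail_pvalue(N, k, M, x)
        n_perm = 10_000
        p = permutation_pvalue(small_net, "HUB", x, M, n_perm=n_perm, rng_seed=123)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) <= 4 * se

    def test_deterministic_given_seed(self, small_net):
        kw = dict(n_perm=2000, rng_seed=99)
        assert permutation_pvalue(small_net, "HUB", 2, 5, **kw) == permutation_pvalue(
            small_net, "HUB", 2, 5, **kw
        )

    def test_x_obs_beyond_support_raises(self, small_net):
        with pytest.raises(ValueError):
            permutation_pvalue(small_net, "HUB", 5, 5, n_perm=100, rng_seed=0)

    def test_cache_makes_p_monotone_in_x(self):
        cache = NullCache(50, n_perm=5000, rng=np.random.default_rng(5))
        ps = [cache.pvalue(8, 10, x) for x in range(9)]
        assert ps == sorted(ps, reverse=True)

    def test_add_one_correction_never_zero(self):
        cache = NullCache(20, n_perm=100, rng=np.random.default_rng(0))
        assert cache.pvalue(3, 3, 3, correction=True) >= 1 / 101

    def test_M_exceeding_N_raises(self):
        cache = NullCache(10, n_perm=10)
        with pytest.raises(ValueError):
            cache.null_counts(3, 11)


class TestCallSurrogates:
    @pytest.fixture
    def setup(self, star_graph):
        gene_set = SurrogateGeneSet(seeds={"X"}, expanded={"X", "L1"})
        profiles = [
            AlterationProfile("S0"),  # M = 0
            AlterationProfile("S1", mutated={"L1", "L2", "L3", "L4"}),
        ]
        return star_graph, gene_set, profiles

    def test_empty_sample_all_p_one(self, setup):
        net, gs, profiles = setup
        calls, _ = call_surrogates(net, gs, profiles)
        s0 = [c for c in calls if c.sample_id == "S0"]
        assert all(c.p_value == 1.0 and not c.significant for c in s0)

    def test_alpha_zero_no_calls(self, setup):
        net, gs, profiles = setup
        calls, _ = call_surrogates(net, gs, profiles, alpha=0.0)
        assert not any(c.significant for c in calls)

    def test_matrix_states_match_calls(self, setup):
        net, gs, profiles = setup
        calls, matrix = call_surrogates(net, gs, profiles, alpha=0.05)
        for c in calls:
            state = matrix.states.loc[c.sample_id, c.gene]
            assert (state in ("surrogate_only", "both")) == c.significant
            assert (state in ("altered_only", "both")) == c.self_altered

    def test_significance_nested_across_alpha(self, ba_network, planted_cohort):
        genes = {g for g, _ in planted_cohort.truth.targets}
        gs = SurrogateGeneSet(seeds=genes, expanded=genes)
        strict, _ = call_surrogates(ba_network, gs, planted_cohort.profiles, alpha=0.01)
        loose, _ = call_surrogates(ba_network, gs, planted_cohort.profiles, alpha=0.05)
        sig_strict = {(c.sample_id, c.gene) for c in strict if c.significant}
        sig_loose = {(c.sample_id, c.gene) for c in loose if c.significant}
        assert sig_strict <= sig_loose
        assert len(sig_loose) > 0

    def test_exact_and_perm_modes_agree_on_significance(self, star_graph):
        gs = SurrogateGeneSet(seeds={"X"}, expanded={"X"})
        profiles = [AlterationProfile("S1", mutated={"L1", "L2", "L3"})]
        exact, _ = call_surrogates(star_graph, gs, profiles, mode="exact")
        perm, _ = call_surrogates(
            star_graph, gs, profiles, mode="perm", n_perm=20_000, rng_seed=1
        )
        assert exact[0].x_obs == perm[0].x_obs == 3
        assert perm[0].p_value == pytest.approx(exact[0].p_value, abs=0.01)


class TestNeighborFrequency:
    def test_counts_across_samples(self, star_graph):
        gs = SurrogateGeneSet(seeds={"X"}, expanded={"X"})
        profiles = [
            AlterationProfile("S1", mutated={"L1", "L2"}),
            AlterationProfile("S2", mutated={"L1"}),
            AlterationProfile("S3", gained={"L1"}),
        ]
        calls, _ = call_surrogates(star_graph, gs, profiles)
        table = neighbor_frequency(calls, "X", net=star_graph).set_index("neighbor")
        assert table.loc["L1", "n_samples_altered"] == 3
        assert table.loc["L2", "n_samples_altered"] == 1

    def test_duplicate_profiles_double_frequencies(self, star_graph):
        gs = SurrogateGeneSet(seeds={"X"}, expanded={"X"})
        one = [AlterationProfile("S1", mutated={"L1"})]
        two = one + [AlterationProfile("S2", mutated={"L1"})]
        c1, _ = call_surrogates(star_graph, gs, one)
        c2, _ = call_surrogates(star_graph, gs, two)
        f1 = neighbor_frequency(c1, "X").set_index("neighbor")["n_samples_altered"]
        f2 = neighbor_frequency(c2, "X").set_index("neighbor")["n_samples_altered"]
        assert (f2 == 2 * f1).all()

    def test_gene_with_no_hits_gives_empty_table(self, star_graph):
        gs = SurrogateGeneSet(seeds={"X"}, expanded={"X"})
        calls, _ = call_surrogates(star_graph, gs, [AlterationProfile("S1")])
        assert neighbor_frequency(calls, "X").empty

    def test_untested_gene_raises(self, star_graph):
        gs = SurrogateGeneSet(seeds={"X"}, expanded={"X"})
        calls, _ = call_surrogates(star_graph, gs, [AlterationProfile("S1")])
        with pytest.raises(KeyError):
            neighbor_frequency(calls, "L1")


def test_calls_table_schema(star_graph):
    gs = SurrogateGeneSet(seeds={"X"}, expanded={"X", "L1"})
    calls, _ = call_surrogates(star_graph, gs, [AlterationProfile("S1", mutated={"L2"})])
    table = calls_to_table(calls)
    assert list(table.columns) == [
        "sample", "gene", "k", "M", "x_obs", "p_value", "significant", "self_altered",
    ]
    assert len(table) == 2
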