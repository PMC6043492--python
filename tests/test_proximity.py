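import math

import networkx as nx
import numpy as np
import pytest

from netprox.interactome import GeneSet, build_degree_bins
from netprox.proximity import (
    DegenerateNullError,
    centre_distance,
    closest_distance,
    kernel_distance,
    null_distribution,
    proximity_z,
    sample_degree_matched,
    shortest_distance,
)

from conftest import gs, str_graph


# ---------------------------------------------------------------------------
# brute-force oracle: exhaustive all-pairs shortest paths + direct formulas


def oracle_distances(g):
    return dict(nx.all_pairs_shortest_path_length(g))


def oracle_closest(g, S, T):
    d = oracle_distances(g)
    return sum(min(d[t][s] for s in S) for t in T) / len(T)


def oracle_shortest(g, S, T):
    d = oracle_distances(g)
    return sum(sum(d[t][s] for s in S) / len(S) for t in T) / len(T)


def oracle_kernel(g, S, T):
    d = oracle_distances(g)
    return sum(
        -math.log(sum(math.exp(-(d[t][s] + 1)) for s in S) / len(S)) for t in T
    ) / len(T)


def oracle_centre(g, S, T):
    d = oracle_distances(g)
    totals = {s: sum(d[s][s2] for s2 in S) for s in S}
    best = min(totals.values())
    centres = [s for s in S if totals[s] == best]
    return sum(sum(d[t][c] for c in centres) / len(centres) for t in T) / len(T)


ORACLES = {
    "closest": (closest_distance, oracle_closest),
    "shortest": (shortest_distance, oracle_shortest),
    "kernel": (kernel_distance, oracle_kernel),
    "centre": (centre_distance, oracle_centre),
}


def random_case(seed, n_max=50):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_max + 1))
    g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(2**31)))
    comp = max(nx.connected_components(g), key=len)
    g = str_graph(g.subgraph(comp).copy())
    nodes = sorted(g.nodes())
    S = set(rng.choice(nodes, size=min(len(nodes), int(rng.integers(1, 6))), replace=False))
    T = set(rng.choice(nodes, size=min(len(nodes), int(rng.integers(1, 6))), replace=False))
    return g, S, T


class TestDistanceExamples:
    def test_closest_single_path(self, path5):
        assert closest_distance(path5, gs("S", 1), gs("T", 5)) == 4.0

    def test_closest_averages_over_targets(self, path5):
        assert closest_distance(path5, gs("S", 1), gs("T", 1, 5)) == 2.0

    def test_shortest_mean_over_disease_set(self, path5):
        assert shortest_distance(path5, gs("S", 1, 5), gs("T", 3)) == 2.0

    def test_shortest_identical_singletons(self, path5):
        assert shortest_distance(path5, gs("S", 3), gs("T", 3)) == 0.0

    def test_kernel_self_distance_is_one(self, path5):
        assert kernel_distance(path5, gs("S", 3), gs("T", 3)) == pytest.approx(1.0)

    def test_kernel_path_ends(self, path5):
        assert kernel_distance(path5, gs("S", 1), gs("T", 5)) == pytest.approx(5.0)

    def test_kernel_two_equidistant_sources(self, path5):
        # |S|=2 both at d=1 from the target: -ln(e^-2) = 2
        assert kernel_distance(path5, gs("S", 2, 4), gs("T", 3)) == pytest.approx(2.0)

    def test_centre_of_path_prefix(self, path5):
        # centre of {1,2,3} on the path is 2; distance 2 -> 5 is 3
        assert centre_distance(path5, gs("S", 1, 2, 3), gs("T", 5)) == 3.0

    def test_centre_singleton_reduces_to_closest(self, path5):
        s, t = gs("S", 2), gs("T", 4, 5)
        assert centre_distance(path5, s, t) == closest_distance(path5, s, t)

    def test_centre_tie_is_averaged(self):
        # path 1-2-3-4: S = {2,3} are tied centres; T = {1}: mean(1, 2) = 1.5
        g = str_graph(nx.path_graph(range(1, 5)))
        assert centre_distance(g, gs("S", 2, 3), gs("T", 1)) == 1.5
        assert oracle_centre(g, {"2", "3"}, {"1"}) == 1.5

    def test_empty_set_is_error(self, path5):
        with pytest.raises(ValueError):
            closest_distance(path5, gs("S", 1), GeneSet("T", frozenset()))

    def test_unreachable_pair_named_in_error(self):
        g, _ = nx.Graph(), None
        g.add_edge("1", "2")
        g.add_edge("3", "4")
        with pytest.raises(ValueError, match="3"):
            closest_distance(g, gs("S", 1), gs("T", 3))


class TestOracleEquivalence:
    @pytest.mark.parametrize("measure", list(ORACLES))
    def test_measures_match_bruteforce_on_random_graphs(self, measure):
        func, oracle = ORACLES[measure]
        for seed in range(30):
            g, S, T = random_case(seed)
            got = func(g, GeneSet("S", frozenset(S)), GeneSet("T", frozenset(T)))
            assert got == pytest.approx(oracle(g, S, T)), f"seed {seed}"

    def test_closest_at_most_shortest(self):
        for seed in range(30):
            g, S, T = random_case(seed)
            Sg, Tg = GeneSet("S", frozenset(S)), GeneSet("T", frozenset(T))
            assert closest_distance(g, Sg, Tg) <= shortest_distance(g, Sg, Tg) + 1e-12

    def test_closest_zero_iff_targets_inside_module(self):
        for seed in range(20):
            g, S, T = random_case(seed)
            Sg, Tg = GeneSet("S", frozenset(S)), GeneSet("T", frozenset(T))
            assert (closest_distance(g, Sg, Tg) == 0) == (set(T) <= set(S))


class TestDegreeMatchedSampling:
    def test_path_leaf_sampled_from_leaf_bin(self, path5):
        bins = build_degree_bins(path5, min_bin_size=1)
        rng = np.random.default_rng(0)
        for _ in range(20):
            (node,) = sample_degree_matched(path5, bins, gs("t", 1), rng)
            assert node in {"1", "5"}

    def test_fixed_seed_reproduces_sample(self, small_interactome):
        bins = build_degree_bins(small_interactome, min_bin_size=10)
        template = gs("t", *sorted(small_interactome.nodes())[:8])
        a = sample_degree_matched(small_interactome, bins, template, np.random.default_rng(42))
        b = sample_degree_matched(small_interactome, bins, template, np.random.default_rng(42))
        assert a == b

    def test_sample_size_and_distinctness(self, small_interactome):
        bins = build_degree_bins(small_interactome, min_bin_size=10)
        template = gs("t", *sorted(small_interactome.nodes())[:12])
        sample = sample_degree_matched(small_interactome, bins, template, np.random.default_rng(3))
        assert len(sample) == len(set(sample)) == 12

    def test_within_bin_sampling_is_uniform(self, path5):
        """Chi-square sanity: a degree-1 template node draws ~uniformly
        from the two-leaf bin over 10,000 draws."""
        bins = build_degree_bins(path5, min_bin_size=1)
        rng = np.random.default_rng(123)
        counts = {"1": 0, "5": 0}
        n = 10_000
        for _ in range(n):
            (node,) = sample_degree_matched(path5, bins, ["1"], rng)
            counts[node] += 1
        chi2 = sum((c - n / 2) ** 2 / (n / 2) for c in counts.values())
        assert chi2 < 10.83  # p ~ 0.001 for 1 df


class TestNullDistribution:
    def test_single_replicate_sd_zero(self, small_interactome, small_module):
        bins = build_degree_bins(small_interactome, min_bin_size=20)
        t = gs("t", *sorted(small_interactome.nodes())[:3])
        null = null_distribution(
            small_interactome, bins, small_module, t, replicates=1, seed=0
        )
        assert null.sd == 0.0 and null.replicates == 1

    def test_fixed_seed_bit_identical(self, small_interactome, small_module):
        bins = build_degree_bins(small_interactome, min_bin_size=20)
        t = gs("t", *sorted(small_interactome.nodes())[:3])
        a = null_distribution(small_interactome, bins, small_module, t, replicates=25, seed=9)
        b = null_distribution(small_interactome, bins, small_module, t, replicates=25, seed=9)
        assert (a.mean, a.sd) == (b.mean, b.sd)

    def test_stored_samples_match_moments(self, small_interactome, small_module):
        bins = build_degree_bins(small_interactome, min_bin_size=20)
        t = gs("t", *sorted(small_interactome.nodes())[:3])
        null = null_distribution(
            small_interactome, bins, small_module, t, replicates=30, seed=1, keep_samples=True
        )
        assert np.mean(null.samples) == pytest.approx(null.mean)
        assert np.std(null.samples) == pytest.approx(null.sd)

    def test_complete_graph_distances_are_overlap_or_one(self):
        """On K_n every inter-node distance is 1, so replicate distances are
        determined by overlap alone: 1 when the sampled groups are disjoint,
        less when they share nodes."""
        g = str_graph(nx.complete_graph(8))
        bins = build_degree_bins(g, min_bin_size=1)
        null = null_distribution(
            g, bins, gs("S", 0, 1), gs("T", 2), replicates=50, seed=4, keep_samples=True
        )
        assert set(null.samples) <= {0.0, 1.0}
        assert null.mean <= 1.0


class TestProximityZ:
    def test_z_formula(self, small_interactome, small_module):
        bins = build_degree_bins(small_interactome, min_bin_size=20)
        t = gs("drug", *sorted(small_interactome.nodes())[10:13])
        res = proximity_z(
            small_interactome, bins, small_module, t, replicates=50, seed=2
        )
        assert res.z == pytest.approx((res.observed - res.null.mean) / res.null.sd)

    def test_degenerate_null_with_matching_observed(self):
        """When every replicate must equal the observed configuration the
        null collapses and z is defined as 0."""
        k2 = str_graph(nx.complete_graph(2))
        bins = build_degree_bins(k2, min_bin_size=2)
        res = proximity_z(k2, bins, gs("S", 0, 1), gs("T", 0, 1), replicates=10, seed=0)
        assert res.z == 0.0 and res.null.sd == 0.0

    def test_planted_targets_score_negative(self, small_interactome, small_module):
        bins = build_degree_bins(small_interactome, min_bin_size=25)
        inside = gs("drug", *sorted(small_module.members)[:4])
        res = proximity_z(
            small_interactome, bins, small_module, inside, replicates=100, seed=3
        )
        assert res.observed == 0.0
        assert res.z < -1.0

    def test_restriction_counts_reported(self, small_interactome, small_module):
        bins = build_degree_bins(small_interactome, min_bin_size=25)
        t = GeneSet("drug", frozenset(list(sorted(small_module.members)[:3]) + ["NOT_A_GENE"]))
        res = proximity_z(small_interactome, bins, small_module, t, replicates=10, seed=0)
        assert res.n_targets_used == 3
        assert res.n_disease_used == len(small_module)
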