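import itertools

import numpy as np
import pytest

from plnet import (
    ClusterTester,
    PhenotypicLinkageNetwork,
    cds_matched_candidates,
    cluster_test,
    degree_matched_candidates,
    link_weight_sum,
    read_gene_lengths,
    sample_null_set,
    write_gene_lengths,
)
from plnet._util import PlnetError


@pytest.fixture
def triangle():
    return PhenotypicLinkageNetwork.from_edges(
        [("a", "b", 1.0), ("b", "c", 2.0), ("a", "c", 3.0)]
    )


class TestLinkWeightSum:
    def test_two_genes_one_edge(self, triangle):
        assert link_weight_sum(triangle, {"a", "b"}) == pytest.approx(1.0)

    def test_set_without_internal_edges_is_zero(self, triangle):
        assert link_weight_sum(triangle, {"a", "zz"}) == 0.0

    def test_triangle_sums_all_three_edges(self, triangle):
        assert link_weight_sum(triangle, {"a", "b", "c"}) == pytest.approx(6.0)

    def test_genes_absent_from_network_contribute_nothing(self, triangle):
        assert link_weight_sum(triangle, {"a", "b", "ghost"}) == pytest.approx(1.0)

    def test_fewer_than_two_distinct_genes_is_error(self, triangle):
        with pytest.raises(PlnetError):
            link_weight_sum(triangle, {"a", "a"})


class TestCdsMatchedCandidates:
    def test_nearest_length_selection(self):
        lengths = {"q": 1000, "near": 990, "same": 1000, "far": 5000, "huge": 9000}
        assert set(cds_matched_candidates(lengths, "q", k=2)) == {"same", "near"}

    def test_query_gene_excluded_from_its_own_list(self):
        lengths = {"q": 1000, "a": 1000, "b": 900}
        assert "q" not in cds_matched_candidates(lengths, "q", k=2)

    def test_k_larger_than_universe_is_error(self):
        with pytest.raises(PlnetError):
            cds_matched_candidates({"q": 1, "a": 2}, "q", k=5)

    def test_missing_gene_error_names_it(self):
        with pytest.raises(KeyError, match="ghost"):
            cds_matched_candidates({"a": 1}, "ghost", k=1)

    def test_equal_distance_tie_breaks_lexicographically(self):
        lengths = {"q": 100, "zz": 110, "aa": 90, "mm": 200}
        # zz and aa both at distance 10; aa wins the final slot
        assert cds_matched_candidates(lengths, "q", k=1) == ["aa"]
        assert cds_matched_candidates(lengths, "q", k=2) == ["aa", "zz"]


class TestDegreeMatchedCandidates:
    def test_same_degree_shell(self):
        net = PhenotypicLinkageNetwork.from_edges(
            [("a", "b", 1), ("c", "d", 1), ("e", "f", 1)]
        )
        assert degree_matched_candidates(net, "a") == ["b", "c", "d", "e", "f"]

    def test_unique_degree_widens_to_nearest_shell(self):
        net = PhenotypicLinkageNetwork.from_edges(
            [("hub", "a", 1), ("hub", "b", 1), ("hub", "c", 1), ("a", "b", 1)]
        )
        # hub has degree 3, nobody else does; shell widens until non-empty
        shell = degree_matched_candidates(net, "hub", tolerance=0)
        assert shell == ["a", "b"]  # degree-2 genes, nearest non-empty shell

    def test_tolerance_one_spans_adjacent_degrees(self):
        net = PhenotypicLinkageNetwork.from_edges(
            [("a", "b", 1), ("b", "c", 1), ("c", "d", 1)]
        )
        # degrees: a=1 b=2 c=2 d=1
        assert degree_matched_candidates(net, "a", tolerance=1) == ["b", "c", "d"]


class TestSampleNullSet:
    def test_singleton_lists_are_deterministic(self, rng):
        assert sample_null_set([["a"], ["b"]], rng) == {"a", "b"}

    def test_same_seed_same_set(self):
        lists = [[f"g{i}", f"h{i}"] for i in range(10)]
        s1 = sample_null_set(lists, np.random.default_rng(7))
        s2 = sample_null_set(lists, np.random.default_rng(7))
        assert s1 == s2

    def test_collision_retry_nearly_always_fills_the_set(self, rng):
        lists = [["a", "b"], ["a", "b"]]
        full = sum(len(sample_null_set(lists, rng)) == 2 for _ in range(1000))
        assert full >= 990


class TestClusterTest:
    def test_p_value_formula_when_observed_tops_all_nulls(self):
        # heavy clique among the study genes, everything else unconnected
        edges = [("s1", "s2", 100.0)]
        genes = [f"f{i}" for i in range(30)]
        edges += [(genes[i], genes[i + 1], 0.001) for i in range(0, 28, 2)]
        net = PhenotypicLinkageNetwork.from_edges(edges)
        res = cluster_test(net, ["s1", "s2"], null_kind="uniform", n_rand=999,
                           seed=3, keep_null=True)
        assert res.statistic == pytest.approx(100.0)
        n_ge = int((res.null >= res.statistic).sum())
        assert res.p_value == pytest.approx((1 + n_ge) / 1000)
        # the study clique tops essentially every null draw (the only null
        # sets reaching it are re-draws of the clique itself)
        assert res.p_value <= 5 / 1000

    def test_uniform_null_empirical_p_matches_exact_enumeration(self):
        # universe of 10 genes, sets of 3: exact null by enumeration
        rng = np.random.default_rng(21)
        nodes = [f"g{i}" for i in range(10)]
        edges = []
        for i, j in itertools.combinations(range(10), 2):
            if rng.random() < 0.4:
                edges.append((nodes[i], nodes[j], float(rng.uniform(0.5, 2.0))))
        net = PhenotypicLinkageNetwork.from_edges(edges)
        study = ["g0", "g3", "g7"]
        s_obs = link_weight_sum(net, study)
        exact = [
            link_weight_sum(net, combo)
            for combo in itertools.combinations(nodes, 3)
        ]
        p_exact = sum(v >= s_obs for v in exact) / len(exact)
        res = cluster_test(net, study, null_kind="uniform", n_rand=30_000, seed=5)
        assert abs(res.p_value - p_exact) < 0.02

    def test_cds_null_empirical_p_matches_product_enumeration(self):
        rng = np.random.default_rng(22)
        nodes = [f"g{i}" for i in range(12)]
        edges = []
        for i, j in itertools.combinations(range(12), 2):
            if rng.random() < 0.5:
                edges.append((nodes[i], nodes[j], float(rng.uniform(0.5, 2.0))))
        net = PhenotypicLinkageNetwork.from_edges(edges)
        study = ["g0", "g4"]
        candidate_lists = [["g1", "g2", "g3"], ["g5", "g6", "g7"]]
        s_obs = link_weight_sum(net, study)
        exact = [
            link_weight_sum(net, combo)
            for combo in itertools.product(*candidate_lists)
        ]
        p_exact = sum(v >= s_obs for v in exact) / len(exact)

        # drive the internal machinery through lengths crafted so that the
        # matched candidate lists are exactly the enumerated ones
        lengths = {"g0": 100, "g1": 101, "g2": 102, "g3": 103,
                   "g4": 1000, "g5": 1001, "g6": 1002, "g7": 1003,
                   "g8": 50_000, "g9": 60_000, "g10": 70_000, "g11": 80_000}
        tester = ClusterTester(net, lengths=lengths, k=3)
        res = tester.test(study, null_kind="cds", n_rand=30_000, seed=9)
        assert abs(res.p_value - p_exact) < 0.02

    def test_missing_length_entries_error_lists_genes(self, triangle):
        with pytest.raises(PlnetError, match="ghost"):
            cluster_test(triangle, ["a", "ghost"], null_kind="cds",
                         lengths={"a": 1, "b": 2}, n_rand=10, seed=0)

    def test_fold_change_of_null_median_draw_is_about_one(self):
        rng = np.random.default_rng(30)
        nodes = [f"g{i}" for i in range(60)]
        edges = [
            (nodes[i], nodes[j], float(rng.uniform(0.5, 1.5)))
            for i, j in itertools.combinations(range(60), 2)
            if rng.random() < 0.3
        ]
        net = PhenotypicLinkageNetwork.from_edges(edges)
        res = cluster_test(net, nodes[:10], null_kind="uniform", n_rand=2000,
                           seed=4, keep_null=True)
        median_draw = float(np.median(res.null))
        assert median_draw / res.null_median == pytest.approx(1.0)
        # an average draw should have fold change near 1
        assert 0.5 < res.statistic / res.null_median < 2.0

    def test_determinism_under_fixed_seed(self, triangle):
        r1 = cluster_test(triangle, ["a", "b", "c"], null_kind="degree",
                          n_rand=500, seed=11)
        r2 = cluster_test(triangle, ["a", "b", "c"], null_kind="degree",
                          n_rand=500, seed=11)
        assert r1.p_value == r2.p_value
        assert r1.null_quantiles == r2.null_quantiles

    def test_summary_mentions_the_essentials(self, triangle):
        res = cluster_test(triangle, ["a", "b"], null_kind="uniform",
                           n_rand=99, seed=0)
        text = res.summary()
        assert "p-value" in text and "fold change" in text.lower()

    def test_p_never_zero_and_at_most_one(self, triangle, rng):
        for seed in range(5):
            res = cluster_test(triangle, ["a", "c"], null_kind="uniform",
                               n_rand=50, seed=seed)
            assert 0.0 < res.p_value <= 1.0


def test_gene_lengths_tsv_round_trip(tmp_path):
    lengths = {"g1": 1500, "g2": 320, "g3": 99_000}
    path = tmp_path / "len.tsv"
    write_gene_lengths(lengths, str(path), header={"seed": 0})
    assert read_gene_lengths(str(path)) == lengths
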