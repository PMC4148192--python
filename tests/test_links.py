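import numpy as np
import pandas as pd
import pytest

from plnet import (
    AnnotationSet,
    FormatError,
    LinkSet,
    Ontology,
    annotation_links,
    coexpression_links,
    map_genes,
    ppi_direct_links,
    ppi_indirect_links,
    read_linkset,
    read_scored_pairs,
    write_linkset,
)
from plnet._util import PlnetError, pair_key


def test_pair_key_is_order_invariant_and_rejects_self():
    assert pair_key("b", "a") == ("a", "b") == pair_key("a", "b")
    with pytest.raises(ValueError):
        pair_key("a", "a")


class TestCoexpression:
    def test_identical_profiles_correlate_perfectly(self):
        expr = pd.DataFrame(
            [np.arange(1, 11), np.arange(1, 11)], index=["g1", "g2"]
        )
        ls = coexpression_links(expr, min_shared=10)
        assert ls.score("g1", "g2") == pytest.approx(1.0)

    def test_nine_shared_samples_is_below_the_tissue_floor(self):
        x = np.arange(1.0, 11.0)
        y = x.copy()
        y[0] = np.nan  # only 9 shared expressed samples
        ls = coexpression_links(pd.DataFrame([x, y], index=["g1", "g2"]), min_shared=10)
        assert len(ls) == 0

    def test_linear_with_small_noise_recovers_high_correlation(self, rng):
        x = np.arange(1.0, 13.0)
        y = 2 * x + rng.normal(0, 0.01, size=12)
        ls = coexpression_links(pd.DataFrame([x, y], index=["g1", "g2"]), min_shared=10)
        assert ls.score("g1", "g2") > 0.99

    def test_correlation_uses_only_shared_expressed_samples(self):
        # g2 missing in two samples; correlation must be over the other 10
        x = np.arange(1.0, 13.0)
        y = 3 * x
        y[[2, 7]] = np.nan
        ls = coexpression_links(pd.DataFrame([x, y], index=["g1", "g2"]), min_shared=10)
        assert ls.score("g1", "g2") == pytest.approx(1.0)

    def test_zero_variance_profile_is_skipped(self):
        x = np.ones(12)
        y = np.arange(1.0, 13.0)
        ls = coexpression_links(pd.DataFrame([x, y], index=["g1", "g2"]), min_shared=10)
        assert len(ls) == 0

    def test_scores_bounded_in_minus_one_one(self, rng):
        expr = pd.DataFrame(
            rng.normal(5, 2, size=(8, 15)), index=[f"g{i}" for i in range(8)]
        )
        ls = coexpression_links(expr, min_shared=10, floor=-np.inf)
        assert all(-1.0 <= v <= 1.0 for v in ls.pairs.values())


class TestPpiDirect:
    def test_assay_pairs_scored_by_benchmark_median(self):
        tab = pd.DataFrame(
            {"gene_a": ["g1", "g2", "g3"], "gene_b": ["g2", "g3", "g4"],
             "assay": ["Y2H"] * 3}
        )
        bench = {("g1", "g2"): 0.0, ("g2", "g3"): 1.0, ("g3", "g4"): 2.0}
        out = ppi_direct_links(tab, bench, min_benchmarked=3)
        assert len(out) == 1
        assert set(out[0].pairs.values()) == {1.0}

    def test_two_assays_get_two_distinct_uniform_scores(self):
        tab = pd.DataFrame(
            {"gene_a": ["g1", "g2", "g1", "g3"],
             "gene_b": ["g2", "g3", "g3", "g4"],
             "assay": ["Y2H", "Y2H", "AP", "AP"]}
        )
        bench = {("g1", "g2"): 1.0, ("g2", "g3"): 1.0, ("g1", "g3"): 3.0,
                 ("g3", "g4"): 5.0}
        out = ppi_direct_links(tab, bench, min_benchmarked=2)
        scores = {ls.meta["assay"]: set(ls.pairs.values()) for ls in out}
        assert scores == {"Y2H": {1.0}, "AP": {4.0}}

    def test_pair_in_two_assays_keeps_both_candidate_scores(self):
        tab = pd.DataFrame(
            {"gene_a": ["g1", "g1", "g2"], "gene_b": ["g2", "g2", "g3"],
             "assay": ["Y2H", "AP", "AP"]}
        )
        bench = {("g1", "g2"): 2.0, ("g2", "g3"): 4.0}
        out = ppi_direct_links(tab, bench, min_benchmarked=1)
        per_assay = {ls.meta["assay"]: ls for ls in out}
        assert ("g1", "g2") in per_assay["Y2H"].pairs
        assert ("g1", "g2") in per_assay["AP"].pairs
        assert per_assay["Y2H"].pairs[("g1", "g2")] != per_assay["AP"].pairs[("g1", "g2")]

    def test_underbenchmarked_assay_dropped(self):
        tab = pd.DataFrame(
            {"gene_a": ["g1"], "gene_b": ["g2"], "assay": ["tiny"]}
        )
        assert ppi_direct_links(tab, {("g1", "g2"): 1.0}, min_benchmarked=100) == []


class TestPpiIndirect:
    def _tab(self, edges):
        return pd.DataFrame(
            {"gene_a": [a for a, _ in edges], "gene_b": [b for _, b in edges],
             "assay": ["x"] * len(edges)}
        )

    def test_identical_partner_sets_give_jaccard_one(self):
        tab = self._tab([("g1", "a"), ("g1", "b"), ("g2", "a"), ("g2", "b")])
        ls = ppi_indirect_links(tab)
        assert ls.score("g1", "g2") == pytest.approx(1.0)

    def test_disjoint_partner_sets_absent(self):
        tab = self._tab([("g1", "a"), ("g2", "b")])
        assert ("g1", "g2") not in ppi_indirect_links(tab)

    def test_partial_overlap_jaccard(self):
        tab = self._tab(
            [("g1", "a"), ("g1", "b"), ("g1", "c"),
             ("g2", "b"), ("g2", "c"), ("g2", "d")]
        )
        assert ppi_indirect_links(tab).score("g1", "g2") == pytest.approx(0.5)

    def test_directly_interacting_pairs_excluded(self):
        tab = self._tab([("g1", "g2"), ("g1", "a"), ("g2", "a")])
        assert ("g1", "g2") not in ppi_indirect_links(tab)

    def test_scores_bounded_zero_one(self, rng):
        genes = [f"g{i}" for i in range(15)]
        edges = [(genes[int(i)], genes[int(j)])
                 for i, j in rng.integers(0, 15, size=(60, 2)) if i != j]
        ls = ppi_indirect_links(self._tab(edges))
        assert all(0.0 <= v <= 1.0 for v in ls.pairs.values())


class TestAnnotationLinks:
    def test_benchmark_source_refused_without_override(self, toy_world):
        ont, ann = toy_world
        with pytest.raises(PlnetError, match="benchmark"):
            annotation_links(ann, ont, benchmark_source="toy")
        ls = annotation_links(ann, ont, benchmark_source="toy", allow_benchmark=True)
        assert len(ls) > 0

    def test_flat_vocabulary_hand_computed_matrix(self):
        ont = Ontology.flat(["k1", "k2", "k3"])
        ann = AnnotationSet(
            {"g1": {"k1"}, "g2": {"k1", "k2"}, "g3": {"k3"}}, source="kegg"
        )
        ls = annotation_links(ann, ont, method="flat")
        # IC: k1 covers 2/3 genes, k2 and k3 one each
        import math

        assert ls.score("g1", "g2") == pytest.approx(-math.log(2 / 3))
        assert ("g1", "g3") not in ls  # disjoint -> score 0 -> filtered

    def test_hierarchical_scores_match_pairwise_helper(self, toy_world):
        from plnet import pairwise_gene_similarity

        ont, ann = toy_world
        ls = annotation_links(ann, ont, method="bma")
        truth = pairwise_gene_similarity(ann, ont, method="bma")
        for key, val in ls.pairs.items():
            assert val == pytest.approx(truth[key])
        # every positive truth pair is present
        assert set(ls.pairs) == {k for k, v in truth.items() if v > 0}


class TestScoredPairsIO:
    def test_duplicates_collapse_to_max_and_self_pairs_drop(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("a\tb\t1.0\nb\ta\t2.0\na\ta\t3.0\n")
        ls = read_scored_pairs(str(path))
        assert ls.pairs == {("a", "b"): 2.0}

    def test_empty_file_is_empty_linkset_not_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert len(read_scored_pairs(str(path))) == 0

    def test_malformed_line_error_names_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\t1.0\na\tb\n")
        with pytest.raises(FormatError, match="bad.tsv:2"):
            read_scored_pairs(str(path))
        path.write_text("a\tb\tnot-a-number\n")
        with pytest.raises(FormatError, match="bad.tsv:1"):
            read_scored_pairs(str(path))

    def test_round_trip_preserves_pairs_scores_and_kind(self, tmp_path, rng):
        pairs = {(f"a{i}", f"b{i}"): float(v)
                 for i, v in enumerate(rng.normal(size=50))}
        ls = LinkSet(source="src", pairs=pairs, score_kind="raw")
        path = tmp_path / "ls.tsv"
        write_linkset(ls, str(path))
        back = read_linkset(str(path))
        assert back.source == "src"
        assert back.score_kind == "raw"
        assert back.pairs == pytest.approx(ls.pairs)

    def test_shuffled_input_yields_identical_linkset(self, tmp_path, rng):
        lines = [f"g{i}\tg{i + 1}\t{i * 0.1:.3f}" for i in range(30)]
        p1 = tmp_path / "fwd.tsv"
        p2 = tmp_path / "shuf.tsv"
        p1.write_text("\n".join(lines) + "\n")
        shuffled = [lines[i] for i in rng.permutation(len(lines))]
        p2.write_text("\n".join(shuffled) + "\n")
        assert read_scored_pairs(str(p1)).pairs == read_scored_pairs(str(p2)).pairs


def test_ortholog_mapping_drops_unmapped_and_collapses(caplog):
    ls = LinkSet("s", {("m1", "m2"): 1.0, ("m3", "m4"): 2.0, ("m1", "m5"): 3.0})
    mapped = map_genes(ls, {"m1": "H1", "m2": "H2", "m3": "H3", "m4": "H3x", "m5": "H2"})
    assert mapped.pairs == {("H1", "H2"): 3.0, ("H3", "H3x"): 2.0}
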