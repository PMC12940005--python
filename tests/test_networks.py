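"""Co-occurrence graphs, modularity, Louvain, and co-mention analysis."""

import itertools
from collections import Counter

import networkx as nx
import numpy as np
import pytest

import litaxis as lx
from litaxis.corpus import CleanDocument
from litaxis.networks import (
    build_cooccurrence,
    comention_matrix,
    louvain_communities,
    modularity,
    top_axes,
)


def _doc(tokens, pmid="d0"):
    return CleanDocument(pmid, list(tokens), 2020)


def _window_oracle(stream, keywords, window):
    """Independent double-loop enumeration of window pairs."""
    counts = Counter()
    for i, ti in enumerate(stream):
        for j in range(i + 1, len(stream)):
            if j - i > window - 1:
                break
            tj = stream[j]
            if ti in keywords and tj in keywords and ti != tj:
                counts[frozenset((ti, tj))] += 1
    return counts


class TestCooccurrence:
    @pytest.mark.parametrize("window", [2, 3, 5])
    def test_matches_enumeration_oracle(self, window, rng):
        alphabet = list("abcdefg")
        for _ in range(30):
            stream = list(rng.choice(alphabet, size=int(rng.integers(2, 40))))
            keywords = set(rng.choice(alphabet, size=4))
            g = build_cooccurrence(
                [_doc(stream)], keywords, window=window, min_weight=1,
                restrict_stream=False,
            )
            oracle = _window_oracle(stream, keywords, window)
            got = {
                frozenset((u, v)): d["weight"] for u, v, d in g.edges(data=True)
            }
            assert got == {k: w for k, w in oracle.items() if w >= 1}

    def test_filtered_stream_mode_matches_oracle_on_filtered_tokens(self, rng):
        stream = list(rng.choice(list("abcxyz"), size=50))
        keywords = {"a", "b", "c"}
        g = build_cooccurrence(
            [_doc(stream)], keywords, window=3, min_weight=1, restrict_stream=True
        )
        filtered = [t for t in stream if t in keywords]
        oracle = _window_oracle(filtered, keywords, 3)
        got = {frozenset((u, v)): d["weight"] for u, v, d in g.edges(data=True)}
        assert got == dict(oracle)

    def test_threshold_drops_light_edges(self):
        g = build_cooccurrence([_doc(["a", "b"])], {"a", "b"}, window=2, min_weight=1)
        assert g["a"]["b"]["weight"] == 1
        g2 = build_cooccurrence([_doc(["a", "b"])], {"a", "b"}, window=2, min_weight=2)
        assert g2.number_of_edges() == 0

    def test_no_self_loops(self):
        g = build_cooccurrence(
            [_doc(["a"] * 10)], {"a"}, window=5, min_weight=1
        )
        assert g.number_of_edges() == 0

    def test_corpus_order_invariance(self, rng):
        docs = [
            _doc(rng.choice(list("abcd"), size=20), pmid=f"d{i}")
            for i in range(5)
        ]
        kw = {"a", "b", "c", "d"}
        g1 = build_cooccurrence(docs, kw, window=4, min_weight=1)
        g2 = build_cooccurrence(list(reversed(docs)), kw, window=4, min_weight=1)
        assert nx.utils.graphs_equal(g1, g2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_cooccurrence([], {"a"}, window=1)
        with pytest.raises(ValueError):
            build_cooccurrence([], set(), window=5)


class TestModularity:
    def _two_triangles(self):
        g = nx.Graph()
        g.add_weighted_edges_from(
            [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
             ("x", "y", 1), ("y", "z", 1), ("x", "z", 1)]
        )
        return g

    def test_single_community_is_zero(self):
        g = self._two_triangles()
        part = {n: 0 for n in g}
        assert modularity(g, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles_natural_partition(self):
        g = self._two_triangles()
        part = {"a": 0, "b": 0, "c": 0, "x": 1, "y": 1, "z": 1}
        assert modularity(g, part) == pytest.approx(0.5, abs=1e-12)

    def test_matches_networkx_oracle(self, rng):
        g = nx.gnp_random_graph(15, 0.3, seed=4)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.integers(1, 5))
        part = {n: int(rng.integers(0, 4)) for n in g}
        comms = [
            {n for n in g if part[n] == c} for c in sorted(set(part.values()))
        ]
        expected = nx.community.modularity(g, comms, weight="weight")
        assert modularity(g, part) == pytest.approx(expected, abs=1e-12)

    def test_uncovered_node_and_empty_graph_rejected(self):
        g = self._two_triangles()
        with pytest.raises(ValueError, match="cover"):
            modularity(g, {"a": 0})
        with pytest.raises(ValueError):
            modularity(nx.Graph(), {})


class TestLouvain:
    def test_two_triangles_found_with_q_half(self):
        g = nx.Graph()
        g.add_weighted_edges_from(
            [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
             ("x", "y", 1), ("y", "z", 1), ("x", "z", 1)]
        )
        part = louvain_communities(g, seed=0)
        assert part.n_communities == 2
        assert part.Q == pytest.approx(0.5, abs=1e-12)
        assert set(part.membership.values()) == {0, 1}

    def test_complete_graph_single_community(self):
        part = louvain_communities(nx.complete_graph(4), seed=0)
        assert part.n_communities == 1

    def test_edgeless_graph_singletons_with_warning(self):
        g = nx.Graph()
        g.add_nodes_from(["u", "v"])
        with pytest.warns(UserWarning, match="edgeless"):
            part = louvain_communities(g, seed=0)
        assert part.Q == 0.0
        assert part.n_communities == 2

    def test_beats_planted_partition_modularity(self):
        for seed in range(5):
            g = nx.planted_partition_graph(3, 10, 0.8, 0.05, seed=seed)
            g = nx.Graph(g)
            nx.set_edge_attributes(g, 1.0, "weight")
            planted = {n: n // 10 for n in g}
            part = louvain_communities(g, seed=seed)
            assert part.Q >= modularity(g, planted) - 1e-9


class TestComention:
    def test_ochiai_arithmetic(self):
        docs = (
            [_doc(["candida", "il6"], pmid=f"a{i}") for i in range(2)]
            + [_doc(["candida"], pmid=f"b{i}") for i in range(2)]
            + [_doc(["il6"], pmid=f"c{i}") for i in range(7)]
        )
        m = comention_matrix(docs, lexicons={"microbial": ["candida"], "cytokine": ["il6"]})
        # c_a=4, c_b=9, c_ab=2 -> 2 / sqrt(36)
        assert m.scores.loc["candida", "il6"] == pytest.approx(1 / 3, abs=1e-12)
        assert m.scores.loc["candida", "candida"] == 1.0
        assert m.scores.loc["il6", "candida"] == m.scores.loc["candida", "il6"]

    def test_absent_and_disjoint_terms_score_zero(self):
        docs = [_doc(["candida"]), _doc(["cortisol"], pmid="d1")]
        m = comention_matrix(docs)
        assert m.scores.loc["candida", "cortisol"] == 0.0
        assert m.scores.loc["tnf", "tnf"] == 0.0  # never mentioned
        assert ((m.scores.values >= 0) & (m.scores.values <= 1)).all()

    def test_duplicating_corpus_leaves_scores_unchanged(self, default_docs):
        docs, _ = default_docs
        m1 = comention_matrix(docs)
        doubled = docs + [
            CleanDocument(d.pmid + "_copy", d.tokens, d.year) for d in docs
        ]
        m2 = comention_matrix(doubled)
        np.testing.assert_allclose(m1.scores.values, m2.scores.values, atol=1e-12)

    def test_lexicon_terms_are_normalised(self):
        docs = [_doc(["mutan", "tnf"])]
        m = comention_matrix(docs)  # default lexicon lists "mutans"
        assert "mutan" in m.terms
        assert m.doc_counts["mutan"] == 1


class TestTopAxes:
    def test_single_nonzero_pair_ranks_first(self):
        docs = [_doc(["candida", "il6", "npy"], pmid="d0"),
                _doc(["cortisol"], pmid="d1")]
        m = comention_matrix(docs)
        pairs, _ = top_axes(m)
        assert pairs[0][0] in {("candida", "il6"), ("il6", "candida")}
        assert pairs[0][1] > 0

    def test_all_equal_scores_tie_breaks_lexicographically(self):
        # every lexicon term in every document -> all pairwise scores 1
        terms = ["candida", "mutan", "il6", "tnf", "cortisol", "dhea", "npy"]
        docs = [_doc(terms, pmid=f"d{i}") for i in range(3)]
        m = comention_matrix(docs)
        _, triad = top_axes(m)
        assert triad.terms == ("candida", "il6", "cortisol")

    def test_planted_triad_recovered(self):
        records, truth = lx.generate_corpus(lx.triad_corpus_config(seed=0, triad_prob=1.0))
        docs = lx.clean_corpus(records)
        m = comention_matrix(docs)
        pairs, triad = top_axes(m, k=10)
        assert triad.terms == ("candida", "il6", "cortisol")
        assert triad.min_pairwise > 0.5
        # the planted pairwise co-mentions appear among the strongest pairs
        top_pairs = {p for p, _ in pairs}
        assert ("candida", "il6") in top_pairs
        assert ("candida", "cortisol") in top_pairs

    def test_empty_lexicon_rejected(self):
        docs = [_doc(["candida"])]
        m = comention_matrix(docs, lexicons={"microbial": ["candida"], "cytokine": ["il6"]})
        with pytest.raises(ValueError, match="neuroendocrine"):
            top_axes(m)
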