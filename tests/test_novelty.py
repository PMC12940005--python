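"""Topic metrics: semantic distance, temporal entropy, Novelty Index."""

import math

import numpy as np
import pytest

import litaxis as lx
from litaxis.novelty import (
    density_score,
    diversity_score,
    novelty_index,
    semantic_distance,
    temporal_entropy,
)


class TestSemanticDistance:
    def test_centroid_equal_to_global_has_zero_distance(self):
        g = np.array([1.0, 2.0, 3.0])
        s, d_raw, _ = semantic_distance(np.vstack([g, [1.0, 0.0, 0.0]]), g)
        assert s[0] == pytest.approx(1.0, abs=1e-12)
        assert d_raw[0] == pytest.approx(0.0, abs=1e-12)

    def test_minmax_scaling_endpoints(self):
        # construct two centroids with d_raw 0.1 and 0.3 against g = e1
        g = np.array([1.0, 0.0])
        def centroid(cos):
            return np.array([cos, math.sqrt(1 - cos ** 2)])
        _, d_raw, d = semantic_distance(
            np.vstack([centroid(0.9), centroid(0.7)]), g
        )
        np.testing.assert_allclose(d_raw, [0.1, 0.3], atol=1e-12)
        np.testing.assert_allclose(d, [0.0, 1.0], atol=1e-12)

    def test_matches_dot_product_oracle(self, rng):
        C = rng.normal(size=(5, 8))
        g = rng.normal(size=8)
        s, d_raw, _ = semantic_distance(C, g)
        for k in range(5):
            expected = (C[k] @ g) / (np.linalg.norm(C[k]) * np.linalg.norm(g))
            assert s[k] == pytest.approx(expected, abs=1e-12)
            assert d_raw[k] == pytest.approx(1 - expected, abs=1e-12)

    def test_zero_norm_centroid_names_topic(self):
        with pytest.raises(ValueError, match="topic 1"):
            semantic_distance(np.array([[1.0, 0.0], [0.0, 0.0]]), np.array([1.0, 0.0]))

    def test_scale_invariance(self, rng):
        C = rng.normal(size=(4, 6))
        g = rng.normal(size=6)
        s1, _, d1 = semantic_distance(C, g)
        s2, _, d2 = semantic_distance(3.7 * C, 3.7 * g)
        np.testing.assert_allclose(s1, s2, atol=1e-12)
        np.testing.assert_allclose(d1, d2, atol=1e-12)


class TestTemporalEntropy:
    def test_single_year_is_zero(self):
        assert temporal_entropy({2020: 17}) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_four_years_is_ln4(self):
        H = temporal_entropy({y: 5 for y in range(2000, 2004)})
        assert H == pytest.approx(math.log(4), abs=1e-12)

    def test_skewed_counts_value(self):
        H = temporal_entropy({2020: 3, 2021: 1})
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert H == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.5623, abs=5e-5)

    def test_new_year_never_decreases_entropy(self, rng):
        for _ in range(50):
            n_years = rng.integers(1, 6)
            counts = {2000 + i: int(c) for i, c in
                      enumerate(rng.integers(1, 20, size=n_years))}
            H_before = temporal_entropy(counts)
            counts[2099] = 1
            assert temporal_entropy(counts) >= H_before - 1e-12

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            temporal_entropy({2020: 0})
        with pytest.raises(ValueError):
            temporal_entropy({2020: -1, 2021: 3})


class TestNoveltyIndex:
    def test_constant_columns_give_zero(self):
        out = novelty_index([0.5, 0.5], [1.0, 1.0])
        np.testing.assert_allclose(out["ni"], [0.0, 0.0], atol=1e-12)

    def test_two_point_extremes(self):
        out = novelty_index([0.0, 1.0], [0.0, 1.0])
        np.testing.assert_allclose(out["ni"], [-2.0, 2.0], atol=1e-12)
        assert list(out["ranking"]) == [1, 0]

    def test_matches_zscore_oracle_and_sums_to_zero(self, rng):
        d = rng.random(7)
        H = rng.random(7) * 3
        out = novelty_index(d, H)
        z = lambda x: (x - x.mean()) / x.std()
        np.testing.assert_allclose(out["ni"], z(d) + z(H), atol=1e-12)
        assert abs(out["ni"].sum()) < 1e-9

    def test_log_base_invariance(self, rng):
        d = rng.random(5)
        H = rng.random(5)
        out_nats = novelty_index(d, H)
        out_bits = novelty_index(d, H / math.log(2))
        np.testing.assert_allclose(out_nats["ni"], out_bits["ni"], atol=1e-10)

    def test_single_topic_rejected(self):
        with pytest.raises(ValueError, match="2 topics"):
            novelty_index([0.3], [1.1])


class TestDensityAndDiversity:
    def test_density_matches_share(self):
        assert density_score(18, 234) == pytest.approx(0.077, abs=5e-4)
        assert density_score(73, 234) == pytest.approx(0.312, abs=5e-4)
        assert density_score(10, 10) == 1.0
        with pytest.raises(ValueError):
            density_score(0, 10)
        with pytest.raises(ValueError):
            density_score(5, 0)

    def test_diversity_default_definition(self):
        score = diversity_score([["term"] * 100], vocab_size=1000)
        assert score == pytest.approx(1e-5, abs=1e-12)

    def test_diversity_symmetry_and_oracle(self, rng):
        words = [f"w{i}" for i in range(30)]
        toks = [list(rng.choice(words, size=40)) for _ in range(3)]
        a = diversity_score(toks, vocab_size=30)
        b = diversity_score(list(reversed(toks)), vocab_size=30)
        assert a == b
        flat = [t for ts in toks for t in ts]
        assert a == pytest.approx(len(set(flat)) / (len(flat) * 30), abs=1e-15)


class TestMetricsTable:
    def test_density_column_sums_to_one(self, default_docs, default_assignment):
        docs, _ = default_docs
        E, assignment = default_assignment
        metrics = lx.compute_topic_metrics(E, assignment, docs)
        assert metrics["density"].sum() == pytest.approx(1.0, abs=1e-9)
        assert metrics["novelty_index"].sum() == pytest.approx(0.0, abs=1e-9)
        assert ((metrics["d"] >= 0) & (metrics["d"] <= 1)).all()

    def test_peripheral_dispersed_topic_ranks_first(self):
        """A topic that is both semantically peripheral and temporally
        dispersed should top the Novelty Index ranking."""
        shared = ["carie", "child", "saliva", "dental", "tooth", "oral", "health"]
        pools = (
            shared + ["fluoride", "enamel", "varnish"],
            shared + ["risk", "mother", "behaviour"],
            ["tac", "gpx", "sod", "antioxidant", "oxidative",
             "redox", "peroxidase", "glutathione", "stress", "enzyme"],
        )
        wins = 0
        for seed in range(20):
            cfg = lx.CorpusSimConfig(
                keyword_pools=pools, year_concentration=(0.05, 0.05, 50.0),
                seed=seed,
            )
            records, truth = lx.generate_corpus(cfg)
            docs = lx.clean_corpus(records)
            _, docs = lx.build_vocabulary(docs)
            E = lx.embed_documents(docs, dim=16, seed=seed)
            labels = np.array([truth.doc_topic_labels[d.pmid] for d in docs])
            centroids = np.vstack(
                [E.vectors[labels == k].mean(axis=0) for k in range(3)]
            )
            a = lx.TopicAssignment(
                doc_ids=[d.pmid for d in docs], labels=labels,
                centroids=centroids, K=3,
            )
            metrics = lx.compute_topic_metrics(E, a, docs)
            top = metrics.sort_values("novelty_index", ascending=False)
            wins += int(top["topic_id"].iloc[0] == 2)
        assert wins >= 19
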