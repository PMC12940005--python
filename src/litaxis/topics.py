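"""Topic assignment: document embedding, partitional clustering with a noise
label, and class-based TF-IDF topic summaries.

The default embedding backend is deterministic: TF-IDF vectors reduced by
truncated SVD (latent semantic analysis) and row-normalised.  Clustering is
spherical k-means (seeded restarts on unit-norm vectors); documents whose
distance to their centroid exceeds the (1 - noise_quantile) quantile are
relabelled -1, emulating the unassigned documents of density-based clustering.

Class-based TF-IDF concatenates each topic's documents into one pseudo-
document and scores term t in class c as

    w(t, c) = tf_{t,c} * ln(1 + A / f_t)

with tf_{t,c} the count of t in class c, f_t the total count of t across
classes, and A the average token count per class.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.preprocessing import normalize

from .corpus import CleanDocument

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingMatrix:
    doc_ids: list[str]
    vectors: np.ndarray
    backend_name: str
    dim: int


@dataclass
class TopicAssignment:
    doc_ids: list[str]
    labels: np.ndarray  # int, -1 = noise
    centroids: np.ndarray  # K x dim, row k = mean vector of members of topic k
    K: int

    def members(self, topic: int) -> list[str]:
        return [d for d, l in zip(self.doc_ids, self.labels) if l == topic]


@dataclass
class TopicSummary:
    topic_id: int
    top_terms: list[tuple[str, float]]
    ctfidf_params: dict


def _identity_analyzer(tokens):  # module-level so the vectorizer is picklable
    return tokens


def embed_documents(
    docs: Sequence[CleanDocument],
    dim: int = 16,
    seed: int = 0,
    backend: str = "tfidf-svd",
) -> EmbeddingMatrix:
    """Embed cleaned documents into a dense semantic space.

    ``dim`` must not exceed the vocabulary size; when it equals the vocabulary
    size the TF-IDF matrix is used densely without reduction.
    """
    if backend != "tfidf-svd":
        raise ValueError(f"unknown embedding backend {backend!r}")
    if not docs:
        raise ValueError("empty corpus")
    vocab = sorted({t for d in docs for t in d.tokens})
    if not vocab:
        raise ValueError("empty vocabulary: no tokens survive cleaning")
    if dim < 1 or dim > len(vocab):
        raise ValueError(f"dim must be in [1, {len(vocab)}] (vocabulary size)")
    vec = TfidfVectorizer(analyzer=_identity_analyzer, vocabulary=vocab)
    X = vec.fit_transform([d.tokens for d in docs])
    if dim == len(vocab):
        V = X.toarray()
    else:
        svd = TruncatedSVD(n_components=dim, random_state=seed)
        V = svd.fit_transform(X)
    V = normalize(V)
    return EmbeddingMatrix(
        doc_ids=[d.pmid for d in docs],
        vectors=np.asarray(V, dtype=float),
        backend_name=backend,
        dim=dim,
    )


def cluster_documents(
    E: EmbeddingMatrix,
    K: int,
    noise_quantile: float = 0.03,
    seed: int = 0,
) -> TopicAssignment:
    """Partition documents into K topics plus a -1 noise label.

    Spherical k-means with 10 seeded restarts, fitted on documents sorted by
    id (so the assignment is equivariant under permutations of the input
    order).  Cluster ids are canonicalised by first appearance in id order.
    """
    n = len(E.doc_ids)
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}] (number of documents)")
    if not 0.0 <= noise_quantile < 1.0:
        raise ValueError("noise_quantile must be in [0, 1)")

    order = np.argsort(np.asarray(E.doc_ids, dtype=object))
    X = normalize(E.vectors[order])
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    raw = km.fit_predict(X)

    # canonical relabelling: clusters numbered by first appearance in id order
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel)
    labels_sorted = np.array([relabel[lab] for lab in raw], dtype=int)

    dists = np.linalg.norm(X - km.cluster_centers_[raw], axis=1)
    if noise_quantile > 0.0:
        threshold = np.quantile(dists, 1.0 - noise_quantile)
        labels_sorted[dists > threshold] = -1

    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted

    centroids = np.zeros((K, E.vectors.shape[1]))
    for k in range(K):
        mask = labels == k
        if mask.any():
            centroids[k] = E.vectors[mask].mean(axis=0)
        else:
            logger.warning("topic %d lost all members to the noise filter", k)
    return TopicAssignment(
        doc_ids=list(E.doc_ids), labels=labels, centroids=centroids, K=K
    )


def ctfidf_keywords(
    docs: Sequence[CleanDocument],
    assignment: TopicAssignment,
    top_n: int = 10,
    include_noise: bool = False,
) -> list[TopicSummary]:
    """Class-based TF-IDF keywords per topic, ties broken lexicographically."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    label_of = dict(zip(assignment.doc_ids, assignment.labels))
    classes = sorted({int(l) for l in assignment.labels if include_noise or l >= 0})

    tf: dict[int, Counter] = {c: Counter() for c in classes}
    for doc in docs:
        lab = int(label_of.get(doc.pmid, -1))
        if lab in tf:
            tf[lab].update(doc.tokens)

    class_sizes = {c: sum(tf[c].values()) for c in classes}
    A = float(np.mean(list(class_sizes.values()))) if classes else 0.0
    f_t: Counter = Counter()
    for c in classes:
        f_t.update(tf[c])

    summaries = []
    for c in classes:
        if class_sizes[c] == 0:
            logger.warning("topic %d has no tokens; empty summary", c)
            summaries.append(
                TopicSummary(topic_id=c, top_terms=[], ctfidf_params={"A": A})
            )
            continue
        weights = {
            term: count * math.log1p(A / f_t[term]) for term, count in tf[c].items()
        }
        ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        summaries.append(
            TopicSummary(
                topic_id=c,
                top_terms=ranked,
                ctfidf_params={"A": A, "f_t": {t: f_t[t] for t, _ in ranked}},
            )
        )
    return summaries
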