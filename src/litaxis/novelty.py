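"""Topic-level novelty metrics.

For each non-noise topic: cosine similarity s of the topic centroid to the
global corpus centroid, distance d_raw = 1 - s min-max scaled to [0, 1]
across topics, Shannon entropy H (nats) of the topic's year distribution,
and the composite Novelty Index

    NI = z(d) + z(H)

where z is the population z-score across topics.  NI sums to zero across
topics by construction; an optional min-max rescaling to [0, 1] is provided
for display.  The noise topic (-1) is excluded throughout.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy

from .corpus import CleanDocument
from .topics import EmbeddingMatrix, TopicAssignment


def semantic_distance(
    centroids: np.ndarray, global_centroid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-topic (s, d_raw, d): cosine to global centroid, 1 - s, min-max scaled."""
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    g = np.asarray(global_centroid, dtype=float)
    gnorm = np.linalg.norm(g)
    if gnorm == 0:
        raise ValueError("global centroid has zero norm")
    norms = np.linalg.norm(centroids, axis=1)
    for k, nk in enumerate(norms):
        if nk == 0:
            raise ValueError(f"topic {k}: centroid has zero norm")
    s = centroids @ g / (norms * gnorm)
    d_raw = 1.0 - s
    span = d_raw.max() - d_raw.min()
    if span == 0:
        d = np.zeros_like(d_raw)
    else:
        d = (d_raw - d_raw.min()) / span
    return s, d_raw, d


def temporal_entropy(year_counts: Mapping[int, float]) -> float:
    """Shannon entropy (nats) of a topic's publication-year distribution."""
    counts = np.asarray(list(year_counts.values()), dtype=float)
    if (counts < 0).any():
        raise ValueError("year counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("at least one year count must be positive")
    return float(_shannon_entropy(counts))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()  # population standard deviation
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def novelty_index(
    d: Sequence[float], H: Sequence[float]
) -> dict[str, np.ndarray]:
    """z-score d and H across topics and combine as NI = z(d) + z(H).

    Returns z_d, z_H, ni, and the NI ranking (topic indices, descending NI).
    Constant columns z-score to all zeros.
    """
    d = np.asarray(d, dtype=float)
    H = np.asarray(H, dtype=float)
    if d.shape != H.shape:
        raise ValueError("d and H must have equal length")
    if len(d) < 2:
        raise ValueError("novelty index needs at least 2 topics")
    z_d = _zscore(d)
    z_H = _zscore(H)
    ni = z_d + z_H
    ranking = np.argsort(-ni, kind="stable")
    return {"z_d": z_d, "z_H": z_H, "ni": ni, "ranking": ranking}


def density_score(n_topic: int, n_total: int) -> float:
    """Topic share of the corpus: n_topic / n_total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 < n_topic <= n_total:
        raise ValueError("n_topic must be in (0, n_total]")
    return n_topic / n_total


def diversity_score(
    topic_token_lists: Sequence[Sequence[str]],
    vocab_size: int,
    definition: str = "distinct-per-token",
) -> float:
    """Lexical diversity of a topic (pluggable definition).

    Default ``distinct-per-token``: number of distinct terms used by the topic
    divided by (topic token count x corpus vocabulary size).  Alternative
    ``type-token``: distinct terms / topic token count.
    """
    tokens = [t for toks in topic_token_lists for t in toks]
    if not tokens:
        raise ValueError("topic has no tokens")
    if vocab_size <= 0:
        raise ValueError("vocab_size must be positive")
    distinct = len(set(tokens))
    if definition == "distinct-per-token":
        return distinct / (len(tokens) * vocab_size)
    if definition == "type-token":
        return distinct / len(tokens)
    raise ValueError(f"unknown diversity definition {definition!r}")


def compute_topic_metrics(
    E: EmbeddingMatrix,
    assignment: TopicAssignment,
    docs: Sequence[CleanDocument],
    diversity_definition: str = "distinct-per-token",
    scaled_ni: bool = True,
) -> pd.DataFrame:
    """Full Table-3-style metrics for topics 0..K-1 (noise excluded).

    Columns: topic_id, n_docs, density, diversity, s, d_raw, d, H, z_d, z_H,
    novelty_index (+ novelty_index_scaled, a [0,1] display rescaling).
    """
    doc_by_id = {d.pmid: d for d in docs}
    topics = [k for k in range(assignment.K) if (assignment.labels == k).any()]
    if len(topics) < 2:
        raise ValueError("metrics need at least 2 non-empty topics")

    global_centroid = E.vectors.mean(axis=0)
    centroids = assignment.centroids[topics]
    s, d_raw, d = semantic_distance(centroids, global_centroid)

    vocab = {t for doc in docs for t in doc.tokens}
    n_total = int(sum((assignment.labels == k).sum() for k in topics))

    rows = []
    H_vals = []
    for i, k in enumerate(topics):
        members = assignment.members(k)
        member_docs = [doc_by_id[m] for m in members if m in doc_by_id]
        year_counts: dict[int, int] = {}
        for md in member_docs:
            year_counts[md.year] = year_counts.get(md.year, 0) + 1
        H = temporal_entropy(year_counts)
        H_vals.append(H)
        rows.append(
            {
                "topic_id": k,
                "n_docs": len(members),
                "density": density_score(len(members), n_total),
                "diversity": diversity_score(
                    [md.tokens for md in member_docs],
                    len(vocab),
                    definition=diversity_definition,
                ),
                "s": s[i],
                "d_raw": d_raw[i],
                "d": d[i],
                "H": H,
            }
        )

    ni = novelty_index(d, np.asarray(H_vals))
    df = pd.DataFrame(rows)
    df["z_d"] = ni["z_d"]
    df["z_H"] = ni["z_H"]
    df["novelty_index"] = ni["ni"]
    if scaled_ni:
        span = df["novelty_index"].max() - df["novelty_index"].min()
        if span == 0:
            df["novelty_index_scaled"] = 0.0
        else:
            df["novelty_index_scaled"] = (
                df["novelty_index"] - df["novelty_index"].min()
            ) / span
    df.attrs["diversity_definition"] = diversity_definition
    return df
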