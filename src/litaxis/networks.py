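"""Keyword co-occurrence networks, Louvain communities, and normalized
document-level co-mention analysis.

Co-occurrence uses a forward-looking sliding window: token position i pairs
with positions j in (i, i + window - 1] when both tokens belong to the
keyword set and differ; multiplicities accumulate across the corpus and edges
below ``min_weight`` are dropped.  By default the token stream is first
filtered to the keyword set (window positions count keywords only); set
``restrict_stream=False`` to slide the window over the full cleaned stream.

Co-mention scores are Ochiai coefficients on document-incidence vectors:
score(a, b) = c_ab / sqrt(c_a * c_b) with c_* document counts.  Jaccard is
available as an alternative normalisation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .corpus import CleanDocument, normalise_term

logger = logging.getLogger(__name__)

#: default lexicons for the microbial-cytokine-neuroendocrine co-mention analysis
DEFAULT_LEXICONS: dict[str, tuple[str, ...]] = {
    "microbial": ("candida", "mutans"),
    "cytokine": ("il6", "tnf"),
    "neuroendocrine": ("cortisol", "dhea", "npy"),
    "peptide_mucosal": ("lactoferrin", "defensin", "iga"),
}

TRIAD_LEXICONS = ("microbial", "cytokine", "neuroendocrine")


@dataclass
class CommunityPartition:
    membership: dict  # node -> community id (contiguous from 0)
    Q: float
    resolution: float = 1.0

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


@dataclass
class ComentionMatrix:
    scores: pd.DataFrame  # symmetric, terms x terms, in [0, 1]
    doc_counts: dict[str, int]
    lexicons: dict[str, list[str]]  # lexicon name -> normalized terms
    normalisation: str = "ochiai"

    @property
    def terms(self) -> list[str]:
        return list(self.scores.index)


# ---------------------------------------------------------------------------
# co-occurrence graph
# ---------------------------------------------------------------------------

def build_cooccurrence(
    docs: Sequence[CleanDocument],
    keywords: set[str] | frozenset[str],
    window: int = 5,
    min_weight: int = 2,
    restrict_stream: bool = True,
) -> nx.Graph:
    """Sliding-window keyword co-occurrence graph (undirected, weighted)."""
    if window < 2:
        raise ValueError("window must be >= 2")
    if not keywords:
        raise ValueError("keywords must be non-empty")
    counts: Counter = Counter()
    for doc in docs:
        stream = (
            [t for t in doc.tokens if t in keywords]
            if restrict_stream
            else doc.tokens
        )
        n = len(stream)
        for i in range(n):
            ti = stream[i]
            if ti not in keywords:
                continue
            for j in range(i + 1, min(i + window, n)):
                tj = stream[j]
                if tj in keywords and tj != ti:
                    counts[tuple(sorted((ti, tj)))] += 1
    g = nx.Graph(window=window, min_weight=min_weight)
    for (a, b), w in counts.items():
        if w >= min_weight:
            g.add_edge(a, b, weight=w)
    return g


def modularity(
    g: nx.Graph,
    partition: Mapping,
    resolution: float = 1.0,
) -> float:
    """Weighted Newman-Girvan modularity Q of a node partition.

    Q = sum_c [ L_c / m - resolution * (d_c / 2m)^2 ], with L_c the total
    weight of edges inside community c, d_c its total weighted degree and m
    the total edge weight.
    """
    missing = [n for n in g.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    m = g.size(weight="weight")
    if m == 0:
        raise ValueError("graph has no edge weight; modularity undefined")
    internal: Counter = Counter()
    degree: Counter = Counter()
    for u, v, w in g.edges(data="weight", default=1.0):
        cu, cv = partition[u], partition[v]
        degree[cu] += w
        degree[cv] += w
        if cu == cv:
            internal[cu] += w
    return float(
        sum(
            internal[c] / m - resolution * (degree[c] / (2.0 * m)) ** 2
            for c in degree
        )
    )


def louvain_communities(
    g: nx.Graph, seed: int = 0, resolution: float = 1.0
) -> CommunityPartition:
    """Louvain partition (two-phase modularity maximisation) with its Q.

    Community ids are contiguous from 0, ordered by each community's smallest
    node.  An edgeless graph yields singleton communities with Q = 0 and a
    warning.
    """
    if g.number_of_edges() == 0:
        warnings.warn("edgeless graph: every node is its own community, Q = 0")
        membership = {n: i for i, n in enumerate(sorted(g.nodes))}
        return CommunityPartition(membership=membership, Q=0.0, resolution=resolution)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: min(c))
    membership = {n: i for i, comm in enumerate(communities) for n in comm}
    Q = modularity(g, membership, resolution=resolution)
    return CommunityPartition(membership=membership, Q=Q, resolution=resolution)


# ---------------------------------------------------------------------------
# co-mention analysis
# ---------------------------------------------------------------------------

def comention_matrix(
    docs: Sequence[CleanDocument],
    lexicons: Mapping[str, Sequence[str]] | None = None,
    normalisation: str = "ochiai",
) -> ComentionMatrix:
    """Normalized document-level co-mention matrix across named lexicons.

    Lexicon terms are passed through the same token normalisation as the
    corpus (so ``mutans`` matches the cleaned token ``mutan``).
    """
    if lexicons is None:
        lexicons = DEFAULT_LEXICONS
    if normalisation not in ("ochiai", "jaccard"):
        raise ValueError(f"unknown normalisation {normalisation!r}")

    norm_lexicons: dict[str, list[str]] = {}
    for name, terms in lexicons.items():
        normed = []
        for t in terms:
            nt = normalise_term(t)
            if nt is None:
                raise ValueError(f"lexicon {name!r}: term {t!r} empty after cleaning")
            normed.append(nt)
        norm_lexicons[name] = sorted(set(normed))

    all_terms = sorted({t for ts in norm_lexicons.values() for t in ts})
    incidence = {t: set() for t in all_terms}
    for doc in docs:
        present = set(doc.tokens)
        for t in all_terms:
            if t in present:
                incidence[t].add(doc.pmid)

    doc_counts = {t: len(incidence[t]) for t in all_terms}
    n = len(all_terms)
    scores = np.zeros((n, n))
    for i, a in enumerate(all_terms):
        for j, b in enumerate(all_terms):
            ca, cb = doc_counts[a], doc_counts[b]
            if ca == 0 or cb == 0:
                scores[i, j] = 0.0
            elif i == j:
                scores[i, j] = 1.0
            else:
                cab = len(incidence[a] & incidence[b])
                if normalisation == "ochiai":
                    scores[i, j] = cab / np.sqrt(ca * cb)
                else:
                    scores[i, j] = cab / len(incidence[a] | incidence[b])
    return ComentionMatrix(
        scores=pd.DataFrame(scores, index=all_terms, columns=all_terms),
        doc_counts=doc_counts,
        lexicons=norm_lexicons,
        normalisation=normalisation,
    )


@dataclass
class TriadResult:
    terms: tuple[str, str, str]
    min_pairwise: float
    lexicons: tuple[str, str, str] = TRIAD_LEXICONS


def top_axes(
    m: ComentionMatrix,
    k: int = 10,
    triad_lexicons: Sequence[str] = TRIAD_LEXICONS,
) -> tuple[list[tuple[tuple[str, str], float]], TriadResult]:
    """Top-k co-mention pairs and the strongest cross-lexicon triad.

    The best triad maximises the minimum pairwise score over all
    (microbial, cytokine, neuroendocrine) term triples; ties resolve to the
    lexicographically first triple.
    """
    terms = m.terms
    if not terms:
        raise ValueError("empty co-mention matrix")
    pairs = []
    for a, b in itertools.combinations(terms, 2):
        pairs.append(((a, b), float(m.scores.loc[a, b])))
    pairs.sort(key=lambda kv: (-kv[1], kv[0]))

    pools = []
    for name in triad_lexicons:
        pool = m.lexicons.get(name, [])
        if not pool:
            raise ValueError(f"lexicon {name!r} has no terms")
        pools.append(sorted(pool))
    best: TriadResult | None = None
    for triple in itertools.product(*pools):
        if len(set(triple)) < 3:
            continue
        score = min(
            float(m.scores.loc[a, b]) for a, b in itertools.combinations(triple, 2)
        )
        if best is None or score > best.min_pairwise:
            best = TriadResult(terms=triple, min_pairwise=score,
                               lexicons=tuple(triad_lexicons))
    if best is None:
        raise ValueError("no valid cross-lexicon triple (term overlap?)")
    return pairs[:k], best


# ---------------------------------------------------------------------------
# export helpers
# ---------------------------------------------------------------------------

def write_edge_list(g: nx.Graph, path) -> None:
    """TSV edge list: source, target, weight."""
    rows = [
        {"source": u, "target": v, "weight": d.get("weight", 1)}
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)
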