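"""Local gene-set over-representation analysis (ORA).

Topic keywords are mapped to human gene symbols through a small editable
lexicon table; candidate gene sets from GMT files are tested for
over-representation against a protein-coding background universe using the
hypergeometric upper-tail test, with Benjamini-Hochberg control of the false
discovery rate (default alpha 0.05).  Everything runs offline; no web
enrichment service is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets harmonised against a background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    source_note: str = ""


def make_collection(
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    source_note: str = "",
) -> GeneSetCollection:
    """Harmonise sets against the universe, dropping outside genes with a warning."""
    uni = frozenset(g.upper() for g in universe)
    if not uni:
        raise ValueError("empty background universe")
    harmonised = {}
    for name, genes in sets.items():
        gs = frozenset(g.upper() for g in genes)
        outside = gs - uni
        if outside:
            logger.warning(
                "set %r: %d gene(s) outside universe dropped", name, len(outside)
            )
        harmonised[name] = gs & uni
    return GeneSetCollection(sets=harmonised, universe=uni, source_note=source_note)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: tab-separated lines of set name, description, then gene symbols."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line."""
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


def default_keyword_lexicon() -> dict[str, set[str]]:
    """Shipped keyword -> gene-symbol lexicon (editable data, not code)."""
    with resources.files("litaxis.data").joinpath("keyword_gene_lexicon.csv").open() as fh:
        df = pd.read_csv(fh)
    lexicon: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        genes = {g.strip().upper() for g in str(row.genes).split(";") if g.strip()}
        lexicon[str(row.keyword).lower()] = genes
    return lexicon


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def map_keywords_to_genes(
    keywords: Sequence[str],
    lexicon: Mapping[str, Iterable[str]] | None = None,
) -> tuple[set[str], list[str]]:
    """Union of mapped gene symbols (uppercased); also reports unmapped keywords."""
    if lexicon is None:
        lexicon = default_keyword_lexicon()
    genes: set[str] = set()
    unmapped: list[str] = []
    for kw in keywords:
        hit = lexicon.get(kw.lower())
        if hit:
            genes.update(g.upper() for g in hit)
        else:
            unmapped.append(kw)
    if unmapped:
        logger.info("unmapped keywords: %s", unmapped)
    return genes, unmapped


def hypergeom_enrich(
    query: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation p for every set.

    Query genes outside the universe are dropped with a warning.  Columns:
    set, k, K, n, N, p.
    """
    q = {g.upper() for g in query}
    outside = q - collection.universe
    if outside:
        logger.warning("%d query gene(s) outside universe dropped", len(outside))
        q &= collection.universe
    N = len(collection.universe)
    n = len(q)
    rows = []
    if n == 0:
        logger.warning("empty query after universe filtering")
    for name in sorted(collection.sets):
        gs = collection.sets[name]
        K = len(gs)
        k = len(q & gs)
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the stable upper tail
        p = float(hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    return pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ORA with BH-adjusted q and a significance flag (q < alpha)."""
    df = hypergeom_enrich(query, collection)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < alpha
    else:
        df["q"] = []
        df["significant"] = []
    return df


def bipartite_network(
    result: pd.DataFrame,
    keyword_genes: Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> list[tuple[str, str]]:
    """Keyword-pathway edges for significant sets.

    An edge (keyword, set) exists when the set's q < alpha and at least one
    gene mapped from the keyword lies in the set.
    """
    edges = []
    significant = result.loc[result["q"] < alpha, "set"]
    for name in significant:
        gs = collection.sets.get(name, frozenset())
        for kw in sorted(keyword_genes):
            mapped = {g.upper() for g in keyword_genes[kw]}
            if mapped & gs:
                edges.append((kw, name))
    return edges
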