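"""Bibliographic records, corpus I/O and text cleaning.

The corpus is a flat table of PubMed-like records (one row per article:
``pmid,title,abstract,journal,year,mesh,country``).  Cleaning lowercases the
title+abstract concatenation, re-joins hyphenated marker names (``il-6`` ->
``il6``), splits on non-alphanumeric characters, drops numeric-only tokens,
applies a pluggable lemmatiser, and filters by token length and a stop list.
A small acronym whitelist (ecc, tac, sod, gpx, il6, tnf, iga, npy) is exempt
from the length and stop-list rules because these marker names are central
vocabulary in the ECC-saliva literature.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["pmid", "title", "abstract", "journal", "year", "mesh", "country"]
REQUIRED_COLUMNS = ["pmid", "title", "abstract", "year"]

#: marker acronyms exempt from the length-3 and stop-list rules
MARKER_WHITELIST = frozenset({"ecc", "tac", "sod", "gpx", "il6", "tnf", "iga", "npy"})

# generic methods vocabulary that carries no topical signal in abstracts;
# plural-stripped variants included because the stop check runs after lemmatisation
DOMAIN_STOPWORDS = frozenset(
    {
        "study", "studies", "studie", "analysis", "analyse", "analysi",
        "patient", "significant", "significantly", "result", "conclusion",
        "objective", "background", "method", "aim",
    }
)

DEFAULT_STOPLIST = frozenset(ENGLISH_STOP_WORDS) | DOMAIN_STOPWORDS

MIN_TOKEN_LEN = 3


class SchemaError(ValueError):
    """A corpus table is missing a required column."""


@dataclass
class DocumentRecord:
    """One bibliographic record (title/abstract plus light metadata)."""

    pmid: str
    title: str
    abstract: str
    journal: str = ""
    year: int = 0
    mesh: list[str] = field(default_factory=list)
    country: str | None = None


@dataclass
class CleanDocument:
    """Ordered lowercase lemma stream for one record."""

    pmid: str
    tokens: list[str]
    year: int


@dataclass
class Vocabulary:
    """Corpus-wide term frequencies after minimum-count filtering."""

    counts: dict[str, int]
    min_count: int = 2

    def __contains__(self, term: str) -> bool:
        return term in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def terms(self) -> set[str]:
        return set(self.counts)


# ---------------------------------------------------------------------------
# lemmatisers
# ---------------------------------------------------------------------------

def identity_lemmatiser(token: str) -> str:
    return token


def plural_strip_lemmatiser(token: str) -> str:
    """Strip a trailing plural ``s`` from tokens longer than four characters.

    Tokens ending in ``ss`` (stress, class) are left alone, which also makes
    the rule idempotent.  Deterministic stand-in for a full NLP lemmatiser;
    note it clips e.g. ``caries`` -> ``carie``.
    """
    if len(token) > 4 and token.endswith("s") and not token.endswith("ss"):
        return token[:-1]
    return token


LEMMATISERS: dict[str, Callable[[str], str]] = {
    "identity": identity_lemmatiser,
    "plural-strip": plural_strip_lemmatiser,
}


def _resolve_lemmatiser(lemmatiser: str | Callable[[str], str]) -> Callable[[str], str]:
    if callable(lemmatiser):
        return lemmatiser
    try:
        return LEMMATISERS[lemmatiser]
    except KeyError:
        raise ValueError(
            f"unknown lemmatiser {lemmatiser!r}; options: {sorted(LEMMATISERS)}"
        ) from None


def _marker_patterns(whitelist: Iterable[str]) -> list[tuple[re.Pattern[str], str]]:
    """Regexes re-joining separator-split marker names, e.g. ``il-6`` -> ``il6``."""
    patterns = []
    for term in sorted(whitelist):
        m = re.fullmatch(r"([a-z]+)(\d+)", term)
        if m:
            pat = re.compile(rf"\b{m.group(1)}[\s\-‐-―/]{m.group(2)}\b")
            patterns.append((pat, term))
    return patterns


_DEFAULT_MARKER_PATTERNS = _marker_patterns(MARKER_WHITELIST)
_TOKEN_RE = re.compile(r"[a-z0-9]+")


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def clean_tokens(
    text: str,
    *,
    stoplist: frozenset[str] | set[str] | None = None,
    lemmatiser: str | Callable[[str], str] = "plural-strip",
    whitelist: frozenset[str] = MARKER_WHITELIST,
) -> list[str]:
    """Apply the full cleaning rule chain to free text, preserving order."""
    stop = DEFAULT_STOPLIST if stoplist is None else stoplist
    lemma = _resolve_lemmatiser(lemmatiser)
    patterns = (
        _DEFAULT_MARKER_PATTERNS
        if whitelist is MARKER_WHITELIST
        else _marker_patterns(whitelist)
    )
    text = text.lower()
    for pat, rep in patterns:
        text = pat.sub(rep, text)
    out: list[str] = []
    for tok in _TOKEN_RE.findall(text):
        if tok.isdigit():
            continue
        if tok in whitelist:
            out.append(tok)
            continue
        tok = lemma(tok)
        if tok in whitelist:
            out.append(tok)
            continue
        if len(tok) < MIN_TOKEN_LEN:
            continue
        if tok in stop:
            continue
        out.append(tok)
    return out


def clean_document(
    record: DocumentRecord,
    *,
    stoplist: frozenset[str] | set[str] | None = None,
    lemmatiser: str | Callable[[str], str] = "plural-strip",
    whitelist: frozenset[str] = MARKER_WHITELIST,
) -> CleanDocument:
    """Clean one record's title+abstract concatenation into a token stream."""
    text = f"{record.title} {record.abstract}".strip()
    if not text:
        raise ValueError(f"record {record.pmid}: empty title+abstract")
    tokens = clean_tokens(
        text, stoplist=stoplist, lemmatiser=lemmatiser, whitelist=whitelist
    )
    if not tokens:
        logger.warning("record %s: all tokens removed by cleaning", record.pmid)
    return CleanDocument(pmid=record.pmid, tokens=tokens, year=record.year)


def clean_corpus(records: Sequence[DocumentRecord], **kwargs) -> list[CleanDocument]:
    return [clean_document(r, **kwargs) for r in records]


def normalise_term(
    term: str,
    *,
    lemmatiser: str | Callable[[str], str] = "plural-strip",
    whitelist: frozenset[str] = MARKER_WHITELIST,
) -> str | None:
    """Canonical cleaned form of a single lexicon term (None if filtered away)."""
    toks = clean_tokens(term, stoplist=frozenset(), lemmatiser=lemmatiser, whitelist=whitelist)
    return toks[0] if toks else None


def build_vocabulary(
    docs: Sequence[CleanDocument], min_count: int = 2
) -> tuple[Vocabulary, list[CleanDocument]]:
    """Corpus-frequency filter: drop terms occurring fewer than ``min_count`` times.

    Returns the vocabulary and the documents rewritten without sub-threshold
    terms (order preserved).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter()
    for doc in docs:
        counts.update(doc.tokens)
    kept = {t: c for t, c in counts.items() if c >= min_count}
    vocab = Vocabulary(counts=kept, min_count=min_count)
    new_docs = [
        replace(doc, tokens=[t for t in doc.tokens if t in kept]) for doc in docs
    ]
    return vocab, new_docs


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_corpus(
    path: str | Path, dialect: str = "csv"
) -> list[DocumentRecord]:
    """Read bibliographic records from CSV or MEDLINE text.

    Duplicate pmids are dropped keeping the first occurrence; rows with an
    unparseable year are dropped with a warning.
    """
    if dialect == "csv":
        records = _read_csv(Path(path))
    elif dialect == "medline":
        records = _read_medline(Path(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}; options: csv, medline")
    seen: set[str] = set()
    unique: list[DocumentRecord] = []
    for rec in records:
        if rec.pmid in seen:
            continue
        seen.add(rec.pmid)
        unique.append(rec)
    n_dup = len(records) - len(unique)
    if n_dup:
        logger.info("removed %d duplicate pmid(s)", n_dup)
    return unique


def _read_csv(path: Path) -> list[DocumentRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    records = []
    for row in df.itertuples(index=False):
        try:
            year = int(float(getattr(row, "year")))
        except (TypeError, ValueError):
            logger.warning(
                "record %s: unparseable year %r, dropped", row.pmid, getattr(row, "year")
            )
            continue
        mesh_raw = getattr(row, "mesh", "") if "mesh" in df.columns else ""
        mesh = [m.strip() for m in str(mesh_raw).split(";") if m.strip()]
        country = getattr(row, "country", "") if "country" in df.columns else ""
        records.append(
            DocumentRecord(
                pmid=str(row.pmid),
                title=str(row.title),
                abstract=str(row.abstract),
                journal=str(getattr(row, "journal", "")) if "journal" in df.columns else "",
                year=year,
                mesh=mesh,
                country=country or None,
            )
        )
    return records


def _read_medline(path: Path) -> list[DocumentRecord]:
    from Bio import Medline

    records = []
    with open(path) as fh:
        for entry in Medline.parse(fh):
            pmid = entry.get("PMID")
            if not pmid:
                continue
            dp = entry.get("DP", "")
            m = re.search(r"\b(\d{4})\b", dp)
            if not m:
                logger.warning("record %s: unparseable year %r, dropped", pmid, dp)
                continue
            records.append(
                DocumentRecord(
                    pmid=str(pmid),
                    title=entry.get("TI", ""),
                    abstract=entry.get("AB", ""),
                    journal=entry.get("JT", ""),
                    year=int(m.group(1)),
                    mesh=list(entry.get("MH", [])),
                    country=None,
                )
            )
    return records


def write_corpus(records: Sequence[DocumentRecord], path: str | Path) -> None:
    """Write records as the canonical CSV schema (mesh semicolon-joined)."""
    rows = [
        {
            "pmid": r.pmid,
            "title": r.title,
            "abstract": r.abstract,
            "journal": r.journal,
            "year": r.year,
            "mesh": ";".join(r.mesh),
            "country": r.country or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def write_clean(docs: Sequence[CleanDocument], path: str | Path) -> None:
    """Write cleaned token streams (space-joined) as CSV."""
    rows = [
        {"pmid": d.pmid, "year": d.year, "tokens": " ".join(d.tokens)} for d in docs
    ]
    pd.DataFrame(rows, columns=["pmid", "year", "tokens"]).to_csv(path, index=False)


def read_clean(path: str | Path) -> list[CleanDocument]:
    df = pd.read_csv(path, dtype={"pmid": str}, keep_default_na=False)
    return [
        CleanDocument(
            pmid=str(row.pmid),
            tokens=str(row.tokens).split() if str(row.tokens) else [],
            year=int(row.year),
        )
        for row in df.itertuples(index=False)
    ]
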