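"""Synthetic PubMed-like corpus generator with known ground truth.

Generates bag-of-words bibliographic records with K topical clusters (each a
distinct keyword pool mixed against a shared background vocabulary),
controllable per-topic year entropy, a configurable fraction of background-only
noise documents, and optionally a planted document-level co-mention triad
(e.g. candida / il6 / cortisol) inside one designated topic.  Every downstream
stage of the pipeline (topic recovery, c-TF-IDF keywords, novelty metrics,
co-mention analysis, trend series) can be validated offline against the
returned ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import DocumentRecord

# Topic pools are disjoint 10-term sets written in their cleaned (lemmatised)
# form so they survive the text-cleaning chain unchanged.  The shared
# background deliberately carries cross-cutting marker terms (mutan, tnf,
# cortisol, dhea, npy) at moderate document frequency so that co-mention
# matrices have realistic non-zero off-topic structure.
DEFAULT_TOPIC_POOLS: tuple[tuple[str, ...], ...] = (
    (  # oral microbiome / biofilm ecology
        "biofilm", "plaque", "microbiome", "bacterial", "microbial",
        "adhesion", "fermentation", "acidogenic", "colonization", "ecology",
    ),
    (  # host immunity / salivary peptides
        "il6", "cytokine", "inflammation", "lactoferrin", "defensin",
        "iga", "peptide", "immunity", "mucosal", "innate",
    ),
    (  # oxidative stress / antioxidant defence
        "tac", "gpx", "sod", "antioxidant", "oxidative",
        "redox", "peroxidase", "glutathione", "stress", "enzyme",
    ),
)

DEFAULT_BACKGROUND: tuple[str, ...] = (
    "carie", "child", "ecc", "saliva", "salivary", "dental", "tooth",
    "enamel", "early", "childhood", "oral", "health", "prevalence", "risk",
    "level", "severity", "sample", "cohort", "baseline", "clinical",
    "marker", "biomarker", "protein", "diet", "sugar", "feeding", "hygiene",
    "brushing", "fluoride", "varnish", "mother", "maternal", "infant",
    "toddler", "preschool", "examination", "dmft", "lesion", "cavity",
    "surface", "primary", "dentition", "secretion", "flow", "buffer",
    "mineral", "calcium", "phosphate", "remineralization", "demineralization",
    "exposure", "socioeconomic", "behaviour", "visit", "treatment",
    "mutan", "tnf", "cortisol", "dhea", "npy",
)

_JOURNALS = (
    "Synthetic Journal of Paediatric Dentistry",
    "Synthetic Archives of Oral Biology",
    "Synthetic Caries Research",
    "Synthetic Oral Health Reports",
    "Synthetic Salivary Diagnostics",
)


@dataclass
class CorpusSimConfig:
    """Study conditions for one simulated corpus.

    ``year_concentration`` is the symmetric Dirichlet concentration over the
    years in ``year_range`` (0 collapses a topic onto a single random year,
    large values approach a uniform year distribution); it may be a scalar or
    a per-topic sequence.  ``triad_prob`` is the per-document probability that
    a document of ``triad_topic`` mentions every term in ``triad_terms``.
    """

    n_topics: int = 3
    docs_per_topic: Sequence[int] = (20, 20, 20)
    keyword_pools: Sequence[Sequence[str]] = DEFAULT_TOPIC_POOLS
    background_vocabulary: Sequence[str] = DEFAULT_BACKGROUND
    topic_term_weight: float = 0.7
    year_range: tuple[int, int] = (2000, 2025)
    year_concentration: float | Sequence[float] = 1.0
    noise_fraction: float = 0.0
    triad_terms: Sequence[str] | None = None
    triad_topic: int = 0
    triad_prob: float = 0.0
    abstract_length: tuple[int, int] = (40, 120)
    title_length: tuple[int, int] = (4, 10)
    seed: int = 0


@dataclass
class GroundTruth:
    """Generator-side labels: per-document topic (-1 = noise) and planted triad docs."""

    doc_topic_labels: dict[str, int] = field(default_factory=dict)
    planted_triad_docs: list[str] = field(default_factory=list)


def _validate(config: CorpusSimConfig) -> list[float]:
    if config.n_topics < 1:
        raise ValueError("n_topics must be >= 1")
    if len(config.docs_per_topic) != config.n_topics:
        raise ValueError("docs_per_topic length must equal n_topics")
    if any(n < 1 for n in config.docs_per_topic):
        raise ValueError("docs_per_topic entries must all be >= 1")
    if len(config.keyword_pools) < config.n_topics:
        raise ValueError("need one keyword pool per topic")
    for k in range(config.n_topics):
        if len(config.keyword_pools[k]) == 0:
            raise ValueError(f"empty keyword pool for topic {k}")
    if not config.background_vocabulary:
        raise ValueError("background vocabulary must be non-empty")
    if not 0.0 < config.topic_term_weight <= 1.0:
        raise ValueError("topic_term_weight must be in (0, 1]")
    lo, hi = config.year_range
    if hi < lo:
        raise ValueError("year_range must be non-empty")
    if not 0.0 <= config.noise_fraction < 1.0:
        raise ValueError("noise_fraction must be in [0, 1)")
    if not 0.0 <= config.triad_prob <= 1.0:
        raise ValueError("triad_prob must be in [0, 1]")
    if config.triad_terms is not None:
        if len(config.triad_terms) < 2:
            raise ValueError("triad_terms must list at least 2 terms")
        if not 0 <= config.triad_topic < config.n_topics:
            raise ValueError("triad_topic out of range")
    conc = config.year_concentration
    if np.isscalar(conc):
        concentrations = [float(conc)] * config.n_topics
    else:
        concentrations = [float(c) for c in conc]
        if len(concentrations) != config.n_topics:
            raise ValueError("year_concentration length must equal n_topics")
    if any(c < 0 for c in concentrations):
        raise ValueError("year_concentration must be >= 0")
    return concentrations


def _year_distribution(
    rng: np.random.Generator, years: np.ndarray, concentration: float
) -> np.ndarray:
    if concentration == 0.0:
        probs = np.zeros(len(years))
        probs[rng.integers(len(years))] = 1.0
        return probs
    return rng.dirichlet(np.full(len(years), concentration))


def _sample_tokens(
    rng: np.random.Generator,
    n: int,
    pool: Sequence[str],
    background: Sequence[str],
    topic_weight: float,
) -> list[str]:
    from_pool = rng.random(n) < topic_weight
    toks = np.where(
        from_pool,
        rng.choice(np.asarray(pool, dtype=object), size=n),
        rng.choice(np.asarray(background, dtype=object), size=n),
    )
    return [str(t) for t in toks]


def generate_corpus(
    config: CorpusSimConfig,
) -> tuple[list[DocumentRecord], GroundTruth]:
    """Generate a corpus and its ground truth, deterministically per seed.

    The number of documents is ``round(sum(docs_per_topic) / (1 - noise_fraction))``;
    the excess beyond the topical documents is background-only noise labelled -1.
    """
    concentrations = _validate(config)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.year_range
    years = np.arange(lo, hi + 1)

    n_topical = int(sum(config.docs_per_topic))
    n_total = int(round(n_topical / (1.0 - config.noise_fraction)))
    n_noise = n_total - n_topical

    year_probs = [
        _year_distribution(rng, years, concentrations[k])
        for k in range(config.n_topics)
    ]

    # interleave topic labels then noise; document ids are assigned in order
    labels: list[int] = []
    for k, n_k in enumerate(config.docs_per_topic):
        labels.extend([k] * int(n_k))
    labels.extend([-1] * n_noise)

    records: list[DocumentRecord] = []
    truth = GroundTruth()
    for idx, label in enumerate(labels):
        pmid = f"SIM{idx:06d}"
        if label >= 0:
            pool = config.keyword_pools[label]
            weight = config.topic_term_weight
            year = int(rng.choice(years, p=year_probs[label]))
        else:
            pool = config.background_vocabulary
            weight = 0.0
            year = int(rng.choice(years))
        n_title = int(rng.integers(config.title_length[0], config.title_length[1] + 1))
        n_abstract = int(
            rng.integers(config.abstract_length[0], config.abstract_length[1] + 1)
        )
        title_toks = _sample_tokens(
            rng, n_title, pool, config.background_vocabulary, weight
        )
        abstract_toks = _sample_tokens(
            rng, n_abstract, pool, config.background_vocabulary, weight
        )

        planted = False
        if (
            config.triad_terms is not None
            and label == config.triad_topic
            and rng.random() < config.triad_prob
        ):
            for term in config.triad_terms:
                pos = int(rng.integers(len(abstract_toks) + 1))
                abstract_toks.insert(pos, str(term))
            planted = True

        mesh = sorted(rng.choice(np.asarray(pool, dtype=object),
                                 size=min(3, len(pool)), replace=False).tolist())
        records.append(
            DocumentRecord(
                pmid=pmid,
                title=" ".join(title_toks),
                abstract=" ".join(abstract_toks),
                journal=str(rng.choice(_JOURNALS)),
                year=year,
                mesh=[str(m) for m in mesh],
                country=None,
            )
        )
        truth.doc_topic_labels[pmid] = label
        if planted:
            truth.planted_triad_docs.append(pmid)

    return records, truth


def default_corpus_config(seed: int = 7, **overrides) -> CorpusSimConfig:
    """The desk-scale reference corpus: 3 topics x 20 documents, no noise."""
    params = dict(
        n_topics=3,
        docs_per_topic=(20, 20, 20),
        noise_fraction=0.0,
        seed=seed,
    )
    params.update(overrides)
    return CorpusSimConfig(**params)


def triad_corpus_config(
    seed: int = 7, triad_prob: float = 1.0, **overrides
) -> CorpusSimConfig:
    """Reference corpus with a candida/il6/cortisol triad planted in topic 0.

    Topic 0 is the microbiome topic, whose pool contains none of the triad
    terms, so the planted co-mentions are attributable solely to the planting.
    """
    params = dict(
        triad_terms=("candida", "il6", "cortisol"),
        triad_topic=0,
        triad_prob=triad_prob,
    )
    params.update(overrides)
    return default_corpus_config(seed=seed, **params)
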