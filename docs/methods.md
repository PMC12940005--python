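# Methods

This note documents the models, defaults and numerical choices behind
`litaxis`, and what the synthetic generators do and do not emulate.

## Text cleaning

Title and abstract are concatenated, lowercased, and separator-joined marker
names are canonicalised before tokenisation (`il-6`, `il 6`, `il/6` → `il6`).
Tokens are alphanumeric runs; numeric-only tokens are dropped; a pluggable
lemmatiser is applied; tokens shorter than three characters or on the stop
list are removed. The stop list is sklearn's English list plus
methods-section vocabulary (study, analysis, patient, significant, …). A
whitelist of marker acronyms (ecc, tac, sod, gpx, il6, tnf, iga, npy) is
exempt from the length and stop rules: these strings are core topical
vocabulary in this literature and would otherwise be unreachable.

The default lemmatiser is deliberately minimal and deterministic: identity
plus stripping one trailing `s` from tokens longer than four characters
(never after `ss`, which also makes cleaning idempotent). It reproduces the
field-typical clipped lemmas such as `caries → carie` and `albicans →
albican` without any model download; a full NLP lemmatiser can be passed as
a callable. Corpus-frequency filtering (default min_count = 2) then removes
hapax terms and rewrites the documents in place, preserving token order for
the window-based network stage.

## Embedding and clustering

The default embedding is TF-IDF followed by truncated SVD to `dim`
dimensions (default 16) with row normalisation — a deterministic latent
semantic analysis stand-in for transformer encoders, adequate for
bag-of-words corpora where topics differ lexically. Clustering is spherical
k-means (sklearn KMeans with `n_init=10` on unit-norm vectors, fixed seed).
Density-based clustering's "unassigned" documents are emulated by a noise
quantile: documents whose distance to their centroid exceeds the
`1 − noise_quantile` distance quantile are relabelled −1 (default 0.03,
matching the few-percent unclassified share typical of corpus-scale runs;
use 0 when the corpus is known to contain no noise). Documents are sorted
by id before fitting and cluster ids canonicalised by first appearance, so
the assignment is invariant to input order. Centroids are recomputed as
member means after noise removal.

c-TF-IDF uses the canonical class-based formula
`w(t,c) = tf_{t,c} · ln(1 + A/f_t)` with natural log; ties break
lexicographically, then by lowest topic id.

## Novelty Index

`NI = z(d) + z(H)` with population z-scores across the non-noise topics;
constant columns z-score to zero, so NI is well defined for degenerate
inputs and always sums to zero. Entropy uses natural log; since z-scoring
is scale-invariant, NI does not depend on the log base (asserted in tests).
Because a z-sum-zero statistic cannot be all-positive, published all-positive
NI columns are treated as a display rescaling; the module reports raw NI and
a separate min–max `novelty_index_scaled` in [0, 1] for presentation.
Density is the topic's share of non-noise documents. The diversity score has
no canonical definition; the default plug-in is
`distinct terms / (topic token count × vocabulary size)` and the chosen
definition is recorded in the output metadata.

## Networks and co-mention

The co-occurrence window is forward-looking: position *i* pairs with
positions *j* ≤ *i* + window − 1, counting each (i, j) position pair once;
self-pairs are excluded and edges under `min_weight` (default 2) are dropped
after accumulation. By default the window slides over the keyword-filtered
stream (the analysis starts from a curated keyword list); a flag switches to
the full cleaned stream. Louvain community detection is delegated to
networkx (seeded); modularity is implemented explicitly in its weighted
Newman–Girvan form and cross-checked against networkx in tests.

Co-mention normalisation is the Ochiai coefficient on document-incidence
vectors (symmetric, bounded in [0, 1], robust to marginal imbalance);
Jaccard is available as an alternative and the choice is recorded in the
output. The default lexicons carry the marker terms named in this
literature — microbial: candida, mutans; cytokine: il6, tnf;
neuroendocrine: cortisol, dhea, npy; peptide/mucosal: lactoferrin,
defensin, iga. Mutans is included so the microbial lexicon is not a
singleton, which would make every candidate triad share one fixed term and
trivialise the max–min triad search. Lexicon terms pass through the same
normalisation as the corpus, so surface variants match their cleaned forms.
The best triad maximises the minimum pairwise score over all cross-lexicon
triples; ties resolve to the lexicographically first triple.

## Enrichment

Over-representation uses the hypergeometric upper tail
(`scipy.stats.hypergeom.sf`) against an explicit background universe, with
Benjamini–Hochberg step-up adjustment (statsmodels) applied within each
collection. Only the one-sided over-representation test is offered. The
keyword→gene lexicon is a shipped editable CSV (data, not code) seeded with
the redox/immune marker genes relevant here (GPX1, SOD2, CAT, HSPA1A, TLR2,
IL6, TNF, …). Gene-set fixtures used in tests are generated synthetically
at test time.

## Trends

Yearly topic counts are zero-filled across the corpus year range (absence of
publications is a zero, which feeds both entropy and trend fits). The trend
model is OLS `count ~ a + b·year` with 95 % prediction intervals from the
t-distribution on n − 2 degrees of freedom; intervals collapse onto the line
for perfect fits and widen with extrapolation distance. An optional single
changepoint splits the fit into two segments, with forecasts taken from the
later segment. A seasonal/changepoint forecaster could be plugged in, but
trend fitting here is descriptive, and a linear model keeps every number
closed-form checkable. The forecast slope between horizon years
(default 2026→2029) is `(ŷ_end − ŷ_start)/span`; this definition reproduces
published slope columns from their printed prediction pairs to within
printing precision. The novelty–slope association is reported as a Spearman
correlation in the pipeline manifest, not asserted, since it is exploratory.

## Synthetic corpus generator

Documents are bags of tokens: titles 4–10 and abstracts 40–120 tokens, each
token drawn from the topic pool with probability `topic_term_weight`
(default 0.7) and otherwise from a shared background vocabulary. Defaults
model a desk-scale corpus of 3 disjoint 10-term topic pools (microbiome,
immunity/peptides, oxidative stress) over a 60-term background of generic
ECC/saliva vocabulary. The background deliberately includes cross-cutting
marker terms (mutan, tnf, cortisol, dhea, npy) at moderate document
frequency (≈ 0.3–0.45 per document) so that co-mention matrices have
non-degenerate null structure: without them, all cross-lexicon scores would
be exactly zero in unplanted corpora and the triad search would be decided
by tie-breaking alone.

Years follow a symmetric Dirichlet-multinomial per topic whose concentration
knob spans a point mass (0) to near-uniform (large); realised temporal
entropy is monotone in the knob (tested by rank correlation). Noise
documents (share `noise_fraction`) draw background tokens only and are
labelled −1. Triad planting inserts each triad term at a random position in
the abstracts of a designated topic with probability `triad_prob`; the
reference triad configuration plants candida/il6/cortisol into the
microbiome topic, whose own pool contains none of the triad terms, so
recovered triads are attributable to the planting.

What the generator does **not** emulate: real English syntax, MeSH ontology
structure, citation behaviour, topic overlap or drift, and realistic
vocabulary sizes. Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and well calibrated on separable
bag-of-words structure, not that it would resolve the subtler topic
boundaries of a real corpus.

## Synthetic cohort generator

Two latent standard-normal axes (neuroendocrine stress, inflammation) drive
eight markers through per-marker loadings plus unit-variance noise; each
marker is anchored to a conventional-unit range (e.g. IL-6 0–50 pg/mL,
cortisol 1–30 nmol/L, TAC 0.2–2 mmol/L) by centring at the midpoint and
scaling three total standard deviations to the half-range, then clipping
(< 1 % of values affected, asserted). Redox markers (TAC, GPx, SOD) load
negatively on inflammation; cortisol, DHEA and NPY on stress. ECC status is
Bernoulli with logit `b₀ + β·X_std` on empirically standardised markers;
`b₀` is solved by Brent root-finding so expected prevalence matches the
configuration (default 0.4). Default log-odds effects are
IL-6 +1.0, cortisol +0.6, TNF +0.5, TAC −0.6, GPx −0.5, SOD −0.4, with DHEA
and NPY as null markers. All ranges and effects are declared illustrative
defaults — the cohort supports methodological demonstrations and parameter
recovery tests, never clinical inference.

The baseline risk model is a standardised L2-regularised logistic regression
(any sklearn-style classifier can be plugged in), evaluated on a stratified
30 % hold-out. Explanations use model-agnostic permutation importance
(mean held-out AUC drop over seeded column shuffles) rather than a specific
explainer library.

## Problem sizes and tolerances

Tests run at desk scale: 60-document corpora, 20-seed replications for
stochastic recovery claims, 2 000-subject cohorts, 1 000-replicate null
calibration for the enrichment FDR. Exact-arithmetic checks use 1e−9–1e−12
tolerances; oracle equivalences compare against independent brute-force
implementations (double-loop window enumeration, rational combinatorial
sums, step-up re-implementation). Printed-table comparisons use the bound
implied by the tables' printed precision (two-decimal predictions propagate
to ±0.0038 on a three-year slope).

## Known limitations

Keyword recovery depends on the minimal lemmatiser, so exact keyword strings
differ from full-NLP stacks; the diversity score is a placeholder
definition; the linear trend cannot mimic saturation or seasonal structure;
Louvain output depends on the seed on near-degenerate graphs; and all
synthetic-data claims are internal calibration, not external validity.
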