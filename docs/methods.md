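# Methods

This note documents the models and procedures `litmap` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmark does and does not
demonstrate.

## Corpus curation

PubMed efetch XML (`PubmedArticleSet`) is parsed with lxml. Per article we
extract PMID, title, abstract, journal title, year, language and author
names. Rules that the XML dialect leaves open:

* **Year** — the structured `PubDate/Year` element is preferred; otherwise
  the first 4-digit token of the free-text `MedlineDate` (e.g. "1998
  Nov-Dec" → 1998); otherwise the year is absent.
* **Structured abstracts** — multiple `AbstractText` sections are
  concatenated in document order with single spaces, labels dropped.
  Internal whitespace of each section is preserved verbatim, because
  downstream regex queries are whitespace-sensitive.
* **Authors** — first author is the first `AuthorList` item, last author
  the final one; collective/consortium names are used verbatim. The curated
  `authors` field is `"first; last"`; for single-author papers (first ==
  last) the name is stored once. A semicolon separator is used because
  names themselves may contain commas.
* **Language** — the first `Language` element when several are present.
* **Duplicates** — repeated PMIDs across efetch batches keep the first
  occurrence; later ones are logged and dropped.

Curation discards records missing an abstract, a year, or a last author;
it is idempotent and order-preserving. Datasets persist as a UTF-8 TSV
(metadata) plus an HDF5 matrix (embeddings) with PMIDs stored alongside for
alignment checking.

## Growth-rate classification

Year-over-year deltas `d_y = counts[y+1] − counts[y]` are computed over the
densified year span. The mean and standard deviation of the deltas define
thresholds `mean ± 1·SD`; years reaching the upper threshold are
high-growth, years at or below the lower one low-growth. Two choices are
deliberate and exposed:

* **SD form** — population SD (denominator *n*) by default, sample SD via
  `ddof=1`. Either convention is defensible for a complete series of year
  pairs; the population form treats the observed span as the object of
  interest rather than a sample.
* **Inclusive thresholds with a zero-spread guard** — a year whose delta
  *equals* `mean + SD` counts as high growth (thresholds are reachable
  bounds, not strict majorants); but when the deltas have zero spread
  (SD = 0) no year is flagged, since nothing stands one standard deviation
  away from the mean of a constant series. This pair of rules makes the
  classification well-defined for degenerate inputs (e.g. constant counts)
  while matching hand computation on small series such as
  {10, 20, 40} → thresholds 15 ± 5, high year = the 20-delta pair.

Term frequencies lowercase and split abstracts on non-alphanumerics,
keeping single-character tokens (statistical shorthand like "n" and "p" is
informative); the stop list is scikit-learn's frozen English list plus the
custom words "used" and "study".

## Field classification

An ordered map of 18 research categories to lowercase keywords is matched
by substring containment against lowercased journal titles; the first
matching category (in map order) wins, and unmatched titles are
"unclassified". Substring matching is deliberate — it mirrors a "title
contains keyword" rule — and has a documented false-positive mode
("cancerous" matches "cancer"). The bundled map
(`data/field_keywords_synthetic.json`) is a package-authored
reconstruction: category names and priority order are fixed, keyword lists
were chosen by us; any JSON file with the same schema can replace it.

## Embeddings

The embedding contract is: tokenize with truncation to 512 tokens, obtain
per-token hidden states, mean-pool to one 768-d vector per abstract.
Pooling is mask-aware by default (mean over real token positions as given
by the tokenizer's attention mask); an unmasked mean over all positions is
available via `mean_pool(..., attention_mask=None)`. Two encoders satisfy
the contract:

* `HashingEncoder` — whitespace tokens hashed (keyed BLAKE2b) to a signed
  coordinate; the document vector is the mean of token vectors. It is
  deterministic, dependency-free, separates disjoint vocabularies, and is
  the default for tests. The empty text maps to the zero vector.
* `TransformerEncoder` — a lazily-imported adapter over a Hugging Face
  model id (default: a PubMed-domain BERT with 768 hidden units); optional,
  never required by the test suite.

## 2-D projection and map quality

t-SNE (scikit-learn) and UMAP (umap-learn) run with `n_components = 2` and
a fixed `random_state` (42 by convention). For tiny inputs the
sample-count-bounded hyperparameters are clipped (t-SNE perplexity to
`(n−1)/3`, UMAP `n_neighbors` to `n−1`, random initialisation when PCA or
spectral initialisation is undefined) so degenerate fixtures still produce
finite layouts.

* **k-NN accuracy** — a `KNeighborsClassifier` (k = 10, brute-force
  distances) is trained on the 2-D coordinates of a seeded train split and
  scored on a held-out fraction (default 1%). Records without a usable
  label can be excluded via `exclude_label`; accuracy over labeled records
  is the reading under which the statistic is well defined.
* **k-NN recall** — for every point the k = 10 Euclidean nearest neighbors
  are found in both spaces (exhaustive chunked search; distance ties break
  toward the lower row index; the query point is excluded, with
  `include_self` exposed because including it rescales the statistic) and
  the mean intersection fraction is returned. It is exactly 1 for any rigid
  transform and invariant to global scaling/rotation/translation of either
  space. The optimized search is tested to 1e-12 against an independent
  O(n²) double-loop oracle.

## Topic modelling

HDBSCAN clusters the full-dimensional embeddings directly (no internal
reduction by default; clustering a reduced representation is possible by
passing reduced coordinates). Full-scale defaults are
`min_cluster_size = 500`, `min_samples = 300`, Euclidean metric,
excess-of-mass cluster selection; at fixture scale the two sizes are scaled
proportionally (e.g. 50/30 for 600 documents) so the cluster-to-corpus
ratio mirrors the full-scale setting. Cluster ids are remapped to be
contiguous from 0 in order of first appearance; outliers are −1.

The class–term matrix counts unigrams and bigrams per topic
(CountVectorizer, English stop words removed, document-frequency floor 10
over abstracts — lowered proportionally at fixture scale). Class-based
TF-IDF uses the standard form

    W[c, t] = tf[c, t] · log(1 + A / f[t])

with raw within-class counts `tf`, total term count `f[t]` and average
class token total `A`; a sublinear-tf variant (`1 + log tf`) is a config
switch. Because the absolute weights depend on these conventions,
cross-implementation comparisons should be rank-based (top-k term sets),
which is how the tests assert topic quality.

Representative abstracts are the topic members with the highest cosine
similarity between their term-count vector and the topic's c-TF-IDF vector
(ties toward earlier corpus order; at most 100 per topic). The labelling
prompt is the deterministic concatenation of a system prompt, one
in-context example, and a main prompt with the topic's keywords and
representative abstracts interpolated; prompt templates are module
constants so the assembly is byte-reproducible. The backend is pluggable;
the offline stub labels a topic with its top-3 terms joined by " / ", and a
backend failure degrades to "Topic <id>" with a warning.

## Metadata mining

Regex queries run as written, case-sensitive, against abstracts only
(titles can be opted in). The p-value pattern `[pP]\s?[<=>]` admits at most
one whitespace character, so "p<0.05", "P = 0.01" and "p > 0.001" match
while the two-space "P  =  0.01" does not — this boundary is tested
explicitly. Sample sizes are captured with `n\s?=\s?(\d+)`; when an
abstract contains several matches the policy is configurable (`first` by
default, `max`, or `all` — distributional summaries depend on this choice).
Phrase queries are literal and case-insensitive. Collaboration size counts
the names stored in the curated authors field (at most first + last, i.e.
1 or 2 under the curation convention).

## Synthetic corpus generator

The generator plants every structure the pipeline consumes and records it
in a truth ledger:

* **Abstracts** — bags of words: each position draws from the record's
  topic vocabulary with probability 0.7, else from shared background terms;
  lengths are Gaussian (mean 200 words, SD 30, floor 30), matching the
  modal length of real abstracts. Bag-of-words text suffices because every
  downstream consumer is bag-of-words or regex based; no prose realism is
  attempted.
* **Topics** — default 3 topics × 200 documents with 40-term disjoint
  vocabularies and 60 background terms; vocabulary disjointness is
  validated.
* **Fields** — each topic is assigned a category whose keyword appears in
  a templated journal title (verified against the bundled map at
  generation time); 10% of records get a keyword-free journal and are
  planted "unclassified".
* **Years** — an exponential curve over 1998–2023 with growth coefficient
  0.27/year (≈ thousand-fold growth across the span, the shape of the real
  corpus), rounded by largest remainder; explicit per-year counts can be
  supplied instead, e.g. a flat series with one spike for growth-recovery
  tests.
* **Metadata** — p-value strings (30% of records), two-space decoys that
  must *not* match (5%), sample sizes (25%, log-uniform 3–2000, varied
  punctuation), and a marker phrase (15%) are inserted at random positions
  into disjoint record subsets; inserted strings never collide with
  vocabulary terms, so planted counts are exact.
* **Embeddings** — topic centers sit at the vertices of a regular simplex;
  rows add isotropic Gaussian noise (per-coordinate SD 1). The `separation`
  parameter is the ratio of between-center distance to the within-cluster
  RMS radius (σ·√d). Defining separation against the RMS radius rather
  than the per-coordinate SD is essential in high dimension: at d = 768 a
  10·σ center distance would be far smaller than typical within-cluster
  distances (≈ σ·√(2d)) and the planted structure would be undetectable,
  whereas 10 RMS radii give unambiguous clusters.
* **XML** — the corpus renders as PubMed efetch XML, optionally with
  invalid records (missing abstract / year / last author) that the
  curation filters must discard; the rendering round-trips exactly through
  the parser.

## What the synthetic benchmark shows — and what it does not

Passing the suite demonstrates that the mechanics are correct: filters
drop exactly the records they should, metrics equal their independent
oracles, planted structure is recovered exactly when it is unambiguous,
and t-SNE preserves more local neighborhood structure than UMAP or a
random projection on cluster-structured data (the scaled analogue of the
full-corpus map evaluation runs on 2,000 points with 5 planted clusters —
a size chosen so the whole comparison completes in well under a minute).
It does not show that real abstracts embed into clean Gaussian clusters
(they do not), that the reconstructed keyword map reproduces the original
field counts (only the authors' supplementary mapping can), or that c-TF-IDF
term rankings on real topics are as unambiguous as on disjoint planted
vocabularies. Quantities tied to the full deposited 80k-record corpus
(its exact record count, mean growth rate, field counts and Table-style
metric values) require downloading that dataset and are out of desk-scale
scope.

## Known limitations

* The reference transformer encoder is untested here; only its contract
  (truncation + mean pooling) is exercised via the hashing encoder and a
  toy mock.
* Whether the original full-scale analysis reduced dimensionality before
  density clustering is not determinable; direct clustering is the
  default and the alternative is a one-line change (cluster reduced
  coordinates).
* k-NN accuracy depends on the unspecified train/test split seed; it is
  reproducible only to tolerance across implementations.
* HDBSCAN label numbering (hence topic ids) depends on input order;
  contiguity and first-appearance remapping make it deterministic for a
  fixed corpus.
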