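"""Density-based topic modelling with class-based TF-IDF representations.

The pipeline clusters precomputed abstract embeddings with HDBSCAN
(hierarchical density-based clustering; points in no dense region get the
outlier label −1), aggregates token counts per cluster into a class–term
matrix, and scores terms with class-based TF-IDF:

    W[c, t] = tf[c, t] * log(1 + A / f[t])

where ``tf[c, t]`` is the count of term ``t`` in class (topic) ``c``,
``f[t] = sum_c tf[c, t]`` is the term's corpus-wide class frequency, and
``A`` is the average total token count per class.  The top-weighted terms
per topic, together with its most representative abstracts (highest cosine
similarity between a document's term vector and the topic's c-TF-IDF
vector), feed a three-part labelling prompt for a pluggable text-generation
backend; an offline stub backend keeps the pipeline runnable with no
network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer

from .records import Corpus

logger = logging.getLogger(__name__)

OUTLIER = -1
DEFAULT_MIN_CLUSTER_SIZE = 500
DEFAULT_MIN_SAMPLES = 300
REPRESENTATIVE_DOC_CAP = 100


def cluster_embeddings(
    embeddings: np.ndarray,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    metric: str = "euclidean",
    cluster_selection_method: str = "eom",
) -> np.ndarray:
    """HDBSCAN cluster assignment over embedding rows.

    Defaults follow the full-scale analysis (min_cluster_size=500,
    min_samples=300, Euclidean metric, "excess of mass" cluster selection);
    for small corpora scale them down proportionally.  Returns one integer
    topic id per row, contiguous from 0, with −1 for outliers.  Inputs
    smaller than ``min_cluster_size`` cannot contain a cluster and come back
    all-outlier with a warning.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    n = X.shape[0]
    if n < min_cluster_size:
        warnings.warn(
            f"{n} points < min_cluster_size={min_cluster_size}; "
            "returning all-outlier assignment"
        )
        return np.full(n, OUTLIER, dtype=int)
    from sklearn.cluster import HDBSCAN

    model = HDBSCAN(
        min_cluster_size=min_cluster_size,
        min_samples=min_samples,
        metric=metric,
        cluster_selection_method=cluster_selection_method,
        copy=True,
    )
    labels = model.fit_predict(X).astype(int)
    return _contiguous(labels)


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Remap non-outlier ids to 0..k-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.full(labels.shape, OUTLIER, dtype=int)
    for i, lab in enumerate(labels):
        if lab == OUTLIER:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


@dataclass
class ClassTermMatrix:
    """Per-topic term counts plus the per-document matrix that built them."""

    counts: np.ndarray  # (n_topics, n_terms) integer counts
    terms: list[str]
    topic_ids: list[int]
    doc_term: sp.csr_matrix  # (n_docs_in_topics, n_terms)
    doc_indices: np.ndarray  # corpus row of each doc_term row
    doc_topics: np.ndarray  # topic id of each doc_term row

    @property
    def n_topics(self) -> int:
        return len(self.topic_ids)


def build_class_term_matrix(
    corpus: Corpus,
    assignment: np.ndarray,
    stop_words: str = "english",
    min_df: int = 10,
    ngram_range: tuple[int, int] = (1, 2),
) -> ClassTermMatrix:
    """Aggregate abstract token counts per topic.

    Abstracts of non-outlier records are vectorized (unigrams + bigrams,
    English stop words removed, vocabulary restricted to terms appearing in
    at least ``min_df`` abstracts) and counts are summed within each topic.
    """
    assignment = np.asarray(assignment, dtype=int)
    if assignment.shape[0] != len(corpus):
        raise ValueError("assignment is not aligned to the corpus")
    member = assignment != OUTLIER
    if not member.any():
        raise ValueError("no non-outlier topic to build a term matrix from")
    doc_indices = np.flatnonzero(member)
    texts = [corpus.records[i].abstract for i in doc_indices]
    vectorizer = CountVectorizer(
        stop_words=stop_words,
        min_df=min_df,
        ngram_range=ngram_range,
        lowercase=True,
    )
    doc_term = vectorizer.fit_transform(texts).tocsr()
    doc_topics = assignment[doc_indices]
    topic_ids = sorted(set(doc_topics.tolist()))
    counts = np.vstack(
        [
            np.asarray(
                doc_term[doc_topics == topic].sum(axis=0)
            ).ravel()
            for topic in topic_ids
        ]
    ).astype(np.int64)
    return ClassTermMatrix(
        counts=counts,
        terms=vectorizer.get_feature_names_out().tolist(),
        topic_ids=topic_ids,
        doc_term=doc_term,
        doc_indices=doc_indices,
        doc_topics=doc_topics,
    )


def ctfidf_weights(
    matrix: ClassTermMatrix, sublinear_tf: bool = False
) -> np.ndarray:
    """Class-based TF-IDF weights, ``(n_topics, n_terms)``.

    ``W[c, t] = tf[c, t] * log(1 + A / f[t])`` with ``f[t]`` the term's total
    count across classes and ``A`` the average total token count per class.
    With ``sublinear_tf`` the term frequency is damped to ``1 + log(tf)``
    where positive.
    """
    tf = np.asarray(matrix.counts, dtype=np.float64)
    if tf.size == 0 or tf.sum() == 0:
        raise ValueError("class-term matrix is empty")
    if sublinear_tf:
        damped = np.zeros_like(tf)
        positive = tf > 0
        damped[positive] = 1.0 + np.log(tf[positive])
        tf_used = damped
    else:
        tf_used = tf
    f = tf.sum(axis=0)
    A = tf.sum(axis=1).mean()
    with np.errstate(divide="ignore"):
        idf = np.log1p(np.where(f > 0, A / f, 0.0))
    return tf_used * idf


def top_topic_terms(
    matrix: ClassTermMatrix, weights: np.ndarray, k: int = 10
) -> dict[int, list[tuple[str, float]]]:
    """The k highest-weighted terms per topic, descending; ties by term."""
    result: dict[int, list[tuple[str, float]]] = {}
    terms = np.asarray(matrix.terms)
    for row, topic in enumerate(matrix.topic_ids):
        w = weights[row]
        order = sorted(range(len(terms)), key=lambda j: (-w[j], terms[j]))
        result[topic] = [
            (str(terms[j]), float(w[j])) for j in order[:k] if w[j] > 0
        ]
    return result


def representative_documents(
    corpus: Corpus,
    matrix: ClassTermMatrix,
    weights: np.ndarray,
    per_topic_cap: int = REPRESENTATIVE_DOC_CAP,
) -> dict[int, list[int]]:
    """Corpus row indices of each topic's most representative abstracts.

    Documents are ranked by cosine similarity between their term-count
    vector and the topic's c-TF-IDF vector; ties break toward earlier corpus
    order.  At most ``per_topic_cap`` documents are returned per topic.
    """
    result: dict[int, list[int]] = {}
    for row, topic in enumerate(matrix.topic_ids):
        mask = matrix.doc_topics == topic
        docs = matrix.doc_term[mask]
        corpus_rows = matrix.doc_indices[mask]
        topic_vec = weights[row]
        topic_norm = np.linalg.norm(topic_vec)
        scores = np.asarray(docs @ topic_vec).ravel()
        doc_norms = np.sqrt(
            np.asarray(docs.multiply(docs).sum(axis=1)).ravel()
        )
        denom = doc_norms * topic_norm
        with np.errstate(invalid="ignore", divide="ignore"):
            cosine = np.where(denom > 0, scores / denom, 0.0)
        order = sorted(
            range(len(corpus_rows)), key=lambda j: (-cosine[j], corpus_rows[j])
        )
        result[topic] = [int(corpus_rows[j]) for j in order[:per_topic_cap]]
    return result


@dataclass
class TopicRepresentation:
    """Everything needed to describe and label one topic."""

    topic_id: int
    terms: list[tuple[str, float]]  # ranked (term, c-TF-IDF weight)
    representative_docs: list[str] = field(default_factory=list)
    label: Optional[str] = None


def topic_representations(
    corpus: Corpus,
    matrix: ClassTermMatrix,
    weights: np.ndarray,
    n_terms: int = 10,
    per_topic_cap: int = REPRESENTATIVE_DOC_CAP,
) -> list[TopicRepresentation]:
    """Bundle ranked terms and representative abstracts for every topic."""
    terms = top_topic_terms(matrix, weights, k=n_terms)
    reps = representative_documents(
        corpus, matrix, weights, per_topic_cap=per_topic_cap
    )
    return [
        TopicRepresentation(
            topic_id=topic,
            terms=terms[topic],
            representative_docs=[
                corpus.records[i].abstract for i in reps[topic]
            ],
        )
        for topic in matrix.topic_ids
    ]


# --- LLM label-prompt assembly -------------------------------------------
#
# The prompt is the deterministic concatenation of three parts, in order:
# a system prompt, one in-context example, and a main prompt with the
# topic's keywords and representative abstracts interpolated.

SYSTEM_PROMPT = (
    "You are a helpful research assistant. Your task is to read keywords "
    "and sample abstracts describing one cluster of scientific publications "
    "and return a single short, informative topic label."
)

EXAMPLE_PROMPT = (
    "Example:\n"
    "Sample abstracts:\n"
    "- Traditional diets are known to reduce risk of cardiovascular "
    "disease through polyphenol intake.\n"
    "Keywords: diet, cardiovascular, polyphenols, risk\n"
    "Topic label: Dietary Polyphenols and Cardiovascular Risk"
)

MAIN_PROMPT_TEMPLATE = (
    "Now label this topic.\n"
    "Sample abstracts:\n"
    "[DOCUMENTS]\n"
    "Keywords: [KEYWORDS]\n"
    "Topic label:"
)


def build_label_prompt(topic: TopicRepresentation) -> str:
    """Assemble the three-part labelling prompt for one topic.

    The output is byte-deterministic given the topic's terms and
    representative documents.
    """
    if not topic.terms:
        raise ValueError(f"topic {topic.topic_id} has no terms")
    documents = "\n".join(
        f"- {doc}" for doc in topic.representative_docs
    ) or "- (no representative abstracts)"
    keywords = ", ".join(term for term, _ in topic.terms)
    main = MAIN_PROMPT_TEMPLATE.replace("[DOCUMENTS]", documents).replace(
        "[KEYWORDS]", keywords
    )
    return "\n\n".join([SYSTEM_PROMPT, EXAMPLE_PROMPT, main])


class LabelBackend(Protocol):
    """A text-generation backend turning a prompt into a topic label."""

    def generate(self, prompt: str, topic: TopicRepresentation) -> str: ...


class StubLabelBackend:
    """Offline backend: labels a topic by joining its top-3 terms."""

    def generate(self, prompt: str, topic: TopicRepresentation) -> str:
        return " / ".join(term for term, _ in topic.terms[:3])


def label_topics(
    topics: Sequence[TopicRepresentation],
    backend: Optional[LabelBackend] = None,
) -> dict[int, str]:
    """Generate a label per topic through the backend (stub by default).

    A backend failure degrades gracefully: the topic is labelled
    ``"Topic <id>"`` and a warning is logged.
    """
    backend = backend or StubLabelBackend()
    labels: dict[int, str] = {}
    for topic in topics:
        prompt = build_label_prompt(topic)
        try:
            label = backend.generate(prompt, topic)
        except Exception:
            logger.warning(
                "label backend failed on topic %d", topic.topic_id
            )
            label = f"Topic {topic.topic_id}"
        topic.label = label
        labels[topic.topic_id] = label
    return labels


__all__ = [
    "ClassTermMatrix",
    "DEFAULT_MIN_CLUSTER_SIZE",
    "DEFAULT_MIN_SAMPLES",
    "EXAMPLE_PROMPT",
    "LabelBackend",
    "MAIN_PROMPT_TEMPLATE",
    "OUTLIER",
    "REPRESENTATIVE_DOC_CAP",
    "StubLabelBackend",
    "SYSTEM_PROMPT",
    "TopicRepresentation",
    "build_class_term_matrix",
    "build_label_prompt",
    "cluster_embeddings",
    "ctfidf_weights",
    "label_topics",
    "representative_documents",
    "top_topic_terms",
    "topic_representations",
]
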