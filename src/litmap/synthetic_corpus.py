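"""Synthetic literature corpora with planted, fully-recorded ground truth.

The generator emulates the statistical structure the pipeline assumes in
real PubMed data, at configurable scale:

* abstracts are bags of words drawn from disjoint per-topic vocabularies
  mixed with shared background terms (every downstream consumer is
  bag-of-words or regex based, so no prose is needed);
* journal titles embed exactly one research-field keyword, or none for a
  configurable "unclassified" share;
* publication years follow an exponential growth curve (or any explicit
  per-year counts, e.g. a flat series with one planted spike);
* metadata strings — p-value phrases, ``n = <int>`` sample sizes, a marker
  phrase — are inserted into disjoint record subsets at known counts,
  together with near-miss decoys ("P  =  0.01", two spaces) that the
  printed p-value pattern must not match;
* cluster-structured embeddings place each topic at a simplex vertex with
  isotropic Gaussian spread, with centers ``separation`` within-cluster
  radii apart.

Everything planted is recorded in a :class:`TruthLedger`, and the corpus can
be rendered as PubMed efetch XML (optionally with invalid records that the
curation filters must discard) so the full parse → curate path is testable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from lxml import etree

from .field_classifier import UNCLASSIFIED, CategoryKeywordMap, classify_journal
from .records import Corpus, PublicationRecord, RawRecord, concat_authors

#: per-category journal-title word guaranteed to contain exactly that
#: category's keyword under the bundled map
_CATEGORY_TITLE_WORDS: dict[str, str] = {
    "oncology": "Cancer",
    "plant biology": "Plant",
    "nephrology": "Nephrology",
    "endocrinology": "Endocrinology",
    "microbiology": "Microbiology",
    "analytical chemistry": "Analytical Chemistry",
    "pharmacology": "Pharmacology",
    "neuroscience": "Neuroscience",
    "food science and nutrition": "Food",
    "toxicology": "Toxicology",
    "environmental science": "Environmental",
    "animal science": "Animal",
    "sports science and medicine": "Sports",
    "epidemiology and public health": "Epidemiology",
    "developmental biology": "Development",
    "aging and gerontology": "Aging",
    "immunology and vaccine research": "Immunology",
    "computational biology": "Computational",
}

UNCLASSIFIED_JOURNAL = "The Interdisciplinary Review"

_PVALUE_FORMS = ("p < 0.05", "p<0.05", "P = 0.01", "p> 0.001", "P =0.02")
_DECOY_PVALUE = "P  =  0.01"
_SAMPLE_SIZE_TEMPLATES = ("n = {v}", "n={v}", "(n = {v})", "n= {v}")

_GIVEN_NAMES = (
    "Alice", "Ben", "Carmen", "Dmitri", "Elena",
    "Farid", "Grace", "Hiro", "Ines", "Jon",
)
_FAMILY_NAMES = (
    "Adler", "Brook", "Chen", "Dias", "Ekwueme",
    "Fischer", "Garcia", "Hansen", "Ito", "Jensen",
)


@dataclass
class SyntheticSpec:
    """Configuration for one synthetic corpus.

    Defaults mirror the emulated study conditions at desk scale: abstracts
    around 200 words (the modal real abstract length), exponential yearly
    growth over 1998–2023 with roughly a thousand-fold increase across the
    span, and a majority of records carrying a field-bearing journal title.
    """

    n_topics: int = 3
    docs_per_topic: int = 200
    topic_vocab_size: int = 40
    background_vocab_size: int = 60
    topic_vocabularies: Optional[list[list[str]]] = None
    background_terms: Optional[list[str]] = None
    words_per_abstract_mean: float = 200.0
    words_per_abstract_sd: float = 30.0
    topic_word_fraction: float = 0.7
    year_start: int = 1998
    year_end: int = 2023
    growth_rate: float = 0.27  # exponential growth coefficient per year
    year_counts: Optional[dict[int, int]] = None
    p_value_fraction: float = 0.30
    decoy_pvalue_fraction: float = 0.05
    sample_size_fraction: float = 0.25
    phrase_fraction: float = 0.15
    phrase: str = "for the first time"
    unlabeled_fraction: float = 0.10
    single_author_fraction: float = 0.20
    n_invalid_records: int = 0
    embedding_dim: int = 768
    separation: float = 10.0
    cluster_sd: float = 1.0
    seed: int = 0

    @property
    def n_docs(self) -> int:
        return self.n_topics * self.docs_per_topic

    def resolve_vocabularies(self) -> tuple[list[list[str]], list[str]]:
        """Topic and background term lists, checked for disjointness."""
        topics = self.topic_vocabularies or [
            [f"topic{t:02d}term{i:02d}" for i in range(self.topic_vocab_size)]
            for t in range(self.n_topics)
        ]
        if len(topics) != self.n_topics:
            raise ValueError("one vocabulary required per topic")
        background = self.background_terms or [
            f"background{i:02d}" for i in range(self.background_vocab_size)
        ]
        seen: set[str] = set(background)
        for vocab in topics:
            overlap = seen & set(vocab)
            if overlap:
                raise ValueError(
                    f"vocabularies are not disjoint: {sorted(overlap)[:5]}"
                )
            seen |= set(vocab)
        return topics, background

    def resolve_year_counts(self) -> dict[int, int]:
        """Per-year record counts summing to ``n_docs``.

        Either the explicit ``year_counts`` (validated to sum correctly) or
        an exponential curve over the span, rounded by largest remainder.
        """
        if self.year_counts is not None:
            if sum(self.year_counts.values()) != self.n_docs:
                raise ValueError("year_counts must sum to n_docs")
            return dict(self.year_counts)
        years = list(range(self.year_start, self.year_end + 1))
        weights = np.exp(
            self.growth_rate * (np.asarray(years) - self.year_start)
        )
        shares = weights / weights.sum() * self.n_docs
        floors = np.floor(shares).astype(int)
        remainder = self.n_docs - floors.sum()
        order = np.argsort(-(shares - floors), kind="stable")
        floors[order[:remainder]] += 1
        return dict(zip(years, floors.tolist()))


@dataclass
class TruthLedger:
    """Record-level and corpus-level planted ground truth."""

    topic_ids: np.ndarray
    field_labels: list[str]
    years: np.ndarray
    pvalue_flags: np.ndarray
    decoy_flags: np.ndarray
    phrase_flags: np.ndarray
    sample_sizes: list[Optional[int]]
    author_counts: np.ndarray
    abstract_word_counts: np.ndarray
    year_counts: dict[int, int]
    topic_sizes: dict[int, int]
    topic_vocabularies: list[list[str]]
    background_terms: list[str]
    term_counts: Counter = field(default_factory=Counter)
    n_invalid: int = 0

    @property
    def pvalue_count(self) -> int:
        return int(self.pvalue_flags.sum())

    @property
    def phrase_count(self) -> int:
        return int(self.phrase_flags.sum())

    @property
    def sample_size_count(self) -> int:
        return sum(v is not None for v in self.sample_sizes)


@dataclass
class GeneratedCorpus:
    """A synthetic corpus, its truth ledger, and the raw-record view."""

    corpus: Corpus
    ledger: TruthLedger
    raw_records: list[RawRecord]

    def to_pubmed_xml(self) -> bytes:
        return render_pubmed_xml(self.raw_records)


def _pick_name(rng: np.random.Generator) -> str:
    return (
        f"{rng.choice(_GIVEN_NAMES)} {rng.choice(_FAMILY_NAMES)}"
    )


def generate_corpus(spec: SyntheticSpec) -> GeneratedCorpus:
    """Generate a corpus with fully-recorded planted structure.

    Deterministic: the same spec (including seed) yields byte-identical
    records, ledger and XML across calls.
    """
    rng = np.random.default_rng(spec.seed)
    topics, background = spec.resolve_vocabularies()
    year_counts = spec.resolve_year_counts()
    n = spec.n_docs

    keyword_map = CategoryKeywordMap.default()
    categories = list(keyword_map.categories)
    topic_categories = [
        categories[t % len(categories)] for t in range(spec.n_topics)
    ]
    for category in topic_categories:
        title = f"Journal of {_CATEGORY_TITLE_WORDS[category]} Research"
        if classify_journal(title, keyword_map) != category:
            raise RuntimeError(
                f"journal template for {category!r} collides with an "
                "earlier category's keywords"
            )
    if classify_journal(UNCLASSIFIED_JOURNAL, keyword_map) != UNCLASSIFIED:
        raise RuntimeError("unclassified journal template matches a keyword")

    # record order: topics in blocks, then a seeded shuffle
    topic_ids = np.repeat(np.arange(spec.n_topics), spec.docs_per_topic)
    rng.shuffle(topic_ids)

    years = np.repeat(
        list(year_counts.keys()), list(year_counts.values())
    )
    rng.shuffle(years)

    # disjoint index sets for planted metadata
    def _count(fraction: float) -> int:
        return int(round(fraction * n))

    n_pval = _count(spec.p_value_fraction)
    n_decoy = _count(spec.decoy_pvalue_fraction)
    n_size = _count(spec.sample_size_fraction)
    n_phrase = _count(spec.phrase_fraction)
    if n_pval + n_decoy + n_size + n_phrase > n:
        raise ValueError("metadata fractions sum to more than 1")
    perm = rng.permutation(n)
    cut1, cut2, cut3 = n_pval, n_pval + n_decoy, n_pval + n_decoy + n_size
    pval_set = set(perm[:cut1].tolist())
    decoy_set = set(perm[cut1:cut2].tolist())
    size_set = set(perm[cut2:cut3].tolist())
    phrase_set = set(perm[cut3 : cut3 + n_phrase].tolist())

    n_unlabeled = _count(spec.unlabeled_fraction)
    unlabeled_set = set(rng.permutation(n)[:n_unlabeled].tolist())

    records: list[PublicationRecord] = []
    raw_records: list[RawRecord] = []
    field_labels: list[str] = []
    pvalue_flags = np.zeros(n, dtype=bool)
    decoy_flags = np.zeros(n, dtype=bool)
    phrase_flags = np.zeros(n, dtype=bool)
    sample_sizes: list[Optional[int]] = [None] * n
    author_counts = np.zeros(n, dtype=int)
    word_counts = np.zeros(n, dtype=int)
    term_counts: Counter = Counter()

    for i in range(n):
        topic = int(topic_ids[i])
        length = max(
            30,
            int(
                round(
                    rng.normal(
                        spec.words_per_abstract_mean,
                        spec.words_per_abstract_sd,
                    )
                )
            ),
        )
        from_topic = rng.random(length) < spec.topic_word_fraction
        vocab_t = topics[topic]
        words = [
            (
                vocab_t[rng.integers(len(vocab_t))]
                if from_topic[j]
                else background[rng.integers(len(background))]
            )
            for j in range(length)
        ]
        term_counts.update(words)

        inserts: list[str] = []
        if i in pval_set:
            inserts.append(str(rng.choice(_PVALUE_FORMS)))
            pvalue_flags[i] = True
        if i in decoy_set:
            inserts.append(_DECOY_PVALUE)
            decoy_flags[i] = True
        if i in size_set:
            value = int(np.exp(rng.uniform(np.log(3), np.log(2000))))
            template = str(rng.choice(_SAMPLE_SIZE_TEMPLATES))
            inserts.append(template.format(v=value))
            sample_sizes[i] = value
        if i in phrase_set:
            inserts.append(spec.phrase)
            phrase_flags[i] = True
        for chunk in inserts:
            words.insert(int(rng.integers(len(words) + 1)), chunk)
        abstract = " ".join(words)
        word_counts[i] = len(abstract.split())

        if i in unlabeled_set:
            journal, label = UNCLASSIFIED_JOURNAL, UNCLASSIFIED
        else:
            category = topic_categories[topic]
            journal = (
                f"Journal of {_CATEGORY_TITLE_WORDS[category]} Research"
            )
            label = category
        field_labels.append(label)

        last_author = _pick_name(rng)
        if rng.random() < spec.single_author_fraction:
            first_author = last_author
        else:
            first_author = _pick_name(rng)
            while first_author == last_author:
                first_author = _pick_name(rng)
        authors = concat_authors(first_author, last_author)
        author_counts[i] = authors.count(";") + 1

        raw = RawRecord(
            pmid=str(1_000_000 + i),
            title=f"Synthetic record {i} on {vocab_t[0]}",
            abstract=abstract,
            journal_title=journal,
            year=int(years[i]),
            language="eng",
            first_author=first_author,
            last_author=last_author,
        )
        raw_records.append(raw)
        records.append(
            PublicationRecord(
                pmid=raw.pmid,
                title=raw.title,
                abstract=abstract,
                journal_title=journal,
                year=int(years[i]),
                language="eng",
                authors=authors,
            )
        )

    # invalid records exercising the curation filters, appended at the end
    for j in range(spec.n_invalid_records):
        kind = j % 3
        raw_records.append(
            RawRecord(
                pmid=str(9_000_000 + j),
                title=f"Invalid synthetic record {j}",
                abstract=None if kind == 0 else "placeholder abstract text",
                journal_title=UNCLASSIFIED_JOURNAL,
                year=None if kind == 1 else spec.year_start,
                language="eng",
                first_author=None,
                last_author=None if kind == 2 else _pick_name(rng),
            )
        )

    topic_sizes = dict(
        zip(*map(list, np.unique(topic_ids, return_counts=True)))
    )
    ledger = TruthLedger(
        topic_ids=topic_ids,
        field_labels=field_labels,
        years=years.astype(int),
        pvalue_flags=pvalue_flags,
        decoy_flags=decoy_flags,
        phrase_flags=phrase_flags,
        sample_sizes=sample_sizes,
        author_counts=author_counts,
        abstract_word_counts=word_counts,
        year_counts=year_counts,
        topic_sizes={int(k): int(v) for k, v in topic_sizes.items()},
        topic_vocabularies=topics,
        background_terms=background,
        term_counts=term_counts,
        n_invalid=spec.n_invalid_records,
    )
    return GeneratedCorpus(
        corpus=Corpus(records=records), ledger=ledger, raw_records=raw_records
    )


def generate_cluster_embeddings(
    ledger: TruthLedger,
    d: int = 768,
    separation: float = 10.0,
    cluster_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Planted Gaussian cluster embeddings aligned to the ledger.

    Cluster centers sit at the vertices of a regular simplex, mutually
    separated by ``separation`` times the within-cluster RMS radius
    (``cluster_sd * sqrt(d)``); each row is its topic's center plus
    isotropic Gaussian noise of per-coordinate SD ``cluster_sd``.
    ``separation=0`` collapses every center onto the origin.
    """
    rng = np.random.default_rng(seed)
    k = int(ledger.topic_ids.max()) + 1
    if k > d:
        raise ValueError("need embedding dimension >= number of topics")
    target = separation * cluster_sd * np.sqrt(d)
    centers = np.zeros((k, d))
    # e_i * target/sqrt(2): all pairwise center distances equal `target`
    for t in range(k):
        centers[t, t] = target / np.sqrt(2.0)
    n = ledger.topic_ids.shape[0]
    noise = rng.normal(scale=cluster_sd, size=(n, d))
    return centers[ledger.topic_ids] + noise


def render_pubmed_xml(raw_records: list[RawRecord]) -> bytes:
    """Render records as PubMed efetch XML (``PubmedArticleSet`` dialect).

    Round-trips through ``parse_pubmed_xml``: absent fields are omitted from
    the XML rather than written as empty elements.
    """
    root = etree.Element("PubmedArticleSet")
    for record in raw_records:
        article_el = etree.SubElement(root, "PubmedArticle")
        citation = etree.SubElement(article_el, "MedlineCitation")
        etree.SubElement(citation, "PMID").text = record.pmid
        article = etree.SubElement(citation, "Article")
        journal = etree.SubElement(article, "Journal")
        if record.journal_title:
            etree.SubElement(journal, "Title").text = record.journal_title
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        if record.year is not None:
            etree.SubElement(pubdate, "Year").text = str(record.year)
        if record.title:
            etree.SubElement(article, "ArticleTitle").text = record.title
        if record.abstract:
            abstract = etree.SubElement(article, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = record.abstract
        authors = [
            name
            for name in (record.first_author, record.last_author)
            if name
        ]
        if record.first_author == record.last_author and authors:
            authors = authors[:1]
        if authors:
            author_list = etree.SubElement(article, "AuthorList")
            for name in authors:
                author = etree.SubElement(author_list, "Author")
                given, _, family = name.rpartition(" ")
                if given:
                    etree.SubElement(author, "LastName").text = family
                    etree.SubElement(author, "ForeName").text = given
                else:
                    etree.SubElement(author, "CollectiveName").text = family
        if record.language:
            etree.SubElement(article, "Language").text = record.language
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


__all__ = [
    "GeneratedCorpus",
    "SyntheticSpec",
    "TruthLedger",
    "UNCLASSIFIED_JOURNAL",
    "generate_cluster_embeddings",
    "generate_corpus",
    "render_pubmed_xml",
]
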