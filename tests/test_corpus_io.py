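"""PubMed XML parsing, curation filters and dataset persistence."""

import logging

import numpy as np
import pytest
from lxml import etree

from litmap import (
    AlignmentError,
    Corpus,
    RawRecord,
    curate_records,
    load_dataset,
    parse_pubmed_xml,
    save_dataset,
)

ONE_ARTICLE = """<?xml version="1.0"?>
<PubmedArticleSet>
  <PubmedArticle><MedlineCitation>
    <PMID>1</PMID>
    <Article>
      <Journal><Title>Metabolites</Title>
        <JournalIssue><PubDate><Year>2005</Year></PubDate></JournalIssue>
      </Journal>
      <ArticleTitle>T</ArticleTitle>
      <Abstract><AbstractText>A</AbstractText></Abstract>
      <AuthorList>
        <Author><LastName>Chen</LastName><ForeName>Alice</ForeName></Author>
        <Author><LastName>Ito</LastName><ForeName>Hiro</ForeName></Author>
      </AuthorList>
      <Language>eng</Language>
    </Article>
  </MedlineCitation></PubmedArticle>
</PubmedArticleSet>
"""


def _wrap(body: str) -> str:
    return f"<PubmedArticleSet>{body}</PubmedArticleSet>"


def test_parse_single_article_echoes_fields():
    (record,) = parse_pubmed_xml(ONE_ARTICLE)
    assert record.pmid == "1"
    assert record.title == "T"
    assert record.abstract == "A"
    assert record.journal_title == "Metabolites"
    assert record.year == 2005
    assert record.language == "eng"
    assert record.first_author == "Alice Chen"
    assert record.last_author == "Hiro Ito"


def test_parse_missing_abstract_is_absent_not_empty():
    xml = _wrap(
        "<PubmedArticle><MedlineCitation><PMID>1</PMID>"
        "<Article><Abstract><AbstractText>A</AbstractText></Abstract>"
        "</Article></MedlineCitation></PubmedArticle>"
        "<PubmedArticle><MedlineCitation><PMID>2</PMID>"
        "<Article/></MedlineCitation></PubmedArticle>"
    )
    first, second = parse_pubmed_xml(xml)
    assert first.abstract == "A"
    assert second.abstract is None


def test_medline_date_free_text_year():
    # oracle: the first 4-digit token of the free-text date
    xml = _wrap(
        "<PubmedArticle><MedlineCitation><PMID>3</PMID><Article>"
        "<Journal><JournalIssue><PubDate>"
        "<MedlineDate>1998 Nov-Dec</MedlineDate>"
        "</PubDate></JournalIssue></Journal>"
        "</Article></MedlineCitation></PubmedArticle>"
    )
    (record,) = parse_pubmed_xml(xml)
    assert record.year == 1998


def test_structured_abstract_sections_concatenated_in_order():
    xml = _wrap(
        "<PubmedArticle><MedlineCitation><PMID>4</PMID><Article><Abstract>"
        '<AbstractText Label="BACKGROUND">First part.</AbstractText>'
        '<AbstractText Label="RESULTS">Second part.</AbstractText>'
        "</Abstract></Article></MedlineCitation></PubmedArticle>"
    )
    (record,) = parse_pubmed_xml(xml)
    assert record.abstract == "First part. Second part."


def test_collective_author_used_verbatim():
    xml = _wrap(
        "<PubmedArticle><MedlineCitation><PMID>5</PMID><Article>"
        "<AuthorList><Author>"
        "<CollectiveName>Metabolomics Consortium</CollectiveName>"
        "</Author></AuthorList>"
        "</Article></MedlineCitation></PubmedArticle>"
    )
    (record,) = parse_pubmed_xml(xml)
    assert record.first_author == "Metabolomics Consortium"
    assert record.last_author == "Metabolomics Consortium"


def test_malformed_xml_raises_with_position():
    with pytest.raises(etree.XMLSyntaxError):
        parse_pubmed_xml("<PubmedArticleSet><oops></PubmedArticleSet>")


def test_article_without_pmid_skipped_with_warning(caplog):
    xml = _wrap(
        "<PubmedArticle><MedlineCitation>"
        "<Article><ArticleTitle>No id</ArticleTitle></Article>"
        "</MedlineCitation></PubmedArticle>"
    )
    with caplog.at_level(logging.WARNING, logger="litmap.corpus_io"):
        records = parse_pubmed_xml(xml)
    assert records == []
    assert any("PMID" in message for message in caplog.messages)


@pytest.mark.parametrize(
    "missing", ["abstract", "year", "last_author"]
)
def test_curation_drops_incomplete_records(missing):
    fields = dict(
        pmid="1", title="T", abstract="A", journal_title="J",
        year=2000, language="eng", first_author="A B", last_author="C D",
    )
    fields[missing] = None
    assert len(curate_records([RawRecord(**fields)])) == 0


def test_curation_retains_and_concatenates_authors():
    raw = RawRecord(
        pmid="1", title="T", abstract="A", journal_title="J",
        year=2000, language="eng",
        first_author="Alice Chen", last_author="Hiro Ito",
    )
    corpus = curate_records([raw])
    assert len(corpus) == 1
    assert corpus.records[0].authors == "Alice Chen; Hiro Ito"
    assert corpus.records[0].author_names == ["Alice Chen", "Hiro Ito"]


def test_curation_single_author_stored_once():
    raw = RawRecord(
        pmid="1", abstract="A", year=2000,
        first_author="Alice Chen", last_author="Alice Chen",
    )
    assert curate_records([raw]).records[0].authors == "Alice Chen"


def test_curation_empty_input_gives_empty_corpus():
    assert len(curate_records([])) == 0


def test_curation_duplicate_pmids_keep_first():
    raws = [
        RawRecord(pmid="9", abstract=f"text {i}", year=2000,
                  last_author="A B")
        for i in range(3)
    ]
    corpus = curate_records(raws)
    assert len(corpus) == 1
    assert corpus.records[0].abstract == "text 0"


def test_curation_is_idempotent(default_corpus):
    raws = [
        RawRecord(
            pmid=r.pmid, title=r.title, abstract=r.abstract,
            journal_title=r.journal_title, year=r.year, language=r.language,
            first_author=r.author_names[0], last_author=r.author_names[-1],
        )
        for r in default_corpus.records
    ]
    once = curate_records(raws)
    assert once.records == default_corpus.records


def test_parse_curate_recovers_planted_valid_records(default_generated):
    parsed = parse_pubmed_xml(default_generated.to_pubmed_xml())
    assert len(parsed) == (
        len(default_generated.corpus) + default_generated.ledger.n_invalid
    )
    curated = curate_records(parsed)
    assert curated.records == default_generated.corpus.records


def test_dataset_round_trip_preserves_records_and_embedding(
    default_corpus, tmp_path
):
    rng = np.random.default_rng(0)
    corpus = Corpus(
        records=default_corpus.records[:50],
        embedding=rng.normal(size=(50, 8)),
    )
    save_dataset(corpus, tmp_path)
    loaded = load_dataset(tmp_path)
    assert loaded.records == corpus.records
    np.testing.assert_allclose(loaded.embedding, corpus.embedding)


def test_dataset_row_count_mismatch_raises(default_corpus, tmp_path):
    import h5py

    corpus = Corpus(records=default_corpus.records[:3])
    save_dataset(corpus, tmp_path)
    with h5py.File(tmp_path / "embeddings.h5", "w") as handle:
        handle.create_dataset("embeddings", data=np.zeros((2, 4)))
    with pytest.raises(AlignmentError):
        load_dataset(tmp_path)


def test_corpus_embedding_alignment_enforced(default_corpus):
    with pytest.raises(AlignmentError):
        Corpus(records=default_corpus.records[:3], embedding=np.zeros((2, 4)))
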