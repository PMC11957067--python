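"""PubMed efetch XML parsing, corpus curation and on-disk persistence.

The reader understands the ``PubmedArticleSet`` dialect produced by NCBI
E-utilities ``efetch -format xml``.  Curation applies the study's inclusion
filters: records missing abstract text, a publication year or a last author
are discarded, and first/last author names are concatenated into a single
``authors`` field.

Persistence keeps metadata as a UTF-8 TSV with a header row and the optional
embedding matrix as an HDF5 dataset, with PMIDs stored alongside so row
alignment can be checked on load.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import h5py
import numpy as np
import pandas as pd
from lxml import etree

from .records import (
    AlignmentError,
    Corpus,
    PublicationRecord,
    RawRecord,
    concat_authors,
)

logger = logging.getLogger(__name__)

METADATA_FILENAME = "metadata.tsv"
EMBEDDING_FILENAME = "embeddings.h5"
EMBEDDING_DATASET = "embeddings"

_YEAR_TOKEN = re.compile(r"\b(\d{4})\b")


def _text(node: Optional[etree._Element]) -> Optional[str]:
    # strip surrounding whitespace only: internal runs of spaces are
    # meaningful to downstream regex queries and must survive round trips
    if node is None:
        return None
    value = "".join(node.itertext()).strip()
    return value or None


def _author_name(author: etree._Element) -> Optional[str]:
    collective = _text(author.find("CollectiveName"))
    if collective:
        return collective
    last = _text(author.find("LastName"))
    fore = _text(author.find("ForeName")) or _text(author.find("Initials"))
    if last and fore:
        return f"{fore} {last}"
    return last or fore


def _extract_year(article: etree._Element) -> Optional[int]:
    # Prefer the structured PubDate/Year; fall back to the first 4-digit
    # token of the free-text MedlineDate (e.g. "1998 Nov-Dec" -> 1998).
    pubdate = article.find(".//Journal/JournalIssue/PubDate")
    if pubdate is None:
        return None
    year = _text(pubdate.find("Year"))
    if year is None:
        medline = _text(pubdate.find("MedlineDate"))
        if medline:
            match = _YEAR_TOKEN.search(medline)
            year = match.group(1) if match else None
    if year is None:
        return None
    value = int(year)
    return value if 1900 <= value <= 2100 else None


def _parse_article(citation: etree._Element) -> Optional[RawRecord]:
    pmid = _text(citation.find("PMID"))
    if pmid is None:
        logger.warning("skipping article without a PMID")
        return None
    article = citation.find("Article")
    if article is None:
        return RawRecord(pmid=pmid)

    # Structured abstracts carry several labelled AbstractText sections;
    # they are concatenated in document order, labels dropped.
    sections = [
        _text(sec) for sec in article.findall("Abstract/AbstractText")
    ]
    abstract = " ".join(s for s in sections if s) or None

    authors = [
        name
        for author in article.findall("AuthorList/Author")
        if (name := _author_name(author)) is not None
    ]

    return RawRecord(
        pmid=pmid,
        title=_text(article.find("ArticleTitle")),
        abstract=abstract,
        journal_title=_text(article.find("Journal/Title")),
        year=_extract_year(article),
        language=_text(article.find("Language")),
        first_author=authors[0] if authors else None,
        last_author=authors[-1] if authors else None,
    )


def parse_pubmed_xml(
    xml_source: Union[str, bytes, Path, IO[bytes]],
) -> list[RawRecord]:
    """Parse PubMed efetch XML into :class:`RawRecord` objects.

    Parameters
    ----------
    xml_source
        A path, open binary stream, or raw XML bytes/text containing a
        ``PubmedArticleSet``.

    Returns
    -------
    list of RawRecord
        One record per ``PubmedArticle`` element, in document order.
        Articles lacking a PMID are skipped with a logged warning.

    Raises
    ------
    lxml.etree.XMLSyntaxError
        If the input is not well-formed XML (the error names the position).
    """
    looks_like_path = isinstance(xml_source, Path) or (
        isinstance(xml_source, str) and "<" not in xml_source
    )
    if looks_like_path:
        tree = etree.parse(str(xml_source))
        root = tree.getroot()
    else:
        data = xml_source
        if hasattr(data, "read"):
            data = data.read()  # type: ignore[union-attr]
        if isinstance(data, str):
            data = data.encode("utf-8")
        root = etree.fromstring(data)

    records = []
    for citation in root.iter("MedlineCitation"):
        record = _parse_article(citation)
        if record is not None:
            records.append(record)
    return records


def curate_records(raw: Iterable[RawRecord]) -> Corpus:
    """Apply the study inclusion filters to raw records.

    Records missing abstract text, a publication year or a last author name
    are discarded; first and last author names are concatenated into the
    single ``authors`` field.  Duplicate PMIDs (across efetch batches) keep
    their first occurrence.  Input order is preserved and the operation is
    idempotent.
    """
    seen: set[str] = set()
    kept: list[PublicationRecord] = []
    for record in raw:
        if not record.abstract or record.year is None or not record.last_author:
            continue
        if record.pmid in seen:
            logger.warning("duplicate PMID %s dropped", record.pmid)
            continue
        seen.add(record.pmid)
        kept.append(
            PublicationRecord(
                pmid=record.pmid,
                title=record.title or "",
                abstract=record.abstract,
                journal_title=record.journal_title or "",
                year=record.year,
                language=record.language or "",
                authors=concat_authors(record.first_author, record.last_author),
            )
        )
    return Corpus(records=kept)


def save_dataset(corpus: Corpus, out_dir: Union[str, Path]) -> Path:
    """Persist a corpus: metadata as TSV, embeddings (if any) as HDF5."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = corpus.to_frame()
    frame.to_csv(out / METADATA_FILENAME, sep="\t", index=False)
    if corpus.embedding is not None:
        with h5py.File(out / EMBEDDING_FILENAME, "w") as handle:
            handle.create_dataset(EMBEDDING_DATASET, data=corpus.embedding)
            handle.create_dataset(
                "pmid",
                data=np.array([r.pmid for r in corpus.records], dtype="S"),
            )
    return out


def load_dataset(path: Union[str, Path]) -> Corpus:
    """Load a corpus written by :func:`save_dataset`.

    Raises
    ------
    AlignmentError
        If the embedding matrix row count differs from the metadata rows.
    """
    root = Path(path)
    frame = pd.read_csv(
        root / METADATA_FILENAME,
        sep="\t",
        dtype=str,
        keep_default_na=False,
    )
    frame["year"] = frame["year"].astype(int)

    embedding = None
    h5_path = root / EMBEDDING_FILENAME
    if h5_path.exists():
        with h5py.File(h5_path, "r") as handle:
            embedding = np.asarray(handle[EMBEDDING_DATASET])
        if embedding.shape[0] != len(frame):
            raise AlignmentError(
                f"{len(frame)} metadata rows but {embedding.shape[0]} "
                "embedding rows"
            )
    return Corpus.from_frame(frame, embedding=embedding)


__all__ = [
    "curate_records",
    "load_dataset",
    "parse_pubmed_xml",
    "save_dataset",
]
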