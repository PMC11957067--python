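"""Core record and corpus containers shared by every pipeline stage.

A :class:`RawRecord` is one PubMed article as parsed from efetch XML, with
every field optional except the PMID.  Curation turns raw records into
:class:`PublicationRecord` objects — abstract, year and last author are then
guaranteed present — and collects them in a :class:`Corpus`, optionally
carrying a row-aligned embedding matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

#: separator used when concatenating first and last author names into the
#: single curated ``authors`` field (names themselves may contain commas,
#: e.g. collective/consortium names, so a semicolon is used)
AUTHOR_SEPARATOR = "; "


class AlignmentError(ValueError):
    """Metadata rows and embedding rows disagree in count or order."""


@dataclass(slots=True)
class RawRecord:
    """One article as extracted from PubMed XML; absent fields are ``None``."""

    pmid: str
    title: Optional[str] = None
    abstract: Optional[str] = None
    journal_title: Optional[str] = None
    year: Optional[int] = None
    language: Optional[str] = None
    first_author: Optional[str] = None
    last_author: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("RawRecord requires a non-empty pmid")
        if self.year is not None and not (1900 <= self.year <= 2100):
            raise ValueError(f"implausible publication year {self.year!r}")


@dataclass(slots=True)
class PublicationRecord:
    """A curated article: abstract, year and authors are guaranteed present."""

    pmid: str
    title: str
    abstract: str
    journal_title: str
    year: int
    language: str
    authors: str

    def __post_init__(self) -> None:
        if not self.abstract:
            raise ValueError("curated record requires a non-empty abstract")
        if not self.authors:
            raise ValueError("curated record requires a non-empty authors field")

    @property
    def author_names(self) -> list[str]:
        """Author names stored in the concatenated ``authors`` field."""
        return self.authors.split(AUTHOR_SEPARATOR)


@dataclass
class Corpus:
    """Ordered curated records plus an optional row-aligned embedding matrix."""

    records: list[PublicationRecord] = field(default_factory=list)
    embedding: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=np.float64)
            if self.embedding.ndim != 2:
                raise AlignmentError("embedding must be a 2-D matrix")
            if self.embedding.shape[0] != len(self.records):
                raise AlignmentError(
                    f"{len(self.records)} records but "
                    f"{self.embedding.shape[0]} embedding rows"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PublicationRecord]:
        return iter(self.records)

    @property
    def abstracts(self) -> list[str]:
        return [r.abstract for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame, one row per record in corpus order."""
        return pd.DataFrame(
            {
                "pmid": [r.pmid for r in self.records],
                "title": [r.title for r in self.records],
                "abstract": [r.abstract for r in self.records],
                "journal_title": [r.journal_title for r in self.records],
                "year": [r.year for r in self.records],
                "language": [r.language for r in self.records],
                "authors": [r.authors for r in self.records],
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, embedding: Optional[np.ndarray] = None
    ) -> "Corpus":
        records = [
            PublicationRecord(
                pmid=str(row.pmid),
                title=str(row.title),
                abstract=str(row.abstract),
                journal_title=str(row.journal_title),
                year=int(row.year),
                language=str(row.language),
                authors=str(row.authors),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records=records, embedding=embedding)


def concat_authors(first: Optional[str], last: str) -> str:
    """Build the curated single authors field from first and last author.

    The first author is omitted when absent or identical to the last author
    (single-author papers), so each name appears once.
    """
    if first and first != last:
        return f"{first}{AUTHOR_SEPARATOR}{last}"
    return last


__all__ = [
    "AUTHOR_SEPARATOR",
    "AlignmentError",
    "Corpus",
    "PublicationRecord",
    "RawRecord",
    "concat_authors",
]
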