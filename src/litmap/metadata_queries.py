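"""Regex and phrase mining over abstracts.

Mirrors the study's metadata queries: p-value presence (``[pP]\\s?[<=>]``,
so "p<0.05" and "P = 0.01" match but a two-space "P  =  0.01" does not),
sample-size capture (``n\\s?=\\s?(\\d+)``), free phrase masks such as
"for the first time", and simple per-record statistics (collaboration size,
journal-title length, abstract length).

Regex patterns run as written (case-sensitive); phrase queries are literal
and case-insensitive by default.  Matching runs on abstracts only unless
titles are explicitly included.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import Corpus, PublicationRecord

#: pattern flagging reported p-values ("p<0.05", "P=0.01", "p > 0.001");
#: \s? admits at most one whitespace between the p and the comparator
P_VALUE_PATTERN = r"[pP]\s?[<=>]"

#: pattern capturing reported sample sizes ("n=30", "n = 500")
SAMPLE_SIZE_PATTERN = r"n\s?=\s?(\d+)"


@dataclass(frozen=True)
class QueryMask:
    """Per-record boolean match flags for one pattern."""

    pattern: str
    flags: np.ndarray  # bool, aligned to corpus records

    @property
    def count(self) -> int:
        return int(self.flags.sum())


def _record_text(record: PublicationRecord, fields: Sequence[str]) -> str:
    parts = []
    for name in fields:
        if name == "abstract":
            parts.append(record.abstract)
        elif name == "title":
            parts.append(record.title)
        else:
            raise ValueError(f"unknown field {name!r}")
    return " ".join(parts)


def flag_pattern(
    corpus: Corpus,
    pattern: str,
    case_sensitive: bool = True,
    literal: bool = False,
    fields: Sequence[str] = ("abstract",),
) -> QueryMask:
    """Flag records whose abstract matches a regular expression.

    ``literal=True`` escapes the pattern first (phrase matching).  Invalid
    patterns raise ``re.error``.
    """
    source = re.escape(pattern) if literal else pattern
    compiled = re.compile(source, flags=0 if case_sensitive else re.IGNORECASE)
    flags = np.fromiter(
        (
            compiled.search(_record_text(record, fields)) is not None
            for record in corpus.records
        ),
        dtype=bool,
        count=len(corpus),
    )
    return QueryMask(pattern=pattern, flags=flags)


def flag_phrase(
    corpus: Corpus, phrase: str, fields: Sequence[str] = ("abstract",)
) -> QueryMask:
    """Case-insensitive literal phrase mask (e.g. "for the first time")."""
    return flag_pattern(
        corpus, phrase, case_sensitive=False, literal=True, fields=fields
    )


def extract_sample_sizes(
    corpus: Corpus,
    policy: str = "first",
    pattern: str = SAMPLE_SIZE_PATTERN,
) -> list[Optional[Union[int, list[int]]]]:
    """Reported sample sizes per record under ``n = <int>`` capture.

    ``policy`` selects among multiple matches in one abstract: ``"first"``
    (default) keeps the first, ``"max"`` the largest, ``"all"`` returns the
    full list.  Records with no match yield ``None``.
    """
    if policy not in {"first", "max", "all"}:
        raise ValueError(f"unknown policy {policy!r}")
    compiled = re.compile(pattern)
    out: list[Optional[Union[int, list[int]]]] = []
    for record in corpus.records:
        values = [int(m.group(1)) for m in compiled.finditer(record.abstract)]
        values = [v for v in values if v >= 1]
        if not values:
            out.append(None)
        elif policy == "first":
            out.append(values[0])
        elif policy == "max":
            out.append(max(values))
        else:
            out.append(values)
    return out


def record_stats(corpus: Corpus) -> pd.DataFrame:
    """Per-record collaboration size and text lengths.

    Columns: ``author_count`` (names stored in the curated authors field),
    ``journal_title_chars``, ``abstract_words`` (whitespace tokens) and
    ``abstract_chars``; one row per record in corpus order.
    """
    return pd.DataFrame(
        {
            "pmid": [r.pmid for r in corpus.records],
            "author_count": [len(r.author_names) for r in corpus.records],
            "journal_title_chars": [
                len(r.journal_title) for r in corpus.records
            ],
            "abstract_words": [
                len(r.abstract.split()) for r in corpus.records
            ],
            "abstract_chars": [len(r.abstract) for r in corpus.records],
        }
    )


__all__ = [
    "P_VALUE_PATTERN",
    "QueryMask",
    "SAMPLE_SIZE_PATTERN",
    "extract_sample_sizes",
    "flag_pattern",
    "flag_phrase",
    "record_stats",
]
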