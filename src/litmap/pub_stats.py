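"""Publication analytics: yearly counts, growth-rate classification,
abstract-length and journal distributions, and abstract term frequencies.

The growth analysis computes the year-over-year change in publication counts
(the discrete derivative of the annual series), then classifies years as
consistently high- or low-growth relative to thresholds of mean ± one
standard deviation of those changes.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping, Optional

import numpy as np
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .records import Corpus

#: custom stop words removed from abstract term frequencies in addition to
#: the standard English list
CUSTOM_STOP_WORDS = frozenset({"used", "study"})

_TOKEN = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class GrowthReport:
    """Year-over-year growth rates with mean ± SD threshold classification.

    ``rates`` holds one ``(year1, year2, delta)`` triple per consecutive year
    pair, where ``delta = counts[year2] - counts[year1]``.  Years whose delta
    reaches ``mean_rate + sd_rate`` are high-growth; years whose delta falls
    to ``mean_rate - sd_rate`` are low-growth (keyed by ``year1``).  When the
    deltas have zero spread no year is flagged: there is no variation to
    stand one standard deviation away from.
    """

    rates: tuple[tuple[int, int, int], ...]
    mean_rate: float
    sd_rate: float
    high_threshold: float
    low_threshold: float
    high_years: frozenset[int]
    low_years: frozenset[int]


def yearly_counts(
    corpus: Corpus, drop_years: AbstractSet[int] = frozenset()
) -> dict[int, int]:
    """Publications per year, densified over the observed span.

    Years listed in ``drop_years`` are excluded entirely (the study removes
    early-2024 records this way); missing years inside the span get count 0.
    """
    counted = Counter(
        r.year for r in corpus.records if r.year not in drop_years
    )
    if not counted:
        return {}
    first, last = min(counted), max(counted)
    return {year: counted.get(year, 0) for year in range(first, last + 1)}


def growth_report(counts: Mapping[int, int], ddof: int = 0) -> GrowthReport:
    """Classify years into high/low publication growth.

    Parameters
    ----------
    counts
        Year -> publication count; at least two years.
    ddof
        Delta degrees of freedom for the standard deviation; 0 (population
        form, the default) or 1 (sample form).
    """
    if len(counts) < 2:
        raise ValueError("insufficient span: need counts for at least 2 years")
    years = sorted(counts)
    deltas = [counts[y2] - counts[y1] for y1, y2 in zip(years, years[1:])]
    mean = float(np.mean(deltas))
    sd = float(np.std(deltas, ddof=ddof))
    high = mean + sd
    low = mean - sd
    if sd > 0:
        high_years = frozenset(
            y1 for y1, d in zip(years, deltas) if d >= high
        )
        low_years = frozenset(y1 for y1, d in zip(years, deltas) if d <= low)
    else:
        high_years = low_years = frozenset()
    return GrowthReport(
        rates=tuple(
            (y1, y2, d) for (y1, y2), d in zip(zip(years, years[1:]), deltas)
        ),
        mean_rate=mean,
        sd_rate=sd,
        high_threshold=high,
        low_threshold=low,
        high_years=high_years,
        low_years=low_years,
    )


def abstract_length_histogram(
    corpus: Corpus, unit: str = "words", bin_width: int = 1
) -> dict[int, int]:
    """Distribution of abstract lengths in words or characters.

    Word length uses whitespace tokenization.  Bins are left edges of width
    ``bin_width``; the default width 1 gives exact-length counts.
    """
    if unit == "words":
        lengths = (len(r.abstract.split()) for r in corpus.records)
    elif unit == "characters":
        lengths = (len(r.abstract) for r in corpus.records)
    else:
        raise ValueError(f"unknown unit {unit!r}; use 'words' or 'characters'")
    histogram: Counter[int] = Counter(
        (length // bin_width) * bin_width for length in lengths
    )
    return dict(sorted(histogram.items()))


def journal_frequencies(corpus: Corpus) -> list[tuple[str, int]]:
    """Journals ranked by publication count, descending; ties alphabetical."""
    counts = Counter(r.journal_title for r in corpus.records)
    return sorted(counts.items(), key=lambda item: (-item[1], item[0]))


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric characters; keeps 1-char
    tokens so statistical shorthand like "n" and "p" survives."""
    return _TOKEN.findall(text.lower())


def term_frequencies(
    corpus: Corpus,
    stopwords: Optional[Iterable[str]] = None,
    custom_stopwords: Iterable[str] = CUSTOM_STOP_WORDS,
) -> dict[str, int]:
    """Token counts over all abstracts with stop words removed.

    ``stopwords`` defaults to scikit-learn's frozen English list; the study's
    two custom additions ("used", "study") are removed on top of it.
    """
    stop = set(ENGLISH_STOP_WORDS if stopwords is None else stopwords)
    stop |= set(custom_stopwords)
    counts: Counter[str] = Counter()
    for record in corpus.records:
        counts.update(
            token for token in tokenize(record.abstract) if token not in stop
        )
    return dict(counts)


def top_terms(frequencies: Mapping[str, int], k: int = 20) -> list[tuple[str, int]]:
    """The ``k`` most frequent terms, ties broken alphabetically."""
    ranked = sorted(frequencies.items(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


__all__ = [
    "CUSTOM_STOP_WORDS",
    "GrowthReport",
    "abstract_length_histogram",
    "growth_report",
    "journal_frequencies",
    "term_frequencies",
    "tokenize",
    "top_terms",
    "yearly_counts",
]
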