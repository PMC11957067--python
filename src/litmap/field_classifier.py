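"""Research-field classification from journal titles.

Each publication is assigned to one of 18 predefined research fields by
lowercase substring matching of category keywords against its journal title;
titles matching no keyword are labelled ``"unclassified"``.  Category order
is the tie-break priority when a title matches several categories.

The bundled keyword map (``data/field_keywords_synthetic.json``) is a
package-authored reconstruction: the category names and order are the
published ones, the keyword lists are our own (seeded from the printed
examples such as "cancer"/"oncogene"/"tumor" for oncology).  A map exported
from the original study can be loaded from any JSON file with the same
schema.
"""

from __future__ import annotations

import json
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .records import Corpus

UNCLASSIFIED = "unclassified"

#: JSON schema: {"categories": {"<category>": ["keyword", ...], ...}}
DEFAULT_KEYWORDS_RESOURCE = "field_keywords_synthetic.json"


class CategoryKeywordMap:
    """Ordered category -> lowercase-keyword mapping.

    Order matters: classification returns the first category (in insertion
    order) with a keyword contained in the lowercased journal title.
    """

    def __init__(self, categories: dict[str, list[str]]):
        if not categories:
            raise ValueError("keyword map must define at least one category")
        cleaned: dict[str, list[str]] = {}
        for category, keywords in categories.items():
            kws = [kw.lower() for kw in keywords]
            if not kws or any(not kw for kw in kws):
                raise ValueError(
                    f"category {category!r} has empty keyword entries"
                )
            cleaned[category] = kws
        self.categories = cleaned

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories.items())

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CategoryKeywordMap":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(payload["categories"])

    @classmethod
    def default(cls) -> "CategoryKeywordMap":
        """The bundled 18-category reconstruction."""
        payload = json.loads(
            resources.files("litmap.data")
            .joinpath(DEFAULT_KEYWORDS_RESOURCE)
            .read_text(encoding="utf-8")
        )
        return cls(payload["categories"])


def classify_journal(
    journal_title: str, keyword_map: Optional[CategoryKeywordMap] = None
) -> str:
    """Assign a journal title to a research field.

    The title is lowercased and each category's keywords are tested for
    substring containment in category order; the first match wins.  Empty or
    unmatched titles return ``"unclassified"``.
    """
    keyword_map = keyword_map or CategoryKeywordMap.default()
    title = (journal_title or "").lower()
    if title:
        for category, keywords in keyword_map:
            if any(kw in title for kw in keywords):
                return category
    return UNCLASSIFIED


def classify_corpus(
    corpus: Corpus, keyword_map: Optional[CategoryKeywordMap] = None
) -> tuple[list[str], dict[str, int]]:
    """Classify every record; returns row-aligned labels and field counts.

    Counts include ``"unclassified"`` and always sum to the corpus size.
    """
    keyword_map = keyword_map or CategoryKeywordMap.default()
    labels = [
        classify_journal(record.journal_title, keyword_map)
        for record in corpus.records
    ]
    return labels, dict(Counter(labels))


__all__ = [
    "CategoryKeywordMap",
    "UNCLASSIFIED",
    "classify_corpus",
    "classify_journal",
]
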