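"""Annotation-keyword triage of screen candidates.

The motivating screen shortlisted its wet-lab candidates by reading the
functional annotations of tissue-exclusive genes — prenyltransferases,
phosphatases, P450s and their reductase, generic oxidases/reductases, and
membrane transporters. This module formalizes that reading as ordered,
case-insensitive substring matching: classes are tried in priority order
and the first class with a matching keyword wins, so composite names
resolve to the most specific class ("NADPH--cytochrome P450 reductase" is
a P450 reductase, not a cytochrome P450, and not a generic reductase).

The default map ships as a plain TSV resource (``data/keyword_map.tsv``)
so users can extend classes without code changes.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .core import FormatError, LinkageError

UNCLASSIFIED = "unclassified"


class KeywordMap:
    """Ordered (class_label, keywords) rules; first match wins."""

    def __init__(self, rules: list[tuple[str, list[str]]]):
        labels = [label for label, _ in rules]
        if len(set(labels)) != len(labels):
            raise FormatError(f"duplicate class labels in keyword map: {labels}")
        if UNCLASSIFIED in labels:
            raise FormatError(f"{UNCLASSIFIED!r} is reserved for the fallback class")
        self.rules = [
            (label, [kw.strip().lower() for kw in kws if kw.strip()])
            for label, kws in rules
        ]
        for label, kws in self.rules:
            if not kws:
                raise FormatError(f"class {label!r} has no keywords")

    @property
    def class_labels(self) -> list[str]:
        return [label for label, _ in self.rules] + [UNCLASSIFIED]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KeywordMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"class_label", "keywords"} <= set(df.columns):
            raise FormatError(f"{path}: expected columns class_label, keywords")
        return cls(
            [(row.class_label, row.keywords.split(",")) for row in df.itertuples()]
        )

    @classmethod
    def default(cls) -> "KeywordMap":
        ref = resources.files("texscreen").joinpath("data/keyword_map.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def classify_annotation(annotation: str, keyword_map: KeywordMap | None = None) -> str:
    """First class whose any keyword occurs (case-insensitively) in the text."""
    keyword_map = keyword_map or KeywordMap.default()
    text = (annotation or "").lower()
    for label, keywords in keyword_map.rules:
        if any(kw in text for kw in keywords):
            return label
    return UNCLASSIFIED


def summarize_classes(
    candidate_ids,
    gene_table: pd.DataFrame,
    keyword_map: KeywordMap | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class assignments and per-class counts over candidate genes.

    Returns ``(assignments, summary)``: assignments has one row per
    candidate (gene_id, annotation, class_label); summary has one row per
    class in map order with its candidate count (zero-count classes kept).
    """
    keyword_map = keyword_map or KeywordMap.default()
    candidate_ids = list(candidate_ids)
    missing = [g for g in candidate_ids if g not in gene_table.index]
    if missing:
        raise LinkageError(f"candidate genes absent from gene table: {missing[:5]}")
    annotations = gene_table.loc[candidate_ids, "annotation"].fillna("")
    assignments = pd.DataFrame(
        {
            "annotation": annotations,
            "class_label": [classify_annotation(a, keyword_map) for a in annotations],
        },
        index=pd.Index(candidate_ids, name="gene_id"),
    )
    counts = assignments["class_label"].value_counts()
    summary = pd.DataFrame(
        {
            "class_label": keyword_map.class_labels,
            "count": [int(counts.get(c, 0)) for c in keyword_map.class_labels],
        }
    )
    return assignments, summary
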