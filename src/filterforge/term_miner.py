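"""Keyword / MeSH-term frequency mining and candidate query generation.

Emulates a PubReMiner-style tabulation: from the relevant records of the
development set it extracts every keyword (title/abstract token of length
>= 3, lower-cased, stop words removed), every MeSH descriptor and every
subheading, with document frequencies.  An optional pass adds truncated
keywords for clusters of morphological variants, and the candidate generator
expands each keyword into six field variants (bare, [tw], [tiab], [majr],
[sh], [mh]) plus one [mesh] query per MeSH descriptor — so K keywords and
M MeSH descriptors yield exactly 6·K + M candidate single-term queries.

The truncation heuristic (maximal clusters of keywords sharing a prefix of a
minimum length, replaced by their longest common prefix) is an emulation:
how truncated forms were constructed in the original workflow is not
documented, so the pass is kept separate and replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os.path import commonprefix

import pandas as pd

from ._text import is_keyword, tokenize
from .corpus_model import LabeledCorpus
from .query_engine import Query, TermQuery

__all__ = [
    "TermEntry",
    "TermFrequencyTable",
    "CandidateSet",
    "mine_terms",
    "add_truncations",
    "generate_candidates",
]

TERM_CLASSES = ("keyword", "mesh_descriptor", "subheading")

#: Field variants generated for every keyword (bare form plus five tags).
KEYWORD_FIELDS = ("all", "tw", "tiab", "majr", "sh", "mh")


@dataclass(frozen=True)
class TermEntry:
    term: str
    term_class: str
    doc_frequency: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.term_class not in TERM_CLASSES:
            raise ValueError(f"unknown term class {self.term_class!r}")
        if self.doc_frequency < 1:
            raise ValueError("doc_frequency must be >= 1")


@dataclass
class TermFrequencyTable:
    """Mined terms with document frequencies over the mined subset.

    ``_doc_ids`` privately retains, per (class, term), the set of record ids
    the term occurred in; truncation needs exact union document counts and
    the public count columns alone cannot provide them.
    """

    entries: list[TermEntry]
    n_docs: int
    _doc_ids: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(e.term_class, e.term, e.truncated) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("terms must be unique within a class")

    def keywords(self) -> list[TermEntry]:
        return [e for e in self.entries if e.term_class == "keyword"]

    def mesh_descriptors(self) -> list[TermEntry]:
        return [e for e in self.entries if e.term_class == "mesh_descriptor"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": e.term,
                    "class": e.term_class,
                    "truncated": int(e.truncated),
                    "doc_frequency": e.doc_frequency,
                }
                for e in self.entries
            ]
        )


@dataclass
class CandidateSet:
    """Candidate single-term queries with their source-term provenance."""

    queries: list[Query]
    provenance: dict[Query, str]

    def __post_init__(self) -> None:
        if len(self.queries) != len(set(self.queries)):
            raise ValueError("candidate queries must be unique under normalization")

    def __len__(self) -> int:
        return len(self.queries)


def mine_terms(corpus: LabeledCorpus, subset: set[str] | None = None) -> TermFrequencyTable:
    """Tabulate keywords, MeSH descriptors and subheadings with document
    frequencies over a subset of relevant records (default: all relevant).

    Frequencies count documents, not occurrences.  Keywords are lower-cased
    tokens of length >= 3 with stop words removed; MeSH descriptors and
    subheadings are taken verbatim from the headings.
    """
    if subset is None:
        subset = corpus.relevant_ids
    if not subset:
        raise ValueError("cannot mine an empty subset")
    not_relevant = [rid for rid in subset if not corpus.labels.get(rid, False)]
    if not_relevant:
        raise ValueError(f"subset ids not labeled relevant: {sorted(not_relevant)[:5]}")

    docs: dict[tuple[str, str], set[str]] = {}
    for rec in corpus.records:
        if rec.record_id not in subset:
            continue
        for tok in set(tokenize(rec.title + " " + rec.abstract)):
            if is_keyword(tok):
                docs.setdefault(("keyword", tok), set()).add(rec.record_id)
        for h in rec.mesh:
            docs.setdefault(("mesh_descriptor", h.descriptor), set()).add(rec.record_id)
            for s in h.subheadings:
                docs.setdefault(("subheading", s.name), set()).add(rec.record_id)

    entries = [
        TermEntry(term, cls, len(ids))
        for (cls, term), ids in sorted(docs.items())
    ]
    return TermFrequencyTable(
        entries=entries,
        n_docs=len(subset),
        _doc_ids={k: frozenset(v) for k, v in docs.items()},
    )


def add_truncations(table: TermFrequencyTable, min_prefix: int = 5) -> TermFrequencyTable:
    """Add truncated keyword entries for morphological variant clusters.

    Scans the sorted keywords for maximal runs of >= 2 entries sharing a
    common prefix of at least ``min_prefix`` characters and adds one
    truncated entry per run, whose pattern is the run's longest common
    prefix and whose document frequency is the union document count.
    All input entries are retained.
    """
    if min_prefix < 4:
        raise ValueError("min_prefix must be >= 4")
    kws = sorted(
        (e for e in table.keywords() if not e.truncated), key=lambda e: e.term
    )
    new_entries = list(table.entries)
    new_docs = dict(table._doc_ids)

    i = 0
    while i < len(kws):
        j = i + 1
        while j < len(kws) and len(
            commonprefix([kws[i].term, kws[j].term])
        ) >= min_prefix:
            j += 1
        if j - i >= 2:
            group = kws[i:j]
            prefix = commonprefix([g.term for g in group])
            union: set[str] = set()
            for g in group:
                union |= table._doc_ids[("keyword", g.term)]
            if ("keyword", prefix) not in {
                (e.term_class, e.term) for e in new_entries if e.truncated
            }:
                new_entries.append(
                    TermEntry(prefix, "keyword", len(union), truncated=True)
                )
                new_docs[("keyword", prefix)] = frozenset(union)
        i = j
    return TermFrequencyTable(entries=new_entries, n_docs=table.n_docs, _doc_ids=new_docs)


def generate_candidates(table: TermFrequencyTable) -> CandidateSet:
    """Expand mined terms into candidate single-term queries.

    Every keyword (truncated or not) yields six queries — the bare form and
    the five field-tagged variants — including MeSH-field variants for plain
    text keywords, which simply retrieve nothing.  Every MeSH descriptor
    yields one [mesh] query.  Total: 6·K + M.
    """
    if not table.entries:
        raise ValueError("cannot generate candidates from an empty table")
    queries: list[Query] = []
    provenance: dict[Query, str] = {}
    for e in table.keywords():
        for f in KEYWORD_FIELDS:
            q = Query((TermQuery(e.term, truncated=e.truncated, field=f),))
            if q not in provenance:
                queries.append(q)
                provenance[q] = e.term
    for e in table.mesh_descriptors():
        q = Query((TermQuery(e.term.lower(), truncated=False, field="mh"),))
        if q not in provenance:
            queries.append(q)
            provenance[q] = e.term
    return CandidateSet(queries=queries, provenance=provenance)
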