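"""PubMed-style boolean query parsing and evaluation over labeled corpora.

A query is a disjunction (OR) of atomic term queries.  Each term is an
optionally truncated pattern (trailing ``*``) with an optional field
restriction:

========  ==========================================================
``tiab``  tokens of title + abstract
``ti``    tokens of title only
``mh``    MeSH descriptor equality (``[mesh]`` and ``[mh]`` are aliases)
``majr``  MeSH descriptor equality, major-topic headings only
``sh``    MeSH subheading equality
``tw``    text word: tiab OR mh OR sh
``all``   no field tag; matched like ``tw``
========  ==========================================================

Matching is case-insensitive; truncation is token-prefix (descriptor-prefix
for MeSH fields).  Bare terms are matched as text words rather than through
PubMed's Automatic Term Mapping, which cannot be reproduced offline.  No MeSH
tree explosion is performed: ``[mh]``/``[majr]`` compare descriptor strings
only.  A bracketed field tag binds to the immediately preceding term only, as
in PubMed's parser.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable

from ._text import tokenize
from .corpus_model import LabeledCorpus, Record

__all__ = [
    "TermQuery",
    "Query",
    "ConfusionMatrix",
    "QueryParseError",
    "parse_query",
    "match_term",
    "evaluate",
    "CorpusIndex",
]

FIELDS = ("all", "tw", "tiab", "ti", "majr", "sh", "mh")

_FIELD_ALIASES = {
    "all": "all",
    "all fields": "all",
    "tw": "tw",
    "text word": "tw",
    "tiab": "tiab",
    "title/abstract": "tiab",
    "ti": "ti",
    "title": "ti",
    "mh": "mh",
    "mesh": "mh",
    "mesh terms": "mh",
    "mesh heading": "mh",
    "majr": "majr",
    "mesh major topic": "majr",
    "sh": "sh",
    "subheading": "sh",
    "mesh subheading": "sh",
}


class QueryParseError(ValueError):
    """Raised on malformed query text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"at position {position}: {message}")
        self.position = position


@dataclass(frozen=True)
class TermQuery:
    """One atomic term: a pattern, a truncation flag and a field restriction."""

    pattern: str
    truncated: bool = False
    field: str = "all"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        if self.field not in FIELDS:
            raise ValueError(f"unknown field {self.field!r}")
        if " " in self.pattern and self.truncated and self.field not in (
            "all", "tw", "tiab", "ti",
        ):
            raise ValueError("truncated phrases allowed only in text fields")

    def __str__(self) -> str:
        pat = f'"{self.pattern}"' if " " in self.pattern else self.pattern
        out = pat + ("*" if self.truncated else "")
        if self.field != "all":
            out += f"[{self.field}]"
        return out


@dataclass(frozen=True)
class Query:
    """An OR-disjunction of term queries."""

    terms: tuple[TermQuery, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("a query needs at least one term")
        # normalize: drop duplicate terms, preserve first-seen order
        seen: dict[TermQuery, None] = {}
        for t in self.terms:
            seen.setdefault(t)
        object.__setattr__(self, "terms", tuple(seen))

    def __str__(self) -> str:
        return " OR ".join(str(t) for t in self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def with_term(self, term: TermQuery) -> "Query":
        return Query(self.terms + (term,))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Retrieval counts against a labeled corpus.

    A: relevant retrieved (true positives); B: non-relevant retrieved
    (false positives); C: relevant missed (false negatives); D: non-relevant
    not retrieved (true negatives).
    """

    A: int
    B: int
    C: int
    D: int

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D) < 0:
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.A + self.B + self.C + self.D


# --- parsing ----------------------------------------------------------------

_QUOTES_OPEN = '"“‘'
_QUOTES_CLOSE = '"”’'


def _split_or(text: str) -> list[tuple[int, str]]:
    """Split on OR outside quotes; returns (position, chunk) pairs."""
    chunks: list[tuple[int, str]] = []
    depth_quote = False
    start = 0
    i = 0
    upper = text.upper()
    while i < len(text):
        ch = text[i]
        if ch in _QUOTES_OPEN or ch in _QUOTES_CLOSE:
            depth_quote = not depth_quote
        elif (
            not depth_quote
            and upper.startswith("OR", i)
            and (i == 0 or not text[i - 1].isalnum())
            and (i + 2 >= len(text) or not text[i + 2].isalnum())
        ):
            chunks.append((start, text[start:i]))
            i += 2
            start = i
            continue
        i += 1
    chunks.append((start, text[start:]))
    return chunks


def _parse_term(chunk: str, offset: int) -> TermQuery:
    text = chunk.strip()
    if not text:
        raise QueryParseError("empty term", offset)
    pos = offset + chunk.index(text[0])

    field = "all"
    if text.endswith("]"):
        lb = text.rfind("[")
        if lb == -1:
            raise QueryParseError("']' without '['", pos + len(text) - 1)
        tag = text[lb + 1 : -1].strip().lower()
        field = _FIELD_ALIASES.get(tag)
        if field is None:
            raise QueryParseError(f"unknown field tag [{tag}]", pos + lb)
        text = text[:lb].strip()
        if not text:
            raise QueryParseError("field tag without a term", pos)

    truncated = False
    if text.endswith("*"):
        truncated = True
        text = text[:-1].strip()
        if not text:
            raise QueryParseError("'*' without a term", pos)

    if text[0] in _QUOTES_OPEN:
        if len(text) < 2 or text[-1] not in _QUOTES_CLOSE:
            raise QueryParseError("unbalanced quotes", pos)
        pattern = text[1:-1].strip()
        if not pattern:
            raise QueryParseError("empty quoted phrase", pos)
    else:
        if any(q in text for q in _QUOTES_OPEN + _QUOTES_CLOSE):
            raise QueryParseError("unbalanced quotes", pos)
        if " " in text:
            raise QueryParseError(
                f"unquoted multi-word term {text!r} (quote phrases)", pos
            )
        pattern = text

    return TermQuery(pattern.lower(), truncated, field)


def parse_query(text: str) -> Query:
    """Parse a query string such as ``"Patient Preference"[mesh] OR Preferen*[tiab]``.

    Case-insensitive; straight and curly quotes are both accepted; a field
    tag binds to the immediately preceding term only.
    """
    if not text or not text.strip():
        raise QueryParseError("empty query", 0)
    return Query(tuple(_parse_term(chunk, off) for off, chunk in _split_or(text)))


# --- matching ---------------------------------------------------------------


def _match_tokens(tokens: list[str], pattern: str, truncated: bool) -> bool:
    words = pattern.split()
    if len(words) == 1:
        if truncated:
            return any(t.startswith(pattern) for t in tokens)
        return pattern in tokens
    # phrase: consecutive token run; truncation applies to the last word
    n = len(words)
    for i in range(len(tokens) - n + 1):
        window = tokens[i : i + n]
        if window[:-1] == words[:-1]:
            last = window[-1]
            if last.startswith(words[-1]) if truncated else last == words[-1]:
                return True
    return False


def match_term(term: TermQuery, record: Record) -> bool:
    """Does one atomic term match one record?"""
    f = term.field
    if f in ("tiab", "ti"):
        text = record.title if f == "ti" else record.title + " " + record.abstract
        return _match_tokens(tokenize(text), term.pattern, term.truncated)
    if f == "mh":
        return any(h.matches(term.pattern, term.truncated) for h in record.mesh)
    if f == "majr":
        return any(
            h.is_major and h.matches(term.pattern, term.truncated) for h in record.mesh
        )
    if f == "sh":
        p = term.pattern
        for h in record.mesh:
            for s in h.subheadings:
                name = s.name.lower()
                if name.startswith(p) if term.truncated else name == p:
                    return True
        return False
    # tw / all: text word = tiab OR mh OR sh
    return (
        match_term(TermQuery(term.pattern, term.truncated, "tiab"), record)
        or match_term(TermQuery(term.pattern, term.truncated, "mh"), record)
        or match_term(TermQuery(term.pattern, term.truncated, "sh"), record)
    )


def evaluate(query: Query, corpus: LabeledCorpus) -> ConfusionMatrix:
    """Tally the confusion matrix of a query against a labeled corpus.

    A record is retrieved iff any term matches (OR semantics).
    """
    if len(corpus) == 0:
        raise ValueError("cannot evaluate against an empty corpus")
    a = b = c = d = 0
    for rec in corpus.records:
        hit = any(match_term(t, rec) for t in query.terms)
        rel = corpus.labels[rec.record_id]
        if hit:
            a, b = a + int(rel), b + int(not rel)
        else:
            c, d = c + int(rel), d + int(not rel)
    return ConfusionMatrix(a, b, c, d)


# --- indexed evaluation -----------------------------------------------------


class CorpusIndex:
    """Inverted index over one corpus for fast repeated query evaluation.

    Semantics are identical to :func:`match_term`/:func:`evaluate` (verified
    by equivalence tests); only the lookup strategy differs.  Intended for
    screening thousands of candidate single-term queries.
    """

    def __init__(self, corpus: LabeledCorpus):
        self.corpus = corpus
        self.n = len(corpus)
        self._labels = [corpus.labels[r.record_id] for r in corpus.records]
        self.n_relevant = sum(self._labels)

        self._doc_tokens: list[list[str]] = []
        tiab: dict[str, set[int]] = {}
        title: dict[str, set[int]] = {}
        mh: dict[str, set[int]] = {}
        majr: dict[str, set[int]] = {}
        sh: dict[str, set[int]] = {}
        for i, rec in enumerate(corpus.records):
            t_tokens = tokenize(rec.title)
            a_tokens = tokenize(rec.abstract)
            self._doc_tokens.append(t_tokens + a_tokens)
            for tok in t_tokens:
                title.setdefault(tok, set()).add(i)
            for tok in self._doc_tokens[-1]:
                tiab.setdefault(tok, set()).add(i)
            for h in rec.mesh:
                d = h.descriptor.lower()
                mh.setdefault(d, set()).add(i)
                if h.is_major:
                    majr.setdefault(d, set()).add(i)
                for s in h.subheadings:
                    sh.setdefault(s.name.lower(), set()).add(i)
        self._postings = {"tiab": tiab, "ti": title, "mh": mh, "majr": majr, "sh": sh}
        self._sorted_keys = {k: sorted(v) for k, v in self._postings.items()}

    def _field_docs(self, field: str, pattern: str, truncated: bool) -> set[int]:
        postings = self._postings[field]
        if " " in pattern and field in ("tiab", "ti"):
            return self._phrase_docs(field, pattern, truncated)
        if not truncated:
            return postings.get(pattern, set())
        keys = self._sorted_keys[field]
        lo = bisect_left(keys, pattern)
        out: set[int] = set()
        for j in range(lo, len(keys)):
            if not keys[j].startswith(pattern):
                break
            out |= postings[keys[j]]
        return out

    def _phrase_docs(self, field: str, pattern: str, truncated: bool) -> set[int]:
        first = pattern.split()[0]
        candidates = self._postings[field].get(first, set())
        out = set()
        for i in candidates:
            tokens = (
                self._doc_tokens[i]
                if field == "tiab"
                else tokenize(self.corpus.records[i].title)
            )
            if _match_tokens(tokens, pattern, truncated):
                out.add(i)
        return out

    def match_docs(self, term: TermQuery) -> set[int]:
        """Indices (into ``corpus.records``) of documents matching one term."""
        f = term.field
        if f in ("tiab", "ti", "mh", "majr", "sh"):
            return self._field_docs(f, term.pattern, term.truncated)
        return (
            self._field_docs("tiab", term.pattern, term.truncated)
            | self._field_docs("mh", term.pattern, term.truncated)
            | self._field_docs("sh", term.pattern, term.truncated)
        )

    def query_docs(self, query: Query) -> set[int]:
        docs: set[int] = set()
        for t in query.terms:
            docs |= self.match_docs(t)
        return docs

    def confusion(self, docs: Iterable[int]) -> ConfusionMatrix:
        docs = set(docs)
        a = sum(1 for i in docs if self._labels[i])
        b = len(docs) - a
        return ConfusionMatrix(a, b, self.n_relevant - a, self.n - self.n_relevant - b)

    def evaluate(self, query: Query) -> ConfusionMatrix:
        return self.confusion(self.query_docs(query))
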