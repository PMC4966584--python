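"""Citation data model, MEDLINE flat-file I/O, eligibility filtering and labels.

The unit of analysis is one MEDLINE citation (:class:`Record`); a corpus with
a binary relevance label per record (:class:`LabeledCorpus`) is the universe
every search filter is evaluated against.  Records are read from and written
to the NLM MEDLINE flat-file dialect (``PMID``, ``TI``, ``AB``, ``MH``,
``TA``, ``JT``, ``DP``, ``PT``, ``LA`` tags; ``MH`` values carry a leading
``*`` for the major-topic flag and ``/`` to attach subheadings, which may be
major-flagged themselves).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Subheading",
    "MeshHeading",
    "Record",
    "LabeledCorpus",
    "MedlineParseError",
    "read_medline",
    "write_medline",
    "filter_eligible",
    "attach_labels",
    "read_labels",
]


class MedlineParseError(ValueError):
    """Raised for a malformed MEDLINE line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class Subheading:
    """A MeSH subheading attached to a descriptor, with its major-topic flag."""

    name: str
    is_major: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("subheading name must be non-empty")


@dataclass(frozen=True)
class MeshHeading:
    """One MeSH descriptor on a record.

    Descriptor comparison is case-insensitive throughout the package;
    the stored string keeps its original case for faithful round-trips.
    """

    descriptor: str
    is_major: bool = False
    subheadings: tuple[Subheading, ...] = ()

    def __post_init__(self) -> None:
        if not self.descriptor:
            raise ValueError("descriptor must be non-empty")

    def matches(self, pattern: str, truncated: bool = False) -> bool:
        d = self.descriptor.lower()
        p = pattern.lower()
        return d.startswith(p) if truncated else d == p


@dataclass
class Record:
    """One citation: the unit that was hand-screened for relevance."""

    record_id: str
    title: str
    journal: str = ""
    year: int = 0
    language: str = "eng"
    pub_types: list[str] = field(default_factory=list)
    abstract: str = ""
    mesh: list[MeshHeading] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.title:
            raise ValueError("title must be non-empty")


@dataclass
class LabeledCorpus:
    """A set of records plus a relevance label per record id."""

    records: list[Record]
    labels: dict[str, bool]

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("record_id values must be unique within a corpus")
        missing = set(self.labels) - set(ids)
        if missing:
            raise ValueError(f"labels refer to unknown record ids: {sorted(missing)[:5]}")
        unlabeled = set(ids) - set(self.labels)
        if unlabeled:
            raise ValueError(f"records without labels: {sorted(unlabeled)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def relevant_ids(self) -> set[str]:
        return {rid for rid, rel in self.labels.items() if rel}

    @property
    def n_relevant(self) -> int:
        return sum(self.labels.values())

    def subset(self, ids: Iterable[str]) -> "LabeledCorpus":
        ids = set(ids)
        return LabeledCorpus(
            records=[r for r in self.records if r.record_id in ids],
            labels={i: self.labels[i] for i in ids},
        )


# --- MEDLINE flat-file I/O -------------------------------------------------

# Canonical NLM form is "TAG - value" with the tag padded to four columns;
# the colon dialect ("TAG: value") produced by some exporters is accepted too.
_TAG_DASH_RE = re.compile(r"^([A-Z][A-Z0-9]{1,3})\s*-\s?(.*)$")
_TAG_COLON_RE = re.compile(r"^([A-Z][A-Z0-9]{1,3}):\s?(.*)$")
_YEAR_RE = re.compile(r"\b(\d{4})\b")


def _parse_mesh(value: str) -> MeshHeading:
    parts = value.split("/")
    desc = parts[0].strip()
    is_major = desc.startswith("*")
    if is_major:
        desc = desc[1:]
    subs = []
    for raw in parts[1:]:
        raw = raw.strip()
        if not raw:
            continue
        sub_major = raw.startswith("*")
        subs.append(Subheading(raw[1:] if sub_major else raw, sub_major))
    return MeshHeading(desc, is_major, tuple(subs))


def _finish_record(fields: dict[str, list[str]], line_number: int) -> Record | None:
    if not fields:
        return None
    if "PMID" not in fields:
        logger.warning("record ending at line %d has no PMID; skipped", line_number)
        return None
    year = 0
    if fields.get("DP"):
        m = _YEAR_RE.search(fields["DP"][0])
        if m:
            year = int(m.group(1))
    journal = fields.get("TA", fields.get("JT", [""]))[0]
    return Record(
        record_id=fields["PMID"][0],
        title=" ".join(fields.get("TI", ["(no title)"])) or "(no title)",
        journal=journal,
        year=year,
        language=fields.get("LA", ["eng"])[0],
        pub_types=fields.get("PT", []),
        abstract=" ".join(fields.get("AB", [])),
        mesh=[_parse_mesh(v) for v in fields.get("MH", [])],
    )


def read_medline(stream: TextIO) -> list[Record]:
    """Parse a MEDLINE flat-file stream into records.

    Citation blocks are separated by blank lines; continuation lines are
    indented.  A malformed tag line raises :class:`MedlineParseError` with
    its line number; a block lacking a PMID is skipped with a warning.
    """
    records: list[Record] = []
    fields: dict[str, list[str]] = {}
    last_tag: str | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            rec = _finish_record(fields, lineno)
            if rec is not None:
                records.append(rec)
            fields, last_tag = {}, None
            continue
        if line[0].isspace():
            if last_tag is None:
                raise MedlineParseError("continuation line before any tag", lineno)
            fields[last_tag][-1] += " " + line.strip()
            continue
        m = _TAG_DASH_RE.match(line) or _TAG_COLON_RE.match(line)
        if m is None:
            raise MedlineParseError(f"unrecognized tag line: {line!r}", lineno)
        tag, value = m.group(1), m.group(2)
        fields.setdefault(tag, []).append(value)
        last_tag = tag
    rec = _finish_record(fields, lineno if fields else 0)
    if rec is not None:
        records.append(rec)
    return records


def _format_mesh(h: MeshHeading) -> str:
    out = ("*" if h.is_major else "") + h.descriptor
    for s in h.subheadings:
        out += "/" + ("*" if s.is_major else "") + s.name
    return out


def write_medline(records: Iterable[Record], stream: TextIO) -> None:
    """Write records in canonical NLM two-space/dash form; round-trips exactly."""

    def emit(tag: str, value: str) -> None:
        stream.write(f"{tag:<4}- {value}\n")

    for rec in records:
        emit("PMID", rec.record_id)
        if rec.year:
            emit("DP", str(rec.year))
        emit("TI", rec.title)
        if rec.abstract:
            emit("AB", rec.abstract)
        if rec.journal:
            emit("TA", rec.journal)
        emit("LA", rec.language)
        for pt in rec.pub_types:
            emit("PT", pt)
        for h in rec.mesh:
            emit("MH", _format_mesh(h))
        stream.write("\n")


# --- Eligibility and labels -------------------------------------------------

DEFAULT_EXCLUDED_TYPES = ("Comment", "News", "Editorial", "Clinical Trial Protocol")


def filter_eligible(
    records: Iterable[Record],
    year: int = 2011,
    language: str = "eng",
    excluded_types: Iterable[str] = DEFAULT_EXCLUDED_TYPES,
) -> list[Record]:
    """Keep records from one publication year and language, dropping excluded
    publication types (comments, news, editorials, study protocols by default).
    Order is preserved; the operation is idempotent."""
    excluded = {t.lower() for t in excluded_types}
    return [
        r
        for r in records
        if r.year == year
        and r.language.lower() == language.lower()
        and not any(pt.lower() in excluded for pt in r.pub_types)
    ]


def attach_labels(
    records: list[Record],
    labels: "pd.DataFrame | Mapping[str, bool] | Iterable[tuple[str, bool]]",
) -> LabeledCorpus:
    """Attach relevance labels to records, defaulting unlabeled records to
    not-relevant (anything not selected by the hand-search is a true negative).

    Raises ``ValueError`` listing orphan ids if a label refers to a record
    that does not exist.
    """
    if isinstance(labels, pd.DataFrame):
        pairs = list(zip(labels["record_id"].astype(str), labels["relevant"].astype(int)))
    elif isinstance(labels, Mapping):
        pairs = list(labels.items())
    else:
        pairs = list(labels)
    ids = {r.record_id for r in records}
    label_map = {str(rid): bool(rel) for rid, rel in pairs}
    orphans = sorted(set(label_map) - ids)
    if orphans:
        raise ValueError(f"label ids not present in records: {orphans}")
    full = {r.record_id: label_map.get(r.record_id, False) for r in records}
    corpus = LabeledCorpus(records=records, labels=full)
    logger.info(
        "attached labels: %d records, %d relevant", len(corpus), corpus.n_relevant
    )
    return corpus


def read_labels(path) -> pd.DataFrame:
    """Read a label table CSV with columns record_id, journal, relevant."""
    df = pd.read_csv(path, dtype={"record_id": str})
    if "record_id" not in df.columns or "relevant" not in df.columns:
        raise ValueError("label CSV must have columns record_id,journal,relevant")
    return df
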