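"""Synthetic labeled MEDLINE-like corpora with planted discriminative terms.

Real hand-search reference corpora cannot be redistributed, so every stage of
the pipeline is exercised on generated corpora that reproduce the statistical
structure the analysis assumes: a low relevance prevalence (22/8238 by
default) spread over ~27 journals, title/abstract token streams drawn from a
Zipf-like background vocabulary, MeSH descriptors with major-topic flags and
subheadings, and planted term signals whose per-class occurrence rates mirror
the sensitivity/specificity contrasts of published single-term filters (e.g.
a token family present in 75 % of relevant vs 2.8 % of non-relevant records).

The generator records ground truth (which documents actually received each
planted signal), enabling parameter-recovery tests: mining + screening must
rediscover the planted family as the best sensitivity-ranked single term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .corpus_model import (
    LabeledCorpus,
    MeshHeading,
    Record,
    Subheading,
    attach_labels,
    read_labels,
    read_medline,
    write_medline,
)

__all__ = [
    "JournalSpec",
    "PlantedTerm",
    "CorpusSpec",
    "GroundTruth",
    "reference_default",
    "load_spec",
    "reference_journal_table",
    "generate_corpus",
    "write_fixture",
    "read_fixture",
]


@dataclass(frozen=True)
class JournalSpec:
    name: str
    total: int
    relevant: int | None = None  # exact relevant count; None = draw from prevalence

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValueError("journal total must be >= 1")


@dataclass(frozen=True)
class PlantedTerm:
    """A discriminative signal planted per class at fixed Bernoulli rates.

    ``tiab`` signals insert one of ``variants`` (morphological forms sharing
    the ``pattern`` prefix, to exercise truncation mining) into the abstract;
    ``mesh`` signals attach ``pattern`` as a MeSH descriptor.
    """

    pattern: str
    field_class: str  # "tiab" or "mesh"
    rate_relevant: float
    rate_irrelevant: float
    variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.field_class not in ("tiab", "mesh"):
            raise ValueError("field_class must be 'tiab' or 'mesh'")
        for r in (self.rate_relevant, self.rate_irrelevant):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def forms(self) -> tuple[str, ...]:
        return self.variants if self.variants else (self.pattern,)


@dataclass
class CorpusSpec:
    journals: list[JournalSpec]
    prevalence: float = 22 / 8238
    exact_counts: bool = True
    planted_terms: list[PlantedTerm] = field(default_factory=list)
    vocab_size: int = 5000
    tokens_per_abstract: int = 150
    tokens_per_title: int = 10
    mesh_per_record: int = 10
    zipf_exponent: float = 1.1
    year: int = 2011
    language: str = "eng"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")

    @property
    def total(self) -> int:
        return sum(j.total for j in self.journals)


@dataclass
class GroundTruth:
    """Realized planted-term document counts per class, recountable from the
    emitted corpus, plus the realized relevant record ids."""

    planted: list[dict]
    relevant_ids: list[str]


def _spec_from_mapping(cfg: dict) -> CorpusSpec:
    journals = [
        JournalSpec(
            name=j["name"],
            total=int(j.get("total", j.get("dev_total", 0) + j.get("val_total", 0))),
            relevant=(
                j.get("relevant")
                if "relevant" in j
                else j.get("dev_relevant", 0) + j.get("val_relevant", 0)
            ),
        )
        for j in cfg["journals"]
    ]
    planted = [
        PlantedTerm(
            pattern=p["pattern"],
            field_class=p["field_class"],
            rate_relevant=float(p["rate_relevant"]),
            rate_irrelevant=float(p["rate_irrelevant"]),
            variants=tuple(p.get("variants", ())),
        )
        for p in cfg.get("planted_terms", [])
    ]
    kwargs = {
        k: cfg[k]
        for k in (
            "prevalence",
            "exact_counts",
            "vocab_size",
            "tokens_per_abstract",
            "tokens_per_title",
            "mesh_per_record",
            "zipf_exponent",
            "year",
            "language",
            "seed",
        )
        if k in cfg
    }
    return CorpusSpec(journals=journals, planted_terms=planted, **kwargs)


def load_spec(path) -> CorpusSpec:
    """Load a corpus specification from a YAML file."""
    with open(path) as fh:
        return _spec_from_mapping(yaml.safe_load(fh))


def _default_cfg() -> dict:
    raw = resources.files("filterforge.data").joinpath("reference_default.yaml").read_text()
    return yaml.safe_load(raw)


def reference_default(seed: int = 0) -> CorpusSpec:
    """The shipped default: 8238 records over 27 journals, 22 relevant,
    with the two anchored planted signals."""
    spec = _spec_from_mapping(_default_cfg())
    spec.seed = seed
    return spec


def reference_journal_table() -> pd.DataFrame:
    """The per-journal development/validation reference table that the
    default specification is built from, with a Total row."""
    rows = [
        {
            "journal": j["name"],
            "dev_total": j["dev_total"],
            "dev_relevant": j["dev_relevant"],
            "val_total": j["val_total"],
            "val_relevant": j["val_relevant"],
        }
        for j in _default_cfg()["journals"]
    ]
    df = pd.DataFrame(rows)
    total = {"journal": "Total"}
    for col in df.columns[1:]:
        total[col] = int(df[col].sum())
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


# --- generation -------------------------------------------------------------

_SUBHEADING_POOL = (
    "psychology", "methods", "therapy", "diagnosis", "economics", "standards",
    "statistics and numerical data", "trends", "ethics", "organization and administration",
)


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    p = ranks ** -exponent
    return p / p.sum()


def generate_corpus(spec: CorpusSpec) -> tuple[LabeledCorpus, GroundTruth]:
    """Generate a labeled corpus per the corpus specification; deterministic for a
    fixed seed.

    Background title/abstract tokens are drawn from a Zipf-like distribution
    over a synthetic vocabulary; planted patterns must not collide with that
    vocabulary (or the background MeSH pool), otherwise ground truth would be
    contaminated and a ``ValueError`` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.total

    vocab = np.array([f"v{i:04d}" for i in range(spec.vocab_size)])
    mesh_pool = np.array([f"Descriptor {i:03d}" for i in range(1500)])
    vocab_set = {v.lower() for v in vocab}
    mesh_set = {m.lower() for m in mesh_pool}
    for t in spec.planted_terms:
        for form in t.forms:
            if t.field_class == "tiab" and form.lower() in vocab_set:
                raise ValueError(f"planted pattern {form!r} collides with background vocabulary")
            if t.field_class == "mesh" and form.lower() in mesh_set:
                raise ValueError(f"planted descriptor {form!r} collides with background MeSH pool")

    # relevance labels
    journal_of = np.empty(n, dtype=object)
    relevant = np.zeros(n, dtype=bool)
    start = 0
    for j in spec.journals:
        end = start + j.total
        journal_of[start:end] = j.name
        if spec.exact_counts:
            k = j.relevant
            if k is None:
                k = int(round(spec.prevalence * j.total))
            if k > j.total:
                raise ValueError(f"journal {j.name!r}: relevant exceeds total")
            idx = rng.choice(j.total, size=k, replace=False)
            relevant[start + idx] = True
        else:
            relevant[start:end] = rng.random(j.total) < spec.prevalence
        start = end

    probs = _zipf_probs(spec.vocab_size, spec.zipf_exponent)
    title_tok = rng.choice(spec.vocab_size, size=(n, spec.tokens_per_title), p=probs)
    abstr_tok = rng.choice(spec.vocab_size, size=(n, spec.tokens_per_abstract), p=probs)
    mesh_idx = rng.choice(1500, size=(n, spec.mesh_per_record), p=_zipf_probs(1500, spec.zipf_exponent))
    mesh_major = rng.random((n, spec.mesh_per_record)) < 0.3
    mesh_sub = rng.random((n, spec.mesh_per_record)) < 0.4
    sub_choice = rng.integers(0, len(_SUBHEADING_POOL), size=(n, spec.mesh_per_record))
    sub_major = rng.random((n, spec.mesh_per_record)) < 0.2

    # planted signals
    plant_hits: list[np.ndarray] = []
    plant_variant: list[np.ndarray] = []
    for t in spec.planted_terms:
        rates = np.where(relevant, t.rate_relevant, t.rate_irrelevant)
        hits = rng.random(n) < rates
        plant_hits.append(hits)
        plant_variant.append(rng.integers(0, len(t.forms), size=n))

    records: list[Record] = []
    labels: dict[str, bool] = {}
    for i in range(n):
        rid = f"{9000000 + i}"
        title = " ".join(vocab[title_tok[i]])
        ab_words = list(vocab[abstr_tok[i]])
        mesh: list[MeshHeading] = []
        seen_desc: set[int] = set()
        for m in range(spec.mesh_per_record):
            di = int(mesh_idx[i, m])
            if di in seen_desc:
                continue
            seen_desc.add(di)
            subs = ()
            if mesh_sub[i, m]:
                subs = (
                    Subheading(
                        _SUBHEADING_POOL[int(sub_choice[i, m])],
                        bool(sub_major[i, m]),
                    ),
                )
            mesh.append(MeshHeading(str(mesh_pool[di]), bool(mesh_major[i, m]), subs))
        for t_idx, t in enumerate(spec.planted_terms):
            if not plant_hits[t_idx][i]:
                continue
            form = t.forms[int(plant_variant[t_idx][i])]
            if t.field_class == "tiab":
                pos = int((title_tok[i, 0] + i) % (len(ab_words) + 1))
                ab_words.insert(pos, form)
            else:
                mesh.append(MeshHeading(form, True, (Subheading("psychology", False),)))
        records.append(
            Record(
                record_id=rid,
                title=title,
                journal=str(journal_of[i]),
                year=spec.year,
                language=spec.language,
                pub_types=["Journal Article"],
                abstract=" ".join(ab_words),
                mesh=mesh,
            )
        )
        labels[rid] = bool(relevant[i])

    truth = GroundTruth(
        planted=[
            {
                "pattern": t.pattern,
                "field_class": t.field_class,
                "rate_relevant": t.rate_relevant,
                "rate_irrelevant": t.rate_irrelevant,
                "variants": list(t.forms),
                "relevant_docs": int(np.count_nonzero(plant_hits[k] & relevant)),
                "irrelevant_docs": int(np.count_nonzero(plant_hits[k] & ~relevant)),
            }
            for k, t in enumerate(spec.planted_terms)
        ],
        relevant_ids=[records[i].record_id for i in np.flatnonzero(relevant)],
    )
    return LabeledCorpus(records=records, labels=labels), truth


# --- fixture I/O ------------------------------------------------------------


def write_fixture(corpus: LabeledCorpus, truth: GroundTruth, directory) -> None:
    """Write corpus.nbib, labels.csv and truth.json; byte-stable for a fixed
    corpus and re-readable via :func:`read_fixture`."""
    if len(corpus) == 0:
        raise ValueError("refusing to write an empty corpus fixture")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "corpus.nbib", "w") as fh:
        write_medline(corpus.records, fh)
    pd.DataFrame(
        {
            "record_id": [r.record_id for r in corpus.records],
            "journal": [r.journal for r in corpus.records],
            "relevant": [int(corpus.labels[r.record_id]) for r in corpus.records],
        }
    ).to_csv(directory / "labels.csv", index=False)
    with open(directory / "truth.json", "w") as fh:
        json.dump(
            {"planted": truth.planted, "relevant_ids": truth.relevant_ids},
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")


def read_fixture(directory) -> LabeledCorpus:
    """Read a fixture directory back into a labeled corpus."""
    directory = Path(directory)
    with open(directory / "corpus.nbib") as fh:
        records = read_medline(fh)
    labels = read_labels(directory / "labels.csv")
    return attach_labels(records, labels)
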