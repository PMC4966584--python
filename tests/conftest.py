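"""Shared fixtures: small hand-built corpora and a randomized corpus factory.

Everything is generated programmatically; no stored data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from filterforge.corpus_model import LabeledCorpus, MeshHeading, Record, Subheading

# small real-word vocabulary so mined keywords look like titles/abstracts
WORDS = [
    "patient", "preference", "preferences", "preferred", "treatment", "outcome",
    "outcomes", "trial", "randomized", "survey", "interview", "questionnaire",
    "adherence", "adherent", "choice", "choices", "elicit", "elicited", "logit",
    "regression", "cancer", "diabetes", "therapy", "clinical", "decision",
    "analysis", "health", "quality", "risk", "benefit", "cohort", "study",
]

MESH_POOL = [
    "Patient Preference", "Patient Satisfaction", "Choice Behavior",
    "Middle Aged", "Decision Making", "Humans", "Treatment Outcome",
    "Quality of Life", "Logistic Models",
]

SUBHEADINGS = ["psychology", "therapy", "methods", "economics"]


def make_record(rng: np.random.Generator, record_id: str, journal: str = "J1") -> Record:
    n_title = int(rng.integers(3, 8))
    n_abs = int(rng.integers(0, 25))
    mesh = []
    for d in rng.choice(len(MESH_POOL), size=int(rng.integers(0, 4)), replace=False):
        subs = ()
        if rng.random() < 0.5:
            subs = (
                Subheading(
                    SUBHEADINGS[int(rng.integers(0, len(SUBHEADINGS)))],
                    bool(rng.random() < 0.3),
                ),
            )
        mesh.append(MeshHeading(MESH_POOL[int(d)], bool(rng.random() < 0.4), subs))
    return Record(
        record_id=record_id,
        title=" ".join(np.random.default_rng(rng.integers(2**31)).choice(WORDS, n_title)),
        journal=journal,
        year=int(rng.choice([2010, 2011, 2012], p=[0.1, 0.8, 0.1])),
        language=str(rng.choice(["eng", "fre"], p=[0.9, 0.1])),
        pub_types=[str(rng.choice(["Journal Article", "Editorial", "Comment"], p=[0.8, 0.1, 0.1]))],
        abstract=" ".join(rng.choice(WORDS, n_abs)) if n_abs else "",
        mesh=mesh,
    )


def make_corpus(
    seed: int,
    n_records: int = 20,
    n_relevant: int = 4,
    n_journals: int = 3,
) -> LabeledCorpus:
    rng = np.random.default_rng(seed)
    records = [
        make_record(rng, f"r{i:04d}", journal=f"J{i % n_journals}")
        for i in range(n_records)
    ]
    rel = rng.choice(n_records, size=min(n_relevant, n_records), replace=False)
    labels = {r.record_id: (i in rel) for i, r in enumerate(records)}
    return LabeledCorpus(records=records, labels=labels)


@pytest.fixture
def small_corpus() -> LabeledCorpus:
    return make_corpus(seed=7, n_records=20, n_relevant=4)


@pytest.fixture
def corpus_factory():
    return make_corpus
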