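"""1:1 randomization of a labeled corpus into development and validation sets.

The split is stratified by journal: within each journal the relevant records
are divided as evenly as possible (difference at most one, with a coin flip
deciding which half receives the extra record when the count is odd), while
non-relevant records are allocated by independent fair draws.  Journal totals
are therefore close to, but not forced exactly, equal — reproducing what a
simple 1:1 randomization of journal table-of-contents listings yields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_model import LabeledCorpus

__all__ = ["SplitResult", "stratified_split", "split_summary"]


@dataclass
class SplitResult:
    development: LabeledCorpus
    validation: LabeledCorpus
    seed: int


def stratified_split(corpus: LabeledCorpus, seed: int) -> SplitResult:
    """Randomize a labeled corpus 1:1 into development and validation halves.

    Deterministic for a fixed seed.  Within every journal the number of
    relevant records on each side differs by at most one.
    """
    if len(corpus) == 0:
        raise ValueError("cannot split an empty corpus")
    rng = np.random.default_rng(seed)

    by_journal: dict[str, list[str]] = {}
    for rec in corpus.records:
        by_journal.setdefault(rec.journal, []).append(rec.record_id)

    dev_ids: set[str] = set()
    for journal in sorted(by_journal):
        ids = by_journal[journal]
        relevant = [i for i in ids if corpus.labels[i]]
        other = [i for i in ids if not corpus.labels[i]]
        rng.shuffle(relevant)
        n_dev = len(relevant) // 2
        if len(relevant) % 2 == 1 and rng.random() < 0.5:
            n_dev += 1
        dev_ids.update(relevant[:n_dev])
        draws = rng.random(len(other)) < 0.5
        dev_ids.update(i for i, d in zip(other, draws) if d)

    val_ids = {r.record_id for r in corpus.records} - dev_ids
    return SplitResult(
        development=corpus.subset(dev_ids),
        validation=corpus.subset(val_ids),
        seed=seed,
    )


def split_summary(split: SplitResult) -> pd.DataFrame:
    """Per-journal totals and relevant counts for each half, plus a Total row."""
    rows = []
    journals = sorted(
        {r.journal for r in split.development.records}
        | {r.journal for r in split.validation.records}
    )
    for journal in journals:
        row = {"journal": journal}
        for name, corpus in (("dev", split.development), ("val", split.validation)):
            ids = [r.record_id for r in corpus.records if r.journal == journal]
            row[f"{name}_total"] = len(ids)
            row[f"{name}_relevant"] = sum(corpus.labels[i] for i in ids)
        rows.append(row)
    df = pd.DataFrame(rows)
    total = {"journal": "Total"}
    for col in ("dev_total", "dev_relevant", "val_total", "val_relevant"):
        total[col] = int(df[col].sum())
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
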