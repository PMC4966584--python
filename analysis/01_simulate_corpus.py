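"""Generate the default synthetic hand-search corpus.

Emits an 8238-record labeled MEDLINE-like corpus over 27 journals with 22
relevant articles (prevalence 0.27 %) and two planted signals — a
title/abstract token family present in 75 % of relevant vs 2.8 % of
non-relevant records, and a MeSH descriptor at 50 % vs 0.7 % — then writes
the fixture (corpus.nbib, labels.csv, truth.json) under scratch/fixture/
(large regenerable data stays out of version control; summary tables go to
results/).

Usage: python analysis/01_simulate_corpus.py [--seed 1]
"""

import argparse
from pathlib import Path

from filterforge.synthetic_data import generate_corpus, reference_default, write_fixture

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    corpus, truth = generate_corpus(reference_default(seed=args.seed))
    out = SCRATCH / "fixture"
    write_fixture(corpus, truth, out)
    print(f"wrote {len(corpus)} records, {corpus.n_relevant} relevant -> {out}")
    for p in truth.planted:
        print(
            f"  planted {p['field_class']} signal {p['pattern']!r}: "
            f"{p['relevant_docs']}/{corpus.n_relevant} relevant, "
            f"{p['irrelevant_docs']} non-relevant docs"
        )


if __name__ == "__main__":
    main()
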