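"""Randomize the corpus 1:1 into development and validation sets.

The split is stratified by journal with relevant articles balanced (per
journal the two halves differ by at most one relevant record).  Writes both
halves as fixtures plus a per-journal summary table under results/.

Usage: python analysis/02_split_corpus.py [--seed 1]
"""

import argparse
from pathlib import Path

from filterforge.splitter import split_summary, stratified_split
from filterforge.synthetic_data import GroundTruth, read_fixture, write_fixture

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    corpus = read_fixture(SCRATCH / "fixture")
    split = stratified_split(corpus, seed=args.seed)
    for corp, name in ((split.development, "dev"), (split.validation, "val")):
        write_fixture(
            corp,
            GroundTruth(planted=[], relevant_ids=sorted(corp.relevant_ids)),
            SCRATCH / name,
        )
    summary = split_summary(split)
    summary.to_csv(RESULTS / "split_summary.csv", index=False)
    total = summary.iloc[-1]
    print(summary.to_string(index=False))
    print(
        f"\ndevelopment: {total.dev_total} records ({total.dev_relevant} relevant); "
        f"validation: {total.val_total} ({total.val_relevant} relevant)"
    )


if __name__ == "__main__":
    main()
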