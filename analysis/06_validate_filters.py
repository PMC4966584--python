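"""Internal validation: apply the development-selected filters to the
held-out validation set.

Re-evaluates each ranked filter on both halves, reports paired
development/validation performance with 95 % Wald CIs, and summarizes the
sensitivity drop from development to validation (the overfitting signature
expected when only ~10 relevant records are available per half).  Writes
results/validation_report.csv.

Usage: python analysis/06_validate_filters.py
"""

from pathlib import Path

from filterforge.filter_search import OBJECTIVES, grow_combinations, screen_singles
from filterforge.query_engine import CorpusIndex
from filterforge.synthetic_data import read_fixture
from filterforge.term_miner import add_truncations, generate_candidates, mine_terms
from filterforge.validation_report import render_report, report_frame, validate_filters

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    dev = read_fixture(SCRATCH / "dev")
    val = read_fixture(SCRATCH / "val")
    table = add_truncations(mine_terms(dev), min_prefix=5)
    index = CorpusIndex(dev)
    survivors = screen_singles(generate_candidates(table), dev, index=index)
    seeds = [q for q, _ in survivors]

    frames = []
    worst_se_drop = 0.0
    for obj in OBJECTIVES:
        ranked = grow_combinations(seeds, dev, objective=obj, index=index)
        report = validate_filters(ranked, dev, val)
        print(render_report(report, "text-table"))
        frames.append(report_frame(report))
        for drop in report.drops:
            worst_se_drop = min(worst_se_drop, drop["se"])

    import pandas as pd

    pd.concat(frames, ignore_index=True).to_csv(
        RESULTS / "validation_report.csv", index=False, float_format="%.6f"
    )
    print(f"largest sensitivity drop dev->val: {worst_se_drop:+.1f} percentage points")
    print(f"wrote results/validation_report.csv")


if __name__ == "__main__":
    main()
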