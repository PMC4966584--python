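"""Grow OR-combination filters from the screened single terms.

For each objective (sensitivity, specificity, accuracy, NNR) the survivors
are combined pairwise, pruned against the combination thresholds
(Sp >= 75 %, Se >= 50 %, Ac >= 75 %), and expanded greedily while the
objective strictly improves.  Writes the top-3 per objective to
results/ranked_filters.csv.

Usage: python analysis/05_build_filters.py
"""

from pathlib import Path

import pandas as pd

from filterforge.filter_search import OBJECTIVES, grow_combinations, screen_singles
from filterforge.query_engine import CorpusIndex
from filterforge.synthetic_data import read_fixture
from filterforge.term_miner import add_truncations, generate_candidates, mine_terms

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    dev = read_fixture(SCRATCH / "dev")
    table = add_truncations(mine_terms(dev), min_prefix=5)
    index = CorpusIndex(dev)
    survivors = screen_singles(generate_candidates(table), dev, index=index)
    seeds = [q for q, _ in survivors]

    rows = []
    for obj in OBJECTIVES:
        ranked = grow_combinations(seeds, dev, objective=obj, index=index)
        print(f"\nbest {obj.measure} combinations:")
        for rank_i, (q, e) in enumerate(ranked.rows, start=1):
            nnr = f"{e.nnr:.1f}" if e.nnr is not None else "—"
            print(f"  {rank_i}. {str(q):50} Se {e.se:5.1f}  Sp {e.sp:5.1f}  "
                  f"Ac {e.ac:5.1f}  NNR {nnr}")
            rows.append(
                {"objective": obj.measure, "rank": rank_i, "query": str(q),
                 "se": e.se, "sp": e.sp, "ac": e.ac, "nnr": e.nnr}
            )
    pd.DataFrame(rows).to_csv(RESULTS / "ranked_filters.csv", index=False)
    print(f"\nwrote {len(rows)} ranked filters -> {RESULTS / 'ranked_filters.csv'}")


if __name__ == "__main__":
    main()
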