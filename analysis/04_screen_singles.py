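"""Screen every candidate single-term query on the development set.

Keeps terms with sensitivity >= 25 % and specificity >= 75 % and writes the
survivors, ranked by sensitivity, to results/singles.csv; prints the top
rows per performance measure (the single-term analogue of a published
best-terms table).

Usage: python analysis/04_screen_singles.py
"""

from pathlib import Path

import pandas as pd

from filterforge.filter_search import OBJECTIVES, rank, screen_singles
from filterforge.query_engine import CorpusIndex
from filterforge.synthetic_data import read_fixture
from filterforge.term_miner import add_truncations, generate_candidates, mine_terms

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    dev = read_fixture(SCRATCH / "dev")
    table = add_truncations(mine_terms(dev), min_prefix=5)
    candidates = generate_candidates(table)
    index = CorpusIndex(dev)
    survivors = screen_singles(candidates, dev, index=index)
    print(f"{len(candidates)} candidates screened; {len(survivors)} survive "
          "(Se >= 25 %, Sp >= 75 %)")

    rows = [
        {"query": str(q), "se": e.se, "sp": e.sp, "ac": e.ac, "nnr": e.nnr}
        for q, e in survivors
    ]
    pd.DataFrame(rows).sort_values("se", ascending=False).to_csv(
        RESULTS / "singles.csv", index=False
    )
    for obj in OBJECTIVES:
        best = rank(survivors, obj, top_k=3)
        print(f"\nbest {obj.measure}:")
        for q, e in best.rows:
            nnr = f"{e.nnr:.1f}" if e.nnr is not None else "—"
            print(f"  {str(q):32} Se {e.se:5.1f}  Sp {e.sp:5.1f}  Ac {e.ac:5.1f}  NNR {nnr}")


if __name__ == "__main__":
    main()
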