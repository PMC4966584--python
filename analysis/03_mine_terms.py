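"""Mine candidate search terms from the relevant development records.

Tabulates keywords (length >= 3, stop words removed), MeSH descriptors and
subheadings with document frequencies, adds truncated forms for morphological
variant clusters, and expands everything into candidate single-term queries
(six field variants per keyword plus one [mesh] query per descriptor).
Writes results/terms.csv.

Usage: python analysis/03_mine_terms.py
"""

from pathlib import Path

from filterforge.synthetic_data import read_fixture
from filterforge.term_miner import add_truncations, generate_candidates, mine_terms

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    dev = read_fixture(SCRATCH / "dev")
    table = add_truncations(mine_terms(dev), min_prefix=5)
    table.to_frame().to_csv(RESULTS / "terms.csv", index=False)
    candidates = generate_candidates(table)
    k = len(table.keywords())
    m = len(table.mesh_descriptors())
    print(
        f"mined {k} keywords and {m} MeSH descriptors from "
        f"{dev.n_relevant} relevant development records"
    )
    print(f"candidate single-term queries: 6*{k} + {m} = {len(candidates)}")
    top = sorted(table.entries, key=lambda e: -e.doc_frequency)[:10]
    print("most frequent terms:")
    for e in top:
        print(f"  {e.term!r:30} {e.term_class:16} df={e.doc_frequency}")


if __name__ == "__main__":
    main()
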