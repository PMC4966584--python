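# filterforge

Development and internal validation of boolean **literature search filters**
(search hedges) over labeled MEDLINE corpora.

## The problem

Finding the handful of papers that report empirical evidence on a narrow
question — here, patients' preferences for *treatment outcomes* — inside a
bibliographic database is a needle-in-haystack task: in a hand-search of
27 general-medical journals, only 22 of 8238 articles (0.27 %) qualified.
A *search filter* is a pre-tested boolean query that retrieves such a class
of studies efficiently. This package implements the standard workflow for
deriving and validating one:

1. **Reference set** — a hand-screened, labeled corpus of citations
   (title, abstract, MeSH headings, journal, publication types), read from
   MEDLINE flat files or generated synthetically.
2. **Split** — 1:1 randomization into a development and a validation set,
   stratified by journal with relevant articles balanced (per journal the
   halves differ by at most one relevant record).
3. **Term mining** — PubReMiner-style tabulation of keywords and MeSH terms
   from the relevant development records, expanded into candidate queries:
   each keyword with and without the `[tw]`, `[tiab]`, `[majr]`, `[sh]` and
   `[mh]` field tags (so K keywords and M MeSH terms give 6·K + M candidate
   single-term searches).
4. **Screening and combination** — every candidate is scored against the
   development set via its confusion matrix (A = true positives, B = false
   positives, C = false negatives, D = true negatives):

   | measure | formula |
   |---|---|
   | sensitivity | Se = A/(A+C) |
   | specificity | Sp = D/(B+D) |
   | accuracy | Ac = (A+D)/(A+B+C+D) |
   | number needed to read | NNR = (A+B)/A |

   Terms with Se ≥ 25 % and Sp ≥ 75 % survive; survivors are OR-combined,
   pairs failing Sp ≥ 75 %, Se ≥ 50 % or Ac ≥ 75 % are pruned, and
   combinations grow greedily while the chosen objective strictly improves.
   The top filters per objective (best Se, best Sp, best Ac, lowest NNR)
   are reported with 95 % Wald confidence intervals.
5. **Internal validation** — the selected filters are re-evaluated on the
   held-out validation set and dev→val performance drops are reported.

Intended users: information specialists and methods researchers studying
search-filter performance, and anyone needing a reproducible, offline
evaluation harness for PubMed-style queries against a labeled corpus.

## Worked example

The library ships a synthetic-corpus generator whose default specification
emulates the reference universe: 8238 records over 27 journals, 22 relevant,
with a planted title/abstract token family (present in 75 % of relevant vs
2.8 % of non-relevant records) and a planted MeSH descriptor (50 % vs 0.7 %).

```python
from filterforge import (
    generate_corpus, reference_default, CorpusIndex, screen_singles,
    mine_terms, add_truncations, generate_candidates,
)
from filterforge.filter_search import Objective, rank

corpus, truth = generate_corpus(reference_default(seed=1))
table = add_truncations(mine_terms(corpus), min_prefix=5)
candidates = generate_candidates(table)
index = CorpusIndex(corpus)
survivors = screen_singles(candidates, corpus, index=index)
best = rank(survivors, Objective("sensitivity"), top_k=1).rows[0]
print(str(best[0]), round(best[1].se, 1), round(best[1].sp, 1))
```

prints (seed 1):

```
preference* 72.7 97.2
```

i.e. the truncated planted family is recovered as the most sensitive single
term: it retrieves 16 of the 22 relevant records (Se 72.7 %, close to the
planted 75 % rate) while keeping specificity at 97.2 %.

The same workflow as a narrative analysis lives under `analysis/`
(`01_simulate_corpus.py` … `06_validate_filters.py`); each script prints
what it found and writes its tables under `results/` (large regenerable
fixtures go to `scratch/`). A `filterforge` command-line interface exposes
the individual stages (`simulate`, `split`, `mine`, `screen`, `search`,
`validate`, `run`) for use on real MEDLINE exports.

Typical end-to-end output on the default corpus shows the expected
small-reference-set behavior: development-set sensitivity reaches 100 % with
three OR-ed terms, and part of that performance is overfitting — background
terms picked up on 8–12 relevant development records can collapse on the
validation half, while the planted signals transfer.

## Confidence intervals

Two Wald-interval conventions are provided. The reproduction default uses
the **total evaluated-set size** as denominator (n = 4122 / 4116 in the
reference tables), which is the convention under which every checkable
printed sensitivity bracket reproduces at one-decimal rounding; the orthodox
class-count denominator (n = A+C for Se) is available via
`CIConfig(denominator_rule="class_count")`. See `docs/methods.md`.

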