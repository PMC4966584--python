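# Methods

This note documents the models, conventions and design choices behind
filterforge, in the order the pipeline runs.

## Corpus model and MEDLINE dialect

A record is one citation: id, title, abstract, journal, year, language,
publication types, and MeSH headings (descriptor, major-topic flag,
subheadings each with their own major flag). The reader accepts both the
canonical NLM `TAG - value` form and the `TAG:` colon variant seen in some
exports, and always emits the canonical form, so write∘read is the identity
(property-tested on randomized records). The publication year is the first
4-digit token of `DP`, since `DP` may carry months or seasons. The journal
key is `TA` with `JT` as fallback — one canonical key is needed for
journal-stratified splitting. A block without a `PMID` is skipped with a
warning; a malformed tag line is a hard error carrying the line number.
Records without labels default to *not relevant*: in a hand-search design,
anything not selected is a true negative.

## Development/validation split

`stratified_split` randomizes 1:1 within each journal: relevant records are
divided ⌊r/2⌋/⌈r/2⌉ with a coin flip for the odd one; non-relevant records
are allocated by independent fair Bernoulli draws. Journal totals are
therefore close to but not exactly equal — deliberately so: forcing exact
halves would misrepresent what a simple 1:1 randomization produces, and the
reference realization itself shows asymmetric journal totals. Consequences
tested as invariants: the halves partition the corpus; per-journal relevant
imbalance ≤ 1 for every seed; overall relevant imbalance is bounded by the
number of journals with an odd relevant count. The generator is a seeded
PCG64; the seed is recorded in the result, because the original Excel-based
randomization is irreproducible and determinism is required for testing.

## Term mining

Keywords are maximal alphanumeric runs, lower-cased, of length ≥ 3, with a
~190-word stop list (shipped as a versioned data file). Matching uses the
same tokenizer but no length/stop filtering — mined terms must match the
documents they were counted in by construction. Frequencies count documents,
not occurrences. MeSH descriptors and subheadings are taken verbatim.

Truncation is a separate, optional pass: sorted keywords are scanned for
maximal runs of ≥ 2 entries sharing a prefix of at least `min_prefix`
(default 5) characters; each run contributes one truncated entry whose
pattern is the run's longest common prefix and whose document frequency is
the exact union count (the mined table privately retains per-term document
sets for this purpose). This is an emulation — how truncated candidate
terms were constructed in the original workflow is not documented — so the
heuristic is isolated and replaceable.

Candidate generation expands every keyword into exactly six queries (bare +
`[tw]`, `[tiab]`, `[majr]`, `[sh]`, `[mh]`) and every MeSH descriptor into
one `[mesh]` query: 6·K + M candidates. MeSH-field variants of plain text
keywords are generated even though they retrieve nothing; this keeps the
cross-product arithmetic exact (251 keywords and 162 MeSH terms give 1668).

## Query semantics

Queries are OR-disjunctions of atomic terms; AND/NOT are out of scope. A
bracketed field tag binds to the immediately preceding term only (PubMed's
parser behavior), so in `Elicit* OR Choice* OR Prescrib*[tiab]` only the
last term is field-restricted. Bare terms are matched as text words
(`tiab` ∪ MeSH descriptors ∪ subheadings) rather than through PubMed's
Automatic Term Mapping, which cannot be reproduced offline; this superset
rule is deterministic and documented. No MeSH tree explosion is performed —
`[mh]`/`[majr]` compare descriptor strings case-insensitively. Truncation is
case-insensitive token-prefix matching; phrases match as consecutive token
runs, with truncation applying to the final word. A `CorpusIndex` provides
an inverted-index fast path whose equivalence to the per-record reference
implementation is property-tested.

## Performance measures and confidence intervals

Se, Sp, Ac are percentages; NNR = (A+B)/A is the reciprocal of precision.
NNR is undefined (not infinite) at A = 0, and ranking treats undefined as
worst — this avoids sentinel arithmetic. A flag marks the degenerate
A+B = 0 (nothing retrieved) case.

Intervals are Wald: 100·(p ± z·√(p(1−p)/n)), z = 1.96, clipped to [0, 100].
The **denominator convention matters**. The reproduction default uses the
total evaluated-set size (4122 development / 4116 validation in the
reference tables) rather than the class count. This is statistically
unorthodox — a sensitivity CI should condition on the number of relevant
records — but it is the unique convention that reproduces every checkable
printed sensitivity bracket at one-decimal rounding (all nine distinct
(p, n) pairs are asserted in the test suite). The orthodox rule is available
as `denominator_rule="class_count"` and is what a user should prefer for
real inference. Display rounding is half-up to one decimal; all threshold
comparisons and ranking use unrounded values, so behavior never depends on
display precision.

## Filter search

Screening keeps single terms with Se ≥ 25 % and Sp ≥ 75 % (unrounded ≥);
candidates with identical retrieval sets are deduplicated keeping the
shortest pattern. Combination growth evaluates all survivor pairs, prunes
those failing Sp ≥ 75 %, Se ≥ 50 % or Ac ≥ 75 %, then expands one survivor
term at a time, keeping an expansion only if it strictly improves the single
configured objective while still meeting the thresholds, up to `max_terms`
(default 4). Survivors that meet the combination thresholds on their own
stay in the ranking pool, so a search where every pair fails still returns
the thresholded singles.

Two genuinely open readings are resolved as follows and shipped as presets:
the screening thresholds follow the methods text (`methods_default`); the
alternative printed with the combination table (sensitivity > 75 %,
specificity > 50 %) ships as `table4_caption` without deciding intent.
"Expansion candidates" are the screened survivors, not the raw candidate
set — the only set the procedure keeps in play after screening — and
"no further increase in performance" is operationalized as strict
improvement of the one objective being optimized, since requiring
simultaneous improvement in several measures would make the plural reading
ambiguous and mostly vacuous.

Combinatorial control is a beam (default width 100) per combination size;
with an unbounded beam the search is exhaustive over reachable combinations,
and the test suite verifies beam = exhaustive on 12 seeds × ≤ 3 terms.
Ranking ties break by fewer terms, then better Sp (under the sensitivity
objective) or better Se (otherwise), then the query string, making output
order-invariant.

## Internal validation

Filters selected on the development set are re-evaluated on the validation
set with the validation set's own size as CI denominator. Drops are reported
signed (val − dev, percentage points) on unrounded values, with a
rounded-value variant alongside, because published drop figures mix display
rounding with exact differences and neither reading should be asserted as
the other. No significance test is attached to dev/val specificity
differences (none is defined for this design here). Validation metrics
provably never read development labels (tested by label permutation).

## Synthetic corpus generator

The generator is the package's study-condition definition, not a test prop.
Defaults: 8238 records across the 27 reference journals with the reference
per-journal relevant counts allocated exactly (22 total; prevalence 0.27 %);
background title/abstract tokens drawn from a Zipf(1.1) distribution over a
5000-token synthetic vocabulary (150 abstract + 10 title tokens per record);
10 MeSH descriptors per record from a 1500-descriptor pool, with 30 % major
flags and 40 % subheading attachment. Two signals are planted by per-class
Bernoulli draws: a title/abstract token family ("preference"/"preferences",
sharing the prefix *preferen*) at 75 % in relevant vs 2.8 % in non-relevant
records, and a MeSH descriptor at 50 % vs 0.7 % — the per-class contrasts
implied by the best published single terms. The family's morphological
variants exist to exercise truncation mining end-to-end. Planted patterns
colliding with the background vocabulary are an error, so ground truth is
never contaminated; realized per-class counts are recorded and recountable
through the query engine (asserted in tests). Fixed seed ⇒ byte-identical
fixtures. The Zipf/vocabulary/length values are plausibility choices for
MEDLINE-like token statistics, exposed as configuration, not claims.

What the generator does *not* emulate: real English phrasing and topical
correlation between tokens, correlated MeSH/keyword co-occurrence, journal-
specific vocabularies, and year/language heterogeneity. Passing tests
therefore demonstrate the machinery (mining, matching, screening, ranking,
validation arithmetic) and signal-recovery at the planted effect sizes; they
do not certify retrieval performance on real literature.

## Problem sizes and runtime choices

The test suite's heaviest check regenerates 50 full-size corpora (8238
records each), mines and screens ~3000 candidate queries per corpus via the
inverted index, and verifies that the planted family ranks top-1 for
sensitivity in ≥ 90 % of seeds with the pooled realized sensitivity inside
the 99 % binomial band around 75 %; pooling across seeds is used because a
per-seed band at 22 relevant records would be nearly vacuous. Oracle
equivalence runs on 200 randomized corpora of ≤ 50 records, and monotonicity
on 500 randomized query/corpus pairs — sizes at which exhaustive reference
implementations stay exact and the whole suite completes in minutes.

## Known limitations

* No Automatic Term Mapping and no MeSH explosion: recall on real PubMed
  may differ for bare terms and descriptor queries.
* The truncation heuristic is one defensible reconstruction, not the
  original procedure.
* Specificity CI brackets under the total-denominator convention reproduce
  printed values only to within ±0.1 (consistent with unrounded inputs we
  cannot recover); sensitivity brackets reproduce exactly.
* The expansion rule optimizes a single objective; Pareto-style
  multi-objective search is out of scope.
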