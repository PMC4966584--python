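"""Threshold-constrained development of OR-combination search filters.

The development algorithm:

1. **Screening** — every candidate single-term query is evaluated on the
   development set; terms with sensitivity >= 25 % and specificity >= 75 %
   (the ``methods_default`` preset) survive.
2. **Pairing** — all OR-pairs of survivors are evaluated; pairs failing the
   combination thresholds (Sp >= 75 %, Se >= 50 %, Ac >= 75 %) are pruned.
3. **Expansion** — surviving combinations are grown one survivor term at a
   time; an expansion is kept only if it strictly improves the configured
   objective while still meeting the combination thresholds, until no
   expansion improves or ``max_terms`` is reached.
4. **Ranking** — combinations (and survivors that meet the combination
   thresholds on their own) are ranked by the objective.

Threshold comparisons use >= on unrounded percentages.  Combinatorial growth
is controlled by a beam (default width 100); with an unbounded beam the
search is exhaustive over reachable combinations, which the test suite
checks against brute-force enumeration on small seed sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .corpus_model import LabeledCorpus
from .filter_metrics import CIConfig, PerformanceEstimate, estimate_performance
from .query_engine import ConfusionMatrix, CorpusIndex, Query
from .term_miner import CandidateSet

__all__ = [
    "SearchThresholds",
    "THRESHOLD_PRESETS",
    "Objective",
    "OBJECTIVES",
    "RankedFilters",
    "screen_singles",
    "grow_combinations",
    "rank",
]


@dataclass(frozen=True)
class SearchThresholds:
    """Minimum performance (percent) for single terms and OR-combinations."""

    single_se_min: float = 25.0
    single_sp_min: float = 75.0
    combo_sp_min: float = 75.0
    combo_se_min: float = 50.0
    combo_ac_min: float = 75.0

    def __post_init__(self) -> None:
        for v in (
            self.single_se_min,
            self.single_sp_min,
            self.combo_sp_min,
            self.combo_se_min,
            self.combo_ac_min,
        ):
            if not 0.0 <= v <= 100.0:
                raise ValueError("thresholds must lie in [0, 100]")

    def combo_ok(self, est: PerformanceEstimate) -> bool:
        return (
            est.sp >= self.combo_sp_min
            and est.se >= self.combo_se_min
            and est.ac >= self.combo_ac_min
        )


#: Named threshold presets.  ``methods_default`` follows the stated screening
#: rules; ``table4_caption`` is the alternative printed alongside the
#: combination table (sensitivity > 75 %, specificity > 50 %), shipped
#: without deciding which was intended.
THRESHOLD_PRESETS = {
    "methods_default": SearchThresholds(),
    "table4_caption": SearchThresholds(
        single_se_min=25.0,
        single_sp_min=75.0,
        combo_se_min=75.0,
        combo_sp_min=50.0,
        combo_ac_min=75.0,
    ),
}


@dataclass(frozen=True)
class Objective:
    """A single performance measure to optimize; NNR is minimized,
    the three percentages are maximized."""

    measure: str

    def __post_init__(self) -> None:
        if self.measure not in ("sensitivity", "specificity", "accuracy", "nnr"):
            raise ValueError(f"unknown objective {self.measure!r}")

    @property
    def direction(self) -> str:
        return "minimize" if self.measure == "nnr" else "maximize"

    def value(self, est: PerformanceEstimate) -> float:
        """Objective value where larger is always better (undefined NNR worst)."""
        if self.measure == "sensitivity":
            return est.se
        if self.measure == "specificity":
            return est.sp
        if self.measure == "accuracy":
            return est.ac
        return -est.nnr if est.nnr is not None else float("-inf")


OBJECTIVES = tuple(Objective(m) for m in ("sensitivity", "specificity", "accuracy", "nnr"))


@dataclass
class RankedFilters:
    objective: Objective
    rows: list[tuple[Query, PerformanceEstimate]]
    top_k: int


def screen_singles(
    candidates: CandidateSet,
    dev: LabeledCorpus,
    thresholds: SearchThresholds = SearchThresholds(),
    ci: CIConfig = CIConfig(),
    index: CorpusIndex | None = None,
) -> list[tuple[Query, PerformanceEstimate]]:
    """Evaluate every candidate on the development set and keep those meeting
    the single-term thresholds (unrounded comparison).

    Candidates retrieving identical document sets are deduplicated keeping
    the shortest pattern (ties broken lexicographically by query string).
    """
    if not candidates.queries:
        raise ValueError("no candidates to screen")
    if dev.n_relevant == 0:
        raise ValueError("development set has no relevant records")
    if index is None:
        index = CorpusIndex(dev)

    survivors: dict[frozenset[int], tuple[Query, PerformanceEstimate]] = {}
    for q in candidates.queries:
        docs = index.query_docs(q)
        cm = index.confusion(docs)
        if cm.A == 0 and thresholds.single_se_min > 0:
            continue
        est = estimate_performance(cm, ci)
        if est.se >= thresholds.single_se_min and est.sp >= thresholds.single_sp_min:
            key = frozenset(docs)
            if key in survivors:
                prev_q, _ = survivors[key]
                if (_pattern_len(q), str(q)) < (_pattern_len(prev_q), str(prev_q)):
                    survivors[key] = (q, est)
            else:
                survivors[key] = (q, est)
    return sorted(survivors.values(), key=lambda r: str(r[0]))


def _pattern_len(q: Query) -> int:
    return sum(len(t.pattern) for t in q.terms)


def grow_combinations(
    seeds: list[Query],
    dev: LabeledCorpus,
    thresholds: SearchThresholds = SearchThresholds(),
    objective: Objective = Objective("sensitivity"),
    max_terms: int = 4,
    beam_width: int = 100,
    top_k: int = 3,
    ci: CIConfig = CIConfig(),
    index: CorpusIndex | None = None,
) -> RankedFilters:
    """Grow OR-combinations of screened seed terms under the combination
    thresholds, optimizing one objective.

    All seed pairs are evaluated first; survivors are expanded one seed at a
    time, keeping an expansion only if it strictly improves the objective and
    still meets the thresholds.  A beam of ``beam_width`` combinations per
    size bounds the frontier; ``beam_width=None`` (or any width at least the
    frontier size) makes the search exhaustive over reachable combinations.
    Output is deterministic for fixed inputs.
    """
    if not seeds:
        raise ValueError("no seed queries to combine")
    if beam_width is not None and beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    if index is None:
        index = CorpusIndex(dev)

    seeds = sorted(seeds, key=str)
    n = index.n
    n_rel = index.n_relevant
    match = np.zeros((len(seeds), n), dtype=bool)
    for i, q in enumerate(seeds):
        match[i, list(index.query_docs(q))] = True
    labels = np.array([index.corpus.labels[r.record_id] for r in index.corpus.records])

    def metrics(vec: np.ndarray) -> PerformanceEstimate:
        a = int(np.count_nonzero(vec & labels))
        b = int(np.count_nonzero(vec) - a)
        cm = ConfusionMatrix(a, b, n_rel - a, n - n_rel - b)
        return estimate_performance(cm, ci)

    pool: dict[frozenset[int], PerformanceEstimate] = {}

    # singles that meet the combination thresholds stand on their own
    singles: list[tuple[frozenset[int], np.ndarray, PerformanceEstimate]] = []
    for i in range(len(seeds)):
        est = metrics(match[i])
        singles.append((frozenset([i]), match[i], est))
        if thresholds.combo_ok(est):
            pool[frozenset([i])] = est

    # all pairs, pruned by the combination thresholds
    frontier: list[tuple[frozenset[int], np.ndarray, float]] = []
    for i, j in itertools.combinations(range(len(seeds)), 2):
        vec = match[i] | match[j]
        est = metrics(vec)
        if thresholds.combo_ok(est):
            key = frozenset([i, j])
            pool[key] = est
            frontier.append((key, vec, objective.value(est)))

    size = 2
    while frontier and size < max_terms:
        frontier.sort(key=lambda t: (-t[2], sorted(t[0])))
        if beam_width is not None:
            frontier = frontier[:beam_width]
        next_frontier: dict[frozenset[int], tuple[np.ndarray, float]] = {}
        for key, vec, val in frontier:
            for i in range(len(seeds)):
                if i in key:
                    continue
                new_key = key | {i}
                if new_key in pool or new_key in next_frontier:
                    continue
                new_vec = vec | match[i]
                est = metrics(new_vec)
                if objective.value(est) > val and thresholds.combo_ok(est):
                    pool[new_key] = est
                    next_frontier[new_key] = (new_vec, objective.value(est))
        frontier = [(k, v, o) for k, (v, o) in next_frontier.items()]
        size += 1

    rows = [
        (Query(tuple(t for i in sorted(key) for t in seeds[i].terms)), est)
        for key, est in pool.items()
    ]
    return rank(rows, objective, top_k)


def rank(
    rows: list[tuple[Query, PerformanceEstimate]],
    objective: Objective,
    top_k: int = 3,
) -> RankedFilters:
    """Order filter rows by the objective on unrounded values.

    Ties break by (1) fewer terms, (2) better specificity under the
    sensitivity objective / better sensitivity otherwise, (3) the query
    string; the result is invariant to input order.
    """

    def sort_key(row: tuple[Query, PerformanceEstimate]):
        q, est = row
        secondary = est.sp if objective.measure == "sensitivity" else est.se
        return (-objective.value(est), len(q.terms), -secondary, str(q))

    ordered = sorted(rows, key=sort_key)
    return RankedFilters(objective=objective, rows=ordered[:top_k], top_k=top_k)
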