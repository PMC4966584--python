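"""Retrieval performance measures and their 95 % confidence intervals.

For a confusion matrix with A true positives, B false positives, C false
negatives and D true negatives:

    sensitivity  Se = A / (A + C)
    specificity  Sp = D / (B + D)
    accuracy     Ac = (A + D) / (A + B + C + D)
    NNR          (A + B) / A   (number needed to read, 1/precision)

All four are reported as percentages except NNR, a dimensionless ratio >= 1.
NNR is undefined when A = 0 (no relevant record retrieved); a separate flag
marks the degenerate case of a query retrieving nothing at all.

Confidence intervals are normal-approximation (Wald) intervals,
100·(p ± z·sqrt(p(1−p)/n)), clipped to [0, 100].  Two denominator
conventions are offered:

* ``total_corpus`` (default): n is the size of the whole evaluated set.
  This is statistically unorthodox — a sensitivity CI should be conditioned
  on the relevant-class count — but it is the convention under which every
  checkable printed sensitivity bracket in the source tables reproduces at
  one-decimal rounding, so it is the reproduction default.
* ``class_count``: n is the denominator of the proportion itself (A+C for
  Se, B+D for Sp); the orthodox choice for real use.

Wilson or exact (Clopper–Pearson) intervals are a documented extension
point; `scipy.stats.binomtest(...).proportion_ci` provides them if needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import sqrt

from .query_engine import ConfusionMatrix, Query

__all__ = [
    "CIConfig",
    "PerformanceEstimate",
    "compute_metrics",
    "wald_ci",
    "estimate_performance",
    "format_row",
    "round_half_up",
]


def round_half_up(x: float, digits: int = 1) -> float:
    """Round half away from zero (so 99.65 -> 99.7), as printed tables do."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CIConfig:
    """Confidence-interval convention: normal quantile and denominator rule."""

    z: float = 1.96
    denominator_rule: str = "total_corpus"

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.denominator_rule not in ("total_corpus", "class_count"):
            raise ValueError(f"unknown denominator_rule {self.denominator_rule!r}")


@dataclass(frozen=True)
class PerformanceEstimate:
    """Point estimates (percent) with Wald CIs for Se and Sp.

    ``nnr`` is None when undefined (A = 0); ``retrieved_nothing`` flags the
    A + B = 0 case.  ``n_ci`` records the CI denominator used.
    """

    se: float
    sp: float
    ac: float
    nnr: float | None
    se_ci: tuple[float, float] = (0.0, 100.0)
    sp_ci: tuple[float, float] = (0.0, 100.0)
    n_ci: int = 0
    retrieved_nothing: bool = False

    def __post_init__(self) -> None:
        for v in (self.se, self.sp, self.ac):
            if not 0.0 <= v <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")
        for lo, hi in (self.se_ci, self.sp_ci):
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError("CI bounds must satisfy 0 <= lo <= hi <= 100")


def compute_metrics(cm: ConfusionMatrix) -> PerformanceEstimate:
    """Point values of Se, Sp, Ac and NNR from a confusion matrix.

    Requires at least one record of each class (A+C > 0 and B+D > 0);
    the measures are undefined otherwise.
    """
    if cm.A + cm.C == 0 or cm.B + cm.D == 0:
        raise ValueError("metrics undefined: corpus lacks one of the two classes")
    se = 100.0 * cm.A / (cm.A + cm.C)
    sp = 100.0 * cm.D / (cm.B + cm.D)
    ac = 100.0 * (cm.A + cm.D) / cm.total
    nnr = (cm.A + cm.B) / cm.A if cm.A > 0 else None
    return PerformanceEstimate(
        se=se, sp=sp, ac=ac, nnr=nnr, retrieved_nothing=(cm.A + cm.B == 0)
    )


def wald_ci(p: float, n: int, cfg: CIConfig = CIConfig()) -> tuple[float, float]:
    """95 % (by default) Wald interval for a proportion, in percent.

    Returns ``100·(p ± z·sqrt(p(1−p)/n))`` clipped to [0, 100]; zero-width
    at p = 0 or p = 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    half = cfg.z * sqrt(p * (1.0 - p) / n)
    return (max(0.0, 100.0 * (p - half)), min(100.0, 100.0 * (p + half)))


def estimate_performance(cm: ConfusionMatrix, cfg: CIConfig = CIConfig()) -> PerformanceEstimate:
    """Full performance estimate: point values plus Se/Sp Wald intervals."""
    point = compute_metrics(cm)
    if cfg.denominator_rule == "total_corpus":
        n_se = n_sp = cm.total
    else:
        n_se, n_sp = cm.A + cm.C, cm.B + cm.D
    return PerformanceEstimate(
        se=point.se,
        sp=point.sp,
        ac=point.ac,
        nnr=point.nnr,
        se_ci=wald_ci(point.se / 100.0, n_se, cfg),
        sp_ci=wald_ci(point.sp / 100.0, n_sp, cfg),
        n_ci=cm.total if cfg.denominator_rule == "total_corpus" else n_se,
        retrieved_nothing=point.retrieved_nothing,
    )


def _fmt_ci(ci: tuple[float, float]) -> str:
    return f"[{round_half_up(ci[0]):.1f}–{round_half_up(ci[1]):.1f}]"


def _estimate_cells(est: PerformanceEstimate) -> list[str]:
    return [
        f"{round_half_up(est.se):.1f}",
        _fmt_ci(est.se_ci),
        f"{round_half_up(est.sp):.1f}",
        _fmt_ci(est.sp_ci),
        f"{round_half_up(est.ac):.1f}",
        "—" if est.nnr is None else f"{round_half_up(est.nnr):.1f}",
    ]


def format_row(
    query: Query, dev: PerformanceEstimate, val: PerformanceEstimate | None = None
) -> list[str]:
    """Render one report row: query string then Se [CI], Sp [CI], Ac, NNR
    cells for the development set, followed by the same four measures for the
    validation set when present.  Percentages and NNR are printed to one
    decimal, rounding half up; undefined NNR renders as an em dash."""
    cells = [str(query)] + _estimate_cells(dev)
    if val is not None:
        cells += _estimate_cells(val)
    return cells
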