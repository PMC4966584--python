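"""Internal validation: apply development-selected filters to the held-out
validation set and report paired development/validation performance.

Performance drops are reported signed (validation minus development, in
percentage points) on unrounded values; because printed tables round to one
decimal, the report also carries drops computed on the rounded values so
either reading can be compared."""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd

from .corpus_model import LabeledCorpus
from .filter_metrics import (
    CIConfig,
    PerformanceEstimate,
    estimate_performance,
    format_row,
    round_half_up,
)
from .filter_search import RankedFilters
from .query_engine import Query, evaluate

__all__ = ["ValidationReport", "validate_filters", "render_report"]

MEASURES = ("se", "sp", "ac")


@dataclass
class ValidationReport:
    objective: str
    rows: list[tuple[Query, PerformanceEstimate, PerformanceEstimate]]
    drops: list[dict[str, float]]  # per row: measure -> val − dev, unrounded
    drops_rounded: list[dict[str, float]]


def validate_filters(
    filters: RankedFilters,
    dev: LabeledCorpus,
    val: LabeledCorpus,
    ci: CIConfig = CIConfig(),
) -> ValidationReport:
    """Re-evaluate each ranked filter on both sets.

    The two corpora must be disjoint; each set's metrics use that set's own
    size as CI denominator (under the total-corpus rule).  A filter that
    retrieves nothing in the validation set keeps its row with NNR undefined.
    """
    dev_ids = {r.record_id for r in dev.records}
    val_ids = {r.record_id for r in val.records}
    if dev_ids & val_ids:
        raise ValueError("development and validation sets overlap")

    rows = []
    drops = []
    drops_rounded = []
    for query, _ in filters.rows:
        dev_est = estimate_performance(evaluate(query, dev), ci)
        val_est = estimate_performance(evaluate(query, val), ci)
        rows.append((query, dev_est, val_est))
        drops.append(
            {m: getattr(val_est, m) - getattr(dev_est, m) for m in MEASURES}
        )
        drops_rounded.append(
            {
                m: round_half_up(
                    round_half_up(getattr(val_est, m)) - round_half_up(getattr(dev_est, m))
                )
                for m in MEASURES
            }
        )
    return ValidationReport(
        objective=filters.objective.measure,
        rows=rows,
        drops=drops,
        drops_rounded=drops_rounded,
    )


_CSV_COLUMNS = [
    "objective", "query",
    "dev_se", "dev_se_lo", "dev_se_hi", "dev_sp", "dev_sp_lo", "dev_sp_hi",
    "dev_ac", "dev_nnr",
    "val_se", "val_se_lo", "val_se_hi", "val_sp", "val_sp_lo", "val_sp_hi",
    "val_ac", "val_nnr",
    "drop_se", "drop_sp", "drop_ac",
]


def report_frame(report: ValidationReport) -> pd.DataFrame:
    """The report as a DataFrame in fixed column order (dev block, val block,
    then signed unrounded drops)."""
    out = []
    for (query, dev_est, val_est), drop in zip(report.rows, report.drops):
        row: dict[str, object] = {"objective": report.objective, "query": str(query)}
        for prefix, est in (("dev", dev_est), ("val", val_est)):
            row[f"{prefix}_se"] = est.se
            row[f"{prefix}_se_lo"], row[f"{prefix}_se_hi"] = est.se_ci
            row[f"{prefix}_sp"] = est.sp
            row[f"{prefix}_sp_lo"], row[f"{prefix}_sp_hi"] = est.sp_ci
            row[f"{prefix}_ac"] = est.ac
            row[f"{prefix}_nnr"] = est.nnr
        for m in MEASURES:
            row[f"drop_{m}"] = drop[m]
        out.append(row)
    return pd.DataFrame(out, columns=_CSV_COLUMNS)


def render_report(report: ValidationReport, format: str = "csv") -> str:
    """Render the validation report as ``csv`` (bit-stable for fixed input)
    or as a human-readable ``text-table`` with bracketed CIs."""
    if format == "csv":
        buf = io.StringIO()
        report_frame(report).to_csv(buf, index=False, float_format="%.6f")
        return buf.getvalue()
    if format == "text-table":
        header = [
            "query",
            "dev Se [95% CI]", "dev Sp [95% CI]", "dev Ac", "dev NNR",
            "val Se [95% CI]", "val Sp [95% CI]", "val Ac", "val NNR",
        ]
        lines = []
        for query, dev_est, val_est in report.rows:
            cells = format_row(query, dev_est, val_est)
            merged = [
                cells[0],
                f"{cells[1]} {cells[2]}", f"{cells[3]} {cells[4]}", cells[5], cells[6],
                f"{cells[7]} {cells[8]}", f"{cells[9]} {cells[10]}", cells[11], cells[12],
            ]
            lines.append(merged)
        widths = [
            max(len(h), *(len(row[i]) for row in lines)) if lines else len(h)
            for i, h in enumerate(header)
        ]
        def fmt(row: list[str]) -> str:
            return "  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip()
        out = [f"objective: {report.objective}", fmt(header)]
        out += [fmt(row) for row in lines]
        return "\n".join(out) + "\n"
    raise ValueError(f"unknown format {format!r}")
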