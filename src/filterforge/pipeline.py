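"""End-to-end orchestration: simulate/read → split → mine → screen → search →
validate, with a JSON run manifest.

A run is fully determined by its configuration (including the seed); rerunning
with the same configuration reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .corpus_model import LabeledCorpus, attach_labels, read_labels, read_medline
from .filter_metrics import CIConfig
from .filter_search import (
    THRESHOLD_PRESETS,
    Objective,
    grow_combinations,
    screen_singles,
)
from .query_engine import CorpusIndex
from .splitter import split_summary, stratified_split
from .synthetic_data import generate_corpus, reference_default, write_fixture
from .term_miner import add_truncations, generate_candidates, mine_terms
from .validation_report import render_report, validate_filters

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str
    records_path: str | None = None  # MEDLINE flat file; None = simulate
    labels_path: str | None = None
    seed: int = 0
    thresholds_preset: str = "methods_default"
    objectives: tuple[str, ...] = ("sensitivity", "specificity", "accuracy", "nnr")
    ci_z: float = 1.96
    ci_denominator_rule: str = "total_corpus"
    min_prefix: int = 5
    max_terms: int = 4
    beam_width: int = 100
    top_k: int = 3
    extra: dict = field(default_factory=dict)


def _stage(manifest: dict, name: str, **counts) -> None:
    manifest["stages"].append({"name": name, **counts})
    logger.info("stage %s: %s", name, counts)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order, writing per-stage outputs and a manifest
    under ``config.out_dir``; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: v for k, v in asdict(config).items()},
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }
    ci = CIConfig(z=config.ci_z, denominator_rule=config.ci_denominator_rule)
    thresholds = THRESHOLD_PRESETS[config.thresholds_preset]

    # --- corpus ---
    if config.records_path is None:
        try:
            corpus, truth = generate_corpus(reference_default(seed=config.seed))
            write_fixture(corpus, truth, out / "fixture")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("simulate", str(e)) from e
        _stage(manifest, "simulate", records=len(corpus), relevant=corpus.n_relevant)
    else:
        try:
            with open(config.records_path) as fh:
                records = read_medline(fh)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("read_medline", str(e)) from e
        try:
            if config.labels_path is None:
                raise ValueError("labels_path required when records_path is given")
            corpus = attach_labels(records, read_labels(config.labels_path))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("attach_labels", str(e)) from e
        _stage(manifest, "read", records=len(corpus), relevant=corpus.n_relevant)

    # --- split ---
    try:
        split = stratified_split(corpus, seed=config.seed)
        split_summary(split).to_csv(out / "split_summary.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("split", str(e)) from e
    _stage(
        manifest,
        "split",
        dev_total=len(split.development),
        dev_relevant=split.development.n_relevant,
        val_total=len(split.validation),
        val_relevant=split.validation.n_relevant,
    )

    # --- mine ---
    try:
        table = mine_terms(split.development)
        table = add_truncations(table, min_prefix=config.min_prefix)
        table.to_frame().to_csv(out / "terms.csv", index=False)
        candidates = generate_candidates(table)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("mine", str(e)) from e
    _stage(
        manifest,
        "mine",
        keywords=len(table.keywords()),
        mesh_descriptors=len(table.mesh_descriptors()),
        candidates=len(candidates),
    )

    # --- screen ---
    try:
        index = CorpusIndex(split.development)
        survivors = screen_singles(candidates, split.development, thresholds, ci, index)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("screen", str(e)) from e
    _stage(manifest, "screen", survivors=len(survivors))

    # --- search + validate, one report per objective ---
    report_paths = []
    n_ranked = 0
    for measure in config.objectives:
        try:
            ranked = grow_combinations(
                [q for q, _ in survivors],
                split.development,
                thresholds,
                Objective(measure),
                max_terms=config.max_terms,
                beam_width=config.beam_width,
                top_k=config.top_k,
                ci=ci,
                index=index,
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("search", f"objective {measure}: {e}") from e
        try:
            report = validate_filters(ranked, split.development, split.validation, ci)
            path = out / f"report_{measure}.csv"
            path.write_text(render_report(report, "csv"))
            report_paths.append(str(path))
            n_ranked += len(ranked.rows)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("validate", f"objective {measure}: {e}") from e
    _stage(manifest, "search", ranked_rows=n_ranked)
    _stage(manifest, "validate", reports=len(report_paths))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
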