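"""End-to-end evaluation pipeline.

Gluing stage: read (or simulate) records, score them, aggregate into the
score / metrics / consistency report tables, run the statistical
comparisons, and write everything to an output directory.  The pipeline
has no hidden state — its outputs equal the composition of the module
operations on the same inputs, and a fixed seed makes the whole run
byte-for-byte reproducible.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import pandas as pd
import yaml

from . import consistency as cons
from . import io as tio
from . import metrics, simulate, stats
from .datamodel import (
    ConfigError,
    IdentificationRecord,
    MatchCategory,
    SampleMeta,
    TaxonRef,
    ValidationError,
    check_unique_attempts,
)
from .scoring import DEFAULT_SCHEME, WeightScheme, score_records, scores_frame

log = logging.getLogger("taxid_eval")


@dataclass(frozen=True)
class PipelineConfig:
    """Input selection and knobs for one pipeline run.

    Exactly one of (records/taxonomy/metadata paths) or a simulation
    config may be given.
    """

    records_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    sim: simulate.SimConfig | None = None
    scheme: WeightScheme = DEFAULT_SCHEME
    alpha: float = 0.05
    out_dir: str = "taxid_eval_out"

    def __post_init__(self) -> None:
        has_paths = self.records_path is not None
        if has_paths == (self.sim is not None):
            raise ConfigError("give either input paths or a simulation config, not both")
        if has_paths and (self.taxonomy_path is None or self.metadata_path is None):
            raise ConfigError("records input needs taxonomy and metadata paths too")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")


def config_from_yaml(path: str) -> PipelineConfig:
    """Load a pipeline configuration from a YAML mapping."""
    with open(path) as fh:
        raw: Mapping[str, Any] = yaml.safe_load(fh) or {}
    scheme_raw = raw.get("scheme", {})
    scheme = WeightScheme(
        increment_fractions=tuple(scheme_raw.get("increment_fractions", (0.50, 0.25, 0.13))),
        misleading_position_values=tuple(
            scheme_raw.get("misleading_position_values", (-5.0, -4.0, -2.0))
        ),
        good_try_value=float(scheme_raw.get("good_try_value", 15.0)),
    )
    sim = None
    if "simulation" in raw:
        sim = simulate.SimConfig(**raw["simulation"])
    inputs = raw.get("inputs", {})
    return PipelineConfig(
        records_path=inputs.get("records"),
        taxonomy_path=inputs.get("taxonomy"),
        metadata_path=inputs.get("metadata"),
        sim=sim,
        scheme=scheme,
        alpha=float(raw.get("alpha", 0.05)),
        out_dir=raw.get("out_dir", "taxid_eval_out"),
    )


@dataclass
class EvaluationReport:
    """Machine form of the full evaluation output."""

    first_choice_table: pd.DataFrame
    first_choice_ranks: pd.DataFrame
    weighted_table: pd.DataFrame
    weighted_ranks: pd.DataFrame
    metrics_table: pd.DataFrame
    consistency_table: pd.DataFrame
    consistency_ranks: pd.DataFrame
    subset_counts: pd.Series
    first_choice_letters: dict[str, str]
    consistency_letters: dict[str, str]
    stats_summary: dict[str, Any]


def _tool_groups(per_sample: pd.DataFrame) -> tuple[list[str], list[list[float]]]:
    tools = list(dict.fromkeys(per_sample["tool"]))
    groups = [per_sample.loc[per_sample["tool"] == t, "score"].tolist() for t in tools]
    return tools, groups


def _sample_groups(per_sample: pd.DataFrame, meta: pd.DataFrame, grouping: str) -> list[list[float]]:
    merged = per_sample.merge(meta[["sample", grouping]], on="sample")
    return [g["score"].tolist() for _, g in merged.groupby(grouping, sort=True)]


def build_report(
    records: list[IdentificationRecord],
    taxonomy: Mapping[str, TaxonRef],
    metadata: Mapping[str, SampleMeta],
    scheme: WeightScheme = DEFAULT_SCHEME,
    alpha: float = 0.05,
    n_replicates: int = 5,
    strict_replicates: bool = False,
) -> EvaluationReport:
    """Score, aggregate and statistically compare one record set."""
    check_unique_attempts(records)
    for rec in records:
        if rec.sample_id not in metadata:
            raise ValidationError(f"record references unknown sample {rec.sample_id!r}")
    expected = n_replicates * len(metadata) * len({r.tool_id for r in records})
    if len(records) != expected:
        log.warning(
            "evaluating %d attempts where the full design would have %d",
            len(records), expected,
        )

    frame = scores_frame(score_records(records, scheme))
    meta = tio.metadata_frame(metadata)

    per_sample_first = metrics.per_sample_scores(frame, "first_choice")
    per_sample_weighted = metrics.per_sample_scores(frame, "weighted")
    first_table, first_ranks = metrics.evaluation_table(per_sample_first, meta)
    weighted_table, weighted_ranks = metrics.evaluation_table(per_sample_weighted, meta)
    metric_table = metrics.metrics_table(frame)

    cons_frame = cons.consistency_frame(
        cons.consistency_results(records, taxonomy, metadata, n_replicates, strict=strict_replicates)
    )
    cons_table, cons_ranks = metrics.consistency_evaluation_table(cons_frame, meta)

    tools, score_groups = _tool_groups(per_sample_first)
    first_cmp = stats.compare_groups(score_groups, tools, alpha)
    _, cons_groups = _tool_groups(cons_frame.rename(columns={"consistency_C": "score"}))
    cons_cmp = stats.compare_groups(cons_groups, tools, alpha)

    concordance = stats.kendall_w(first_ranks.to_numpy().T)
    part_h, part_p = stats.kruskal_wallis(_sample_groups(per_sample_first, meta, "plant_part"))
    type_h, type_p = stats.kruskal_wallis(_sample_groups(per_sample_first, meta, "plant_type"))

    summary = {
        "n_records": len(records),
        "n_tools": len(tools),
        "n_samples": len(metadata),
        "first_choice_kruskal": {"H": first_cmp.H, "p": first_cmp.p},
        "consistency_kruskal": {"H": cons_cmp.H, "p": cons_cmp.p},
        "plant_part_kruskal": {"H": part_h, "p": part_p},
        "plant_type_kruskal": {"H": type_h, "p": type_p},
        "ranking_concordance": {
            "W": concordance.W,
            "chi2": concordance.chi2,
            "p": concordance.p,
            "m": concordance.m,
            "n": concordance.n,
        },
        "alpha": alpha,
    }
    return EvaluationReport(
        first_choice_table=first_table,
        first_choice_ranks=first_ranks,
        weighted_table=weighted_table,
        weighted_ranks=weighted_ranks,
        metrics_table=metric_table,
        consistency_table=cons_table,
        consistency_ranks=cons_ranks,
        subset_counts=metrics.subset_counts(meta),
        first_choice_letters=first_cmp.letters,
        consistency_letters=cons_cmp.letters,
        stats_summary=summary,
    )


def write_report_files(report: EvaluationReport, out_dir: str) -> list[str]:
    """Write CSV, aligned-text and JSON renderings of a report."""
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def _csv(frame: pd.DataFrame, name: str, decimals: int = 1) -> None:
        path = os.path.join(out_dir, name)
        tio.write_report(frame, path, decimals)
        written.append(path)

    _csv(report.first_choice_table, "scores_first_choice.csv")
    _csv(report.weighted_table, "scores_weighted.csv")
    _csv(report.metrics_table, "metrics.csv")
    _csv(report.consistency_table, "consistency.csv")

    text_path = os.path.join(out_dir, "report.txt")
    with open(text_path, "w") as fh:
        fh.write("First-choice mean scores by subset (rank in parentheses)\n")
        fh.write(
            metrics.format_report(
                report.first_choice_table, report.first_choice_ranks,
                letters=report.first_choice_letters,
            )
        )
        fh.write("\n\nWeighted mean scores by subset (rank in parentheses)\n")
        fh.write(metrics.format_report(report.weighted_table, report.weighted_ranks))
        fh.write("\n\nAccuracy and error percentages per tool\n")
        fh.write(metrics.format_report(report.metrics_table, decimals=0, average_decimals=1))
        fh.write("\n\nMean consistency C by subset (rank in parentheses)\n")
        fh.write(
            metrics.format_report(
                report.consistency_table, report.consistency_ranks,
                decimals=1, letters=report.consistency_letters,
            )
        )
        fh.write("\n\nSamples per subset\n")
        fh.write(report.subset_counts.to_string())
        fh.write("\n")
    written.append(text_path)

    json_path = os.path.join(out_dir, "summary.json")
    with open(json_path, "w") as fh:
        json.dump(report.stats_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(json_path)
    return written


def run_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Execute the full pipeline and write report files to ``out_dir``.

    On failure, partially written outputs are removed.
    """
    if config.sim is not None:
        sim = config.sim
        taxonomy, metadata = simulate.generate_taxonomy(sim)
        records = simulate.simulate_records(simulate.default_profiles(), metadata, taxonomy, sim)
        n_replicates = sim.n_replicates
        log.info("simulated %d records (%d tools x %d samples x %d reps)",
                 len(records), 9, sim.n_samples, sim.n_replicates)
    else:
        taxonomy = tio.read_taxonomy(config.taxonomy_path)
        metadata = tio.read_metadata(config.metadata_path, taxonomy)
        records = tio.read_records(config.records_path)
        reps = {r.replicate for r in records}
        n_replicates = max(reps) if reps else 0
        log.info("read %d records from %s", len(records), config.records_path)

    written: list[str] = []
    try:
        report = build_report(
            records, taxonomy, metadata,
            scheme=config.scheme, alpha=config.alpha, n_replicates=n_replicates,
        )
        written = write_report_files(report, config.out_dir)
        if config.sim is not None:
            os.makedirs(config.out_dir, exist_ok=True)
            tio.write_records(records, os.path.join(config.out_dir, "records.csv"))
            tio.write_taxonomy(taxonomy, os.path.join(config.out_dir, "taxonomy.csv"))
            tio.write_metadata(metadata, os.path.join(config.out_dir, "metadata.csv"))
    except Exception:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise
    return report
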