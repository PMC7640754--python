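"""Aggregation of per-attempt scores into tool-level summary tables.

The observation unit for tool comparison is the per-sample mean over
replicates (one value per tool x sample); accuracy/error percentages are
computed over all replicate-level attempts.  Report layouts mirror the
standard presentation: a tools x subsets matrix of mean scores with
per-subset ranks and an overall average, an accuracy/error percentage
table (% = 100, % >= 80, % >= 50, %mad, %wrong), and the analogous
consistency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    PLANT_PARTS,
    PLANT_TYPES,
    WRONG_CATEGORIES,
    SampleMeta,
    ValidationError,
)


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero, as report tables conventionally do.

    Internal computation keeps exact floats; rounding is purely a
    formatting concern.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pooled_mean(means: Sequence[float], counts: Sequence[int]) -> float:
    """Count-weighted mean of subset means = mean over the pooled samples."""
    if len(means) != len(counts) or not means:
        raise ValidationError("means and counts must be equal-length, non-empty")
    return float(np.average(np.asarray(means, float), weights=np.asarray(counts, float)))


def per_sample_scores(frame: pd.DataFrame, score: str = "first_choice") -> pd.DataFrame:
    """Mean score over replicates for every tool x sample.

    ``frame`` is the tidy per-attempt table from ``scoring.scores_frame``.
    Returns columns ``tool, sample, score``.
    """
    if score not in ("first_choice", "weighted"):
        raise ValidationError(f"score must be 'first_choice' or 'weighted', got {score!r}")
    out = (
        frame.groupby(["tool", "sample"], sort=False)[score]
        .mean()
        .reset_index()
        .rename(columns={score: "score"})
    )
    return out


def validate_partition(meta: pd.DataFrame, grouping: str, n_samples: int | None = None) -> None:
    """Refuse metadata whose subset counts do not partition the sample set."""
    if n_samples is None:
        n_samples = meta["sample"].nunique()
    counts = meta.drop_duplicates("sample")[grouping].value_counts()
    if int(counts.sum()) != n_samples:
        raise ValidationError(
            f"{grouping} subsets cover {int(counts.sum())} samples, expected {n_samples}"
        )


def _meta_frame(metadata: Mapping[str, SampleMeta] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(metadata, pd.DataFrame):
        return metadata
    return pd.DataFrame(
        [
            {"sample": m.sample_id, "plant_part": m.plant_part, "plant_type": m.plant_type}
            for m in metadata.values()
        ]
    )


def subset_means(
    per_sample: pd.DataFrame,
    metadata: Mapping[str, SampleMeta] | pd.DataFrame,
    grouping: str = "plant_part",
) -> pd.DataFrame:
    """Per-tool mean score for each subset of one grouping (tools x subsets)."""
    meta = _meta_frame(metadata)
    missing = sorted(set(per_sample["sample"]) - set(meta["sample"]))
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    levels = PLANT_PARTS if grouping == "plant_part" else PLANT_TYPES
    merged = per_sample.merge(meta[["sample", grouping]], on="sample", how="left")
    table = merged.pivot_table(index="tool", columns=grouping, values="score", aggfunc="mean")
    cols = [c for c in levels if c in table.columns]
    return table[cols]


def rank_table(means: pd.DataFrame) -> pd.DataFrame:
    """Per-column ranks, 1 = highest mean; ties take the average rank."""
    return means.rank(ascending=False, method="average", axis=0)


def evaluation_table(
    per_sample: pd.DataFrame,
    metadata: Mapping[str, SampleMeta] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tools x (part subsets + type subsets + Average) means, with ranks.

    The overall Average column is the mean over all samples; by
    construction it equals the sample-count-weighted mean of the part
    subset means (and likewise of the type subsets).
    """
    meta = _meta_frame(metadata)
    n_samples = meta["sample"].nunique()
    validate_partition(meta, "plant_part", n_samples)
    validate_partition(meta, "plant_type", n_samples)
    parts = subset_means(per_sample, meta, "plant_part")
    types = subset_means(per_sample, meta, "plant_type")
    overall = per_sample.groupby("tool", sort=False)["score"].mean().rename("Average")
    table = pd.concat([parts, types, overall], axis=1)
    ranks = rank_table(table.drop(columns=["Average"]))
    return table, ranks


def subset_counts(metadata: Mapping[str, SampleMeta] | pd.DataFrame) -> pd.Series:
    """Number of samples in each part and type subset (plus the total)."""
    meta = _meta_frame(metadata).drop_duplicates("sample")
    counts = {}
    for level in PLANT_PARTS:
        counts[level] = int((meta["plant_part"] == level).sum())
    for level in PLANT_TYPES:
        counts[level] = int((meta["plant_type"] == level).sum())
    counts["Average"] = int(len(meta))
    return pd.Series(counts, name="n_samples")


def accuracy_thresholds(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-tool percentages of attempts at %=100, %>=80 and %>=50.

    Computed over all replicate-level first-choice scores (denominator =
    every attempt, including no-identification ones).  Nesting
    %=100 <= %>=80 <= %>=50 holds by construction.
    """
    def per_tool(scores: pd.Series) -> pd.Series:
        n = len(scores)
        return pd.Series(
            {
                "pct_eq_100": 100.0 * (scores == 100).sum() / n,
                "pct_ge_80": 100.0 * (scores >= 80).sum() / n,
                "pct_ge_50": 100.0 * (scores >= 50).sum() / n,
            }
        )

    return frame.groupby("tool", sort=False)["first_choice"].apply(per_tool).unstack()


def error_rates(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-tool %mad and %wrong.

    %mad is the share of all attempts scored below zero (totally
    misleading).  %wrong is the share of attempts whose first suggestion
    was the wrong family or worse, among attempts that returned any
    identification — a similar-family suggestion does not count as wrong.
    """
    def per_tool(sub: pd.DataFrame) -> pd.Series:
        n_all = len(sub)
        pct_mad = 100.0 * (sub["first_choice"] < 0).sum() / n_all
        returned = sub[sub["returned_id"]]
        wrong = returned["first_category"].isin({c.value for c in WRONG_CATEGORIES})
        pct_wrong = 100.0 * wrong.sum() / len(returned) if len(returned) else 0.0
        return pd.Series({"pct_mad": pct_mad, "pct_wrong": pct_wrong})

    return frame.groupby("tool", sort=False)[["first_choice", "first_category", "returned_id"]].apply(per_tool)


def metrics_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Accuracy thresholds and error rates side by side (one row per tool)."""
    return pd.concat([accuracy_thresholds(frame), error_rates(frame)], axis=1)


def consistency_evaluation_table(
    consistency: pd.DataFrame,
    metadata: Mapping[str, SampleMeta] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tools x subsets matrix of mean consistency C, with per-subset ranks."""
    per_sample = consistency.rename(columns={"consistency_C": "score"})[
        ["tool", "sample", "score"]
    ]
    return evaluation_table(per_sample, metadata)


def format_report(
    table: pd.DataFrame,
    ranks: pd.DataFrame | None = None,
    decimals: int = 0,
    average_decimals: int = 1,
    letters: Mapping[str, str] | None = None,
) -> str:
    """Aligned plain-text rendering of a tools x subsets table.

    Subset means are rounded (half-up) to ``decimals``, the Average column
    to ``average_decimals``; per-subset ranks are shown in parentheses and
    letter groupings, when given, in a final column.
    """
    out = pd.DataFrame(index=table.index)
    for col in table.columns:
        d = average_decimals if col == "Average" else decimals
        values = [f"{round_half_up(v, d):.{d}f}" for v in table[col]]
        if ranks is not None and col in ranks.columns:
            rk = []
            for r in ranks[col]:
                rk.append(f"({int(r)})" if float(r).is_integer() else f"({r:g})")
            values = [f"{v} {k}" for v, k in zip(values, rk)]
        out[col] = values
    if letters is not None:
        out["letters"] = [letters.get(ix, "") for ix in table.index]
    return out.to_string()
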