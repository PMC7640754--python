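"""Rubric scoring of identification attempts.

Two scores are computed for every attempt:

* **first-choice score** — the rubric value of the top suggestion only
  (100 for the correct species down to -5 for a totally misleading one;
  0 when no identification was returned);
* **weighted score** — a sequential, upward-only update over up to the
  first four suggestions.  Starting from the first-choice value ``S1``,
  each later suggestion at rank ``k`` can close a fraction ``f_k`` of the
  gap between the running score and what that suggestion would have scored
  as first choice::

      S_k = S_{k-1} + f_k * max(0, v(c_k, k) - S_{k-1}),   f = (0.50, 0.25, 0.13)

  Downward differences never reduce the score, so the weighted score is
  always >= the first-choice score and is capped at 100.

The ``misleading`` grade is position dependent: -5/-4/-2 at ranks 1/2/3
(rank >= 4 carries the rank-3 value; being upward-only, it is inert unless
the running score is below -2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datamodel import (
    DEFAULT_BASE_VALUES,
    ConfigError,
    IdentificationRecord,
    MatchCategory,
    SampleMeta,
)


@dataclass(frozen=True)
class WeightScheme:
    """Weighting constants of the rubric.

    ``increment_fractions`` are the gap fractions applied at suggestion
    ranks 2, 3 and 4 — exactly as published (the rank-4 fraction is 0.13,
    not 0.125).  ``good_try_value`` is the score of a "similar looking
    plant" suggestion; the rubric prints a 10-20 range, defaulting here to
    the midpoint 15.
    """

    increment_fractions: tuple[float, float, float] = (0.50, 0.25, 0.13)
    misleading_position_values: tuple[float, float, float] = (-5.0, -4.0, -2.0)
    good_try_value: float = 15.0

    def __post_init__(self) -> None:
        f = self.increment_fractions
        if len(f) != 3 or not all(0.0 < x < 1.0 for x in f) or not f[0] > f[1] > f[2]:
            raise ConfigError(
                f"increment fractions must be 3 strictly decreasing values in (0, 1), got {f}"
            )
        if len(self.misleading_position_values) != 3:
            raise ConfigError("misleading values must cover positions 1-3")
        if not 10.0 <= self.good_try_value <= 20.0:
            raise ConfigError(
                f"good_try value must lie in the rubric's 10-20 range, got {self.good_try_value}"
            )


DEFAULT_SCHEME = WeightScheme()


def target_value(
    category: MatchCategory, position: int, scheme: WeightScheme = DEFAULT_SCHEME
) -> float:
    """Rubric value a suggestion would score if it were the first choice.

    Position only matters for ``misleading``; every other category is
    position-independent.
    """
    if position < 1:
        raise ConfigError(f"position must be >= 1, got {position}")
    if category is MatchCategory.MISLEADING:
        return scheme.misleading_position_values[min(position, 3) - 1]
    if category is MatchCategory.GOOD_TRY:
        return scheme.good_try_value
    return DEFAULT_BASE_VALUES[category]


def first_choice_score(
    record: IdentificationRecord, scheme: WeightScheme = DEFAULT_SCHEME
) -> float:
    """Rubric value of the top suggestion; 0 when nothing was returned."""
    if record.no_identification:
        return 0.0
    return target_value(record.suggestions[0].category, 1, scheme)


def weighted_score(
    record: IdentificationRecord, scheme: WeightScheme = DEFAULT_SCHEME
) -> float:
    """Upward-only sequential score over the first four suggestions."""
    if record.no_identification:
        return 0.0
    score = target_value(record.suggestions[0].category, 1, scheme)
    for k, suggestion in enumerate(record.suggestions[1:4], start=2):
        gap = target_value(suggestion.category, k, scheme) - score
        if gap > 0:
            score += scheme.increment_fractions[k - 2] * gap
    return score


@dataclass(frozen=True)
class ScoredRecord:
    """An identification attempt together with both rubric scores."""

    record: IdentificationRecord
    first_choice_score: float
    weighted_score: float


def score_record(record: IdentificationRecord, scheme: WeightScheme = DEFAULT_SCHEME) -> ScoredRecord:
    return ScoredRecord(record, first_choice_score(record, scheme), weighted_score(record, scheme))


def score_records(
    records: Iterable[IdentificationRecord], scheme: WeightScheme = DEFAULT_SCHEME
) -> list[ScoredRecord]:
    return [score_record(rec, scheme) for rec in records]


def scores_frame(scored: Iterable[ScoredRecord]) -> pd.DataFrame:
    """Tidy per-attempt frame: one row per (tool, sample, replicate).

    Columns: ``tool, sample, replicate, first_choice, weighted,
    first_category, returned_id``.
    """
    rows = []
    for sr in scored:
        rec = sr.record
        rows.append(
            {
                "tool": rec.tool_id,
                "sample": rec.sample_id,
                "replicate": rec.replicate,
                "first_choice": sr.first_choice_score,
                "weighted": sr.weighted_score,
                "first_category": rec.first_category.value,
                "returned_id": not rec.no_identification,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tool",
            "sample",
            "replicate",
            "first_choice",
            "weighted",
            "first_category",
            "returned_id",
        ],
    )
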