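"""Core domain types for ranked taxonomic identification records.

The atomic unit of an evaluation is one *identification attempt*: a tool is
shown one sample image once (one replicate) and returns an ordered run of
suggested taxa, or nothing at all.  Each suggestion carries a
:class:`MatchCategory` expressing how taxonomically close it is to the
reference determination of the sample.  Objective categories (correct
species / genus / family) can be derived mechanically from a reference
taxonomy with :func:`classify_exact`; the subjective grades (``very_close``,
``similar_genus``, ``good_try`` ...) encode expert judgement and therefore
only ever enter through explicit annotation in the input data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping


class EvalError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EvalError):
    """A file does not have the expected tabular structure."""


class ValidationError(EvalError):
    """Structurally well-formed input that violates a domain invariant."""


class ConfigError(EvalError):
    """An invalid configuration value."""


class UnresolvableTaxonError(ValidationError):
    """A taxon name absent from the reference taxonomy."""


class MatchCategory(str, Enum):
    """Closed vocabulary of taxonomic-match outcomes.

    Labels are parsed case-insensitively; any other string is rejected,
    never silently coerced.  ``no_id`` marks an attempt where the tool
    returned no identification at all — it scores 0 like ``unknown`` but is
    tracked separately because the wrong-family error rate excludes it from
    its denominator.
    """

    SPECIES_CORRECT = "species_correct"
    VERY_CLOSE = "very_close"
    SMALL_GENUS = "small_genus"
    GENUS_CORRECT = "genus_correct"
    SIMILAR_GENUS = "similar_genus"
    FAMILY_CORRECT = "family_correct"
    SIMILAR_FAMILY = "similar_family"
    GOOD_TRY = "good_try"
    UNKNOWN = "unknown"
    MISLEADING = "misleading"
    NO_ID = "no_id"

    @classmethod
    def parse(cls, label: str) -> "MatchCategory":
        key = str(label).strip().lower()
        try:
            return cls(key)
        except ValueError:
            raise ValidationError(
                f"unknown match category {label!r}; expected one of "
                f"{sorted(c.value for c in cls)}"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Position-independent rubric base values.  ``good_try`` is printed as a
#: range (10-20) in the source rubric and is configurable via the weighting
#: scheme; the value here is the default midpoint.  ``misleading`` is
#: position dependent (-5/-4/-2 at ranks 1/2/3) — see ``scoring.target_value``.
DEFAULT_BASE_VALUES: Mapping[MatchCategory, float] = {
    MatchCategory.SPECIES_CORRECT: 100.0,
    MatchCategory.VERY_CLOSE: 95.0,
    MatchCategory.SMALL_GENUS: 90.0,
    MatchCategory.GENUS_CORRECT: 80.0,
    MatchCategory.SIMILAR_GENUS: 70.0,
    MatchCategory.FAMILY_CORRECT: 50.0,
    MatchCategory.SIMILAR_FAMILY: 40.0,
    MatchCategory.GOOD_TRY: 15.0,
    MatchCategory.UNKNOWN: 0.0,
    MatchCategory.MISLEADING: -5.0,
    MatchCategory.NO_ID: 0.0,
}

#: Categories produced only by expert annotation, never by classify_exact.
SUBJECTIVE_CATEGORIES = frozenset(
    {
        MatchCategory.VERY_CLOSE,
        MatchCategory.SMALL_GENUS,
        MatchCategory.SIMILAR_GENUS,
        MatchCategory.SIMILAR_FAMILY,
        MatchCategory.GOOD_TRY,
        MatchCategory.MISLEADING,
    }
)

#: First-choice categories counted as "wrong family or worse".  A
#: ``similar_family`` suggestion (40 points) is *not* wrong: it still lands
#: in the right neighbourhood of the classification.  ``no_id`` is excluded
#: from the denominator of the wrong rate, not counted as wrong.
WRONG_CATEGORIES = frozenset(
    {MatchCategory.GOOD_TRY, MatchCategory.UNKNOWN, MatchCategory.MISLEADING}
)

#: First-choice categories that carry no usable family information when
#: counting distinct families across replicates.
IRRELEVANT_CATEGORIES = frozenset(
    {
        MatchCategory.GOOD_TRY,
        MatchCategory.UNKNOWN,
        MatchCategory.MISLEADING,
        MatchCategory.NO_ID,
    }
)

PLANT_PARTS = ("flower", "fruit", "leaf", "plant")
PLANT_TYPES = ("herb", "monocot", "woody")


@dataclass(frozen=True)
class TaxonRef:
    """A resolved taxon: binomial species name, its genus and family."""

    species_name: str
    genus: str
    family: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValidationError(f"taxon {self.species_name!r} has empty family")
        tokens = self.species_name.split()
        if len(tokens) >= 2 and tokens[0] != self.genus:
            raise ValidationError(
                f"binomial {self.species_name!r} does not start with genus "
                f"{self.genus!r}"
            )


@dataclass(frozen=True)
class Suggestion:
    """One ranked suggestion within an identification attempt.

    ``suggested_name`` may be empty when the tool returned a category-level
    judgement without a usable name.  Only positions 1-4 influence the
    weighted score; later positions are retained but inert.
    """

    position: int
    suggested_name: str
    category: MatchCategory

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"suggestion position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class IdentificationRecord:
    """One tool x sample x replicate attempt with its ordered suggestions.

    An empty suggestion run means the tool returned no identification
    (scored 0, flagged ``no_identification``).
    """

    tool_id: str
    sample_id: str
    replicate: int
    suggestions: tuple[Suggestion, ...] = ()

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"replicate index must be >= 1, got {self.replicate} "
                f"({self.tool_id}/{self.sample_id})"
            )
        positions = [s.position for s in self.suggestions]
        if positions != list(range(1, len(positions) + 1)):
            raise ValidationError(
                f"suggestion positions must be consecutive from 1, got {positions} "
                f"({self.tool_id}/{self.sample_id}/rep {self.replicate})"
            )
        if any(s.category is MatchCategory.NO_ID for s in self.suggestions):
            raise ValidationError(
                "no_id is not a per-suggestion category; encode a "
                "no-identification attempt as an empty suggestion run "
                f"({self.tool_id}/{self.sample_id}/rep {self.replicate})"
            )

    @property
    def no_identification(self) -> bool:
        return not self.suggestions

    @property
    def first_suggestion(self) -> Suggestion | None:
        return self.suggestions[0] if self.suggestions else None

    @property
    def first_category(self) -> MatchCategory:
        """Category of the top suggestion; ``no_id`` for an empty run."""
        return self.suggestions[0].category if self.suggestions else MatchCategory.NO_ID


@dataclass(frozen=True)
class SampleMeta:
    """Reference determination and grouping metadata for one sample image."""

    sample_id: str
    reference: TaxonRef
    plant_part: str
    plant_type: str

    def __post_init__(self) -> None:
        if self.plant_part not in PLANT_PARTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: plant_part {self.plant_part!r} "
                f"not in {PLANT_PARTS}"
            )
        if self.plant_type not in PLANT_TYPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: plant_type {self.plant_type!r} "
                f"not in {PLANT_TYPES}"
            )


def classify_exact(suggested: TaxonRef, reference: TaxonRef) -> MatchCategory:
    """Mechanical taxonomic match of a suggested taxon against the reference.

    Returns ``species_correct`` when the binomials agree, else
    ``genus_correct`` when the genera agree, else ``family_correct`` when the
    families agree, else ``unknown``.  Subjective grades are never produced
    here; they must come from annotation and may override this fallback.
    """
    if suggested.species_name == reference.species_name:
        return MatchCategory.SPECIES_CORRECT
    if suggested.genus == reference.genus:
        return MatchCategory.GENUS_CORRECT
    if suggested.family == reference.family:
        return MatchCategory.FAMILY_CORRECT
    return MatchCategory.UNKNOWN


def resolve_taxon(name: str, taxonomy: Mapping[str, TaxonRef]) -> TaxonRef:
    """Look up a species name in the reference taxonomy."""
    try:
        return taxonomy[name]
    except KeyError:
        raise UnresolvableTaxonError(f"taxon {name!r} not in reference taxonomy") from None


def check_unique_attempts(records: Iterable[IdentificationRecord]) -> None:
    """Enforce uniqueness of (tool, sample, replicate) across a record set."""
    seen: set[tuple[str, str, int]] = set()
    for rec in records:
        key = (rec.tool_id, rec.sample_id, rec.replicate)
        if key in seen:
            raise ValidationError(f"duplicate attempt {key}")
        seen.add(key)
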