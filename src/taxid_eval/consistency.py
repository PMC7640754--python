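"""Replicate consistency of identifications.

For one tool repeatedly shown the same sample image, the *inconsistency*
``I`` counts how taxonomically scattered the replicate answers are:

* count the distinct families named by the replicates' first suggestions,
  with every "irrelevant" answer (misleading, unknown, good-try or no
  identification at all) counted as its own singleton family;
* add 0.2 for each additional distinct genus+species combination beyond
  the first within any family.

With ``R`` replicates, ``I`` lies in ``[1, R]`` before the 0.2 additions.
The *consistency score* is ``C = R - I`` (``C = 5 - I`` in the reference
five-replicate design), so identical replicates give the maximum ``C = 4``
and five different families give ``C = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datamodel import (
    IRRELEVANT_CATEGORIES,
    IdentificationRecord,
    MatchCategory,
    SampleMeta,
    TaxonRef,
    ValidationError,
)

#: Sentinel entry for a replicate carrying no usable family information.
IRRELEVANT = None

#: A replicate's first-choice identity: (family, genus, species) strings,
#: or IRRELEVANT.
Entry = tuple[str, str, str] | None


@dataclass(frozen=True)
class ConsistencyResult:
    tool_id: str
    sample_id: str
    inconsistency_I: float
    consistency_C: float
    n_replicates: int


def inconsistency(entries: Sequence[Entry], n_replicates: int | None = None) -> float:
    """Inconsistency ``I`` over one tool x sample's replicate first choices.

    ``entries`` holds one item per replicate, in any order (``I`` is
    permutation invariant).  Each irrelevant entry counts as a separate
    singleton family and contributes no genus/species additions.
    """
    if n_replicates is None:
        n_replicates = len(entries)
    if n_replicates == 0:
        raise ValidationError("inconsistency needs at least one replicate")
    if len(entries) != n_replicates:
        raise ValidationError(
            f"expected {n_replicates} replicate entries, got {len(entries)}"
        )
    families: dict[str, set[tuple[str, str]]] = {}
    n_irrelevant = 0
    for entry in entries:
        if entry is IRRELEVANT:
            n_irrelevant += 1
            continue
        family, genus, species = entry
        families.setdefault(family, set()).add((genus, species))
    value = float(len(families) + n_irrelevant)
    for members in families.values():
        value += 0.2 * (len(members) - 1)
    return value


def consistency_score(inconsistency_value: float, n_replicates: int = 5) -> float:
    """``C = R - I``; the five-replicate design gives the familiar 0-4 range."""
    if inconsistency_value < 1:
        raise ValidationError(f"I must be >= 1, got {inconsistency_value}")
    return n_replicates - inconsistency_value


def normalized_consistency(consistency_value: float, n_replicates: int = 5) -> float:
    """``C / (R - 1)``: a 0-1 scale comparable across replicate designs."""
    if n_replicates < 2:
        raise ValidationError("normalization needs R >= 2")
    return consistency_value / (n_replicates - 1)


def first_choice_entry(
    record: IdentificationRecord,
    taxonomy: Mapping[str, TaxonRef],
    reference: TaxonRef,
) -> Entry:
    """Family/genus/species identity of a record's first suggestion.

    Irrelevant grades (misleading, unknown, good-try, no identification)
    yield the IRRELEVANT sentinel.  For relevant grades the suggested name
    is resolved in the taxonomy; when it cannot be resolved (vernacular or
    off-list name), grades that imply agreement with the reference fall
    back to the reference's classification at the implied level, and
    "similar" grades key on the literal suggested name so that distinct
    names stay distinct.
    """
    if record.no_identification:
        return IRRELEVANT
    first = record.suggestions[0]
    if first.category in IRRELEVANT_CATEGORIES:
        return IRRELEVANT
    taxon = taxonomy.get(first.suggested_name)
    if taxon is not None:
        return (taxon.family, taxon.genus, taxon.species_name)
    name = first.suggested_name or f"<unnamed:{first.category.value}>"
    cat = first.category
    if cat in (MatchCategory.SPECIES_CORRECT, MatchCategory.VERY_CLOSE):
        return (reference.family, reference.genus, reference.species_name)
    if cat in (MatchCategory.SMALL_GENUS, MatchCategory.GENUS_CORRECT):
        return (reference.family, reference.genus, name)
    if cat is MatchCategory.FAMILY_CORRECT:
        return (reference.family, name, name)
    # similar_genus / similar_family with an unresolvable name: the named
    # taxon is outside the reference taxonomy; key everything on the name.
    return (name, name, name)


def consistency_results(
    records: Iterable[IdentificationRecord],
    taxonomy: Mapping[str, TaxonRef],
    metadata: Mapping[str, SampleMeta],
    n_replicates: int = 5,
    strict: bool = True,
) -> list[ConsistencyResult]:
    """Per-(tool, sample) inconsistency and consistency over replicates.

    With ``strict=False`` a tool x sample with fewer than ``n_replicates``
    attempts is evaluated over the replicates present (R = count), instead
    of raising.
    """
    grouped: dict[tuple[str, str], list[IdentificationRecord]] = {}
    for rec in records:
        if rec.sample_id not in metadata:
            raise ValidationError(f"sample {rec.sample_id!r} missing from metadata")
        grouped.setdefault((rec.tool_id, rec.sample_id), []).append(rec)

    results = []
    for (tool, sample), recs in grouped.items():
        reference = metadata[sample].reference
        entries = [first_choice_entry(r, taxonomy, reference) for r in recs]
        if strict and len(entries) != n_replicates:
            raise ValidationError(
                f"{tool}/{sample}: expected {n_replicates} replicates, got {len(entries)}"
            )
        r_used = n_replicates if strict else len(entries)
        value = inconsistency(entries, r_used)
        results.append(
            ConsistencyResult(tool, sample, value, consistency_score(value, r_used), r_used)
        )
    return results


def consistency_frame(results: Iterable[ConsistencyResult]) -> pd.DataFrame:
    """Tidy frame: one row per (tool, sample) with I and C."""
    return pd.DataFrame(
        [
            {
                "tool": r.tool_id,
                "sample": r.sample_id,
                "inconsistency_I": r.inconsistency_I,
                "consistency_C": r.consistency_C,
                "n_replicates": r.n_replicates,
            }
            for r in results
        ],
        columns=["tool", "sample", "inconsistency_I", "consistency_C", "n_replicates"],
    )
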