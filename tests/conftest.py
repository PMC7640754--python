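"""Shared fixtures: a small hand-built taxonomy, metadata and record helpers."""

from __future__ import annotations

import pytest

from taxid_eval.datamodel import (
    IdentificationRecord,
    MatchCategory,
    SampleMeta,
    Suggestion,
    TaxonRef,
)

C = MatchCategory


def make_record(
    categories,
    tool="toolA",
    sample="s1",
    replicate=1,
    names=None,
):
    """Build a record from a category sequence (positions assigned 1..n)."""
    categories = list(categories)
    if names is None:
        names = [""] * len(categories)
    suggestions = tuple(
        Suggestion(i + 1, name, cat)
        for i, (cat, name) in enumerate(zip(categories, names))
    )
    return IdentificationRecord(tool, sample, replicate, suggestions)


@pytest.fixture
def taxonomy():
    taxa = [
        TaxonRef("Quercus robur", "Quercus", "Fagaceae"),
        TaxonRef("Quercus petraea", "Quercus", "Fagaceae"),
        TaxonRef("Fagus sylvatica", "Fagus", "Fagaceae"),
        TaxonRef("Rosa canina", "Rosa", "Rosaceae"),
        TaxonRef("Crataegus monogyna", "Crataegus", "Rosaceae"),
        TaxonRef("Prunus spinosa", "Prunus", "Rosaceae"),
        TaxonRef("Poa annua", "Poa", "Poaceae"),
        TaxonRef("Lolium perenne", "Lolium", "Poaceae"),
        TaxonRef("Lamium album", "Lamium", "Lamiaceae"),
        TaxonRef("Urtica dioica", "Urtica", "Urticaceae"),
    ]
    return {t.species_name: t for t in taxa}


@pytest.fixture
def metadata(taxonomy):
    rows = [
        ("s1", "Quercus robur", "leaf", "woody"),
        ("s2", "Rosa canina", "flower", "woody"),
        ("s3", "Poa annua", "plant", "monocot"),
        ("s4", "Lamium album", "flower", "herb"),
    ]
    return {
        sample: SampleMeta(sample, taxonomy[species], part, ptype)
        for sample, species, part, ptype in rows
    }
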