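"""Tabular readers and writers for records, taxonomy and sample metadata.

File formats (UTF-8 CSV; TSV accepted for records via the ``sep`` argument
or a ``.tsv`` extension):

* records: columns ``tool,sample,replicate,position,suggested_name,category``
  with one row per suggestion.  A row with ``position=0`` and
  ``category=no_id`` encodes an attempt where the tool returned nothing.
* taxonomy: columns ``species,genus,family``.
* sample metadata: columns ``sample,species,plant_part,plant_type``; the
  ``species`` column names the reference determination and must resolve in
  the taxonomy.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datamodel import (
    PLANT_PARTS,
    PLANT_TYPES,
    FormatError,
    IdentificationRecord,
    MatchCategory,
    SampleMeta,
    Suggestion,
    TaxonRef,
    ValidationError,
)

RECORD_COLUMNS = ("tool", "sample", "replicate", "position", "suggested_name", "category")
TAXONOMY_COLUMNS = ("species", "genus", "family")
METADATA_COLUMNS = ("sample", "species", "plant_part", "plant_type")


def _infer_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if os.path.splitext(path)[1].lower() in {".tsv", ".tab"} else ","


def _read_table(path: str, required: Sequence[str], sep: str | None = None) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV structure
        raise FormatError(f"could not parse {path}: {exc}") from exc
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return frame


def _parse_int(value: str, what: str, row: int, path: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"{path} row {row}: {what} {value!r} is not an integer") from None


def read_records(path: str, sep: str | None = None) -> list[IdentificationRecord]:
    """Read identification attempts grouped by (tool, sample, replicate).

    Row numbers in error messages count the header as row 1.  Category
    labels are parsed case-insensitively against the closed vocabulary.
    """
    frame = _read_table(path, RECORD_COLUMNS, sep)
    grouped: dict[tuple[str, str, int], dict[int, Suggestion]] = {}
    no_id_keys: set[tuple[str, str, int]] = set()
    order: list[tuple[str, str, int]] = []

    for i, row in enumerate(frame.itertuples(index=False)):
        rownum = i + 2
        key = (
            str(row.tool),
            str(row.sample),
            _parse_int(row.replicate, "replicate", rownum, path),
        )
        position = _parse_int(row.position, "position", rownum, path)
        try:
            category = MatchCategory.parse(row.category)
        except ValidationError as exc:
            raise ValidationError(f"{path} row {rownum}: {exc}") from None
        if key not in grouped and key not in no_id_keys:
            order.append(key)
        if position == 0:
            if category is not MatchCategory.NO_ID:
                raise ValidationError(
                    f"{path} row {rownum}: position 0 is reserved for no_id rows"
                )
            if key in no_id_keys or grouped.get(key):
                raise ValidationError(
                    f"{path} row {rownum}: duplicate or conflicting no_id row for {key}"
                )
            no_id_keys.add(key)
            grouped.setdefault(key, {})
            continue
        if category is MatchCategory.NO_ID:
            raise ValidationError(
                f"{path} row {rownum}: no_id must be encoded with position 0"
            )
        if key in no_id_keys:
            raise ValidationError(
                f"{path} row {rownum}: suggestion given for attempt {key} "
                "already marked no_id"
            )
        slots = grouped.setdefault(key, {})
        if position in slots:
            raise ValidationError(
                f"{path} row {rownum}: duplicate position {position} for {key}"
            )
        slots[position] = Suggestion(position, str(row.suggested_name), category)

    records = []
    for key in order:
        tool, sample, replicate = key
        suggestions = tuple(s for _, s in sorted(grouped[key].items()))
        records.append(IdentificationRecord(tool, sample, replicate, suggestions))
    return records


def write_records(records: Iterable[IdentificationRecord], path: str, sep: str | None = None) -> None:
    """Write records in the format ``read_records`` consumes (round-trip safe)."""
    rows = []
    for rec in records:
        if rec.no_identification:
            rows.append((rec.tool_id, rec.sample_id, rec.replicate, 0, "", "no_id"))
        for s in rec.suggestions:
            rows.append(
                (rec.tool_id, rec.sample_id, rec.replicate, s.position, s.suggested_name, s.category.value)
            )
    frame = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    frame.to_csv(path, sep=_infer_sep(path, sep), index=False)


def read_taxonomy(path: str) -> dict[str, TaxonRef]:
    """Read the reference taxonomy into a species -> TaxonRef lookup.

    Identical duplicate rows collapse to one entry; duplicates that
    disagree on genus or family are rejected.
    """
    frame = _read_table(path, TAXONOMY_COLUMNS)
    taxonomy: dict[str, TaxonRef] = {}
    for i, row in enumerate(frame.itertuples(index=False)):
        taxon = TaxonRef(str(row.species), str(row.genus), str(row.family))
        existing = taxonomy.get(taxon.species_name)
        if existing is not None and existing != taxon:
            raise ValidationError(
                f"{path} row {i + 2}: species {taxon.species_name!r} listed with "
                f"conflicting classification ({existing.genus}/{existing.family} "
                f"vs {taxon.genus}/{taxon.family})"
            )
        taxonomy[taxon.species_name] = taxon
    return taxonomy


def write_taxonomy(taxonomy: Mapping[str, TaxonRef], path: str) -> None:
    frame = pd.DataFrame(
        [(t.species_name, t.genus, t.family) for t in taxonomy.values()],
        columns=TAXONOMY_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_metadata(path: str, taxonomy: Mapping[str, TaxonRef]) -> dict[str, SampleMeta]:
    """Read per-sample metadata; reference species must resolve in the taxonomy."""
    frame = _read_table(path, METADATA_COLUMNS)
    meta: dict[str, SampleMeta] = {}
    for i, row in enumerate(frame.itertuples(index=False)):
        rownum = i + 2
        sample = str(row.sample)
        if sample in meta:
            raise ValidationError(f"{path} row {rownum}: duplicate sample {sample!r}")
        species = str(row.species)
        if species not in taxonomy:
            raise ValidationError(
                f"{path} row {rownum}: reference species {species!r} for sample "
                f"{sample!r} not in taxonomy"
            )
        part = str(row.plant_part).strip().lower()
        ptype = str(row.plant_type).strip().lower()
        meta[sample] = SampleMeta(sample, taxonomy[species], part, ptype)
    return meta


def write_metadata(metadata: Mapping[str, SampleMeta] | Iterable[SampleMeta], path: str) -> None:
    items = metadata.values() if isinstance(metadata, Mapping) else metadata
    frame = pd.DataFrame(
        [(m.sample_id, m.reference.species_name, m.plant_part, m.plant_type) for m in items],
        columns=METADATA_COLUMNS,
    )
    frame.to_csv(path, index=False)


def metadata_frame(metadata: Mapping[str, SampleMeta]) -> pd.DataFrame:
    """Tidy DataFrame view of sample metadata (one row per sample)."""
    return pd.DataFrame(
        [
            {
                "sample": m.sample_id,
                "species": m.reference.species_name,
                "plant_part": m.plant_part,
                "plant_type": m.plant_type,
            }
            for m in metadata.values()
        ]
    )


def write_report(frame: pd.DataFrame, path: str, decimals: int = 1) -> None:
    """Serialize a report table; scores formatted with fixed decimals."""
    frame.to_csv(path, float_format=f"%.{decimals}f")
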