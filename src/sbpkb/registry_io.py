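"""Read, validate and normalize Registry-style parts and sequence-feature tables.

The Registry of Standard Biological Parts distributes its parts and
Sequence Feature tables as database dumps; this module consumes (and, for
fixtures, emits) a delimited-text rendering of those tables: tab-separated,
UTF-8, one header row, the multi-valued category cell joined by single
spaces, and an empty cell for a missing DNA sequence.  A minimal reader for
the original one-element-per-row XML dump shape is provided behind the same
record types.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TableDialect",
    "PartRecord",
    "FeatureRecord",
    "ValidationReport",
    "TableParseError",
    "RecordValidationError",
    "STANDARD_STATUSES",
    "normalize_status",
    "read_parts_table",
    "read_features_table",
    "write_parts_table",
    "write_features_table",
    "read_parts_xml",
    "read_features_xml",
    "validate_records",
]

#: Canonical status vocabulary.  Unknown tokens are preserved verbatim and
#: surfaced by :func:`validate_records` rather than silently dropped.
STANDARD_STATUSES = frozenset(
    {"Available", "Sent", "Deleted", "Planning", "Unavailable"}
)

_SEQUENCE_ALPHABET = frozenset("acgt")

PART_COLUMNS = (
    "id",
    "name",
    "type",
    "short_desc",
    "long_desc",
    "author",
    "owner_id",
    "status",
    "date",
    "categories",
    "sequence",
)

FEATURE_COLUMNS = (
    "id",
    "part_id",
    "label",
    "feature_type",
    "start",
    "end",
    "direction",
)


class TableParseError(ValueError):
    """A table file is structurally malformed (names the offending line)."""


class RecordValidationError(ValueError):
    """A record violates an invariant that cannot be deferred to reporting."""


@dataclass(frozen=True)
class TableDialect:
    """Concrete delimited-text rendering of the Registry dump tables."""

    delimiter: str = "\t"
    encoding: str = "utf-8"
    category_sep: str = " "


DEFAULT_DIALECT = TableDialect()


def normalize_status(raw: str) -> str:
    """Map a raw status token to the canonical vocabulary, case-insensitively.

    Tokens outside the vocabulary come back stripped but otherwise verbatim,
    so nothing is lost; callers detect them via membership in
    :data:`STANDARD_STATUSES`.
    """
    token = raw.strip()
    for canonical in STANDARD_STATUSES:
        if token.lower() == canonical.lower():
            return canonical
    return token


@dataclass(frozen=True)
class PartRecord:
    """One row of the Registry parts table.

    ``status`` holds the normalized token, ``status_raw`` the as-read cell;
    ``date`` is kept verbatim (no date arithmetic is ever performed on it).
    ``dna_sequence`` is lower-cased; empty string means no sequence deposited.
    """

    registry_id: int
    name: str
    part_type: str = ""
    short_desc: str = ""
    long_desc: str = ""
    author: str = ""
    owner_id: int = 0
    status: str = "Available"
    date: str = ""
    categories: tuple[str, ...] = ()
    dna_sequence: str = ""
    status_raw: str = ""

    def __post_init__(self) -> None:
        if self.registry_id <= 0:
            raise RecordValidationError(
                f"registry_id must be positive, got {self.registry_id}"
            )
        if not self.name:
            raise RecordValidationError("part name must be non-empty")
        if not self.status_raw:
            object.__setattr__(self, "status_raw", self.status)
        object.__setattr__(self, "status", normalize_status(self.status))
        object.__setattr__(self, "dna_sequence", self.dna_sequence.strip().lower())
        object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def has_sequence(self) -> bool:
        return bool(self.dna_sequence)

    @property
    def sequence_is_clean(self) -> bool:
        return set(self.dna_sequence) <= _SEQUENCE_ALPHABET


@dataclass(frozen=True)
class FeatureRecord:
    """One position-based sequence-feature row, linked to a part.

    Coordinates are 1-based inclusive on the part's own sequence, the
    Registry web convention.
    """

    feature_id: int
    part_registry_id: int
    label: str
    feature_type: str = ""
    start: int = 1
    end: int = 1
    direction: str = "forward"

    def __post_init__(self) -> None:
        if self.feature_id <= 0:
            raise RecordValidationError(
                f"feature_id must be positive, got {self.feature_id}"
            )
        if not (1 <= self.start <= self.end):
            raise RecordValidationError(
                f"feature {self.feature_id}: require 1 <= start <= end, "
                f"got start={self.start} end={self.end}"
            )
        if self.direction not in ("forward", "reverse"):
            raise RecordValidationError(
                f"feature {self.feature_id}: direction must be forward/reverse, "
                f"got {self.direction!r}"
            )


@dataclass(frozen=True)
class ValidationReport:
    """Defect inventory over a (parts, features) table pair.

    Purely reporting: nothing is mutated or dropped.  ``missing_sequence_ids``
    is not necessarily a defect (many Registry parts legitimately lack a
    deposited sequence) but the cleaning queries need it surfaced.
    """

    orphan_features: tuple[int, ...] = ()
    missing_sequence_ids: tuple[int, ...] = ()
    duplicate_ids: tuple[int, ...] = ()
    nonstandard_status: tuple[tuple[int, str], ...] = ()
    invalid_sequence_ids: tuple[int, ...] = ()

    @property
    def has_defects(self) -> bool:
        """True if structurally broken records exist (missing sequences and
        nonstandard statuses are data facts, not structural defects)."""
        return bool(
            self.orphan_features or self.duplicate_ids or self.invalid_sequence_ids
        )


def _parse_int(cell: str, what: str, lineno: int) -> int:
    try:
        return int(cell)
    except ValueError:
        raise TableParseError(
            f"line {lineno}: {what} must be an integer, got {cell!r}"
        ) from None


def _read_rows(
    path: str | Path, dialect: TableDialect, expected_header: Sequence[str]
) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding=dialect.encoding, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise TableParseError(f"{path}: empty file, expected a header row")
        if header != list(expected_header):
            raise TableParseError(
                f"{path}: header {header!r} does not match dialect "
                f"{list(expected_header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected_header):
                raise TableParseError(
                    f"{path}: line {lineno}: expected {len(expected_header)} "
                    f"columns, found {len(row)}"
                )
            yield lineno, row


def read_parts_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[PartRecord]:
    """Parse a parts table; one :class:`PartRecord` per data row.

    The category cell is split on the dialect separator into a list of
    category paths; the sequence is lower-cased.  A duplicate ``id`` raises,
    since every downstream mapping keys on it.
    """
    records: list[PartRecord] = []
    seen: dict[int, int] = {}
    for lineno, row in _read_rows(path, dialect, PART_COLUMNS):
        rid = _parse_int(row[0], "id", lineno)
        if rid in seen:
            raise RecordValidationError(
                f"{path}: line {lineno}: duplicate registry id {rid} "
                f"(first seen line {seen[rid]})"
            )
        seen[rid] = lineno
        categories = tuple(
            tok for tok in row[9].split(dialect.category_sep) if tok
        )
        records.append(
            PartRecord(
                registry_id=rid,
                name=row[1],
                part_type=row[2],
                short_desc=row[3],
                long_desc=row[4],
                author=row[5],
                owner_id=_parse_int(row[6], "owner_id", lineno),
                status=row[7],
                date=row[8],
                categories=categories,
                dna_sequence=row[10],
                status_raw=row[7].strip(),
            )
        )
    return records


def read_features_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[FeatureRecord]:
    """Parse a sequence-feature table; positions parsed as integers."""
    records: list[FeatureRecord] = []
    for lineno, row in _read_rows(path, dialect, FEATURE_COLUMNS):
        records.append(
            FeatureRecord(
                feature_id=_parse_int(row[0], "id", lineno),
                part_registry_id=_parse_int(row[1], "part_id", lineno),
                label=row[2],
                feature_type=row[3],
                start=_parse_int(row[4], "start", lineno),
                end=_parse_int(row[5], "end", lineno),
                direction=row[6],
            )
        )
    return records


def write_parts_table(
    records: Iterable[PartRecord],
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    with open(path, "w", encoding=dialect.encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(PART_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.registry_id,
                    r.name,
                    r.part_type,
                    r.short_desc,
                    r.long_desc,
                    r.author,
                    r.owner_id,
                    r.status_raw,
                    r.date,
                    dialect.category_sep.join(r.categories),
                    r.dna_sequence,
                ]
            )


def write_features_table(
    records: Iterable[FeatureRecord],
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    with open(path, "w", encoding=dialect.encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(FEATURE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.feature_id,
                    r.part_registry_id,
                    r.label,
                    r.feature_type,
                    r.start,
                    r.end,
                    r.direction,
                ]
            )


def _xml_rows(path: str | Path) -> Iterable[dict[str, str]]:
    # MySQL XML dump shape: <resultset><row><field name="...">value</field>...
    root = ET.parse(path).getroot()
    for row in root.iter("row"):
        cells: dict[str, str] = {}
        for f in row.iter("field"):
            cells[f.get("name", "")] = f.text or ""
        yield cells


def read_parts_xml(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[PartRecord]:
    """Read the original XML dump shape (one <row> element per record)."""
    records = []
    for cells in _xml_rows(path):
        records.append(
            PartRecord(
                registry_id=int(cells["id"]),
                name=cells["name"],
                part_type=cells.get("type", ""),
                short_desc=cells.get("short_desc", ""),
                long_desc=cells.get("long_desc", ""),
                author=cells.get("author", ""),
                owner_id=int(cells.get("owner_id", "0") or 0),
                status=cells.get("status", ""),
                date=cells.get("date", ""),
                categories=tuple(
                    t
                    for t in cells.get("categories", "").split(dialect.category_sep)
                    if t
                ),
                dna_sequence=cells.get("sequence", ""),
                status_raw=cells.get("status", "").strip(),
            )
        )
    return records


def read_features_xml(path: str | Path) -> list[FeatureRecord]:
    records = []
    for cells in _xml_rows(path):
        records.append(
            FeatureRecord(
                feature_id=int(cells["id"]),
                part_registry_id=int(cells["part_id"]),
                label=cells.get("label", ""),
                feature_type=cells.get("feature_type", ""),
                start=int(cells["start"]),
                end=int(cells["end"]),
                direction=cells.get("direction", "forward"),
            )
        )
    return records


def validate_records(
    parts: Sequence[PartRecord], features: Sequence[FeatureRecord]
) -> ValidationReport:
    """Enumerate defects across a table pair without mutating anything.

    Reports: features whose part foreign key resolves to nothing, parts
    without a deposited sequence, duplicated registry ids, statuses outside
    the canonical vocabulary, and sequences containing non-ACGT characters.
    """
    ids_seen: set[int] = set()
    duplicates: list[int] = []
    for p in parts:
        if p.registry_id in ids_seen and p.registry_id not in duplicates:
            duplicates.append(p.registry_id)
        ids_seen.add(p.registry_id)
    missing = [p.registry_id for p in parts if not p.has_sequence]
    invalid = [
        p.registry_id for p in parts if p.has_sequence and not p.sequence_is_clean
    ]
    nonstandard = [
        (p.registry_id, p.status_raw)
        for p in parts
        if p.status not in STANDARD_STATUSES
    ]
    orphans = [
        f.feature_id for f in features if f.part_registry_id not in ids_seen
    ]
    return ValidationReport(
        orphan_features=tuple(orphans),
        missing_sequence_ids=tuple(missing),
        duplicate_ids=tuple(duplicates),
        nonstandard_status=tuple(nonstandard),
        invalid_sequence_ids=tuple(invalid),
    )
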