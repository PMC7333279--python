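"""Dictionary/reference tables backing dictionary composite CDEs.

A dictionary table is a keyed reference table (typically a lab-test
catalogue) whose rows supply, per key:

* a unit list in a ``'^'``-delimited cell, e.g. ``mEq/L^mmol/L``;
* a unit -> normal-range map in a JSON-encoded cell, e.g.
  ``{"mEq/L": "135 ~ 145", "mmol/L": "135 ~ 145"}``.

A dictionary cCDE links to such a table through a *variable* foreign-key
member; validation checks the key, the entered unit, the result against
the unit-specific inclusive normal range, the abnormal flag against the
range verdict, and the "clinically significant" dependency.
"""

from __future__ import annotations

import csv
import io as _io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

__all__ = [
    "DictionaryError",
    "UnknownKeyError",
    "UnknownUnitError",
    "NumericInterval",
    "DictionaryTable",
    "parse_units",
    "parse_range",
    "load_dictionary",
    "lookup_normal_range",
]


class DictionaryError(ValueError):
    """Malformed dictionary content (bad range, empty unit, dup key ...)."""


class UnknownKeyError(KeyError):
    """Lookup key is not a primary key of the table."""


class UnknownUnitError(KeyError):
    """Key exists but does not offer the requested unit."""


@dataclass(frozen=True)
class NumericInterval:
    """Inclusive numeric reference interval ``[lo, hi]``."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.hi):
            raise DictionaryError(f"interval lower bound exceeds upper: {self.lo}~{self.hi}")

    def __contains__(self, x: float) -> bool:
        return self.lo <= float(x) <= self.hi


_RANGE_RE = re.compile(r"\s*(-?\d+(?:\.\d+)?)\s*~\s*(-?\d+(?:\.\d+)?)\s*\Z")


def parse_units(cell: str) -> list:
    """Split a ``'^'``-delimited unit cell, trimming and preserving order."""
    if cell is None or not cell.strip():
        raise DictionaryError("empty unit cell")
    units = []
    for seg in cell.split("^"):
        seg = seg.strip()
        if not seg:
            raise DictionaryError(f"empty unit segment in {cell!r}")
        units.append(seg)
    return units


def parse_range(spec: str) -> NumericInterval:
    """Parse ``"<lo> ~ <hi>"`` into an inclusive interval."""
    m = _RANGE_RE.match(spec or "")
    if m is None:
        raise DictionaryError(f"malformed range spec: {spec!r}")
    return NumericInterval(float(m.group(1)), float(m.group(2)))


@dataclass
class DictionaryTable:
    id: str
    key_column: str
    unit_column: str
    range_column: str
    rows: dict = field(default_factory=dict)  # key -> raw attribute map
    source: Optional[str] = None  # CSV path the table was loaded from
    columns: tuple = ()

    def keys(self) -> Iterable[str]:
        return self.rows.keys()

    def __contains__(self, key: str) -> bool:
        return key in self.rows

    def row(self, key: str) -> dict:
        try:
            return self.rows[key]
        except KeyError:
            raise UnknownKeyError(f"{self.id}: unknown key {key!r}") from None

    def units(self, key: str) -> list:
        return parse_units(self.row(key)[self.unit_column])

    def ranges(self, key: str) -> dict:
        cell = self.row(key)[self.range_column]
        try:
            mapping = json.loads(cell)
        except json.JSONDecodeError as exc:
            raise DictionaryError(f"{self.id}[{key!r}]: range cell is not JSON: {exc}")
        if not isinstance(mapping, dict):
            raise DictionaryError(f"{self.id}[{key!r}]: range cell must be a JSON object")
        return {unit: parse_range(spec) for unit, spec in mapping.items()}

    def normal_range(self, key: str, unit: str) -> NumericInterval:
        ranges = self.ranges(key)
        if unit not in ranges:
            raise UnknownUnitError(
                f"{self.id}[{key!r}]: no normal range for unit {unit!r}"
                f" (offers {sorted(ranges)})"
            )
        return ranges[unit]


def load_dictionary(
    source: Union[str, Path, _io.TextIOBase],
    *,
    table_id: str,
    key_column: str,
    unit_column: str,
    range_column: str,
) -> DictionaryTable:
    """Load and verify a dictionary table from CSV.

    Every row is checked on load: unique non-empty key, parseable unit
    list, strict-JSON range map whose every unit appears in the row's unit
    list and whose every range is a valid interval.  Violations name the
    offending row number (header = row 1).
    """
    path: Optional[str] = None
    if isinstance(source, (str, Path)):
        path = str(source)
        fh = open(source, newline="", encoding="utf-8")
    else:
        fh = source
    try:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in (key_column, unit_column, range_column):
            if col not in header:
                raise DictionaryError(f"{table_id}: missing column {col!r}")
        table = DictionaryTable(
            id=table_id,
            key_column=key_column,
            unit_column=unit_column,
            range_column=range_column,
            source=path,
            columns=tuple(header),
        )
        for lineno, row in enumerate(reader, start=2):
            key = (row.get(key_column) or "").strip()
            if not key:
                raise DictionaryError(f"{table_id} row {lineno}: empty key")
            if key in table.rows:
                raise DictionaryError(f"{table_id} row {lineno}: duplicate key {key!r}")
            table.rows[key] = {k: (v if v is not None else "") for k, v in row.items()}
            units = parse_units(row[unit_column])
            try:
                ranges = table.ranges(key)
            except DictionaryError as exc:
                raise DictionaryError(f"{table_id} row {lineno}: {exc}") from None
            for unit in ranges:
                if unit not in units:
                    raise DictionaryError(
                        f"{table_id} row {lineno}: range unit {unit!r} not in unit"
                        f" list {units}"
                    )
    finally:
        if path is not None:
            fh.close()
    return table


def lookup_normal_range(table: DictionaryTable, key: str, unit: str) -> NumericInterval:
    """Normal range for exactly (key, unit); missing unit and missing key
    raise distinct errors."""
    return table.normal_range(key, unit)
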