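"""Readers and writers for the registry JSON dialect and record files.

The registry serializes to a single JSON document with three top-level
arrays — ``data_elements``, ``rules``, ``dictionaries`` — where dictionary
entries are descriptors naming their CSV source.  Saving is canonical
(sorted keys, two-space indent, trailing newline) so files are diff-stable
and ``save(load(x)) == x`` byte-for-byte on files in canonical form.

Records travel as CSV (header = CDE ids, one row per record, ``__set_id``
grouping rows of a repeated cCDE, ``<id>__unit`` columns for entered
units) or as an equivalent JSON array of objects.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import List, Optional, Union

from . import dictionary as dl
from . import registry as rc
from . import rules as rl
from .validation import DataRecord, RecordSet

__all__ = [
    "RegistryFormatError",
    "load_registry",
    "save_registry",
    "load_records",
    "save_records",
]

log = logging.getLogger("cdekit")

SET_COLUMN = "__set_id"
UNIT_SUFFIX = "__unit"

_ELEMENT_KEYS = {
    "id", "name", "definition", "semantic_type", "subtype", "kind",
    "value_domain", "members", "vocabulary_ref", "dictionary_ref",
    "dictionary_roles", "rule_ids", "dec",
}
_DOMAIN_KEYS = {"datatype", "unit", "permissible_values", "format"}
_RULE_KEYS = {"id", "kind", "expr", "target", "description"}
_DICT_KEYS = {"id", "source", "key_column", "unit_column", "range_column"}
_TOP_KEYS = {"data_elements", "rules", "dictionaries"}


class RegistryFormatError(ValueError):
    """Registry JSON does not conform to the dialect."""


def _check_keys(obj: dict, allowed: set, where: str, strict: bool) -> None:
    unknown = sorted(set(obj) - allowed)
    if unknown:
        msg = f"{where}: unknown keys {unknown}"
        if strict:
            raise RegistryFormatError(msg)
        log.warning("%s (ignored in lenient mode)", msg)


def _domain_from_json(payload: Optional[dict], where: str, strict: bool):
    if payload is None:
        return None
    _check_keys(payload, _DOMAIN_KEYS, where + "/value_domain", strict)
    pv = payload.get("permissible_values")
    return rc.ValueDomain(
        datatype=payload["datatype"],
        unit_of_measure=payload.get("unit"),
        permissible_values=tuple((p[0], p[1]) for p in pv) if pv else None,
        format=payload.get("format"),
    )


def _domain_to_json(domain: Optional[rc.ValueDomain]) -> Optional[dict]:
    if domain is None:
        return None
    out: dict = {"datatype": domain.datatype}
    if domain.unit_of_measure is not None:
        out["unit"] = domain.unit_of_measure
    if domain.permissible_values:
        out["permissible_values"] = [list(p) for p in domain.permissible_values]
    if domain.format is not None:
        out["format"] = domain.format
    return out


def load_registry(path: Union[str, Path], *, mode: str = "strict") -> rc.Registry:
    """Load a registry document; ``mode`` is ``strict`` (unknown keys are
    errors) or ``lenient`` (warned and ignored)."""
    strict = mode == "strict"
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise RegistryFormatError(f"{path}: not valid JSON: {exc}") from None
    _check_keys(payload, _TOP_KEYS, str(path), strict)
    reg = rc.Registry()

    for i, desc in enumerate(payload.get("dictionaries", ())):
        _check_keys(desc, _DICT_KEYS, f"/dictionaries/{i}", strict)
        source = desc["source"]
        table = dl.load_dictionary(
            path.parent / source,
            table_id=desc["id"],
            key_column=desc["key_column"],
            unit_column=desc["unit_column"],
            range_column=desc["range_column"],
        )
        table.source = source  # keep the relative spec for round-tripping
        reg.add_dictionary(table)

    for i, rdesc in enumerate(payload.get("rules", ())):
        _check_keys(rdesc, _RULE_KEYS, f"/rules/{i}", strict)
        reg.add_rule(
            rdesc.get("expr"),
            id=rdesc["id"],
            kind=rl.RuleKind(rdesc["kind"]) if "kind" in rdesc else None,
            target=rdesc.get("target"),
            description=rdesc.get("description", ""),
        )

    # register in file order, deferring elements whose members are not yet
    # known, so dependency-consistent files round-trip in order
    pending = list(enumerate(payload.get("data_elements", ())))
    while pending:
        progressed = False
        deferred = []
        for i, el in pending:
            _check_keys(el, _ELEMENT_KEYS, f"/data_elements/{i}", strict)
            members = el.get("members", ())
            if any(m not in reg.cdes for m in members):
                deferred.append((i, el))
                continue
            _register_element(reg, el, f"/data_elements/{i}")
            progressed = True
        if not progressed:
            missing = {
                m
                for _, el in deferred
                for m in el.get("members", ())
                if m not in reg.cdes
            }
            raise RegistryFormatError(
                f"unresolved member references: {sorted(missing)}"
            )
        pending = deferred
    return reg


def _register_element(reg: rc.Registry, el: dict, where: str) -> None:
    semantic = el.get("semantic_type", "atomic")
    dec = None
    if el.get("dec"):
        dec = rc.DataElementConcept(
            object_class=el["dec"]["object_class"],
            property=el["dec"]["property"],
            concept_codes=tuple(tuple(c) for c in el["dec"].get("concept_codes", ())) or None,
        )
    try:
        if semantic == "atomic":
            reg.register_atomic(
                el["name"],
                id=el["id"],
                definition=el.get("definition", ""),
                dec=dec,
                value_domain=_domain_from_json(el.get("value_domain"), where, True),
                subtype=el.get("subtype", "plain"),
                members=tuple(el.get("members", ())),
                vocabulary_ref=tuple(el["vocabulary_ref"]) if el.get("vocabulary_ref") else None,
                rules=tuple(el.get("rule_ids", ())),
            )
        elif semantic == "composite":
            reg.compose(
                el["name"],
                el.get("kind", "general"),
                tuple(el.get("members", ())),
                tuple(el.get("rule_ids", ())),
                id=el["id"],
                definition=el.get("definition", ""),
                dictionary_ref=tuple(el["dictionary_ref"]) if el.get("dictionary_ref") else None,
                dictionary_roles=el.get("dictionary_roles"),
            )
        else:
            raise RegistryFormatError(f"{where}: unknown semantic_type {semantic!r}")
    except rc.RegistryError as exc:
        raise RegistryFormatError(f"{where}: {exc}") from None


def _element_to_json(cde) -> dict:
    if isinstance(cde, rc.AtomicCDE):
        out: dict = {
            "id": cde.id,
            "name": cde.name,
            "semantic_type": "atomic",
            "subtype": cde.subtype,
        }
        if cde.definition:
            out["definition"] = cde.definition
        if cde.dec is not None:
            out["dec"] = {
                "object_class": cde.dec.object_class,
                "property": cde.dec.property,
            }
            if cde.dec.concept_codes:
                out["dec"]["concept_codes"] = [list(c) for c in cde.dec.concept_codes]
        if cde.value_domain is not None:
            out["value_domain"] = _domain_to_json(cde.value_domain)
        if cde.members:
            out["members"] = list(cde.members)
        if cde.vocabulary_ref is not None:
            out["vocabulary_ref"] = list(cde.vocabulary_ref)
        if cde.rules:
            out["rule_ids"] = list(cde.rules)
        return out
    out = {
        "id": cde.id,
        "name": cde.name,
        "semantic_type": "composite",
        "kind": cde.kind,
        "members": list(cde.members),
    }
    if cde.definition:
        out["definition"] = cde.definition
    if cde.rules:
        out["rule_ids"] = list(cde.rules)
    if cde.dictionary_ref is not None:
        out["dictionary_ref"] = list(cde.dictionary_ref)
    if cde.dictionary_roles:
        out["dictionary_roles"] = dict(sorted(cde.dictionary_roles.items()))
    return out


def save_registry(reg: rc.Registry, path: Union[str, Path]) -> None:
    """Write the canonical registry document (plus any dictionary CSVs
    that have no source file yet)."""
    path = Path(path)
    dictionaries = []
    for table in reg.dictionaries.values():
        source = table.source
        if source is None:
            source = f"{table.id}.csv"
            _write_dictionary_csv(table, path.parent / source)
        dictionaries.append(
            {
                "id": table.id,
                "source": source,
                "key_column": table.key_column,
                "unit_column": table.unit_column,
                "range_column": table.range_column,
            }
        )
    payload = {
        "data_elements": [_element_to_json(c) for c in reg.cdes.values()],
        "rules": [
            {
                "id": r.id,
                "kind": r.kind.value,
                **({"expr": r.expr_text} if r.expression is not None else {}),
                **({"target": r.target} if r.target else {}),
                **({"description": r.description} if r.description else {}),
            }
            for r in reg.rules.values()
        ],
        "dictionaries": dictionaries,
    }
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def _write_dictionary_csv(table: dl.DictionaryTable, path: Path) -> None:
    columns = list(table.columns) or [
        table.key_column, table.unit_column, table.range_column
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for row in table.rows.values():
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


def _record_from_mapping(obj: dict, field_order: Optional[list]) -> DataRecord:
    values: dict = {}
    units: dict = {}
    for key, raw in obj.items():
        if key == SET_COLUMN:
            continue
        if key.endswith(UNIT_SUFFIX):
            if raw not in (None, ""):
                units[key[: -len(UNIT_SUFFIX)]] = str(raw).strip()
            continue
        values[key] = None if (isinstance(raw, str) and raw == "") else raw
    if field_order is None:
        field_order = [
            k for k in obj if k != SET_COLUMN and not k.endswith(UNIT_SUFFIX)
        ]
    return DataRecord(values=values, entered_units=units, field_order=list(field_order))


def load_records(
    path: Union[str, Path], format: Optional[str] = None
) -> List[Union[DataRecord, RecordSet]]:
    """Load records from CSV or a JSON array of objects.

    Rows sharing a ``__set_id`` become one :class:`RecordSet` (in first-
    appearance order); rows without one stay independent records.  Column
    order is captured as each record's ``field_order``.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    rows: List[dict] = []
    order: Optional[list] = None
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            order = [
                c
                for c in (reader.fieldnames or [])
                if c != SET_COLUMN and not c.endswith(UNIT_SUFFIX)
            ]
            for lineno, row in enumerate(reader, start=2):
                if None in row or any(v is None for v in row.values()):
                    raise ValueError(f"{path} row {lineno}: ragged CSV row")
                rows.append(row)
    elif format == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(payload, list):
            raise ValueError(f"{path}: expected a JSON array of objects")
        rows = payload
    else:
        raise ValueError(f"unknown record format: {format!r}")

    out: List[Union[DataRecord, RecordSet]] = []
    sets: dict = {}
    for obj in rows:
        record = _record_from_mapping(obj, order)
        set_id = obj.get(SET_COLUMN)
        if set_id in (None, ""):
            out.append(record)
        else:
            if set_id not in sets:
                sets[set_id] = RecordSet(set_id=str(set_id))
                out.append(sets[set_id])
            sets[set_id].rows.append(record)
    return out


def save_records(
    items: List[Union[DataRecord, RecordSet]],
    path: Union[str, Path],
    *,
    columns: Optional[list] = None,
) -> None:
    """Write records back to CSV in the dialect :func:`load_records` reads."""
    flat: List[tuple] = []  # (set_id, record)
    for item in items:
        if isinstance(item, RecordSet):
            flat.extend((item.set_id, r) for r in item.rows)
        else:
            flat.append((None, item))
    if columns is None:
        seen: dict = {}
        for _, r in flat:
            for k in r.field_order or r.values:
                seen.setdefault(k, None)
        columns = list(seen)
    unit_columns = sorted({k for _, r in flat for k in r.entered_units})
    header = columns + [c + UNIT_SUFFIX for c in unit_columns]
    has_sets = any(s is not None for s, _ in flat)
    if has_sets:
        header = [SET_COLUMN] + header
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for set_id, r in flat:
            row = []
            if has_sets:
                row.append(set_id or "")
            for c in columns:
                v = r.values.get(c)
                row.append("" if v is None else v)
            for c in unit_columns:
                row.append(r.entered_units.get(c, ""))
            writer.writerow(row)
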