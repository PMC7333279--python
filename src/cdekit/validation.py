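"""Record validation against CDE definitions and constraint rules.

Validates single records (one form) and repeated record sets (tabular
entry) and produces structured findings rather than exceptions, so a
whole form is always checked end to end.  Rules execute in a fixed kind
order — Required, Dependent, Operated, Ordered, Dictionary — and within a
kind in rule-id order, which makes reports deterministic.

Null handling is deliberately asymmetric: *Required* looks at the raw
entered value (a value that was typed but does not parse is still "a
value"), while Operated/Dependent rules see domain-parsed values, where
an unparseable entry degrades to NULL and conditions over it come back
*indeterminate* (an info finding, never an error — nullness is Required's
job).
"""

from __future__ import annotations

import datetime as _dt
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from . import dictionary as dl
from . import registry as rc
from . import rules as rl
from .rules import FALSE, INDETERMINATE, NULL, TRUE, Value, ValueTag

__all__ = [
    "ValidationError",
    "DataRecord",
    "RecordSet",
    "Finding",
    "ValidationReport",
    "infer_value",
    "parse_by_domain",
    "check_value",
    "check_required",
    "check_dependent",
    "check_operated",
    "check_ordered",
    "check_dictionary_rule",
    "validate_record",
    "validate_table",
    "DEFAULT_FLAG_VOCAB",
]

DEFAULT_FLAG_VOCAB = ("Normal", "Abnormal")
REL_TOL = 1e-6
ABS_TOL = 1e-9

KIND_ORDER = (
    rl.RuleKind.REQUIRED,
    rl.RuleKind.DEPENDENT,
    rl.RuleKind.OPERATED,
    rl.RuleKind.ORDERED,
    rl.RuleKind.DICTIONARY,
)


class ValidationError(ValueError):
    """Unrecoverable input problem (unknown CDE id in strict mode, ...)."""


@dataclass
class DataRecord:
    """One filled form: raw values keyed by member CDE id.

    ``entered_units`` carries per-field units as typed; ``field_order`` is
    the order fields were presented/collected in (CSV column order), used
    by Ordered checks.
    """

    values: dict = field(default_factory=dict)
    entered_units: dict = field(default_factory=dict)
    field_order: Optional[list] = None

    def raw(self, cde_id: str):
        return self.values.get(cde_id)

    def is_entered(self, cde_id: str) -> bool:
        raw = self.values.get(cde_id)
        if raw is None:
            return False
        if isinstance(raw, str) and (not raw.strip() or raw.strip() == "NULL"):
            return False
        if isinstance(raw, Value):
            return not raw.is_missing()
        return True


@dataclass
class RecordSet:
    """Ordered rows all keyed to the same repeated cCDE."""

    set_id: str
    rows: list = field(default_factory=list)


@dataclass(frozen=True)
class Finding:
    kind: str  # datatype|permissible|hybrid|required|dependent|operated|ordered|dictionary_range|dictionary_flag|indeterminate|structure
    severity: str  # error|warning|info
    cde_id: str
    code: str
    message: str
    rule_id: Optional[str] = None
    row: Optional[int] = None

    def at_row(self, row: int) -> "Finding":
        return Finding(self.kind, self.severity, self.cde_id, self.code,
                       self.message, self.rule_id, row)


@dataclass
class ValidationReport:
    findings: list = field(default_factory=list)
    hybrid_resolutions: dict = field(default_factory=dict)  # (cde, row) -> member
    derived: dict = field(default_factory=dict)  # (cde, row) -> Value payload

    def add(self, finding: Finding) -> None:
        self.findings.append(finding)

    def extend(self, findings: Iterable[Finding]) -> None:
        self.findings.extend(findings)

    @property
    def tallies(self) -> dict:
        out: dict = {}
        for f in self.findings:
            out[f.kind] = out.get(f.kind, 0) + 1
        return out

    def errors(self) -> list:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def n_errors(self) -> int:
        return len(self.errors())

    def to_dict(self) -> dict:
        return {
            "findings": [
                {
                    "kind": f.kind,
                    "severity": f.severity,
                    "cde_id": f.cde_id,
                    "rule_id": f.rule_id,
                    "row": f.row,
                    "code": f.code,
                    "message": f.message,
                }
                for f in self.findings
            ],
            "tallies": self.tallies,
            "derived": {f"{cde}@{row}": v for (cde, row), v in self.derived.items()},
            "hybrid_resolutions": {
                f"{cde}@{row}": m for (cde, row), m in self.hybrid_resolutions.items()
            },
        }


# ---------------------------------------------------------------------------
# Raw -> Value parsing
# ---------------------------------------------------------------------------

_DATE_RE = re.compile(r"\d{4}-\d{2}-\d{2}\Z")
_TIME_RE = re.compile(r"\d{1,2}:\d{2}(:\d{2})?\Z")
_DATETIME_RE = re.compile(r"\d{4}-\d{2}-\d{2}[T ]\d{2}:\d{2}")
_TIME_FORMATS = {"HH:MM": "%H:%M", "HH:MM:SS": "%H:%M:%S"}


def infer_value(raw, unit: Optional[str] = None) -> Value:
    """Best-effort typing of a raw value with no domain at hand.

    ISO-shaped strings become dates/times, numeric strings numbers,
    None/''/'NULL' null, everything else text.  Used when rules run
    directly over a record without a registry.
    """
    if isinstance(raw, Value):
        return raw
    if raw is None:
        return NULL
    if isinstance(raw, bool):
        return Value.boolean(raw)
    if isinstance(raw, (int, float)):
        return Value.number(float(raw), unit)
    s = str(raw).strip()
    if not s or s == "NULL":
        return NULL
    if _DATETIME_RE.match(s):
        try:
            return Value.datetime(_dt.datetime.fromisoformat(s))
        except ValueError:
            return Value.text(s)
    if _DATE_RE.match(s):
        try:
            return Value.date(_dt.date.fromisoformat(s))
        except ValueError:
            return Value.text(s)
    if _TIME_RE.match(s):
        try:
            return Value.time(_dt.time.fromisoformat(s.zfill(5)))
        except ValueError:
            return Value.text(s)
    try:
        return Value.number(float(s), unit)
    except ValueError:
        return Value.text(s)


def parse_by_domain(domain: rc.ValueDomain, raw, unit: Optional[str] = None):
    """Parse a raw value against one value domain.

    Returns ``(Value, problem)`` where ``problem`` is None on success or a
    (finding-kind, message) pair.
    """
    if raw is None or (isinstance(raw, str) and (not raw.strip() or raw.strip() == "NULL")):
        return NULL, None
    if isinstance(raw, Value):
        return raw, None
    dt = domain.datatype
    if dt == "numeric":
        try:
            return Value.number(float(raw), unit or domain.unit_of_measure), None
        except (TypeError, ValueError):
            return NULL, ("datatype", f"{raw!r} is not numeric")
    s = str(raw).strip()
    if dt == "text":
        return Value.text(s), None
    if dt == "enumerated":
        if s in domain.codes():
            return Value.text(s), None
        return NULL, (
            "permissible",
            f"{s!r} is not among permissible values {list(domain.codes())}",
        )
    if dt == "time":
        fmt = _TIME_FORMATS.get(domain.format or "HH:MM", domain.format or "%H:%M")
        try:
            return Value.time(_dt.datetime.strptime(s, fmt).time()), None
        except ValueError:
            return NULL, ("datatype", f"{s!r} does not match time format {fmt!r}")
    if dt == "date":
        try:
            return Value.date(_dt.date.fromisoformat(s)), None
        except ValueError:
            return NULL, ("datatype", f"{s!r} is not an ISO date (YYYY-MM-DD)")
    if dt == "datetime":
        try:
            return Value.datetime(_dt.datetime.fromisoformat(s)), None
        except ValueError:
            return NULL, ("datatype", f"{s!r} is not an ISO datetime")
    if dt == "boolean":
        if s.lower() in ("true", "false"):
            return Value.boolean(s.lower() == "true"), None
        return NULL, ("datatype", f"{s!r} is not boolean (true/false)")
    return NULL, ("datatype", f"unknown datatype {dt!r}")


@dataclass
class ValueCheck:
    value: Value
    finding: Optional[Finding] = None
    matched_member: Optional[str] = None


def check_value(
    acde: rc.AtomicCDE,
    raw,
    entered_unit: Optional[str] = None,
    *,
    registry: Optional[rc.Registry] = None,
) -> ValueCheck:
    """Parse one raw value against an aCDE's (effective) value domain.

    Plain domains parse directly; variable aCDEs parse by their base
    domain and defer key membership to the dictionary check; hybrids try
    their members in declared order and report the first that accepts
    (first match wins — member order is meaningful).
    """
    if acde.subtype == "hybrid":
        if registry is None:
            raise rc.RegistryError("hybrid parse requires the registry to resolve members")
        if raw is None or (isinstance(raw, str) and not raw.strip()):
            return ValueCheck(NULL)
        for mid in acde.members:
            member = registry.atomic(mid)
            value, problem = parse_by_domain(member.value_domain, raw, entered_unit)
            if problem is None:
                return ValueCheck(value, matched_member=mid)
        return ValueCheck(
            NULL,
            Finding(
                "hybrid",
                "error",
                acde.id,
                "no_member_match",
                f"{raw!r} matches none of the hybrid member domains of {acde.id}",
            ),
        )
    value, problem = parse_by_domain(acde.value_domain, raw, entered_unit)
    if problem is not None:
        kind, msg = problem
        return ValueCheck(value, Finding(kind, "error", acde.id, kind + "_mismatch", msg))
    return ValueCheck(value)


# ---------------------------------------------------------------------------
# Rule checks
# ---------------------------------------------------------------------------


def _context_from_record(record: DataRecord) -> rl.EvalContext:
    ctx = rl.EvalContext(mode="lenient")
    for cde_id, raw in record.values.items():
        ctx.bind(cde_id, infer_value(raw, record.entered_units.get(cde_id)))
    for cde_id, unit in record.entered_units.items():
        ctx.bind_unit(cde_id, unit)
    return ctx


def check_required(rule: rc.ConstraintRule, record: DataRecord) -> list:
    """One error per listed reference whose raw value is null or absent."""
    findings = []
    for ref_id, _attr in rl.collect_refs(rule.expression):
        if not record.is_entered(ref_id):
            findings.append(
                Finding(
                    "required",
                    "error",
                    ref_id,
                    "required_null",
                    f"{ref_id} is required but has no value",
                    rule_id=rule.id,
                )
            )
    return findings


def check_dependent(
    rule: rc.ConstraintRule,
    record: DataRecord,
    ctx: Optional[rl.EvalContext] = None,
) -> list:
    """(IF cond target NULL): a true condition forces the target to null."""
    ctx = ctx or _context_from_record(record)
    cond, target_ref = rule.expression.args[0], rule.expression.args[1]
    target = target_ref.cde_id
    try:
        verdict = rl.evaluate(cond, ctx)
    except rl.RuleEvalError as exc:
        return [Finding("dependent", "warning", target, "eval_failed", str(exc), rule.id)]
    if verdict is TRUE:
        if record.is_entered(target):
            return [
                Finding(
                    "dependent",
                    "error",
                    target,
                    "must_be_null",
                    f"{target} must be null when {rl.unparse(cond)} holds",
                    rule_id=rule.id,
                )
            ]
        return []
    if verdict.is_indeterminate():
        return [
            Finding(
                "indeterminate",
                "info",
                target,
                "condition_indeterminate",
                f"dependency condition {rl.unparse(cond)} is indeterminate",
                rule_id=rule.id,
            )
        ]
    return []


def check_operated(
    rule: rc.ConstraintRule,
    record: DataRecord,
    ctx: Optional[rl.EvalContext] = None,
    *,
    rel_tol: float = REL_TOL,
    abs_tol: float = ABS_TOL,
):
    """Evaluate an operated rule: boolean results assert, numeric derive.

    Returns ``(findings, derived)`` where ``derived`` is the computed
    number for a derivation (None otherwise).  A derivation with a target
    already filled in is cross-checked at the given tolerance; with the
    target empty the derived value is reported for fill-in.
    """
    ctx = ctx or _context_from_record(record)
    subject = rule.target or (rl.collect_refs(rule.expression) or [("", None)])[0][0]
    try:
        result = rl.evaluate(rule.expression, ctx)
    except rl.RuleEvalError as exc:
        return [Finding("operated", "warning", subject, "eval_failed", str(exc), rule.id)], None
    if result.tag is ValueTag.BOOLEAN:
        if result is FALSE:
            return [
                Finding(
                    "operated",
                    "error",
                    subject,
                    "assertion_failed",
                    f"assertion {rl.unparse(rule.expression)} is violated",
                    rule_id=rule.id,
                )
            ], None
        return [], None
    if result.is_indeterminate():
        return [
            Finding(
                "indeterminate",
                "info",
                subject,
                "operated_indeterminate",
                f"{rl.unparse(rule.expression)} is indeterminate (null operand)",
                rule_id=rule.id,
            )
        ], None
    if result.tag is ValueTag.NUMBER:
        derived = float(result.payload)
        if rule.target and record.is_entered(rule.target):
            entered = infer_value(record.raw(rule.target))
            if entered.tag is ValueTag.NUMBER and not math.isclose(
                float(entered.payload), derived, rel_tol=rel_tol, abs_tol=abs_tol
            ):
                return [
                    Finding(
                        "operated",
                        "error",
                        rule.target,
                        "derivation_mismatch",
                        f"{rule.target} = {entered.payload} but the formula derives"
                        f" {derived:.6g}",
                        rule_id=rule.id,
                    )
                ], derived
        return [], derived
    return [
        Finding(
            "operated",
            "warning",
            subject,
            "non_numeric_result",
            f"operated rule produced a {result.tag.value} value",
            rule_id=rule.id,
        )
    ], None


def check_ordered(rule: rc.ConstraintRule, record: DataRecord) -> list:
    """The rule's refs must appear in field_order as a subsequence."""
    if record.field_order is None:
        return [
            Finding(
                "ordered",
                "info",
                (rule.target or rl.collect_refs(rule.expression)[0][0]),
                "order_unverifiable",
                "record supplies no field order; ordering not verifiable",
                rule_id=rule.id,
            )
        ]
    findings = []
    positions = []
    ordered_ids = [ref for ref, _ in rl.collect_refs(rule.expression)]
    index = {cde: i for i, cde in enumerate(record.field_order)}
    for ref in ordered_ids:
        if ref not in index:
            findings.append(
                Finding(
                    "ordered",
                    "info",
                    ref,
                    "ref_not_presented",
                    f"{ref} is not among the presented fields; skipped",
                    rule_id=rule.id,
                )
            )
        else:
            positions.append((ref, index[ref]))
    if any(b[1] < a[1] for a, b in zip(positions, positions[1:])):
        presented = [ref for ref, _ in sorted(positions, key=lambda p: p[1])]
        findings.append(
            Finding(
                "ordered",
                "error",
                positions[0][0],
                "order_violated",
                f"fields presented as {presented}, rule orders {ordered_ids}",
                rule_id=rule.id,
            )
        )
    return findings


# ---------------------------------------------------------------------------
# Dictionary cCDE check
# ---------------------------------------------------------------------------


def check_dictionary_rule(
    ccde: rc.CompositeCDE,
    table: dl.DictionaryTable,
    record: DataRecord,
    *,
    rule_id: Optional[str] = None,
    flag_vocab: tuple = DEFAULT_FLAG_VOCAB,
) -> list:
    """Validate a dictionary cCDE record against its reference table.

    Checks, in order: the foreign-key value is a table key; the entered
    unit is among the key's units; the numeric result against the unit's
    inclusive normal range implies an expected flag (``Normal`` inside,
    ``Abnormal`` outside) which must match the entered flag; and the
    significance dependency — an ``Abnormal`` flag requires a non-null
    significance (error), a ``Normal`` flag a null one (warning).
    """
    normal_flag, abnormal_flag = flag_vocab
    roles = ccde.dictionary_roles or {}
    fk = ccde.dictionary_ref[1]
    findings: list = []

    def add(kind, severity, cde_id, code, message):
        findings.append(Finding(kind, severity, cde_id, code, message, rule_id=rule_id))

    if not record.is_entered(fk):
        add("dictionary_range", "info", fk, "key_missing",
            f"foreign key {fk} has no value; dictionary check skipped")
        return findings
    key = str(record.raw(fk)).strip()
    if key not in table:
        add("dictionary_range", "error", fk, "unknown_key",
            f"{key!r} is not a key of dictionary table {table.id!r}")
        return findings

    unit_member = roles.get("unit")
    result_member = roles.get("result")
    unit = None
    if unit_member and record.is_entered(unit_member):
        unit = str(record.raw(unit_member)).strip()
    elif result_member and result_member in record.entered_units:
        unit = record.entered_units[result_member].strip()
    offered = table.units(key)
    if unit is not None and unit not in offered:
        add("dictionary_range", "error", unit_member or fk, "unknown_unit",
            f"unit {unit!r} is not offered for {key!r} (offers {offered})")
        return findings

    expected_flag = None
    if result_member and record.is_entered(result_member) and unit is not None:
        result = infer_value(record.raw(result_member))
        if result.tag is not ValueTag.NUMBER:
            add("dictionary_range", "error", result_member, "non_numeric_result",
                f"result {record.raw(result_member)!r} is not numeric")
        else:
            interval = table.normal_range(key, unit)
            expected_flag = (
                normal_flag if float(result.payload) in interval else abnormal_flag
            )

    flag_member = roles.get("flag")
    entered_flag = None
    if flag_member and record.is_entered(flag_member):
        entered_flag = str(record.raw(flag_member)).strip()
        if entered_flag not in flag_vocab:
            add("dictionary_flag", "error", flag_member, "unknown_flag",
                f"flag {entered_flag!r} not in {list(flag_vocab)}")
            entered_flag = None
        elif expected_flag is not None and entered_flag != expected_flag:
            add("dictionary_flag", "error", flag_member, "flag_mismatch",
                f"result implies {expected_flag!r} but {entered_flag!r} was entered")

    sig_member = roles.get("significance")
    if sig_member and entered_flag is not None:
        if entered_flag == abnormal_flag and not record.is_entered(sig_member):
            add("dictionary_flag", "error", sig_member, "significance_required",
                f"{sig_member} must be non-null when the result is {abnormal_flag!r}")
        elif entered_flag == normal_flag and record.is_entered(sig_member):
            add("dictionary_flag", "warning", sig_member, "significance_unexpected",
                f"{sig_member} should be null when the result is {normal_flag!r}")
    return findings


# ---------------------------------------------------------------------------
# Record / table drivers
# ---------------------------------------------------------------------------


def _resolve_cde(registry: rc.Registry, cde: Union[str, rc.AtomicCDE, rc.CompositeCDE]):
    return registry.get(cde) if isinstance(cde, str) else cde


def validate_record(
    registry: rc.Registry,
    cde: Union[str, rc.AtomicCDE, rc.CompositeCDE],
    record: DataRecord,
    *,
    mode: str = "strict",
    flag_vocab: tuple = DEFAULT_FLAG_VOCAB,
) -> ValidationReport:
    """Validate one record against an aCDE or cCDE and all attached rules."""
    owner = _resolve_cde(registry, cde)
    report = ValidationReport()
    if isinstance(owner, rc.CompositeCDE):
        members = [registry.atomic(m) for m in owner.members]
    else:
        members = [owner]
    member_ids = {m.id for m in members}
    member_ids.add(owner.id)

    unknown = [k for k in record.values if k not in member_ids]
    if unknown:
        if mode == "strict":
            raise ValidationError(
                f"record keys {unknown} are not members of {owner.id}"
            )
        for k in unknown:
            report.add(
                Finding("structure", "warning", owner.id, "unknown_key",
                        f"record key {k!r} is not a member of {owner.id}")
            )

    # value checks + typed context
    ctx = rl.EvalContext(mode="lenient")
    for member in members:
        raw = record.values.get(member.id)
        unit = record.entered_units.get(member.id)
        if member.id in record.values:
            vc = check_value(member, raw, unit, registry=registry)
            if vc.finding is not None:
                report.add(vc.finding)
            if vc.matched_member is not None:
                report.hybrid_resolutions[(member.id, None)] = vc.matched_member
            ctx.bind(member.id, vc.value)
        else:
            ctx.bind(member.id, NULL)
        domain_unit = (
            member.value_domain.unit_of_measure
            if member.subtype != "hybrid" and member.value_domain
            else None
        )
        if unit is not None:
            ctx.bind_unit(member.id, unit)
        elif domain_unit is not None:
            ctx.bind_unit(member.id, domain_unit)

    # gather rules from the owner and (for composites) its members
    attached: list = [(rid, registry.rule(rid)) for rid in owner.rules]
    if isinstance(owner, rc.CompositeCDE):
        for member in members:
            attached.extend((rid, registry.rule(rid)) for rid in member.rules)
    dictionary_rule_ids = [rid for rid, r in attached if r.kind is rl.RuleKind.DICTIONARY]

    for kind in KIND_ORDER:
        for rid, rule in sorted(
            (it for it in attached if it[1].kind is kind), key=lambda it: it[0]
        ):
            if kind is rl.RuleKind.REQUIRED:
                report.extend(check_required(rule, record))
            elif kind is rl.RuleKind.DEPENDENT:
                report.extend(check_dependent(rule, record, ctx))
            elif kind is rl.RuleKind.OPERATED:
                findings, derived = check_operated(rule, record, ctx)
                report.extend(findings)
                if derived is not None and rule.target:
                    report.derived[(rule.target, None)] = derived
            elif kind is rl.RuleKind.ORDERED:
                report.extend(check_ordered(rule, record))
            # Dictionary handled once below (table-driven, not expression-driven)

    if isinstance(owner, rc.CompositeCDE) and owner.kind == "dictionary":
        table_id = owner.dictionary_ref[0]
        if table_id not in registry.dictionaries:
            report.add(
                Finding("dictionary_range", "warning", owner.id, "table_missing",
                        f"dictionary table {table_id!r} is not loaded")
            )
        else:
            report.extend(
                check_dictionary_rule(
                    owner,
                    registry.dictionaries[table_id],
                    record,
                    rule_id=dictionary_rule_ids[0] if dictionary_rule_ids else None,
                    flag_vocab=flag_vocab,
                )
            )
    return report


def validate_table(
    registry: rc.Registry,
    ccde: Union[str, rc.CompositeCDE],
    recordset: RecordSet,
    *,
    mode: str = "strict",
    flag_vocab: tuple = DEFAULT_FLAG_VOCAB,
) -> ValidationReport:
    """Per-row validation of a repeated cCDE record set.

    Rows are independent; the combined report is the concatenation of the
    per-row reports with row indices attached.
    """
    owner = _resolve_cde(registry, ccde)
    if not isinstance(owner, rc.CompositeCDE) or owner.kind != "repeated":
        raise ValidationError(f"{getattr(owner, 'id', ccde)} is not a repeated cCDE")
    report = ValidationReport()
    for i, row in enumerate(recordset.rows):
        row_report = validate_record(
            registry, owner, row, mode=mode, flag_vocab=flag_vocab
        )
        report.extend(f.at_row(i) for f in row_report.findings)
        for (cde_id, _), member in row_report.hybrid_resolutions.items():
            report.hybrid_resolutions[(cde_id, i)] = member
        for (cde_id, _), value in row_report.derived.items():
            report.derived[(cde_id, i)] = value
    return report
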