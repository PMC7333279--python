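"""Metadata registry of atomic and composite common data elements.

The registry follows the ISO/IEC 11179 picture of a data element — a data
element concept (object class + property) joined to a value domain
(datatype, unit, permissible values, format) — and extends it with
semantic subtypes:

* atomic CDEs (aCDE): ``plain``, ``variable`` (values are keys of a
  controlled vocabulary / dictionary table) or ``hybrid`` (the value
  domain is the ordered union of >=2 member domains of distinct datatypes);
* composite CDEs (cCDE): ``general``, ``repeated`` (tabular multi-row
  entry) or ``dictionary`` (linked through a variable foreign-key member
  to a reference table).

Constraint rules (Operated / Required / Dependent / Ordered / Dictionary)
attach to aCDEs and cCDEs; the Ordered constraint only makes sense inside
a composite and never attaches to an aCDE.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import rules as rl

__all__ = [
    "DATATYPES",
    "RegistryError",
    "ValueDomain",
    "DataElementConcept",
    "AtomicCDE",
    "CompositeCDE",
    "ConstraintRule",
    "LintFinding",
    "Registry",
    "signature",
    "normalize_name",
]

DATATYPES = ("numeric", "text", "enumerated", "time", "date", "datetime", "boolean")
ATOMIC_SUBTYPES = ("plain", "variable", "hybrid")
COMPOSITE_KINDS = ("general", "repeated", "dictionary")
ID_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_:.\-]*\Z")


class RegistryError(ValueError):
    """Invariant violation or unresolved reference in registry content."""


@dataclass(frozen=True)
class ValueDomain:
    """Representation half of a data element."""

    datatype: str
    unit_of_measure: Optional[str] = None
    permissible_values: Optional[tuple] = None  # ((code, meaning), ...)
    format: Optional[str] = None  # time/date pattern; default ISO 8601 / HH:MM

    def validate(self) -> None:
        if self.datatype not in DATATYPES:
            raise RegistryError(f"unknown datatype: {self.datatype!r}")
        if self.datatype == "enumerated":
            if not self.permissible_values:
                raise RegistryError("enumerated domain requires permissible values")
            codes = [c for c, _ in self.permissible_values]
            if len(set(codes)) != len(codes):
                raise RegistryError("permissible value codes must be unique")
        elif self.permissible_values:
            raise RegistryError(
                f"{self.datatype} domain must not carry permissible values"
            )
        if self.unit_of_measure is not None and not self.unit_of_measure.strip():
            raise RegistryError("unit_of_measure must be a non-empty token")

    def codes(self) -> tuple:
        return tuple(c for c, _ in (self.permissible_values or ()))


@dataclass(frozen=True)
class DataElementConcept:
    """Semantic half of a data element: object class + property."""

    object_class: str
    property: str
    concept_codes: Optional[tuple] = None  # ((system, code), ...)

    def validate(self) -> None:
        if not self.object_class or not self.property:
            raise RegistryError("DEC requires non-empty object class and property")


@dataclass
class AtomicCDE:
    id: str
    name: str
    definition: str = ""
    dec: Optional[DataElementConcept] = None
    value_domain: Optional[ValueDomain] = None
    subtype: str = "plain"
    members: tuple = ()  # hybrid only: ordered member aCDE ids
    vocabulary_ref: Optional[tuple] = None  # variable only: (table id, key column)
    rules: tuple = ()  # ConstraintRule ids (never Ordered)

    semantic_type = "atomic"


@dataclass
class CompositeCDE:
    id: str
    name: str
    definition: str = ""
    kind: str = "general"
    members: tuple = ()
    rules: tuple = ()
    dictionary_ref: Optional[tuple] = None  # (table id, foreign-key member id)
    dictionary_roles: Optional[dict] = None  # role -> member id

    semantic_type = "composite"


@dataclass
class ConstraintRule:
    id: str
    kind: rl.RuleKind
    expression: Optional[rl.Expression]
    target: Optional[str] = None
    description: str = ""

    @property
    def expr_text(self) -> Optional[str]:
        return None if self.expression is None else rl.unparse(self.expression)


@dataclass(frozen=True)
class LintFinding:
    code: str
    item_id: str
    message: str


def normalize_name(name: str) -> str:
    return " ".join(name.split()).casefold()


def signature(cde: AtomicCDE, registry: Optional["Registry"] = None) -> str:
    """Canonical identity text used when two CDEs count as "the same".

    Built from the case-folded, whitespace-collapsed name plus datatype and
    unit, so cosmetic differences never split an element in two.  For a
    hybrid the datatype is the '+'-joined member datatypes (registry needed
    to resolve them).
    """
    if cde.subtype == "hybrid":
        if registry is not None:
            dt = "+".join(
                registry.atomic(m).value_domain.datatype for m in cde.members
            )
        else:
            dt = "hybrid"
        unit = None
    else:
        dt = cde.value_domain.datatype if cde.value_domain else "text"
        unit = cde.value_domain.unit_of_measure if cde.value_domain else None
    return "|".join([normalize_name(cde.name), dt, unit or ""])


class Registry:
    """Container for CDEs, constraint rules and dictionary tables.

    Ids are unique across all item classes; the membership graph is
    acyclic and at most two levels deep (cCDE -> aCDE -> hybrid members).
    """

    def __init__(self) -> None:
        self.cdes: dict = {}
        self.rules: dict = {}
        self.dictionaries: dict = {}  # id -> DictionaryTable
        self._by_name: dict = {}
        self._counter = 0

    # -- lookup -------------------------------------------------------------

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.cdes or item_id in self.rules or item_id in self.dictionaries

    def get(self, cde_id: str):
        try:
            return self.cdes[cde_id]
        except KeyError:
            raise RegistryError(f"unknown CDE id: {cde_id!r}") from None

    def atomic(self, cde_id: str) -> AtomicCDE:
        cde = self.get(cde_id)
        if not isinstance(cde, AtomicCDE):
            raise RegistryError(f"{cde_id} is not an atomic CDE")
        return cde

    def composite(self, cde_id: str) -> CompositeCDE:
        cde = self.get(cde_id)
        if not isinstance(cde, CompositeCDE):
            raise RegistryError(f"{cde_id} is not a composite CDE")
        return cde

    def rule(self, rule_id: str) -> ConstraintRule:
        try:
            return self.rules[rule_id]
        except KeyError:
            raise RegistryError(f"unknown rule id: {rule_id!r}") from None

    def by_name(self, name: str):
        key = normalize_name(name)
        if key not in self._by_name:
            raise RegistryError(f"no CDE named {name!r}")
        return self.cdes[self._by_name[key]]

    def atomics(self) -> Iterable[AtomicCDE]:
        return (c for c in self.cdes.values() if isinstance(c, AtomicCDE))

    def composites(self) -> Iterable[CompositeCDE]:
        return (c for c in self.cdes.values() if isinstance(c, CompositeCDE))

    # -- registration -------------------------------------------------------

    def _fresh_id(self, prefix: str = "DE") -> str:
        while True:
            self._counter += 1
            cand = f"{prefix}:{self._counter:05d}"
            if cand not in self:
                return cand

    def _claim_id(self, item_id: Optional[str], prefix: str = "DE") -> str:
        if item_id is None:
            return self._fresh_id(prefix)
        if not ID_RE.match(item_id):
            raise RegistryError(f"malformed id: {item_id!r}")
        if item_id in self:
            raise RegistryError(f"duplicate id: {item_id!r}")
        return item_id

    def register_atomic(
        self,
        name: str,
        *,
        id: Optional[str] = None,
        definition: str = "",
        dec: Optional[DataElementConcept] = None,
        value_domain: Optional[ValueDomain] = None,
        subtype: str = "plain",
        members: Iterable[str] = (),
        vocabulary_ref: Optional[tuple] = None,
        rules: Iterable[str] = (),
    ) -> str:
        """Register an atomic CDE and return its id."""
        cde = AtomicCDE(
            id=self._claim_id(id),
            name=name,
            definition=definition,
            dec=dec,
            value_domain=value_domain,
            subtype=subtype,
            members=tuple(members),
            vocabulary_ref=vocabulary_ref,
            rules=tuple(rules),
        )
        self._validate_atomic(cde)
        self._insert(cde)
        return cde.id

    def make_hybrid(
        self,
        name: str,
        member_ids: Iterable[str],
        *,
        id: Optional[str] = None,
        definition: str = "",
        dec: Optional[DataElementConcept] = None,
        rules: Iterable[str] = (),
    ) -> str:
        """Create a hybrid aCDE whose effective domain is the ordered union
        of >=2 existing plain members with pairwise distinct datatypes."""
        return self.register_atomic(
            name,
            id=id,
            definition=definition,
            dec=dec,
            subtype="hybrid",
            members=tuple(member_ids),
            rules=rules,
        )

    def compose(
        self,
        name: str,
        kind: str,
        member_ids: Iterable[str],
        rule_ids: Iterable[str] = (),
        *,
        id: Optional[str] = None,
        definition: str = "",
        dictionary_ref: Optional[tuple] = None,
        dictionary_roles: Optional[dict] = None,
    ) -> str:
        """Create a composite CDE; declared member order is preserved and is
        the default Ordered sequence."""
        ccde = CompositeCDE(
            id=self._claim_id(id),
            name=name,
            definition=definition,
            kind=kind,
            members=tuple(member_ids),
            rules=tuple(rule_ids),
            dictionary_ref=dictionary_ref,
            dictionary_roles=dict(dictionary_roles) if dictionary_roles else None,
        )
        self._validate_composite(ccde)
        self._insert(ccde)
        return ccde.id

    def add_rule(
        self,
        expr_text: Optional[str],
        *,
        id: Optional[str] = None,
        kind: Optional[rl.RuleKind] = None,
        target: Optional[str] = None,
        description: str = "",
    ) -> str:
        """Register a constraint rule from its prefix-notation text.

        ``kind`` defaults to :func:`cdekit.rules.classify_rule`; Dictionary
        rules may omit the expression (their semantics are table-driven).
        """
        expr = None if expr_text is None else rl.parse_rule(expr_text)
        if kind is None:
            if expr is None:
                raise RegistryError("a rule needs an expression or an explicit kind")
            kind = rl.classify_rule(expr)
        kind = rl.RuleKind(kind)
        if expr is None and kind is not rl.RuleKind.DICTIONARY:
            raise RegistryError(f"{kind.value} rule requires an expression")
        if kind is rl.RuleKind.DEPENDENT:
            dep = rl.dependent_target(expr)
            if dep is None:
                raise RegistryError("Dependent rule must match (IF <bool> <ref> NULL)")
            if target is None:
                target = dep
            elif target != dep:
                raise RegistryError(
                    f"Dependent target {target!r} disagrees with expression ({dep!r})"
                )
        rule = ConstraintRule(
            id=self._claim_id(id, prefix="RULE"),
            kind=kind,
            expression=expr,
            target=target,
            description=description,
        )
        self.rules[rule.id] = rule
        return rule.id

    def add_dictionary(self, table) -> str:
        if table.id in self:
            raise RegistryError(f"duplicate id: {table.id!r}")
        self.dictionaries[table.id] = table
        return table.id

    def _insert(self, cde) -> None:
        self.cdes[cde.id] = cde
        self._by_name.setdefault(normalize_name(cde.name), cde.id)

    # -- invariants ---------------------------------------------------------

    def _validate_atomic(self, cde: AtomicCDE) -> None:
        if cde.subtype not in ATOMIC_SUBTYPES:
            raise RegistryError(f"unknown atomic subtype: {cde.subtype!r}")
        if cde.dec is not None:
            cde.dec.validate()
        if cde.subtype == "hybrid":
            if cde.value_domain is not None:
                raise RegistryError(
                    "hybrid aCDE derives its domain from members; leave value_domain unset"
                )
            if len(cde.members) < 2:
                raise RegistryError("hybrid aCDE requires >=2 members")
            if len(set(cde.members)) != len(cde.members):
                raise RegistryError("hybrid members must be distinct")
            datatypes = []
            for mid in cde.members:
                member = self.atomic(mid)
                if member.subtype != "plain":
                    raise RegistryError(f"hybrid member {mid} is not a plain aCDE")
                datatypes.append(member.value_domain.datatype)
            if len(set(datatypes)) != len(datatypes):
                raise RegistryError("hybrid members must have pairwise distinct datatypes")
            if cde.vocabulary_ref is not None:
                raise RegistryError("a hybrid aCDE cannot also be a variable aCDE")
        else:
            if cde.members:
                raise RegistryError(f"{cde.subtype} aCDE carries no members")
            if cde.value_domain is None:
                raise RegistryError("non-hybrid aCDE requires a value domain")
            cde.value_domain.validate()
            if cde.subtype == "variable" and cde.vocabulary_ref is None:
                raise RegistryError("variable aCDE requires a vocabulary_ref")
            if cde.subtype == "plain" and cde.vocabulary_ref is not None:
                raise RegistryError("plain aCDE must not carry a vocabulary_ref")
        for rid in cde.rules:
            rule = self.rule(rid)
            if rule.kind is rl.RuleKind.ORDERED:
                raise RegistryError(
                    f"Ordered rule {rid} cannot attach to aCDE {cde.id}"
                )

    def _validate_composite(self, ccde: CompositeCDE) -> None:
        if ccde.kind not in COMPOSITE_KINDS:
            raise RegistryError(f"unknown composite kind: {ccde.kind!r}")
        if len(ccde.members) < 2:
            raise RegistryError("composite CDE requires >=2 members")
        if len(set(ccde.members)) != len(ccde.members):
            raise RegistryError("composite members must be distinct")
        for mid in ccde.members:
            self.atomic(mid)  # raises if missing or composite (no nesting)
        for rid in ccde.rules:
            self.rule(rid)
        if ccde.kind == "dictionary":
            if ccde.dictionary_ref is None:
                raise RegistryError("dictionary cCDE requires a dictionary_ref")
            table_id, fk = ccde.dictionary_ref
            if fk not in ccde.members:
                raise RegistryError(f"foreign-key member {fk} is not a member")
            if self.atomic(fk).subtype != "variable":
                raise RegistryError(
                    f"dictionary foreign-key member {fk} must be a variable aCDE"
                )
        elif ccde.dictionary_ref is not None:
            raise RegistryError(f"{ccde.kind} cCDE must not carry a dictionary_ref")

    # -- lint ---------------------------------------------------------------

    def lint(self) -> list:
        """Walk the whole registry and report every structural fault.

        Returns findings rather than raising: a registry built through the
        typed API is clean, but one loaded leniently from JSON may not be.
        """
        findings: list = []

        def fault(code: str, item_id: str, message: str) -> None:
            findings.append(LintFinding(code, item_id, message))

        for cde in list(self.cdes.values()):
            try:
                if isinstance(cde, AtomicCDE):
                    self._validate_atomic(cde)
                else:
                    self._validate_composite(cde)
            except RegistryError as exc:
                fault("invariant", cde.id, str(exc))
                continue
            if isinstance(cde, AtomicCDE) and cde.subtype == "variable":
                table_id, key_col = cde.vocabulary_ref
                if table_id not in self.dictionaries:
                    fault("unresolved", cde.id, f"vocabulary table {table_id!r} not loaded")
            member_ids = set(cde.members) | {cde.id}
            for rid in cde.rules:
                rule = self.rules.get(rid)
                if rule is None:
                    fault("unresolved", cde.id, f"rule {rid!r} not registered")
                    continue
                if isinstance(cde, AtomicCDE) and rule.kind is rl.RuleKind.ORDERED:
                    fault(
                        "ordered-on-atomic",
                        cde.id,
                        f"Ordered rule {rid} attached to aCDE {cde.id}",
                    )
                if rule.kind is rl.RuleKind.DICTIONARY and not (
                    isinstance(cde, CompositeCDE) and cde.kind == "dictionary"
                ):
                    fault(
                        "dictionary-rule-owner",
                        cde.id,
                        f"Dictionary rule {rid} must attach to a dictionary cCDE",
                    )
                if rule.expression is None:
                    continue
                declared = rl.classify_rule(rule.expression)
                if rule.kind not in (declared, rl.RuleKind.DICTIONARY):
                    fault(
                        "kind-mismatch",
                        rid,
                        f"declared {rule.kind.value} but expression classifies as"
                        f" {declared.value}",
                    )
                for ref_id, _attr in rl.collect_refs(rule.expression):
                    if ref_id not in self.cdes:
                        fault("unresolved", rid, f"rule references unknown CDE {ref_id!r}")
                    elif ref_id not in member_ids:
                        fault(
                            "non-member-ref",
                            rid,
                            f"rule on {cde.id} references non-member CDE {ref_id}",
                        )
            if isinstance(cde, CompositeCDE) and cde.dictionary_ref is not None:
                table_id, _fk = cde.dictionary_ref
                if table_id not in self.dictionaries:
                    fault("unresolved", cde.id, f"dictionary table {table_id!r} not loaded")
                if cde.dictionary_roles:
                    for role, mid in cde.dictionary_roles.items():
                        if mid not in cde.members:
                            fault(
                                "non-member-ref",
                                cde.id,
                                f"dictionary role {role!r} names non-member {mid}",
                            )
        return findings
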