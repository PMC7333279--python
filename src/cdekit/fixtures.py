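"""Worked-example registry content and a seeded synthetic-fixture generator.

``example_registry`` builds, through the typed API, the canonical worked
examples this package is organized around: a smoking-history form with
skip logic, a BMI panel with a unit-aware derivation, a demography form
with required fields, a hemodialysis table whose *Time* column is a
hybrid (clock time or Start/Finish marker), an electrolyte laboratory
panel backed by a reference dictionary, and a medical-history table
carrying one rule of every constraint kind.

``generate_fixture`` produces a synthetic registry + extraction corpus +
record table with *planted ground truth*: the generator records its own
draws (per-group occurrence and unique counts, composite assignments,
exact injected-violation counts), so downstream metrics and validation
can be checked against an answer key rather than against themselves.
"""

from __future__ import annotations

import datetime as _dt
import io as _io
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import dictionary as dl
from . import io as cio
from . import metrics as im
from . import registry as rc
from . import rules as rl
from .validation import DataRecord, RecordSet

__all__ = [
    "example_registry",
    "electrolyte_dictionary",
    "sodium_record",
    "medical_history_record",
    "FixtureSpec",
    "Fixture",
    "build_fixture",
    "generate_fixture",
]

ELECTROLYTE_TABLE_ID = "DICT:ELECTROLYTE"

_ELECTROLYTE_CSV = """\
Lab Test Name,Unit of Result,Normal Range
Sodium (Na+),mEq/L^mmol/L,"{""mEq/L"": ""135 ~ 145"", ""mmol/L"": ""135 ~ 145""}"
Potassium (K+),mEq/L^mmol/L,"{""mEq/L"": ""3.5 ~ 5.1"", ""mmol/L"": ""3.5 ~ 5.1""}"
"""


def electrolyte_dictionary() -> dl.DictionaryTable:
    """Electrolyte laboratory-test reference table (2 rows).

    The sodium row carries the canonical 135~145 mEq/L adult reference
    interval; the potassium row is a synthetic stand-in using the
    conventional 3.5~5.1 mEq/L adult interval.
    """
    return dl.load_dictionary(
        _io.StringIO(_ELECTROLYTE_CSV),
        table_id=ELECTROLYTE_TABLE_ID,
        key_column="Lab Test Name",
        unit_column="Unit of Result",
        range_column="Normal Range",
    )


def _yes_no(*, unknown: bool = True) -> rc.ValueDomain:
    pv = [("Yes", "Yes"), ("No", "No")]
    if unknown:
        pv.append(("Unknown", "Unknown"))
    return rc.ValueDomain("enumerated", permissible_values=tuple(pv))


def example_registry() -> rc.Registry:
    """Registry holding every worked example; see the module docstring."""
    reg = rc.Registry()

    # --- smoking history (skip logic + ordering) ---------------------------
    reg.register_atomic("Current Smoking Indicator", id="CDE20", value_domain=_yes_no())
    reg.register_atomic("Past Smoking Indicator", id="CDE21", value_domain=_yes_no())
    reg.register_atomic(
        "Age When Tobacco Use Started",
        id="CDE22",
        value_domain=rc.ValueDomain("numeric", unit_of_measure="years"),
    )
    r_smoke_dep = reg.add_rule(
        "(IF (or (!= CDE20 'Yes') (!= CDE21 'Yes')) CDE22 NULL)",
        id="RULE:SMOKE-DEP",
        description="Skip start age unless current and past use are both Yes",
    )
    r_smoke_ord = reg.add_rule(
        "(Ordered CDE20 CDE21 CDE22)", id="RULE:SMOKE-ORD"
    )
    reg.compose(
        "Smoking History",
        "general",
        ["CDE20", "CDE21", "CDE22"],
        [r_smoke_dep, r_smoke_ord],
        id="CDE2X",
    )

    # --- BMI panel (derivation, unit-aware) --------------------------------
    reg.register_atomic(
        "Body Weight Value",
        id="CDE30",
        value_domain=rc.ValueDomain("numeric", unit_of_measure="kg"),
    )
    reg.register_atomic(
        "Body Height Value",
        id="CDE31",
        value_domain=rc.ValueDomain("numeric", unit_of_measure="cm"),
    )
    reg.register_atomic(
        "Body Mass Index Value",
        id="CDE32",
        value_domain=rc.ValueDomain("numeric", unit_of_measure="kg/m2"),
    )
    r_bmi_req = reg.add_rule("(Required CDE30 CDE31)", id="RULE:BMI-REQ")
    r_bmi = reg.add_rule(
        "(IF (= CDE31.unit_of_measure 'm') (/ CDE30 CDE31 CDE31)"
        " (* (/ CDE30 CDE31 CDE31) 10000))",
        id="RULE:BMI-OP",
        kind=rl.RuleKind.OPERATED,
        target="CDE32",
        description="BMI kg/m^2 from weight and height, height in m or cm",
    )
    reg.compose(
        "Body Mass Index Panel",
        "general",
        ["CDE30", "CDE31", "CDE32"],
        [r_bmi_req, r_bmi],
        id="CDE3X",
    )

    # --- demography (required) ---------------------------------------------
    reg.register_atomic(
        "Patient Age",
        id="CDE40",
        value_domain=rc.ValueDomain("numeric", unit_of_measure="years"),
    )
    reg.register_atomic(
        "Patient Gender",
        id="CDE41",
        value_domain=rc.ValueDomain(
            "enumerated",
            permissible_values=(
                ("Female", "Female"), ("Male", "Male"), ("Unknown", "Unknown"),
                ("Unspecified", "Unspecified"), ("Not reported", "Not reported"),
            ),
        ),
    )
    reg.register_atomic(
        "Patient Ethnicity",
        id="CDE42",
        value_domain=rc.ValueDomain(
            "enumerated",
            permissible_values=(
                ("Hispanic or Latino", "Hispanic or Latino"),
                ("Not Hispanic or Latino", "Not Hispanic or Latino"),
                ("Unknown", "Unknown"), ("Not reported", "Not reported"),
            ),
        ),
    )
    r_demo_req = reg.add_rule("(Required CDE40 CDE41)", id="RULE:DEMO-REQ")
    reg.compose(
        "Demography", "general", ["CDE40", "CDE41", "CDE42"], [r_demo_req], id="CDE4X"
    )

    # --- hemodialysis table (hybrid Time inside a repeated cCDE) ------------
    reg.register_atomic(
        "Hemodialysis Time",
        id="DE:43239",
        value_domain=rc.ValueDomain("time", format="HH:MM"),
    )
    reg.register_atomic(
        "Hemodialysis Time Marker",
        id="DE:47614",
        value_domain=rc.ValueDomain(
            "enumerated",
            permissible_values=(("Start", "Start"), ("Finish", "Finish")),
        ),
    )
    reg.make_hybrid("Time", ["DE:43239", "DE:47614"], id="DE:47616")
    hemo_numeric = [
        ("DE:43340", "Systolic Blood Pressure", "mmHg"),
        ("DE:43197", "Diastolic Blood Pressure", "mmHg"),
        ("DE:43195", "Pulse Rate", "beats/min"),
        ("DE:43155", "Blood Flow Rate", "mL/min"),
        ("DE:43092", "Venous Pressure", "mmHg"),
        ("DE:43372", "Ultrafiltration Volume", "mL"),
        ("DE:43166", "Body Weight During Dialysis", "kg"),
    ]
    for cde_id, name, unit in hemo_numeric:
        reg.register_atomic(
            name, id=cde_id, value_domain=rc.ValueDomain("numeric", unit_of_measure=unit)
        )
    reg.compose(
        "Hemodialysis Observations",
        "repeated",
        ["DE:47616"] + [cde_id for cde_id, _, _ in hemo_numeric],
        id="DE:47575",
    )

    # --- electrolyte laboratory tests (dictionary cCDE) ----------------------
    reg.add_dictionary(electrolyte_dictionary())
    reg.register_atomic(
        "Laboratory Finding Test Name",
        id="DE:43938",
        subtype="variable",
        value_domain=rc.ValueDomain("text"),
        vocabulary_ref=(ELECTROLYTE_TABLE_ID, "Lab Test Name"),
    )
    reg.register_atomic(
        "Laboratory Test Date",
        id="DE:43936",
        value_domain=rc.ValueDomain("date"),
    )
    reg.register_atomic(
        "Laboratory Test Result",
        id="DE:43939",
        value_domain=rc.ValueDomain("numeric"),
    )
    reg.register_atomic(
        "Laboratory Test Result Unit",
        id="DE:43940",
        value_domain=rc.ValueDomain("text"),
    )
    reg.register_atomic(
        "Test Result Abnormal Indicator",
        id="DE:47566",
        value_domain=rc.ValueDomain(
            "enumerated",
            permissible_values=(("Normal", "Normal"), ("Abnormal", "Abnormal")),
        ),
    )
    reg.register_atomic(
        "Abnormal Result Clinically Significant Indicator",
        id="DE:44135",
        value_domain=_yes_no(unknown=False),
    )
    r_dict = reg.add_rule(
        None,
        id="RULE:LAB-DICT",
        kind=rl.RuleKind.DICTIONARY,
        description=(
            "Validate test name against the dictionary key, the entered unit"
            " against the key's unit list, the result against the unit-specific"
            " normal range, and the abnormal/significance dependency"
        ),
    )
    reg.compose(
        "Electrolyte Laboratory Tests",
        "dictionary",
        ["DE:43938", "DE:43936", "DE:43939", "DE:43940", "DE:47566", "DE:44135"],
        [r_dict],
        id="DE:47571",
        dictionary_ref=(ELECTROLYTE_TABLE_ID, "DE:43938"),
        dictionary_roles={
            "result": "DE:43939",
            "unit": "DE:43940",
            "flag": "DE:47566",
            "significance": "DE:44135",
        },
    )

    # --- medical history table (one rule of every kind) ----------------------
    reg.register_atomic(
        "Medical History Body System", id="DE:37059", value_domain=rc.ValueDomain("text")
    )
    reg.register_atomic(
        "Medical History Specify", id="DE:47621", value_domain=rc.ValueDomain("text")
    )
    reg.register_atomic(
        "Medical History Condition Code", id="DE:31106", value_domain=rc.ValueDomain("text")
    )
    reg.register_atomic(
        "Medical History Start Date", id="DE:47618", value_domain=rc.ValueDomain("date")
    )
    reg.register_atomic(
        "Medical History Ongoing Indicator", id="DE:44078", value_domain=_yes_no()
    )
    reg.register_atomic(
        "Medical History End Date", id="DE:47619", value_domain=rc.ValueDomain("date")
    )
    r_mh_op = reg.add_rule(
        "(< DE:47618 DE:47619)",
        id="RULE:MH-1-OP",
        description="Start date must be earlier than end date",
    )
    r_mh_req = reg.add_rule(
        "(Required DE:37059 DE:47621 DE:31106 DE:47618 DE:44078)",
        id="RULE:MH-2-REQ",
    )
    r_mh_dep = reg.add_rule(
        "(IF (!= DE:44078 'Yes') DE:47619 NULL)",
        id="RULE:MH-3-DEP",
        description="End date only when the condition is not ongoing = No ... follows the printed form: null end date unless ongoing is Yes",
    )
    r_mh_ord = reg.add_rule(
        "(Ordered DE:37059 DE:47621 DE:31106 DE:47618 DE:44078 DE:47619)",
        id="RULE:MH-4-ORD",
    )
    reg.compose(
        "Medical History",
        "repeated",
        ["DE:37059", "DE:47621", "DE:31106", "DE:47618", "DE:44078", "DE:47619"],
        [r_mh_op, r_mh_req, r_mh_dep, r_mh_ord],
        id="DE:47620",
    )
    return reg


def sodium_record(
    result: float = 138,
    unit: str = "mEq/L",
    flag: str = "Normal",
    significance: Optional[str] = None,
    test: str = "Sodium (Na+)",
) -> DataRecord:
    """One electrolyte-panel row; defaults are the in-range sodium case."""
    members = ["DE:43938", "DE:43936", "DE:43939", "DE:43940", "DE:47566", "DE:44135"]
    return DataRecord(
        values={
            "DE:43938": test,
            "DE:43936": "2020-01-15",
            "DE:43939": result,
            "DE:43940": unit,
            "DE:47566": flag,
            "DE:44135": significance,
        },
        field_order=members,
    )


MEDICAL_HISTORY_FIELDS = [
    "DE:37059", "DE:47621", "DE:31106", "DE:47618", "DE:44078", "DE:47619"
]


def medical_history_record(
    body_system: str = "Cardiovascular",
    specify: str = "Hypertension",
    code: str = "I10",
    start: str = "2019-03-01",
    ongoing: str = "Yes",
    end: Optional[str] = None,
    field_order: Optional[list] = None,
) -> DataRecord:
    """One medical-history row; defaults satisfy all four constraints."""
    return DataRecord(
        values={
            "DE:37059": body_system,
            "DE:47621": specify,
            "DE:31106": code,
            "DE:47618": start,
            "DE:44078": ongoing,
            "DE:47619": end,
        },
        field_order=list(field_order or MEDICAL_HISTORY_FIELDS),
    )


# ---------------------------------------------------------------------------
# Synthetic fixture generator
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Parameters of a synthetic registry/corpus/record fixture.

    Defaults mirror the evaluated study shape: 5 groups of 5 documents
    drawing from a shared element pool, with roughly half of each
    document's draws reusing already-seen elements and composites
    absorbing under half of each group's unique pool.
    """

    seed: int = 0
    n_groups: int = 5
    n_documents: int = 5
    pool_size: int = 60
    doc_size: tuple = (10, 20)
    reuse_probability: float = 0.5
    composite_fraction: float = 0.4
    composite_size: tuple = (2, 5)
    n_records: int = 8
    violations: dict = field(
        default_factory=lambda: {
            "required": 2,
            "dependent": 2,
            "operated": 1,
            "ordered": 1,
            "datatype": 1,
        }
    )

    def validate(self) -> None:
        if not (0.0 <= self.reuse_probability <= 1.0):
            raise ValueError("reuse_probability must be in [0, 1]")
        if not (0.0 <= self.composite_fraction <= 1.0):
            raise ValueError("composite_fraction must be in [0, 1]")
        if min(self.n_groups, self.n_documents, self.pool_size, self.n_records) < 1:
            raise ValueError("counts must be positive")
        if any(v < 0 for v in self.violations.values()):
            raise ValueError("violation counts must be non-negative")
        if sum(self.violations.values()) > self.n_records:
            raise ValueError(
                "violation plan exceeds the number of generated records"
            )


@dataclass
class Fixture:
    registry: rc.Registry
    corpus: im.ExtractionCorpus
    records: RecordSet
    answer_key: dict


def _generate_corpus(spec: FixtureSpec, rng: random.Random):
    pool = [f"elem-{i:03d}|numeric|" for i in range(spec.pool_size)]
    groups = []
    key_groups = []
    all_used: set = set()
    n_total_all = 0
    for gi in range(spec.n_groups):
        gname = f"group-{chr(ord('A') + gi % 26)}{gi // 26 or ''}"
        used: list = []  # group-unique signatures in first-use order
        occ_count: dict = {}
        documents = []
        for di in range(spec.n_documents):
            size = rng.randint(*spec.doc_size)
            doc: list = []
            for _ in range(size):
                reusable = [s for s in used if s not in doc]
                fresh = [s for s in pool if s not in used]
                if reusable and (not fresh or rng.random() < spec.reuse_probability):
                    sig = rng.choice(reusable)
                elif fresh:
                    sig = rng.choice(fresh)
                    used.append(sig)
                else:
                    break  # pool exhausted and nothing reusable in this doc
                doc.append(sig)
                occ_count[sig] = occ_count.get(sig, 0) + 1
            documents.append(im.Document(f"doc-{di + 1}", doc))
        # composite assignments over a fraction of the group's unique pool
        shuffled = sorted(used)
        rng.shuffle(shuffled)
        n_capture = int(round(spec.composite_fraction * len(used)))
        captured = shuffled[:n_capture]
        composites = []
        ci = 0
        while captured:
            take = min(rng.randint(*spec.composite_size), len(captured))
            if take < 2 and composites:
                composites[-1].members.extend(captured)
                captured = []
                break
            ci += 1
            composites.append(
                im.CompositeAssignment(f"{gname}-C{ci}", captured[:take])
            )
            captured = captured[take:]
        captured_sigs = {m for c in composites for m in c.members}
        groups.append(im.Group(gname, documents, composites))
        n_total = sum(len(d.occurrences) for d in documents)
        n_total_all += n_total
        all_used |= set(used)
        key_groups.append(
            {
                "name": gname,
                "n_total": n_total,
                "n_unique": len(used),
                "n_ccde": len(composites),
                "captured_unique": len(captured_sigs),
                "captured_total": sum(occ_count[s] for s in captured_sigs),
                "n_free": len(used) - len(captured_sigs),
            }
        )
    corpus = im.ExtractionCorpus(groups)
    key = {"groups": key_groups, "overall": {"n_total": n_total_all, "n_unique": len(all_used)}}
    return corpus, key


def _history_registry() -> rc.Registry:
    """Small generator-owned registry: a repeated history table carrying
    one rule of each constraint kind."""
    reg = rc.Registry()
    reg.register_atomic("Event Category", id="FX:CAT", value_domain=rc.ValueDomain("text"))
    reg.register_atomic("Event Detail", id="FX:DET", value_domain=rc.ValueDomain("text"))
    reg.register_atomic("Event Start Date", id="FX:START", value_domain=rc.ValueDomain("date"))
    reg.register_atomic("Event Ongoing Indicator", id="FX:ONGOING", value_domain=_yes_no())
    reg.register_atomic("Event End Date", id="FX:END", value_domain=rc.ValueDomain("date"))
    rules = [
        reg.add_rule("(< FX:START FX:END)", id="FXRULE:1-OP"),
        reg.add_rule("(Required FX:CAT FX:DET FX:START FX:ONGOING)", id="FXRULE:2-REQ"),
        reg.add_rule("(IF (!= FX:ONGOING 'Yes') FX:END NULL)", id="FXRULE:3-DEP"),
        reg.add_rule("(Ordered FX:CAT FX:DET FX:START FX:ONGOING FX:END)", id="FXRULE:4-ORD"),
    ]
    reg.compose(
        "Event History",
        "repeated",
        ["FX:CAT", "FX:DET", "FX:START", "FX:ONGOING", "FX:END"],
        rules,
        id="FX:HISTORY",
    )
    return reg


FIXTURE_CCDE_ID = "FX:HISTORY"
_FX_FIELDS = ["FX:CAT", "FX:DET", "FX:START", "FX:ONGOING", "FX:END"]


def _valid_row(i: int) -> DataRecord:
    start = _dt.date(2020, 1, 1) + _dt.timedelta(days=7 * i)
    end = start + _dt.timedelta(days=30)
    return DataRecord(
        values={
            "FX:CAT": f"Category {i + 1}",
            "FX:DET": f"Detail {i + 1}",
            "FX:START": start.isoformat(),
            "FX:ONGOING": "Yes",
            "FX:END": end.isoformat(),
        },
        field_order=list(_FX_FIELDS),
    )


def _inject(record: DataRecord, kind: str) -> None:
    if kind == "required":
        record.values["FX:CAT"] = None
    elif kind == "dependent":
        record.values["FX:ONGOING"] = "No"  # end date present -> must be null
    elif kind == "operated":
        start, end = record.values["FX:START"], record.values["FX:END"]
        record.values["FX:START"], record.values["FX:END"] = end, start
    elif kind == "ordered":
        record.field_order = _FX_FIELDS[:-2] + [_FX_FIELDS[-1], _FX_FIELDS[-2]]
    elif kind == "datatype":
        record.values["FX:START"] = "not-a-date"
    else:
        raise ValueError(f"unknown violation kind: {kind!r}")


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Deterministically build registry, corpus, records and answer key."""
    spec.validate()
    rng = random.Random(spec.seed)
    corpus, corpus_key = _generate_corpus(spec, rng)
    registry = _history_registry()

    rows = [_valid_row(i) for i in range(spec.n_records)]
    free_rows = list(range(spec.n_records))
    planted: dict = {}
    for kind in sorted(spec.violations):
        count = spec.violations[kind]
        planted[kind] = count
        for _ in range(count):
            idx = free_rows.pop(rng.randrange(len(free_rows)))
            _inject(rows[idx], kind)
    records = RecordSet(set_id="SET1", rows=rows)
    answer_key = {
        "seed": spec.seed,
        "corpus": corpus_key,
        "validation": {"errors_by_kind": planted, "n_records": spec.n_records},
    }
    return Fixture(registry, corpus, records, answer_key)


def generate_fixture(spec: FixtureSpec, outdir) -> dict:
    """Write registry.json, corpus.json, records.csv and answer_key.json.

    Byte-identical for identical specs (same seed included).  Returns the
    answer key.
    """
    fixture = build_fixture(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.save_registry(fixture.registry, outdir / "registry.json")
    (outdir / "corpus.json").write_text(
        json.dumps(fixture.corpus.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    cio.save_records([fixture.records], outdir / "records.csv")
    # JSON form is authoritative for per-row field order (ordered checks):
    # object key order carries each row's presentation order, which a CSV
    # with one shared header cannot express.
    objs = []
    for row in fixture.records.rows:
        obj: dict = {"__set_id": fixture.records.set_id}
        for k in row.field_order or row.values:
            obj[k] = row.values.get(k)
        for k, u in row.entered_units.items():
            obj[k + "__unit"] = u
        objs.append(obj)
    (outdir / "records.json").write_text(
        json.dumps(objs, indent=2) + "\n", encoding="utf-8"
    )
    (outdir / "answer_key.json").write_text(
        json.dumps(fixture.answer_key, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return fixture.answer_key
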