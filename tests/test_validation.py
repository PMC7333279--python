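"""Validation-engine tests: value parsing, rule checks, record drivers."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdekit import fixtures as fx
from cdekit import rules as rl
from cdekit import validation as ve
from cdekit.validation import DataRecord, RecordSet, check_value, validate_record, validate_table


def errors(report):
    return [f for f in report.findings if f.severity == "error"]


class TestCheckValue:
    @pytest.mark.parametrize(
        "raw,member",
        [("08:00", "DE:43239"), ("Finish", "DE:47614"), ("Start", "DE:47614")],
    )
    def test_hybrid_time_first_match(self, reg, raw, member):
        vc = check_value(reg.atomic("DE:47616"), raw, registry=reg)
        assert vc.finding is None
        assert vc.matched_member == member

    def test_hybrid_no_member_matches(self, reg):
        vc = check_value(reg.atomic("DE:47616"), "banana", registry=reg)
        assert vc.finding is not None and vc.finding.kind == "hybrid"

    def test_hybrid_equivalence_with_exhaustive_member_trial(self, reg):
        """First-match-wins agrees with brute-force trial of every member."""
        hybrid = reg.atomic("DE:47616")
        for raw in ["08:00", "23:59", "Start", "Finish", "banana", "24:99", "", "7:5"]:
            accepted = [
                mid
                for mid in hybrid.members
                if ve.parse_by_domain(reg.atomic(mid).value_domain, raw)[1] is None
            ]
            vc = check_value(hybrid, raw, registry=reg)
            if raw == "":
                assert vc.value.is_null()
            elif accepted:
                assert vc.finding is None and vc.matched_member == accepted[0]
            else:
                assert vc.finding is not None

    def test_enumerated_membership(self, reg):
        assert check_value(reg.atomic("CDE41"), "Female").finding is None
        bad = check_value(reg.atomic("CDE41"), "F")
        assert bad.finding.kind == "permissible"

    def test_numeric_and_date_parsing(self, reg):
        assert check_value(reg.atomic("CDE40"), "63").value.payload == 63.0
        assert check_value(reg.atomic("DE:47618"), "2020-02-30").finding is not None


class TestRequired:
    def test_listed_refs_only(self, reg):
        rule = reg.rule("RULE:DEMO-REQ")
        rec = DataRecord(values={"CDE40": 63, "CDE41": "Female", "CDE42": None})
        assert ve.check_required(rule, rec) == []

    def test_null_listed_ref_flagged(self, reg):
        rule = reg.rule("RULE:DEMO-REQ")
        rec = DataRecord(values={"CDE40": None, "CDE41": "Female"})
        findings = ve.check_required(rule, rec)
        assert [f.cde_id for f in findings] == ["CDE40"]

    def test_zero_is_a_value(self, reg):
        rule = reg.rule("RULE:DEMO-REQ")
        rec = DataRecord(values={"CDE40": 0, "CDE41": "Female"})
        assert ve.check_required(rule, rec) == []


class TestDependent:
    @pytest.mark.parametrize(
        "cur,past,expect_error",
        # skip-age rule fires unless both indicators are Yes
        [("No", "No", True), ("Yes", "No", True), ("No", "Yes", True),
         ("Yes", "Yes", False)],
    )
    def test_smoking_truth_table(self, reg, cur, past, expect_error):
        rule = reg.rule("RULE:SMOKE-DEP")
        rec = DataRecord(values={"CDE20": cur, "CDE21": past, "CDE22": 35})
        findings = ve.check_dependent(rule, rec)
        if expect_error:
            assert [f.cde_id for f in errors_list(findings)] == ["CDE22"]
        else:
            assert findings == []

    def test_history_end_date_forced_null(self, reg):
        rule = reg.rule("RULE:MH-3-DEP")
        rec = DataRecord(values={"DE:44078": "No", "DE:47619": "2020-02-01"})
        findings = ve.check_dependent(rule, rec)
        assert [f.cde_id for f in errors_list(findings)] == ["DE:47619"]

    def test_null_condition_downgrades_to_info(self, reg):
        # past use 'Yes' makes its disjunct false, so the unanswered current-use
        # question leaves the whole condition genuinely indeterminate
        rule = reg.rule("RULE:SMOKE-DEP")
        rec = DataRecord(values={"CDE20": None, "CDE21": "Yes", "CDE22": 35})
        findings = ve.check_dependent(rule, rec)
        assert [f.severity for f in findings] == ["info"]

    def test_determinate_disjunct_dominates_null(self, reg):
        # Kleene: or(indeterminate, TRUE) is TRUE — past use 'No' already
        # settles the skip condition, so the constraint fires despite the
        # unanswered current-use question
        rule = reg.rule("RULE:SMOKE-DEP")
        rec = DataRecord(values={"CDE20": None, "CDE21": "No", "CDE22": 35})
        findings = ve.check_dependent(rule, rec)
        assert [f.severity for f in findings] == ["error"]


def errors_list(findings):
    return [f for f in findings if f.severity == "error"]


class TestOperated:
    def test_bmi_derivation_cm(self, reg):
        rule = reg.rule("RULE:BMI-OP")
        rec = DataRecord(values={"CDE30": 70, "CDE31": 175})
        ctx = rl.EvalContext(mode="lenient")
        ctx.bind("CDE30", rl.Value.number(70))
        ctx.bind("CDE31", rl.Value.number(175, "cm"))
        findings, derived = ve.check_operated(rule, rec, ctx)
        assert findings == []
        assert derived == pytest.approx(70e4 / 175**2)  # 22.857...

    def test_bmi_derivation_metre_branch(self, reg):
        rule = reg.rule("RULE:BMI-OP")
        rec = DataRecord(values={"CDE30": 70, "CDE31": 1.75},
                         entered_units={"CDE31": "m"})
        findings, derived = ve.check_operated(rule, rec)
        assert findings == []
        assert derived == pytest.approx(70 / 1.75 / 1.75)

    def test_filled_target_cross_checked(self, reg):
        rule = reg.rule("RULE:BMI-OP")
        rec = DataRecord(values={"CDE30": 70, "CDE31": 1.75, "CDE32": 30.0},
                         entered_units={"CDE31": "m"})
        findings, _ = ve.check_operated(rule, rec)
        assert [f.code for f in findings] == ["derivation_mismatch"]

    def test_date_assertion_violated(self, reg):
        rule = reg.rule("RULE:MH-1-OP")
        rec = DataRecord(values={"DE:47618": "2021-05-01", "DE:47619": "2020-01-01"})
        findings, _ = ve.check_operated(rule, rec)
        assert [f.code for f in errors_list(findings)] == ["assertion_failed"]

    def test_assertion_with_null_is_info(self, reg):
        rule = reg.rule("RULE:MH-1-OP")
        rec = DataRecord(values={"DE:47618": "2021-05-01", "DE:47619": None})
        findings, _ = ve.check_operated(rule, rec)
        assert [f.severity for f in findings] == ["info"]


class TestOrdered:
    def test_matching_order_passes(self, reg):
        rule = reg.rule("RULE:SMOKE-ORD")
        rec = DataRecord(values={}, field_order=["CDE20", "CDE21", "CDE22"])
        assert ve.check_ordered(rule, rec) == []

    def test_swapped_order_fails(self, reg):
        rule = reg.rule("RULE:SMOKE-ORD")
        rec = DataRecord(values={}, field_order=["CDE20", "CDE22", "CDE21"])
        assert [f.code for f in ve.check_ordered(rule, rec)] == ["order_violated"]

    def test_missing_field_order_is_unverifiable_info(self, reg):
        rule = reg.rule("RULE:SMOKE-ORD")
        findings = ve.check_ordered(rule, DataRecord(values={}))
        assert [f.severity for f in findings] == ["info"]

    def test_subsequence_with_extra_fields_passes(self, reg):
        rule = reg.rule("RULE:SMOKE-ORD")
        rec = DataRecord(values={}, field_order=["X", "CDE20", "Y", "CDE21", "CDE22"])
        assert ve.check_ordered(rule, rec) == []

    def test_absent_refs_skipped_with_info(self, reg):
        rule = reg.rule("RULE:SMOKE-ORD")
        rec = DataRecord(values={}, field_order=["CDE20", "CDE22"])
        findings = ve.check_ordered(rule, rec)
        assert [f.code for f in findings] == ["ref_not_presented"]


class TestValidateRecord:
    def test_valid_history_row_has_no_errors(self, reg):
        report = validate_record(reg, "DE:47620", fx.medical_history_record())
        assert errors(report) == []

    def test_reversed_dates_single_error(self, reg):
        rec = fx.medical_history_record(start="2021-05-01", ongoing="Yes",
                                        end="2020-01-01")
        report = validate_record(reg, "DE:47620", rec)
        assert [f.rule_id for f in errors(report)] == ["RULE:MH-1-OP"]

    def test_sodium_row_clean(self, reg):
        report = validate_record(reg, "DE:47571", fx.sodium_record())
        assert errors(report) == []

    def test_unknown_key_strict_raises_lenient_warns(self, reg):
        rec = DataRecord(values={"CDE99": 1, "CDE20": "No", "CDE21": "No"})
        with pytest.raises(ve.ValidationError):
            validate_record(reg, "CDE2X", rec)
        report = validate_record(reg, "CDE2X", rec, mode="lenient")
        assert any(f.code == "unknown_key" for f in report.findings)

    def test_fill_then_verify_consistency(self, reg):
        """Writing the derived value back yields zero operated findings."""
        rec = DataRecord(values={"CDE30": 70, "CDE31": 175})
        report = validate_record(reg, "CDE3X", rec)
        derived = report.derived[("CDE32", None)]
        filled = DataRecord(values={"CDE30": 70, "CDE31": 175, "CDE32": derived})
        report2 = validate_record(reg, "CDE3X", filled)
        assert report2.tallies.get("operated", 0) == 0
        assert errors(report2) == []

    def test_required_monotonicity(self, reg, fresh_reg):
        """Adding a Required ref never decreases the finding count."""
        rec = DataRecord(values={"CDE40": None, "CDE41": None, "CDE42": None})
        base = len(validate_record(reg, "CDE4X", rec).findings)
        fresh_reg.rules["RULE:DEMO-REQ"].expression = rl.parse_rule(
            "(Required CDE40 CDE41 CDE42)"
        )
        wider = len(validate_record(fresh_reg, "CDE4X", rec).findings)
        assert wider >= base

    @pytest.mark.parametrize("kind", ["required", "dependent", "operated",
                                      "ordered", "datatype"])
    def test_single_fault_locality(self, kind):
        """Every error a single injected fault produces names the fault's CDE."""
        fixture = fx.build_fixture(fx.FixtureSpec(seed=11, violations={kind: 1},
                                                  n_records=3))
        report = validate_table(fixture.registry, fx.FIXTURE_CCDE_ID, fixture.records)
        errs = errors(report)
        assert len(errs) == 1
        touched = {
            "required": {"FX:CAT"},
            "dependent": {"FX:END"},
            "operated": {"FX:START", "FX:END"},
            "ordered": {"FX:CAT", "FX:DET", "FX:START", "FX:ONGOING", "FX:END"},
            "datatype": {"FX:START"},
        }[kind]
        assert errs[0].cde_id in touched


class TestValidateTable:
    def _hemo_rows(self, times):
        rows = []
        for t in times:
            rows.append(DataRecord(values={
                "DE:47616": t, "DE:43340": 120, "DE:43197": 80, "DE:43195": 70,
                "DE:43155": 250, "DE:43092": 100, "DE:43372": 1800, "DE:43166": 63.5,
            }))
        return RecordSet(set_id="HD1", rows=rows)

    def test_three_valid_rows(self, reg):
        report = validate_table(reg, "DE:47575", self._hemo_rows(["Start", "08:00", "Finish"]))
        assert errors(report) == []
        assert report.hybrid_resolutions[("DE:47616", 0)] == "DE:47614"
        assert report.hybrid_resolutions[("DE:47616", 1)] == "DE:43239"

    def test_fault_localized_to_row(self, reg):
        report = validate_table(reg, "DE:47575", self._hemo_rows(["08:00", "nonsense", "Finish"]))
        errs = errors(report)
        assert len(errs) == 1 and errs[0].row == 1 and errs[0].kind == "hybrid"

    def test_empty_recordset_is_valid(self, reg):
        report = validate_table(reg, "DE:47575", RecordSet(set_id="HD0", rows=[]))
        assert report.findings == []

    def test_row_permutation_permutes_findings(self, reg):
        """Rows are independent: permuting rows permutes row-indexed
        findings and changes nothing else."""
        times = ["nonsense", "08:00", "also bad"]
        base = validate_table(reg, "DE:47575", self._hemo_rows(times))
        base_key = sorted((f.row, f.cde_id, f.kind) for f in base.findings)
        for perm in itertools.permutations(range(3)):
            permuted = validate_table(
                reg, "DE:47575", self._hemo_rows([times[i] for i in perm])
            )
            # map each permuted row index back to the original row it holds
            mapped = sorted((perm[f.row], f.cde_id, f.kind) for f in permuted.findings)
            assert mapped == base_key
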