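"""Constraint-language tests: parsing, canonical text, evaluation."""

import datetime as dt
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdekit import rules as rl
from cdekit.rules import (
    Apply,
    CdeRef,
    EvalContext,
    FALSE,
    INDETERMINATE,
    Literal,
    NULL,
    TRUE,
    Value,
    classify_rule,
    collect_refs,
    evaluate,
    parse_rule,
    unparse,
)


def ctx(**bindings):
    c = EvalContext()
    for k, v in bindings.items():
        c.bind(k.replace("__", ":"), v)
    return c


class TestParsing:
    def test_required_form(self):
        e = parse_rule("(Required CDE40 CDE41)")
        assert e == Apply("Required", (CdeRef("CDE40"), CdeRef("CDE41")))

    def test_skip_logic_form(self):
        e = parse_rule("(IF (or (!= CDE20 'Yes') (!= CDE21 'Yes')) CDE22 NULL)")
        assert e.operator == "IF"
        assert e.args[0].operator == "or"
        assert e.args[1] == CdeRef("CDE22")
        assert e.args[2] == Literal(NULL)

    def test_bang_equals_with_interior_space(self):
        assert parse_rule("(! = DE:44078 'Yes')") == parse_rule("(!= DE:44078 'Yes')")

    def test_colon_ids_parse_as_single_tokens(self):
        e = parse_rule("(< DE:47618 DE:47619)")
        assert e == Apply("<", (CdeRef("DE:47618"), CdeRef("DE:47619")))

    def test_attribute_access(self):
        e = parse_rule("(= CDE31.unit_of_measure 'm')")
        assert e.args[0] == CdeRef("CDE31", "unit_of_measure")

    def test_commas_are_whitespace(self):
        # the garbled scaling token splits into two numeric literals
        e = parse_rule("(/ CDE30 CDE31 CDE31 100,100)")
        assert unparse(e) == "(/ CDE30 CDE31 CDE31 100 100)"
        assert e.args[3] == Literal(Value.number(100))

    @pytest.mark.parametrize(
        "bad",
        [
            "(= CDE20",
            "(= CDE20))",
            "(frobnicate 1 2)",
            "(not 1 2)",
            "(IF 1 2)",
            "(!= a b c)",
            "(Required 5)",
            "(Ordered CDE20)",
            "(+ 1)",
            "CDE20",
            "",
        ],
    )
    def test_malformed_rules_raise_at_parse_time(self, bad):
        with pytest.raises(rl.RuleSyntaxError):
            parse_rule(bad)


# random expression generator for round-trip properties -----------------------

_symbols = st.sampled_from(["CDE20", "CDE21", "DE:47618", "DE:1.2-x", "a_b"])
_literals = st.one_of(
    st.integers(-1000, 1000).map(lambda i: Literal(Value.number(i))),
    # decimal-only literal syntax: keep to values repr'd without exponents
    st.integers(-10000, 10000).map(lambda i: Literal(Value.number(i / 100))),
    st.sampled_from(["Yes", "No", "m", ""]).map(lambda s: Literal(Value.text(s))),
    st.just(Literal(NULL)),
)
_atoms = st.one_of(_literals, _symbols.map(CdeRef))


def _applies(children):
    def build(op_and_args):
        op, args = op_and_args
        spec = rl.OPERATORS[op]
        n = max(spec.min_arity, len(args))
        args = (args * n)[:n] if args else None
        if args is None:
            return None
        if spec.max_arity is not None:
            args = args[: spec.max_arity]
            args = (args * spec.max_arity)[: spec.max_arity] if op == "IF" else args
        return Apply(op, tuple(args))

    ops = st.sampled_from(["+", "-", "*", "/", "=", "<", ">", "<=", ">=", "and", "or", "not", "IF"])
    return st.tuples(ops, st.lists(children, min_size=1, max_size=4)).map(build).filter(
        lambda e: e is not None
    )


_expressions = st.recursive(_atoms, _applies, max_leaves=12).filter(
    lambda e: isinstance(e, Apply)
)


class TestCanonicalText:
    @given(_expressions)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_parse_unparse_identity(self, expr):
        assert parse_rule(unparse(expr)) == expr

    @given(_expressions)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_unparse_parse_idempotent_on_text(self, expr):
        text = unparse(expr)
        assert unparse(parse_rule(text)) == text

    def test_normalization_collapses_commas_and_spaces(self):
        assert unparse(parse_rule("(Required  CDE40,CDE41)")) == "(Required CDE40 CDE41)"

    def test_string_literal_requoted(self):
        assert unparse(parse_rule("(= CDE20 'Yes')")) == "(= CDE20 'Yes')"

    def test_unit_branch_rule_round_trips(self):
        text = (
            "(IF (= CDE31.unit_of_measure 'm') (/ CDE30 CDE31 CDE31)"
            " (/ CDE30 CDE31 CDE31 100 100))"
        )
        assert unparse(parse_rule(text)) == text


class TestEvaluation:
    def test_left_fold_division(self):
        v = evaluate(parse_rule("(/ 70 1.75 1.75)"), EvalContext())
        assert v.payload == pytest.approx(70 / 1.75 / 1.75)

    def test_if_true_branch(self):
        assert evaluate(parse_rule("(IF (= 'm' 'm') 1 2)"), EvalContext()).payload == 1

    def test_chained_equality(self):
        assert evaluate(parse_rule("(= 'No' 'No' 'No')"), EvalContext()) is TRUE

    def test_chronological_comparison(self):
        c = ctx(A=Value.date(dt.date(2020, 1, 1)), B=Value.date(dt.date(2019, 1, 1)))
        assert evaluate(parse_rule("(< A B)"), c) is FALSE
        assert evaluate(parse_rule("(> A B)"), c) is TRUE

    def test_null_comparison_is_indeterminate(self):
        assert evaluate(parse_rule("(< 5 NULL)"), EvalContext()).is_indeterminate()

    def test_division_by_zero(self):
        with pytest.raises(rl.RuleEvalError):
            evaluate(parse_rule("(/ 1 0)"), EvalContext())

    def test_numeric_op_on_text_is_type_error(self):
        with pytest.raises(rl.RuleEvalError):
            evaluate(parse_rule("(+ 1 'two')"), EvalContext())

    def test_strict_unbound_ref_raises(self):
        with pytest.raises(rl.UnboundRefError):
            evaluate(parse_rule("(= CDE99 'x')"), EvalContext(mode="strict"))

    def test_lenient_unbound_ref_is_null(self):
        c = EvalContext(mode="lenient")
        assert evaluate(parse_rule("(= CDE99 'x')"), c).is_indeterminate()
        assert c.warnings

    def test_arithmetic_with_null_operand_is_indeterminate(self):
        c = ctx(A=NULL)
        assert evaluate(parse_rule("(+ 1 A)"), c).is_indeterminate()


class TestArithmeticOracle:
    """Evaluator vs an independent brute-force left-fold recursion."""

    @staticmethod
    def _oracle(expr):
        if isinstance(expr, Literal):
            return float(expr.value.payload)
        acc = TestArithmeticOracle._oracle(expr.args[0])
        for a in expr.args[1:]:
            x = TestArithmeticOracle._oracle(a)
            acc = {
                "+": acc + x, "-": acc - x, "*": acc * x,
                "/": acc / x if x else None,
            }[expr.operator]
            if acc is None:
                raise ZeroDivisionError
        return acc

    @staticmethod
    def _random_expr(rng, depth):
        if depth == 0 or rng.random() < 0.3:
            if rng.random() < 0.5:
                return Literal(Value.number(rng.randint(-50, 50)))
            return Literal(Value.number(round(rng.uniform(-50, 50), 3)))
        op = rng.choice("+-*/")
        n = rng.randint(2, 4)
        return Apply(op, tuple(
            TestArithmeticOracle._random_expr(rng, depth - 1) for _ in range(n)
        ))

    def test_thousand_random_expressions_match_oracle(self):
        rng = random.Random(20200703)
        checked = 0
        while checked < 1000:
            expr = self._random_expr(rng, 4)
            if not isinstance(expr, Apply):
                continue
            try:
                expected = self._oracle(expr)
            except ZeroDivisionError:
                with pytest.raises(rl.RuleEvalError):
                    evaluate(expr, EvalContext())
                checked += 1
                continue
            got = evaluate(expr, EvalContext()).payload
            if expected == 0:
                assert abs(got) <= 1e-12
            else:
                assert abs(got - expected) / abs(expected) <= 1e-12
            checked += 1


class TestChainedRelational:
    @given(
        st.sampled_from(["=", "<", ">", "<=", ">="]),
        st.tuples(st.integers(-5, 5), st.integers(-5, 5), st.integers(-5, 5)),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_chain_equals_conjunction_of_pairs(self, op, triple):
        a, b, c = triple
        chained = evaluate(
            Apply(op, (Literal(Value.number(a)), Literal(Value.number(b)),
                       Literal(Value.number(c)))),
            EvalContext(),
        )
        pairwise = evaluate(
            Apply("and", (
                Apply(op, (Literal(Value.number(a)), Literal(Value.number(b)))),
                Apply(op, (Literal(Value.number(b)), Literal(Value.number(c)))),
            )),
            EvalContext(),
        )
        assert chained == pairwise


class TestThreeValuedSoundness:
    """No binary comparison with a NULL operand returns true/false, and
    indeterminacy propagates through the logical connectives per Kleene."""

    @given(
        st.sampled_from(["=", "!=", "<", ">", "<=", ">="]),
        st.one_of(st.integers(-5, 5).map(lambda i: Literal(Value.number(i))),
                  st.just(Literal(NULL))),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_null_operand_comparison_indeterminate(self, op, other):
        for args in ((Literal(NULL), other), (other, Literal(NULL))):
            v = evaluate(Apply(op, args), EvalContext())
            assert v.is_indeterminate()  # NULL is one of the operands

    def test_kleene_tables(self):
        A = Apply("=", (Literal(NULL), Literal(Value.number(1))))  # indeterminate
        T = Apply("=", (Literal(Value.number(1)), Literal(Value.number(1))))
        F = Apply("=", (Literal(Value.number(1)), Literal(Value.number(2))))
        e = EvalContext()
        assert evaluate(Apply("and", (A, F)), e) is FALSE
        assert evaluate(Apply("and", (A, T)), e).is_indeterminate()
        assert evaluate(Apply("or", (A, T)), e) is TRUE
        assert evaluate(Apply("or", (A, F)), e).is_indeterminate()
        assert evaluate(Apply("not", (A,)), e).is_indeterminate()
        assert evaluate(Apply("IF", (A, Literal(Value.number(1)),
                                     Literal(Value.number(2)))), e).is_indeterminate()


class TestStaticAnalysis:
    def test_collect_refs_depth_first(self):
        e = parse_rule("(IF (or (!= CDE20 'Yes') (!= CDE21 'Yes')) CDE22 NULL)")
        assert [r for r, _ in collect_refs(e)] == ["CDE20", "CDE21", "CDE22"]

    def test_collect_refs_attribute_flag(self):
        e = parse_rule("(= CDE31.unit_of_measure 'm')")
        assert ("CDE31", "unit_of_measure") in collect_refs(e)

    def test_collect_refs_literal_only(self):
        assert collect_refs(parse_rule("(+ 1 2)")) == []

    @pytest.mark.parametrize(
        "text,kind",
        [
            ("(Ordered CDE20 CDE21 CDE22)", rl.RuleKind.ORDERED),
            ("(Required CDE40 CDE41)", rl.RuleKind.REQUIRED),
            ("(IF (! = DE:44078 'Yes') DE:47619 NULL)", rl.RuleKind.DEPENDENT),
            ("(< DE:47618 DE:47619)", rl.RuleKind.OPERATED),
            ("(* (/ CDE30 CDE31 CDE31) 10000)", rl.RuleKind.OPERATED),
            # IF that does not match the dependent shape stays Operated
            ("(IF (= CDE31.unit_of_measure 'm') (/ CDE30 CDE31 CDE31) 1)",
             rl.RuleKind.OPERATED),
        ],
    )
    def test_classification(self, text, kind):
        assert classify_rule(parse_rule(text)) is kind

    def test_dependent_target_extraction(self):
        e = parse_rule("(IF (! = DE:44078 'Yes') DE:47619 NULL)")
        assert rl.dependent_target(e) == "DE:47619"
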