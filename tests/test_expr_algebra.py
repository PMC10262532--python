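"""Algebra layer: parsing, normalization, rational form, and the
structural queries, cross-checked against sympy-based oracles."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinlaw.expr_algebra import (
    Add,
    Div,
    Mul,
    Num,
    ParseError,
    Pow,
    Sub,
    Sym,
    as_two_term_difference,
    evaluate,
    expand_terms,
    is_single_product,
    match_hill,
    match_michaelis_menten,
    normalize,
    parse_infix,
    species_in,
    species_in_denominator,
    substitute,
    symbols_of,
    to_infix,
    to_rational_form,
    UnresolvedSymbolError,
)

from _oracles import (
    numeric_equal,
    oracle_hill,
    oracle_michaelis_menten,
    oracle_single_product,
    oracle_species_in,
    oracle_species_in_denominator,
    random_positive_env,
    species_symbols,
    sympy_value,
    to_sympy,
)


# ---------------------------------------------------------------------------
# parsing / printing / evaluation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,env,expected",
    [
        ("1 + 2*3", {}, 7.0),
        ("2^3^2", {}, 512.0),  # right associative
        ("-2^2", {}, -4.0),  # unary minus binds looser than power
        ("(1 + 2)*3", {}, 9.0),
        ("pow(2, -1)", {}, 0.5),
        ("a - b - c", {"a": 10, "b": 3, "c": 2}, 5.0),
        ("a/b/c", {"a": 12, "b": 3, "c": 2}, 2.0),
        ("k*S/(K + S)", {"k": 2, "S": 3, "K": 1}, 1.5),
        ("2e-3 + 1.5", {}, 1.502),
        ("exp(0) + sqrt(4)", {}, 3.0),
    ],
)
def test_parse_and_evaluate(text, env, expected):
    assert evaluate(parse_infix(text), env) == pytest.approx(expected)


def test_parse_errors():
    for bad in ["k +", "(a", "a b", "pow(x)", "*a", "1..2"]:
        with pytest.raises(ParseError):
            parse_infix(bad)


def test_infix_round_trip_preserves_value(templates, rng):
    for law, roles in templates:
        expr = parse_infix(law)
        back = parse_infix(to_infix(expr))
        for _ in range(5):
            env = random_positive_env(symbols_of(expr), rng)
            assert numeric_equal(evaluate(expr, env), evaluate(back, env))


def test_symbols_and_substitution():
    e = parse_infix("k*A + f(B)")
    assert symbols_of(e) == {"k", "A", "B"}
    e2 = substitute(e, {"A": parse_infix("x + y")})
    assert symbols_of(e2) == {"k", "x", "y", "B"}


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_normalize_folds_numeric_subtrees():
    assert normalize(parse_infix("2*3*k")) == Mul(Num(6), Sym("k"))
    assert normalize(parse_infix("2 + 3")) == Num(5)
    assert normalize(parse_infix("pow(2, 3)")) == Num(8)
    assert normalize(parse_infix("k^1")) == Sym("k")
    # additive structure containing a symbol is preserved
    n = normalize(parse_infix("1 + -1*M"))
    assert n.kind == "add"


def test_normalize_is_idempotent(templates):
    for law, _ in templates:
        n = normalize(parse_infix(law))
        assert normalize(n) == n


def test_normalization_preserves_value(templates, rng):
    for law, _ in templates:
        expr = parse_infix(law)
        n = normalize(expr)
        for _ in range(20):
            env = random_positive_env(symbols_of(expr), rng)
            assert numeric_equal(evaluate(expr, env), evaluate(n, env)), law


# ---------------------------------------------------------------------------
# rational form
# ---------------------------------------------------------------------------


def test_rational_form_worked_cases():
    roles = {"Cell": "compartment", "MI": "species", "V1": "parameter", "K1": "parameter"}
    rf = to_rational_form(parse_infix("Cell*MI*V1*pow(K1 + MI, -1)"))
    assert species_in(rf.numerator, roles) == {"MI"}
    assert species_in(rf.denominator, roles) == {"MI"}
    assert symbols_of(rf.denominator) == {"K1", "MI"}

    rf = to_rational_form(parse_infix("k1*A*B"))
    assert rf.denominator == Num(1)

    # (a/b)/(c/d) -> a*d / (b*c)
    rf = to_rational_form(parse_infix("(a/b)/(c/d)"))
    assert symbols_of(rf.numerator) == {"a", "d"}
    assert symbols_of(rf.denominator) == {"b", "c"}


def test_rational_form_symbolic_exponent_stays_out_of_denominator():
    rf = to_rational_form(parse_infix("pow(S, n)*k"))
    assert rf.denominator == Num(1)
    # ... unless the exponent is explicitly negated
    rf = to_rational_form(parse_infix("pow(S, -n)*k"))
    assert symbols_of(rf.denominator) == {"S", "n"}


def test_rational_form_preserves_value(templates, rng):
    for law, _ in templates:
        expr = parse_infix(law)
        rf = to_rational_form(expr)
        for _ in range(20):
            env = random_positive_env(symbols_of(expr), rng)
            expected = evaluate(expr, env)
            got = evaluate(rf.numerator, env) / evaluate(rf.denominator, env)
            assert numeric_equal(expected, got), law


def test_expand_terms_preserves_value(templates, rng):
    for law, roles in templates:
        expr = parse_infix(law)
        terms = expand_terms(expr, roles)
        for _ in range(10):
            env = random_positive_env(symbols_of(expr), rng)
            total = math.fsum(
                coeff * math.prod(evaluate(f, env) for f in factors)
                for coeff, factors in terms
            )
            assert numeric_equal(evaluate(expr, env), total), law


# ---------------------------------------------------------------------------
# structural queries vs the spec'd examples
# ---------------------------------------------------------------------------

_MMCAT_ROLES = {
    "uVol": "compartment",
    "k3": "parameter",
    "KK3": "parameter",
    "MKKK_P": "species",
    "MKK": "species",
}


def test_species_census_examples():
    assert species_in(
        parse_infix("Cell*k1aa"), {"Cell": "compartment", "k1aa": "parameter"}
    ) == set()
    assert species_in(
        parse_infix("Cell*CP*k9"),
        {"Cell": "compartment", "CP": "species", "k9": "parameter"},
    ) == {"CP"}
    assert species_in(
        parse_infix("uVol*k3*MKKK_P*MKK/(KK3 + MKK)"), _MMCAT_ROLES
    ) == {"MKKK_P", "MKK"}


def test_species_census_unresolved_symbol():
    with pytest.raises(UnresolvedSymbolError):
        species_in(parse_infix("k*A"), {"k": "parameter"})


def test_single_product_examples():
    assert is_single_product(
        parse_infix("Cell*CP*k9"),
        {"Cell": "compartment", "CP": "species", "k9": "parameter"},
    )
    assert not is_single_product(
        parse_infix("Comp1*(kf_0*B - kr_0*BL)"),
        {"Comp1": "compartment", "kf_0": "parameter", "kr_0": "parameter",
         "B": "species", "BL": "species"},
    )
    # species-free additive factors do not disqualify
    assert is_single_product(
        parse_infix("(k1 + k2)*A"),
        {"k1": "parameter", "k2": "parameter", "A": "species"},
    )
    # a species in the denominator always disqualifies (MM laws are not
    # "products" even when written with pow(..., -1))
    assert not is_single_product(
        parse_infix("Cell*MI*V1*pow(K1 + MI, -1)"),
        {"Cell": "compartment", "MI": "species", "V1": "parameter", "K1": "parameter"},
    )


def test_two_term_difference_examples():
    roles = {"Comp1": "compartment", "kf_0": "parameter", "kr_0": "parameter",
             "B": "species", "BL": "species"}
    pair = as_two_term_difference(parse_infix("Comp1*(kf_0*B - kr_0*BL)"), roles)
    assert pair is not None
    pos, neg = pair
    assert species_in(pos, roles) == {"B"}
    assert species_in(neg, roles) == {"BL"}
    # the common compartment prefactor is distributed into both terms
    assert "Comp1" in symbols_of(pos) and "Comp1" in symbols_of(neg)

    roles2 = {"c1": "compartment", "g": "parameter", "s173": "species",
              "s172": "species", "s135": "species"}
    pair2 = as_two_term_difference(parse_infix("c1*g*s173*(s172 - s135)"), roles2)
    assert pair2 is not None
    assert species_in(pair2[0], roles2) == {"s173", "s172"}
    assert species_in(pair2[1], roles2) == {"s173", "s135"}

    assert as_two_term_difference(
        parse_infix("k1*A"), {"k1": "parameter", "A": "species"}
    ) is None


def test_two_term_difference_value_identity(rng):
    roles = {"Comp1": "compartment", "kf_0": "parameter", "kr_0": "parameter",
             "B": "species", "BL": "species"}
    law = parse_infix("Comp1*(kf_0*B - kr_0*BL)")
    pos, neg = as_two_term_difference(law, roles)
    for _ in range(20):
        env = random_positive_env(symbols_of(law), rng)
        assert numeric_equal(
            evaluate(law, env), evaluate(pos, env) - evaluate(neg, env)
        )


def test_michaelis_menten_examples():
    roles = {"Cell": "compartment", "MI": "species", "V1": "parameter",
             "K1": "parameter"}
    assert match_michaelis_menten(
        parse_infix("Cell*MI*V1*pow(K1 + MI, -1)"), {"MI"}, roles
    ) == "MM"
    assert match_michaelis_menten(
        parse_infix("uVol*k3*MKKK_P*MKK/(KK3 + MKK)"), {"MKK"}, _MMCAT_ROLES
    ) == "MMCAT"
    froles = {"Cell": "compartment", "M": "species", "V1": "parameter",
              "K1": "parameter"}
    assert match_michaelis_menten(
        parse_infix("Cell*(1 + -1*M)*V1*pow(K1 + -1*M + 1, -1)"), set(), froles
    ) is None
    # substrate must be a reactant
    assert match_michaelis_menten(
        parse_infix("Cell*MI*V1*pow(K1 + MI, -1)"), set(), roles
    ) is None


def test_michaelis_menten_enzyme_must_stay_out_of_denominator():
    roles = {"k": "parameter", "Km": "parameter", "E": "species", "S": "species"}
    assert match_michaelis_menten(
        parse_infix("k*E*S/(Km + S)"), {"S"}, roles
    ) == "MMCAT"
    assert match_michaelis_menten(
        parse_infix("k*E*S/(Km + S + E)"), {"S"}, roles
    ) is None


def test_hill_examples():
    roles = {"Compartment": "compartment", "n1": "parameter", "a": "parameter",
             "g1": "parameter", "cXn": "species"}
    assert match_hill(
        parse_infix("Compartment*(n1*pow(cXn, a)/(pow(g1, a) + pow(cXn, a)))"),
        roles,
    )
    # exponent 1 collapses to Michaelis-Menten shape
    assert not match_hill(
        parse_infix("V*S/(K + S)"),
        {"V": "parameter", "K": "parameter", "S": "species"},
    )
    # literal exponents: only the species' exponent must agree
    assert match_hill(
        parse_infix("n1*pow(S, 2)/(pow(g1, 3) + pow(S, 2))"),
        {"n1": "parameter", "g1": "parameter", "S": "species"},
    )
    # mismatched exponents on the species power are not Hill
    assert not match_hill(
        parse_infix("V*pow(S, h)/(pow(K, h) + pow(S, g))"),
        {"V": "parameter", "h": "parameter", "g": "parameter",
         "K": "parameter", "S": "species"},
    )


def test_species_in_denominator_examples():
    assert species_in_denominator(
        parse_infix("uVol*k3*MKKK_P*MKK/(KK3 + MKK)"), _MMCAT_ROLES
    )
    assert not species_in_denominator(
        parse_infix("Cell*CP*k9"),
        {"Cell": "compartment", "CP": "species", "k9": "parameter"},
    )
    assert not species_in_denominator(
        parse_infix("S/(k1 + k2)"),
        {"S": "species", "k1": "parameter", "k2": "parameter"},
    )


# ---------------------------------------------------------------------------
# oracle equivalence over the template library
# ---------------------------------------------------------------------------


def test_queries_agree_with_sympy_oracles(templates):
    """Every structural query agrees with an independent re-derivation on
    sympy structures, template by template.

    sympy auto-cancels identical factors (V*S/S -> V), which can only
    *remove* a denominator; the denominator query is therefore compared
    one-sidedly on templates where cancellation applies.
    """
    for law, roles in templates:
        expr = parse_infix(law)
        se = to_sympy(expr)
        species = species_symbols(roles)
        reactant_choices = sorted(
            n for n, r in roles.items() if r == "species"
        )

        # sympy cancels identical factors at construction (V*S/S -> V);
        # such templates keep their written structure on our side, so the
        # oracle comparison is one-sided there
        lost = symbols_of(expr) - {s.name for s in se.free_symbols}
        if lost:
            assert oracle_species_in(se, species) <= species_in(expr, roles), law
            continue

        assert species_in(expr, roles) == oracle_species_in(se, species), law
        assert species_in_denominator(expr, roles) == (
            oracle_species_in_denominator(se, species)
        ), law
        assert is_single_product(expr, roles) == oracle_single_product(
            se, species
        ), law
        assert match_hill(expr, roles) == oracle_hill(se, species), law
        # MM shape, with every plausible substrate choice as reactant set
        for reactants in [set()] + [{s} for s in reactant_choices]:
            assert match_michaelis_menten(expr, reactants, roles) == (
                oracle_michaelis_menten(se, reactants, species)
            ), (law, reactants)


def test_values_agree_with_sympy(templates, rng):
    for law, _ in templates:
        expr = parse_infix(law)
        se = to_sympy(expr)
        for _ in range(5):
            env = random_positive_env(symbols_of(expr), rng)
            mine = evaluate(expr, env)
            theirs = sympy_value(se, env)
            assert numeric_equal(mine, theirs, 1e-7), law


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

_rename_suffix = st.integers(min_value=0, max_value=10**6)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(suffix=_rename_suffix, idx=st.integers(min_value=0, max_value=10**9))
def test_parameter_renaming_never_changes_query_results(suffix, idx):
    """Consistently renaming non-species symbols is invisible to every
    structural query."""
    templates = __import__("kinlaw.examples", fromlist=["expression_templates"])
    lib = templates.expression_templates()
    law, roles = lib[idx % len(lib)]
    expr = parse_infix(law)
    mapping = {
        n: f"renamed_{suffix}_{i}"
        for i, (n, r) in enumerate(sorted(roles.items()))
        if r != "species"
    }
    renamed = substitute(expr, {k: Sym(v) for k, v in mapping.items()})
    new_roles = {mapping.get(n, n): r for n, r in roles.items()}
    reactants = {n for n, r in roles.items() if r == "species"}

    assert species_in(expr, roles) == species_in(renamed, new_roles)
    assert is_single_product(expr, roles) == is_single_product(renamed, new_roles)
    assert species_in_denominator(expr, roles) == species_in_denominator(
        renamed, new_roles
    )
    assert match_hill(expr, roles) == match_hill(renamed, new_roles)
    assert match_michaelis_menten(expr, reactants, roles) == match_michaelis_menten(
        renamed, reactants, new_roles
    )


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    values=st.lists(
        st.floats(min_value=0.1, max_value=4.0, allow_nan=False), min_size=4, max_size=4
    )
)
def test_rational_form_value_identity_property(values):
    a, b, c, d = (Num(v) for v in values)
    S = Sym("S")
    expr = Div(Add(Mul(a, S), b), Add(Mul(c, S), Pow(S, Num(2)), d))
    rf = to_rational_form(expr)
    env = {"S": 1.7}
    assert numeric_equal(
        evaluate(expr, env),
        evaluate(rf.numerator, env) / evaluate(rf.denominator, env),
    )
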