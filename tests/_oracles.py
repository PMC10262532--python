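"""Independent sympy-based oracles for the structural queries.

These re-derive each structural property directly on sympy's own
expression structures (after ``sympy.together`` rationalization), sharing
no code with the package's algebra layer.  They are deliberately
brute-force: walk every subexpression, no gating or short-circuiting.
"""

from __future__ import annotations

import random
from typing import Mapping, Optional

import sympy as sp

from kinlaw.expr_algebra import Expr, evaluate


def to_sympy(expr: Expr, cache: Optional[dict] = None) -> sp.Expr:
    cache = cache if cache is not None else {}

    def sym(name: str) -> sp.Symbol:
        if name not in cache:
            cache[name] = sp.Symbol(name, positive=True)
        return cache[name]

    def conv(e: Expr) -> sp.Expr:
        k = e.kind
        if k == "num":
            v = e.value
            if isinstance(v, int) or (isinstance(v, float) and v.is_integer()):
                return sp.Integer(int(v))
            return sp.Rational(str(v)) if v == round(v, 12) else sp.Float(v)
        if k == "sym":
            return sym(e.name)
        if k == "add":
            return sp.Add(*(conv(a) for a in e.args))
        if k == "sub":
            return conv(e.args[0]) - conv(e.args[1])
        if k == "mul":
            return sp.Mul(*(conv(a) for a in e.args))
        if k == "div":
            return conv(e.args[0]) / conv(e.args[1])
        if k == "pow":
            return conv(e.args[0]) ** conv(e.args[1])
        if k == "neg":
            return -conv(e.args[0])
        if k == "call":
            fns = {"exp": sp.exp, "ln": sp.log, "sqrt": sp.sqrt, "abs": sp.Abs}
            if e.name in fns:
                return fns[e.name](*(conv(a) for a in e.args))
            return sp.Function(e.name)(*(conv(a) for a in e.args))
        raise ValueError(f"cannot convert {e.kind} node to sympy")

    return conv(expr)


def species_symbols(roles: Mapping[str, str]) -> set[sp.Symbol]:
    return {sp.Symbol(n, positive=True) for n, r in roles.items() if r == "species"}


def _has_species(e: sp.Expr, species: set[sp.Symbol]) -> bool:
    return bool(e.free_symbols & species)


def oracle_fraction(e: sp.Expr) -> tuple[sp.Expr, sp.Expr]:
    return sp.fraction(sp.together(e))


def oracle_species_in(e: sp.Expr, species: set[sp.Symbol]) -> set[str]:
    return {s.name for s in e.free_symbols & species}


def oracle_species_in_denominator(e: sp.Expr, species: set[sp.Symbol]) -> bool:
    _, den = oracle_fraction(e)
    return _has_species(den, species)


def oracle_single_product(e: sp.Expr, species: set[sp.Symbol]) -> bool:
    """Single product of terms: no species inside any additive subexpression,
    no species in the denominator, species only as symbols or positive
    powers of symbols."""
    _, den = oracle_fraction(e)
    if _has_species(den, species):
        return False
    # walk the expression as written: together() would factor common
    # species out of sums (kf*A - kr*A -> A*(kf - kr)), which changes the
    # syntactic class being tested
    for node in sp.preorder_traversal(e):
        if isinstance(node, sp.Add) and _has_species(node, species):
            return False
        if isinstance(node, sp.Function) and _has_species(node, species):
            return False
        if isinstance(node, sp.Pow) and _has_species(node.base, species):
            if not node.base.is_Symbol:
                return False
            exp = node.exp
            if exp.is_number and not exp.is_positive:
                return False
    return True


def _mul_args(e: sp.Expr) -> list[sp.Expr]:
    return list(sp.Mul.make_args(e))


def _species_profile(
    term: sp.Expr, species: set[sp.Symbol]
) -> Optional[dict[sp.Symbol, sp.Expr]]:
    """species -> exponent for one product term; None when not clean."""
    profile: dict[sp.Symbol, sp.Expr] = {}
    for f in _mul_args(term):
        if not _has_species(f, species):
            continue
        base, exp = (f.base, f.exp) if isinstance(f, sp.Pow) else (f, sp.Integer(1))
        if not (base.is_Symbol and base in species) or _has_species(exp, species):
            return None
        if base in profile:
            if profile[base].is_number and exp.is_number:
                profile[base] = profile[base] + exp
            else:
                return None
        else:
            profile[base] = exp
    return profile


def oracle_michaelis_menten(
    e: sp.Expr, reactants: set[str], species: set[sp.Symbol]
) -> Optional[str]:
    num, den = oracle_fraction(e)
    if not _has_species(den, species):
        return None
    if isinstance(num, sp.Add):
        return None
    profile = _species_profile(num, species)
    if profile is None or not profile:
        return None
    if any(p != 1 for p in profile.values()):
        return None
    den_expanded = sp.expand(den)
    den_terms = list(sp.Add.make_args(den_expanded))
    if len(den_terms) < 2:
        return None
    den_species = den_expanded.free_symbols & species

    def den_ok(s: sp.Symbol) -> bool:
        if den_species != {s}:
            return False
        for t in den_terms:
            p = _species_profile(t, species)
            if p is None:
                return False
        return any(_species_profile(t, species) == {s: sp.Integer(1)} for t in den_terms)

    if len(profile) == 1:
        (s,) = profile
        return "MM" if s.name in reactants and den_ok(s) else None
    if len(profile) == 2:
        for s in profile:
            if s.name in reactants and den_ok(s):
                return "MMCAT"
        return None
    return None


def oracle_hill(e: sp.Expr, species: set[sp.Symbol]) -> bool:
    num, den = oracle_fraction(e)
    if not _has_species(den, species):
        return False
    if isinstance(num, sp.Add):
        return False
    powers = [
        f
        for f in _mul_args(num)
        if isinstance(f, sp.Pow)
        and f.base.is_Symbol
        and f.base in species
        and not _has_species(f.exp, species)
    ]
    if len(powers) != 1:
        return False
    leftover = [
        f for f in _mul_args(num) if _has_species(f, species) and f not in powers
    ]
    if leftover:
        return False
    s, p = powers[0].base, powers[0].exp
    if p == 1:
        return False
    den_terms = list(sp.Add.make_args(den))
    if len(den_terms) != 2:
        return False
    free = [t for t in den_terms if not _has_species(t, species)]
    bound = [t for t in den_terms if _has_species(t, species)]
    if len(free) != 1 or len(bound) != 1:
        return False
    sf = [f for f in _mul_args(bound[0]) if _has_species(f, species)]
    return len(sf) == 1 and sf[0] == s**p


def random_positive_env(names, rng: random.Random) -> dict[str, float]:
    # kept inside (0, 1) so subtractive structures like 1 - S stay positive
    # and fractional powers remain real
    return {n: rng.uniform(0.1, 0.9) for n in names}


def sympy_value(e: sp.Expr, env: Mapping[str, float]) -> float:
    subs = {sp.Symbol(k, positive=True): v for k, v in env.items()}
    return float(e.evalf(subs=subs))


def numeric_equal(
    a_value: float, b_value: float, rel_tol: float = 1e-9
) -> bool:
    scale = max(1.0, abs(a_value), abs(b_value))
    return abs(a_value - b_value) <= rel_tol * scale
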