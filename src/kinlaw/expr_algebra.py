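"""Algebraic expression trees for kinetic laws and the structural queries
that drive kinetics-type classification.

A kinetic law is held as a small immutable expression tree (:class:`Expr`).
The classifier never evaluates a law numerically; it asks structural
questions instead:

* which species symbols occur in the law (:func:`species_in`),
* whether the law is a single product of terms (:func:`is_single_product`),
* whether it is a difference of exactly two products
  (:func:`as_two_term_difference`),
* whether it has Michaelis-Menten shape, with or without an explicit
  enzyme in the numerator (:func:`match_michaelis_menten`),
* whether it has Hill shape (:func:`match_hill`),
* whether any species appears in the denominator of its rational form
  (:func:`species_in_denominator`).

All queries operate on a normalized n-ary form with purely numeric
subtrees folded; every transformation preserves the numeric value of the
expression at positive assignments (this is asserted by the test suite
against independent sympy oracles).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

__all__ = [
    "Expr",
    "Num",
    "Sym",
    "Add",
    "Sub",
    "Mul",
    "Div",
    "Pow",
    "Neg",
    "Call",
    "Opaque",
    "RationalForm",
    "ExprError",
    "ParseError",
    "EvaluationError",
    "UnresolvedSymbolError",
    "parse_infix",
    "to_infix",
    "evaluate",
    "symbols_of",
    "substitute",
    "normalize",
    "constant_fold",
    "contains_opaque",
    "species_in",
    "to_rational_form",
    "expand_terms",
    "is_single_product",
    "as_two_term_difference",
    "match_michaelis_menten",
    "match_hill",
    "species_in_denominator",
]

# node kinds
NUM = "num"
SYM = "sym"
ADD = "add"
SUB = "sub"
MUL = "mul"
DIV = "div"
POW = "pow"
NEG = "neg"
CALL = "call"
OPAQUE = "opaque"

#: function names treated as atomic algebraic factors (never expanded)
BUILTIN_FUNCTIONS = frozenset(
    {
        "exp",
        "ln",
        "log",
        "log10",
        "sqrt",
        "abs",
        "floor",
        "ceiling",
        "sin",
        "cos",
        "tan",
        "sinh",
        "cosh",
        "tanh",
        "asin",
        "acos",
        "atan",
        "arcsin",
        "arccos",
        "arctan",
    }
)


class ExprError(Exception):
    """Base class for expression-layer errors."""


class ParseError(ExprError):
    pass


class EvaluationError(ExprError):
    pass


class UnresolvedSymbolError(ExprError):
    """A symbol in the expression has no entry in the role table."""


@dataclass(frozen=True)
class Expr:
    """One node of a kinetic-law expression tree.

    ``kind`` is one of ``num, sym, add, sub, mul, div, pow, neg, call,
    opaque``.  ``call`` covers both user function applications (to be
    inlined from SBML function definitions) and builtin math functions;
    ``opaque`` marks non-algebraic MathML constructs (piecewise, delay,
    boolean logic) that make a law unanalyzable.
    """

    kind: str
    args: tuple = ()
    name: str = ""
    value: float = 0.0

    def __repr__(self) -> str:  # compact, debugging only
        if self.kind == NUM:
            return f"Num({self.value!r})"
        if self.kind == SYM:
            return f"Sym({self.name!r})"
        inner = ", ".join(repr(a) for a in self.args)
        tag = self.name or self.kind
        return f"{tag}({inner})"


def Num(value: float) -> Expr:
    return Expr(NUM, value=value)


def Sym(name: str) -> Expr:
    return Expr(SYM, name=name)


def Add(*args: Expr) -> Expr:
    return Expr(ADD, args=tuple(args))


def Sub(a: Expr, b: Expr) -> Expr:
    return Expr(SUB, args=(a, b))


def Mul(*args: Expr) -> Expr:
    return Expr(MUL, args=tuple(args))


def Div(a: Expr, b: Expr) -> Expr:
    return Expr(DIV, args=(a, b))


def Pow(base: Expr, exponent: Expr) -> Expr:
    return Expr(POW, args=(base, exponent))


def Neg(a: Expr) -> Expr:
    return Expr(NEG, args=(a,))


def Call(name: str, *args: Expr) -> Expr:
    return Expr(CALL, args=tuple(args), name=name)


def Opaque(tag: str, *args: Expr) -> Expr:
    return Expr(OPAQUE, args=tuple(args), name=tag)


ONE = Num(1)
ZERO_NUM = Num(0)


# ---------------------------------------------------------------------------
# infix parsing / printing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<number>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>\*\*|[-+*/^(),]))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"unexpected character {text[pos]!r} at position {pos}")
        pos = m.end()
        if m.lastgroup == "number":
            tokens.append(("number", m.group("number")))
        elif m.lastgroup == "name":
            tokens.append(("name", m.group("name")))
        else:
            op = m.group("op")
            tokens.append(("op", "^" if op == "**" else op))
    tokens.append(("end", ""))
    return tokens


class _Parser:
    """Recursive-descent parser for the fixture grammar: + - * / ^ pow() ()."""

    def __init__(self, text: str) -> None:
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str]:
        return self.tokens[self.i]

    def next(self) -> tuple[str, str]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, op: str) -> None:
        kind, val = self.next()
        if kind != "op" or val != op:
            raise ParseError(f"expected {op!r}, found {val or 'end of input'!r}")

    def parse(self) -> Expr:
        expr = self.expression()
        kind, val = self.peek()
        if kind != "end":
            raise ParseError(f"trailing input starting at {val!r}")
        return expr

    def expression(self) -> Expr:
        node = self.term()
        while True:
            kind, val = self.peek()
            if kind == "op" and val in "+-":
                self.next()
                rhs = self.term()
                node = Add(node, rhs) if val == "+" else Sub(node, rhs)
            else:
                return node

    def term(self) -> Expr:
        node = self.unary()
        while True:
            kind, val = self.peek()
            if kind == "op" and val in "*/":
                self.next()
                rhs = self.unary()
                node = Mul(node, rhs) if val == "*" else Div(node, rhs)
            else:
                return node

    def unary(self) -> Expr:
        kind, val = self.peek()
        if kind == "op" and val == "-":
            self.next()
            return Neg(self.unary())
        if kind == "op" and val == "+":
            self.next()
            return self.unary()
        return self.power()

    def power(self) -> Expr:
        base = self.atom()
        kind, val = self.peek()
        if kind == "op" and val == "^":
            self.next()
            return Pow(base, self.unary())  # right associative
        return base

    def atom(self) -> Expr:
        kind, val = self.next()
        if kind == "number":
            text = val
            if re.fullmatch(r"\d+", text):
                return Num(int(text))
            return Num(float(text))
        if kind == "name":
            k2, v2 = self.peek()
            if k2 == "op" and v2 == "(":
                self.next()
                args = [self.expression()]
                while True:
                    k3, v3 = self.peek()
                    if k3 == "op" and v3 == ",":
                        self.next()
                        args.append(self.expression())
                    else:
                        break
                self.expect(")")
                if val == "pow":
                    if len(args) != 2:
                        raise ParseError("pow() takes exactly two arguments")
                    return Pow(args[0], args[1])
                return Call(val, *args)
            return Sym(val)
        if kind == "op" and val == "(":
            node = self.expression()
            self.expect(")")
            return node
        raise ParseError(f"unexpected token {val or 'end of input'!r}")


def parse_infix(text: str) -> Expr:
    """Parse an infix rate-law string (operators ``+ - * / ^``, ``pow``)."""
    return _Parser(text).parse()


_PREC = {ADD: 1, SUB: 1, MUL: 2, DIV: 2, NEG: 3, POW: 4}


def to_infix(expr: Expr) -> str:
    """Render an expression as a canonical infix string."""

    def render(e: Expr, parent_prec: int) -> str:
        if e.kind == NUM:
            v = e.value
            if isinstance(v, int) or (isinstance(v, float) and v.is_integer()):
                text = str(int(v))
            else:
                text = repr(v)
            if (isinstance(v, (int, float)) and v < 0) and parent_prec >= 2:
                return f"({text})"
            return text
        if e.kind == SYM:
            return e.name
        if e.kind == CALL:
            return f"{e.name}({', '.join(render(a, 0) for a in e.args)})"
        if e.kind == OPAQUE:
            return f"<{e.name}>({', '.join(render(a, 0) for a in e.args)})"
        if e.kind == NEG:
            return _paren(f"-{render(e.args[0], _PREC[NEG])}", _PREC[NEG], parent_prec)
        if e.kind == POW:
            base = render(e.args[0], _PREC[POW] + 1)
            exponent = render(e.args[1], _PREC[POW] + 1)
            return _paren(f"{base}^{exponent}", _PREC[POW], parent_prec)
        ops = {ADD: " + ", SUB: " - ", MUL: "*", DIV: "/"}
        prec = _PREC[e.kind]
        parts = []
        for idx, a in enumerate(e.args):
            # right operand of - and / needs strict parenthesization
            child_prec = prec + 1 if (idx > 0 and e.kind in (SUB, DIV)) else prec
            parts.append(render(a, child_prec))
        return _paren(ops[e.kind].join(parts), prec, parent_prec)

    def _paren(text: str, prec: int, parent_prec: int) -> str:
        return f"({text})" if prec < parent_prec else text

    return render(expr, 0)


# ---------------------------------------------------------------------------
# evaluation, symbol census, substitution
# ---------------------------------------------------------------------------

_BUILTIN_EVAL: dict[str, Callable[..., float]] = {
    "exp": math.exp,
    "ln": math.log,
    "log": math.log10,
    "log10": math.log10,
    "sqrt": math.sqrt,
    "abs": abs,
    "floor": math.floor,
    "ceiling": math.ceil,
    "sin": math.sin,
    "cos": math.cos,
    "tan": math.tan,
    "sinh": math.sinh,
    "cosh": math.cosh,
    "tanh": math.tanh,
    "asin": math.asin,
    "acos": math.acos,
    "atan": math.atan,
    "arcsin": math.asin,
    "arccos": math.acos,
    "arctan": math.atan,
}


def evaluate(expr: Expr, env: Mapping[str, float]) -> float:
    """Numerically evaluate ``expr`` with symbol values taken from ``env``."""
    if expr.kind == NUM:
        return float(expr.value)
    if expr.kind == SYM:
        try:
            return float(env[expr.name])
        except KeyError as exc:
            raise EvaluationError(f"no value for symbol {expr.name!r}") from exc
    if expr.kind == ADD:
        return math.fsum(evaluate(a, env) for a in expr.args)
    if expr.kind == SUB:
        return evaluate(expr.args[0], env) - evaluate(expr.args[1], env)
    if expr.kind == MUL:
        out = 1.0
        for a in expr.args:
            out *= evaluate(a, env)
        return out
    if expr.kind == DIV:
        return evaluate(expr.args[0], env) / evaluate(expr.args[1], env)
    if expr.kind == POW:
        return evaluate(expr.args[0], env) ** evaluate(expr.args[1], env)
    if expr.kind == NEG:
        return -evaluate(expr.args[0], env)
    if expr.kind == CALL:
        fn = _BUILTIN_EVAL.get(expr.name)
        if fn is None:
            raise EvaluationError(f"cannot evaluate function {expr.name!r}")
        return fn(*(evaluate(a, env) for a in expr.args))
    raise EvaluationError(f"cannot evaluate {expr.kind} node ({expr.name})")


def symbols_of(expr: Expr) -> frozenset[str]:
    """All symbol identifiers occurring anywhere in the tree.

    Function and opaque-construct names are not symbols; their arguments
    are still traversed.
    """
    out: set[str] = set()

    def walk(e: Expr) -> None:
        if e.kind == SYM:
            out.add(e.name)
        for a in e.args:
            walk(a)

    walk(expr)
    return frozenset(out)


def substitute(expr: Expr, mapping: Mapping[str, Expr]) -> Expr:
    """Simultaneously replace symbols by expressions."""
    if expr.kind == SYM:
        return mapping.get(expr.name, expr)
    if not expr.args:
        return expr
    return Expr(
        expr.kind,
        args=tuple(substitute(a, mapping) for a in expr.args),
        name=expr.name,
        value=expr.value,
    )


def contains_opaque(expr: Expr) -> bool:
    if expr.kind == OPAQUE:
        return True
    return any(contains_opaque(a) for a in expr.args)


# ---------------------------------------------------------------------------
# normalization: n-ary add/mul, constant folding
# ---------------------------------------------------------------------------


def _is_num(e: Expr) -> bool:
    return e.kind == NUM


def _num_value(e: Expr) -> float:
    return e.value


def _make_num(v) -> Expr:
    if isinstance(v, float) and v.is_integer() and abs(v) < 1e15:
        return Num(int(v))
    return Num(v)


def _nmul(args: Sequence[Expr]) -> Expr:
    """Smart n-ary product: flattens, folds the numeric coefficient."""
    flat: list[Expr] = []
    coeff = 1.0
    for a in args:
        if a.kind == MUL:
            for b in a.args:
                if _is_num(b):
                    coeff *= _num_value(b)
                else:
                    flat.append(b)
        elif _is_num(a):
            coeff *= _num_value(a)
        else:
            flat.append(a)
    if coeff == 0:
        return Num(0)
    if not flat:
        return _make_num(coeff)
    if coeff != 1:
        flat = [_make_num(coeff)] + flat
    if len(flat) == 1:
        return flat[0]
    return Mul(*flat)


def _nadd(args: Sequence[Expr]) -> Expr:
    flat: list[Expr] = []
    const = 0.0
    for a in args:
        if a.kind == ADD:
            for b in a.args:
                if _is_num(b):
                    const += _num_value(b)
                else:
                    flat.append(b)
        elif _is_num(a):
            const += _num_value(a)
        else:
            flat.append(a)
    if not flat:
        return _make_num(const)
    if const != 0:
        flat = flat + [_make_num(const)]
    if len(flat) == 1:
        return flat[0]
    return Add(*flat)


def _npow(base: Expr, exponent: Expr) -> Expr:
    if _is_num(base) and _num_value(base) == 1:
        return Num(1)
    if _is_num(exponent):
        v = _num_value(exponent)
        if v == 1:
            return base
        if v == 0:
            return Num(1)  # sound on the positive orthant
        if _is_num(base):
            try:
                return _make_num(float(_num_value(base)) ** float(v))
            except (OverflowError, ValueError, ZeroDivisionError):
                pass
    return Pow(base, exponent)


def normalize(expr: Expr) -> Expr:
    """Normalize to n-ary ``add``/``mul`` with folded numeric subtrees.

    ``sub``/``neg`` become additions with a ``-1`` coefficient and
    ``div`` becomes multiplication by a ``-1`` power, so downstream
    queries only see five node kinds (plus calls/opaques, kept atomic).
    Additive structure is preserved: ``1 + -1*M`` stays a sum because it
    contains a non-numeric leaf.
    """
    k = expr.kind
    if k in (NUM, SYM):
        return expr
    if k == CALL and expr.name == "sqrt" and len(expr.args) == 1:
        return _npow(normalize(expr.args[0]), Num(0.5))
    if k in (CALL, OPAQUE):
        return Expr(k, args=tuple(normalize(a) for a in expr.args), name=expr.name)
    if k == NEG:
        return _nmul([Num(-1), normalize(expr.args[0])])
    if k == SUB:
        a, b = expr.args
        return _nadd([normalize(a), _nmul([Num(-1), normalize(b)])])
    if k == DIV:
        a, b = expr.args
        return _nmul([normalize(a), _npow(normalize(b), Num(-1))])
    if k == ADD:
        return _nadd([normalize(a) for a in expr.args])
    if k == MUL:
        return _nmul([normalize(a) for a in expr.args])
    if k == POW:
        return _npow(normalize(expr.args[0]), normalize(expr.args[1]))
    raise ExprError(f"unknown node kind {k!r}")


def constant_fold(expr: Expr) -> Expr:
    """Alias for :func:`normalize` (folding is part of normalization)."""
    return normalize(expr)


# ---------------------------------------------------------------------------
# species census
# ---------------------------------------------------------------------------


def species_in(expr: Expr, roles: Mapping[str, str]) -> frozenset[str]:
    """Distinct identifiers with role ``species`` occurring in ``expr``."""
    out: set[str] = set()
    for name in symbols_of(expr):
        try:
            role = roles[name]
        except KeyError as exc:
            raise UnresolvedSymbolError(
                f"symbol {name!r} has no role assignment"
            ) from exc
        if role == "species":
            out.add(name)
    return frozenset(out)


def _has_species(expr: Expr, roles: Mapping[str, str]) -> bool:
    return bool(species_in(expr, roles))


# ---------------------------------------------------------------------------
# rational form
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RationalForm:
    """A kinetic law as a single numerator/denominator pair.

    ``numerator / denominator`` equals the original expression at every
    positive assignment where both are defined; a fraction-free law has
    denominator 1.
    """

    numerator: Expr
    denominator: Expr


def _negated_exponent(exponent: Expr) -> Optional[Expr]:
    """If ``exponent`` is explicitly negated, return its positive part."""
    if _is_num(exponent) and _num_value(exponent) < 0:
        return _make_num(-_num_value(exponent))
    if exponent.kind == MUL and exponent.args and _is_num(exponent.args[0]):
        c = _num_value(exponent.args[0])
        if c < 0:
            return _nmul([_make_num(-c), *exponent.args[1:]])
    return None


def _rat(e: Expr) -> tuple[Expr, Expr]:
    """Return (numerator, denominator) trees for a normalized expression."""
    if e.kind in (NUM, SYM, CALL, OPAQUE):
        return e, ONE
    if e.kind == MUL:
        nums, dens = [], []
        for a in e.args:
            n, d = _rat(a)
            nums.append(n)
            dens.append(d)
        return _nmul(nums), _nmul(dens)
    if e.kind == ADD:
        # combine over a common denominator
        parts = [_rat(a) for a in e.args]
        den = _nmul([d for _, d in parts])
        terms = []
        for i, (n, _) in enumerate(parts):
            others = [parts[j][1] for j in range(len(parts)) if j != i]
            terms.append(_nmul([n, *others]))
        return _nadd(terms), den
    if e.kind == POW:
        base, exponent = e.args
        nb, db = _rat(base)
        if _is_num(exponent):
            v = _num_value(exponent)
            if float(v).is_integer():
                k = int(v)
                if k >= 0:
                    return _npow(nb, _make_num(k)), _npow(db, _make_num(k))
                return _npow(db, _make_num(-k)), _npow(nb, _make_num(-k))
        pos = _negated_exponent(exponent)
        if pos is not None:
            return _npow(db, pos), _npow(nb, pos)
        # symbolic / non-integer positive exponent: keep the power intact;
        # an explicitly divided base still contributes to the denominator
        return _npow(nb, exponent), _npow(db, exponent)
    raise ExprError(f"unexpected node kind {e.kind!r} in rational form")


def to_rational_form(expr: Expr) -> RationalForm:
    """Collapse divisions and negative-literal powers into one fraction."""
    n, d = _rat(normalize(expr))
    return RationalForm(n, d)


# ---------------------------------------------------------------------------
# term expansion (products distributed over species-containing sums)
# ---------------------------------------------------------------------------

#: one additive term: numeric coefficient and non-numeric factors
Term = tuple[float, tuple[Expr, ...]]


def expand_terms(expr: Expr, roles: Mapping[str, str]) -> list[Term]:
    """Flatten ``expr`` into a sum of product terms.

    Products are distributed over sums *containing species*; a purely
    species-free sum (e.g. ``K1 + K2``) is kept intact as one atomic
    factor, since it cannot affect any species-based criterion.
    """
    e = normalize(expr)

    def terms(x: Expr) -> list[Term]:
        if x.kind == NUM:
            return [(float(x.value), ())]
        if x.kind == ADD:
            if _has_species(x, roles):
                out: list[Term] = []
                for a in x.args:
                    out.extend(terms(a))
                return out
            return [(1.0, (x,))]
        if x.kind == MUL:
            acc: list[Term] = [(1.0, ())]
            for a in x.args:
                nxt: list[Term] = []
                for c1, f1 in acc:
                    for c2, f2 in terms(a):
                        nxt.append((c1 * c2, f1 + f2))
                acc = nxt
            return acc
        return [(1.0, (x,))]

    return terms(e)


def _term_expr(coeff: float, factors: Sequence[Expr]) -> Expr:
    parts: list[Expr] = []
    if coeff != 1:
        parts.append(_make_num(coeff))
    parts.extend(factors)
    if not parts:
        return ONE
    return _nmul(parts)


def _simple_product_term(
    coeff: float, factors: Sequence[Expr], roles: Mapping[str, str]
) -> bool:
    """True iff the term is a plain product: every species occurrence is a
    bare species symbol or a positive power of one."""
    for f in factors:
        if not _has_species(f, roles):
            continue
        if f.kind == SYM:
            continue
        if (
            f.kind == POW
            and f.args[0].kind == SYM
            and _has_species(f.args[0], roles)
            and not _has_species(f.args[1], roles)
        ):
            exponent = f.args[1]
            if _is_num(exponent):
                if _num_value(exponent) > 0:
                    continue
                return False
            if _negated_exponent(exponent) is None:
                continue
            return False
        return False
    return True


def is_single_product(expr: Expr, roles: Mapping[str, str]) -> bool:
    """Is the law a single product of terms?

    False whenever a species occurs in the denominator of the rational
    form (fraction-type laws are handled by the MM/Hill/FR branch of the
    decision table; without this gate a Michaelis-Menten law written as
    ``V*S*pow(K + S, -1)`` would literally be a product and the type
    categories would overlap).
    """
    if contains_opaque(expr):
        return False
    rf = to_rational_form(expr)
    if species_in(rf.denominator, roles):
        return False
    ts = expand_terms(rf.numerator, roles)
    if len(ts) != 1:
        return False
    coeff, factors = ts[0]
    return _simple_product_term(coeff, factors, roles)


def as_two_term_difference(
    expr: Expr, roles: Mapping[str, str]
) -> Optional[tuple[Expr, Expr]]:
    """Decompose a law into ``positive - negative`` products, if possible.

    Returns ``(positive_term, negative_term)`` when the law, with products
    distributed over species-containing sums, is exactly two terms of
    opposite sign and each term is itself a plain product.  Species-free
    common prefactors (compartments, rate constants) end up distributed
    into both terms.  Returns ``None`` otherwise, and always ``None`` when
    a species sits in the denominator.
    """
    if contains_opaque(expr):
        return None
    rf = to_rational_form(expr)
    if species_in(rf.denominator, roles):
        return None
    ts = expand_terms(rf.numerator, roles)
    if len(ts) != 2:
        return None
    (c1, f1), (c2, f2) = ts
    if c1 == 0 or c2 == 0 or (c1 > 0) == (c2 > 0):
        return None
    if not (_simple_product_term(c1, f1, roles) and _simple_product_term(c2, f2, roles)):
        return None
    pos, neg = ((c1, f1), (c2, f2)) if c1 > 0 else ((c2, f2), (c1, f1))
    den = rf.denominator
    pos_expr = _term_expr(pos[0], pos[1])
    neg_expr = _term_expr(-neg[0], neg[1])
    if not (_is_num(den) and _num_value(den) == 1):
        pos_expr = Div(pos_expr, den)
        neg_expr = Div(neg_expr, den)
    return pos_expr, neg_expr


# -- species exponent profiles ---------------------------------------------


def _term_species_profile(
    factors: Sequence[Expr], roles: Mapping[str, str]
) -> Optional[dict[str, Expr]]:
    """Map species -> exponent expression for a product term.

    Returns None when some species occurs inside a factor that is not a
    bare symbol or a power of one (the term then has no clean profile).
    Repeated factors accumulate literal exponents (``A*A`` -> A^2).
    """
    profile: dict[str, Expr] = {}

    def bump(name: str, exponent: Expr) -> bool:
        if name not in profile:
            profile[name] = exponent
            return True
        old = profile[name]
        if _is_num(old) and _is_num(exponent):
            profile[name] = _make_num(_num_value(old) + _num_value(exponent))
            return True
        return False  # mixed symbolic exponents: no clean profile

    for f in factors:
        if not _has_species(f, roles):
            continue
        if f.kind == SYM:
            if not bump(f.name, Num(1)):
                return None
        elif (
            f.kind == POW
            and f.args[0].kind == SYM
            and roles.get(f.args[0].name) == "species"
            and not _has_species(f.args[1], roles)
        ):
            if not bump(f.args[0].name, f.args[1]):
                return None
        else:
            return None
    return profile


def _single_term_profile(
    expr: Expr, roles: Mapping[str, str]
) -> Optional[tuple[float, tuple[Expr, ...], dict[str, Expr]]]:
    ts = expand_terms(expr, roles)
    if len(ts) != 1:
        return None
    coeff, factors = ts[0]
    profile = _term_species_profile(factors, roles)
    if profile is None:
        return None
    return coeff, factors, profile


def _exponent_is_one(exponent: Expr) -> bool:
    return _is_num(exponent) and _num_value(exponent) == 1


def _denominator_mm_ok(
    den: Expr, species: str, roles: Mapping[str, str]
) -> bool:
    """Michaelis-Menten denominator test for substrate ``species``:
    a sum of >= 2 terms, the substrate appears with exponent 1 in at least
    one of them, and no other species occurs anywhere in the denominator."""
    if species_in(den, roles) - {species}:
        return False
    ts = expand_terms(den, roles)
    if len(ts) < 2:
        return False
    found_linear = False
    for _, factors in ts:
        profile = _term_species_profile(factors, roles)
        if profile is None:
            return False
        if set(profile) == {species} and _exponent_is_one(profile[species]):
            found_linear = True
    return found_linear


def match_michaelis_menten(
    expr: Expr,
    reactants: Iterable[str],
    roles: Mapping[str, str],
) -> Optional[str]:
    """Match the Michaelis-Menten shapes.

    Returns ``"MM"`` when the numerator is a single product containing
    exactly one species S (exponent 1) with S a reactant, and the
    denominator is a >= 2 term sum in which the only species is S and S
    appears linearly in some term; ``"MMCAT"`` when the numerator instead
    contains exactly {S, E} (the explicit enzyme E being any other
    species, absent from the denominator); ``None`` otherwise.
    """
    if contains_opaque(expr):
        return None
    reactant_set = set(reactants)
    rf = to_rational_form(expr)
    if not species_in(rf.denominator, roles):
        return None
    top = _single_term_profile(rf.numerator, roles)
    if top is None:
        return None
    _, _, profile = top
    linear = {s for s, p in profile.items() if _exponent_is_one(p)}
    if len(profile) == 1 and linear == set(profile):
        (s,) = linear
        if s in reactant_set and _denominator_mm_ok(rf.denominator, s, roles):
            return "MM"
        return None
    if len(profile) == 2 and linear == set(profile):
        for s in sorted(linear):
            other = next(iter(linear - {s}))
            if s in reactant_set and _denominator_mm_ok(rf.denominator, s, roles):
                # the enzyme must stay out of the denominator; mm_ok already
                # rejects any species other than s there
                return "MMCAT"
        return None
    return None


def match_hill(expr: Expr, roles: Mapping[str, str]) -> bool:
    """Match the Hill shape ``c * S^p / (c1*K^q + c2*S^p)``.

    The numerator must contain exactly one species, as a single power
    ``S^p`` with ``p`` either symbolic or a literal other than 1 (a Hill
    coefficient of exactly 1 collapses to Michaelis-Menten shape); the
    denominator must be exactly two terms, one species-free and one whose
    species content is the syntactically identical power ``S^p``.
    """
    if contains_opaque(expr):
        return False
    rf = to_rational_form(expr)
    if not species_in(rf.denominator, roles):
        return False
    ts = expand_terms(rf.numerator, roles)
    if len(ts) != 1:
        return False
    _, factors = ts[0]
    powers = [
        f
        for f in factors
        if f.kind == POW
        and f.args[0].kind == SYM
        and roles.get(f.args[0].name) == "species"
        and not _has_species(f.args[1], roles)
    ]
    others_with_species = [
        f for f in factors if _has_species(f, roles) and f not in powers
    ]
    if len(powers) != 1 or others_with_species:
        return False
    hill_pow = powers[0]
    s_name = hill_pow.args[0].name
    exponent = normalize(hill_pow.args[1])
    if _exponent_is_one(exponent):
        return False
    den_terms = expand_terms(rf.denominator, roles)
    if len(den_terms) != 2:
        return False
    free = [t for t in den_terms if not any(_has_species(f, roles) for f in t[1])]
    bound = [t for t in den_terms if t not in free]
    if len(free) != 1 or len(bound) != 1:
        return False
    _, bfactors = bound[0]
    species_factors = [f for f in bfactors if _has_species(f, roles)]
    if len(species_factors) != 1:
        return False
    f = species_factors[0]
    return (
        f.kind == POW
        and f.args[0].kind == SYM
        and f.args[0].name == s_name
        and normalize(f.args[1]) == exponent
    )


def species_in_denominator(expr: Expr, roles: Mapping[str, str]) -> bool:
    """Does any species occur in the denominator of the rational form?"""
    if contains_opaque(expr):
        return False
    return bool(species_in(to_rational_form(expr).denominator, roles))
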