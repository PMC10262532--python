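"""Reading and writing SBML reaction-network models.

Reads SBML levels 1-3 with a deliberately narrow focus: the information
kinetics classification needs — compartments, species, parameters,
function definitions, and reactions with their kinetic-law math.  Level 1
kinetic laws (infix ``formula`` attributes) and level 2/3 content MathML
are both parsed into :class:`~kinlaw.expr_algebra.Expr` trees.  Rate
rules, assignment rules, events and unit definitions are outside the
classification scheme; their presence is logged, not interpreted.

Output is always SBML Level 3 Version 1, and a written model round-trips
through :func:`load_model` to an equivalent record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

from lxml import etree

from .expr_algebra import (
    BUILTIN_FUNCTIONS,
    Call,
    Div,
    Expr,
    ExprError,
    Neg,
    Num,
    Opaque,
    Pow,
    Sub,
    Sym,
    parse_infix,
    substitute,
    symbols_of,
)
from .expr_algebra import ADD, CALL, DIV, MUL, NEG, NUM, OPAQUE, POW, SUB, SYM

__all__ = [
    "SymbolRole",
    "FunctionDefinition",
    "ReactionRecord",
    "ModelRecord",
    "SBMLError",
    "SBMLLoadError",
    "SymbolResolutionError",
    "ExpansionError",
    "SerializationError",
    "load_model",
    "load_corpus",
    "write_model",
    "resolve_symbol_roles",
    "effective_roles",
    "expand_function_definitions",
]

logger = logging.getLogger("kinlaw")

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
SBML_L3V1_NS = "http://www.sbml.org/sbml/level3/version1/core"

#: csymbol definitionURL fragments for SBML built-in symbols
_TIME_URLS = ("symbols/time", "symbols/delay", "symbols/avogadro", "symbols/rateOf")


class SBMLError(Exception):
    pass


class SBMLLoadError(SBMLError):
    pass


class SymbolResolutionError(SBMLError):
    pass


class ExpansionError(SBMLError):
    """Function-definition inlining failed (unknown name, arity, cycle)."""


class SerializationError(SBMLError):
    pass


@dataclass(frozen=True)
class SymbolRole:
    """An identifier paired with its resolved role in a model."""

    identifier: str
    role: str  # species | parameter | compartment | local-parameter |
    #            function-name | time-like | other


@dataclass(frozen=True)
class FunctionDefinition:
    name: str
    parameters: tuple[str, ...]
    body: Expr


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: distinct participant sets plus its kinetic law.

    Reactant/product/modifier lists are *sets of distinct species*; a
    species listed twice (or with stoichiometry 2) contributes a single
    element, which is what the reaction-type bins count.
    """

    reaction_id: str
    reactants: frozenset[str]
    products: frozenset[str]
    modifiers: frozenset[str] = frozenset()
    reversible: bool = False
    kinetic_law: Optional[Expr] = None
    local_parameters: frozenset[str] = frozenset()


@dataclass
class ModelRecord:
    """A parsed SBML model, reduced to what classification needs."""

    model_id: str
    species: tuple[str, ...] = ()
    parameters: tuple[str, ...] = ()
    compartments: tuple[str, ...] = ()
    function_definitions: dict[str, FunctionDefinition] = field(default_factory=dict)
    reactions: list[ReactionRecord] = field(default_factory=list)
    source_path: Optional[str] = None

    @property
    def roles(self) -> dict[str, str]:
        return resolve_symbol_roles(self)

    @property
    def symbol_table(self) -> frozenset[SymbolRole]:
        return frozenset(SymbolRole(k, v) for k, v in self.roles.items())


# ---------------------------------------------------------------------------
# MathML parsing
# ---------------------------------------------------------------------------


def _lname(el: etree._Element) -> str:
    return etree.QName(el).localname


_NARY = {"plus": ADD, "times": MUL}
_UNSUPPORTED_OPS = {
    "eq",
    "neq",
    "gt",
    "lt",
    "geq",
    "leq",
    "and",
    "or",
    "xor",
    "not",
    "factorial",
    "min",
    "max",
    "rem",
    "quotient",
    "implies",
}


def parse_mathml(element: etree._Element) -> Expr:
    """Parse a content-MathML element (``<math>`` or any subexpression)."""
    tag = _lname(element)
    if tag == "math":
        children = [c for c in element if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SBMLLoadError("<math> must contain exactly one expression")
        return parse_mathml(children[0])
    if tag == "ci":
        return Sym(element.text.strip())
    if tag == "cn":
        return _parse_cn(element)
    if tag == "csymbol":
        return _parse_csymbol(element)
    if tag == "pi":
        return Num(math.pi)
    if tag == "exponentiale":
        return Num(math.e)
    if tag in ("true", "false", "notanumber", "infinity", "semantics"):
        return Opaque(tag)
    if tag == "piecewise":
        args = [parse_mathml(c) for c in _pieces(element)]
        return Opaque("piecewise", *args)
    if tag == "apply":
        return _parse_apply(element)
    if tag == "lambda":
        raise SBMLLoadError("<lambda> only allowed inside a functionDefinition")
    raise SBMLLoadError(f"unsupported MathML element <{tag}>")


def _pieces(piecewise: etree._Element) -> list[etree._Element]:
    out = []
    for piece in piecewise:
        if not isinstance(piece.tag, str):
            continue
        for child in piece:
            if isinstance(child.tag, str) and _lname(child) not in _UNSUPPORTED_OPS:
                # keep value expressions for the species census; conditions
                # with relational operators are dropped structurally but
                # their operands are retained below via apply handling
                out.append(child)
    return out


def _parse_cn(el: etree._Element) -> Expr:
    ctype = el.get("type", "real")
    if ctype == "integer":
        return Num(int(el.text.strip()))
    if ctype in ("e-notation", "rational"):
        sep = el.find(f"{{{MATHML_NS}}}sep")
        if sep is None:
            sep = next((c for c in el if isinstance(c.tag, str)), None)
        mantissa = float(el.text.strip())
        tail = float(sep.tail.strip()) if sep is not None and sep.tail else 0.0
        if ctype == "e-notation":
            return Num(mantissa * 10.0 ** tail)
        return Num(mantissa / tail)
    return Num(float(el.text.strip()))


def _parse_csymbol(el: etree._Element) -> Expr:
    url = el.get("definitionURL", "")
    if url.endswith("time"):
        return Sym("time")
    if url.endswith("avogadro"):
        return Num(6.02214179e23)
    return Opaque(_lname(el) + ":" + url.rsplit("/", 1)[-1])


def _parse_apply(el: etree._Element) -> Expr:
    children = [c for c in el if isinstance(c.tag, str)]
    if not children:
        raise SBMLLoadError("empty <apply>")
    op = children[0]
    op_tag = _lname(op)
    raw_args = children[1:]

    if op_tag == "minus":
        args = [parse_mathml(a) for a in raw_args]
        if len(args) == 1:
            return Neg(args[0])
        if len(args) == 2:
            return Sub(args[0], args[1])
        raise SBMLLoadError("<minus> takes one or two operands")
    if op_tag == "divide":
        a, b = (parse_mathml(x) for x in raw_args)
        return Div(a, b)
    if op_tag == "power":
        a, b = (parse_mathml(x) for x in raw_args)
        return Pow(a, b)
    if op_tag in _NARY:
        args = [parse_mathml(a) for a in raw_args]
        if not args:
            return Num(0) if op_tag == "plus" else Num(1)
        if len(args) == 1:
            return args[0]
        return Expr(_NARY[op_tag], args=tuple(args))
    if op_tag == "root":
        degree = Num(2)
        operands = []
        for a in raw_args:
            if _lname(a) == "degree":
                inner = [c for c in a if isinstance(c.tag, str)]
                degree = parse_mathml(inner[0]) if inner else Num(2)
            else:
                operands.append(parse_mathml(a))
        return Pow(operands[0], Div(Num(1), degree))
    if op_tag == "log":
        base = None
        operands = []
        for a in raw_args:
            if _lname(a) == "logbase":
                inner = [c for c in a if isinstance(c.tag, str)]
                base = parse_mathml(inner[0]) if inner else Num(10)
            else:
                operands.append(parse_mathml(a))
        if base is not None:
            return Div(Call("ln", operands[0]), Call("ln", base))
        return Call("log10", operands[0])
    if op_tag in BUILTIN_FUNCTIONS:
        return Call(op_tag, *(parse_mathml(a) for a in raw_args))
    if op_tag == "ci":
        return Call(op.text.strip(), *(parse_mathml(a) for a in raw_args))
    if op_tag == "csymbol":
        url = op.get("definitionURL", "")
        return Opaque(
            "csymbol:" + url.rsplit("/", 1)[-1],
            *(_safe_parse(a) for a in raw_args),
        )
    if op_tag in _UNSUPPORTED_OPS:
        return Opaque(op_tag, *(_safe_parse(a) for a in raw_args))
    raise SBMLLoadError(f"unsupported MathML operator <{op_tag}>")


def _safe_parse(el: etree._Element) -> Expr:
    try:
        return parse_mathml(el)
    except SBMLLoadError:
        return Opaque(_lname(el))


# ---------------------------------------------------------------------------
# SBML reading
# ---------------------------------------------------------------------------


def _find_children(parent: Optional[etree._Element], name: str) -> list:
    if parent is None:
        return []
    return [c for c in parent.iter() if isinstance(c.tag, str) and _lname(c) == name]


def _child(parent: etree._Element, name: str) -> Optional[etree._Element]:
    for c in parent:
        if isinstance(c.tag, str) and _lname(c) == name:
            return c
    return None


def load_model(path: str | Path) -> ModelRecord:
    """Load one SBML file (level 1, 2 or 3) into a :class:`ModelRecord`.

    Reactions lacking a kinetic law are retained with ``kinetic_law``
    absent and a warning logged; malformed XML or non-SBML content raises
    :class:`SBMLLoadError` naming the file.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLLoadError(f"cannot read SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if _lname(root) != "sbml":
        raise SBMLLoadError(f"{path}: root element is <{_lname(root)}>, not <sbml>")
    level = int(root.get("level", "3"))
    model_el = _child(root, "model")
    if model_el is None:
        raise SBMLLoadError(f"{path}: no <model> element")

    model_id = model_el.get("id") or model_el.get("name") or path.stem

    compartments = tuple(
        c.get("id") or c.get("name")
        for c in _find_children(_child(model_el, "listOfCompartments"), "compartment")
    )
    species = tuple(
        s.get("id") or s.get("name")
        for s in _find_children(_child(model_el, "listOfSpecies"), "species")
        + _find_children(_child(model_el, "listOfSpecies"), "specie")
    )
    parameters = tuple(
        p.get("id") or p.get("name")
        for p in _find_children(_child(model_el, "listOfParameters"), "parameter")
    )

    function_definitions: dict[str, FunctionDefinition] = {}
    fd_list = _child(model_el, "listOfFunctionDefinitions")
    for fd in _find_children(fd_list, "functionDefinition"):
        name = fd.get("id") or fd.get("name")
        math_el = _child(fd, "math")
        lam = _child(math_el, "lambda") if math_el is not None else None
        if lam is None:
            logger.warning("model %s: function %s has no lambda body", model_id, name)
            continue
        formals = []
        body_el = None
        for c in lam:
            if not isinstance(c.tag, str):
                continue
            if _lname(c) == "bvar":
                ci = _child(c, "ci")
                formals.append(ci.text.strip())
            else:
                body_el = c
        if body_el is None:
            raise SBMLLoadError(f"{path}: function {name} has no body")
        function_definitions[name] = FunctionDefinition(
            name, tuple(formals), parse_mathml(body_el)
        )

    for extra in ("listOfRules", "listOfEvents", "listOfConstraints"):
        if _child(model_el, extra) is not None:
            logger.warning(
                "model %s: %s present; rules/events are ignored by classification",
                model_id,
                extra,
            )

    reactions: list[ReactionRecord] = []
    rx_list = _child(model_el, "listOfReactions")
    for rx in _find_children(rx_list, "reaction"):
        rid = rx.get("id") or rx.get("name")
        reactants = _participants(rx, "listOfReactants")
        products = _participants(rx, "listOfProducts")
        modifiers = frozenset(
            m.get("species") or m.get("specie")
            for m in _find_children(
                _child(rx, "listOfModifiers"), "modifierSpeciesReference"
            )
        )
        reversible = rx.get("reversible", "true").lower() == "true"
        law_expr = None
        local_params: frozenset[str] = frozenset()
        kl = _child(rx, "kineticLaw")
        if kl is not None:
            local_params = frozenset(
                p.get("id") or p.get("name")
                for lp_list_name, lp_name in (
                    ("listOfLocalParameters", "localParameter"),
                    ("listOfParameters", "parameter"),
                )
                for p in _find_children(_child(kl, lp_list_name), lp_name)
            )
            math_el = _child(kl, "math")
            if math_el is not None:
                law_expr = parse_mathml(math_el)
            elif kl.get("formula"):
                law_expr = parse_infix(kl.get("formula"))
        if law_expr is None:
            logger.warning("model %s: reaction %s has no kinetic law", model_id, rid)
        reactions.append(
            ReactionRecord(
                reaction_id=rid,
                reactants=reactants,
                products=products,
                modifiers=modifiers,
                reversible=reversible,
                kinetic_law=law_expr,
                local_parameters=local_params,
            )
        )

    record = ModelRecord(
        model_id=model_id,
        species=species,
        parameters=parameters,
        compartments=compartments,
        function_definitions=function_definitions,
        reactions=reactions,
        source_path=str(path),
    )
    resolve_symbol_roles(record)  # fail fast on irreconcilable duplicates
    if level == 1:
        logger.debug("model %s read as SBML level 1", model_id)
    return record


def _participants(rx: etree._Element, list_name: str) -> frozenset[str]:
    parent = _child(rx, list_name)
    refs = _find_children(parent, "speciesReference") + _find_children(
        parent, "specieReference"
    )
    return frozenset(r.get("species") or r.get("specie") for r in refs)


def load_corpus(paths: Sequence[str | Path]) -> list[ModelRecord]:
    """Load many SBML files; per-file failures are logged and skipped."""
    out = []
    for p in paths:
        try:
            out.append(load_model(p))
        except SBMLError as exc:
            logger.warning("skipping %s: %s", p, exc)
    return out


# ---------------------------------------------------------------------------
# symbol roles
# ---------------------------------------------------------------------------


def resolve_symbol_roles(model: ModelRecord) -> dict[str, str]:
    """Map every model-level identifier to its role.

    Compartment identifiers are never species (a variable compartment
    size acts as a parameter as far as kinetics shape is concerned).
    Duplicate identifiers across the species/parameter/compartment
    namespaces cannot be reconciled and raise.
    """
    roles: dict[str, str] = {"time": "time-like"}
    groups = (
        (model.species, "species"),
        (model.parameters, "parameter"),
        (model.compartments, "compartment"),
        (tuple(model.function_definitions), "function-name"),
    )
    for identifiers, role in groups:
        for ident in identifiers:
            prior = roles.get(ident)
            if prior is not None and prior != role:
                raise SymbolResolutionError(
                    f"model {model.model_id}: identifier {ident!r} declared as "
                    f"both {prior} and {role}"
                )
            roles[ident] = role
    return roles


def effective_roles(model: ModelRecord, reaction: ReactionRecord) -> dict[str, str]:
    """Model roles with the reaction's local parameters shadowing globals."""
    roles = resolve_symbol_roles(model)
    for ident in reaction.local_parameters:
        roles[ident] = "local-parameter"
    return roles


# ---------------------------------------------------------------------------
# function-definition expansion
# ---------------------------------------------------------------------------


def expand_function_definitions(
    expr: Expr, defs: Mapping[str, FunctionDefinition]
) -> Expr:
    """Inline every user function application, recursively.

    Call sites are replaced by the definition body with formal arguments
    substituted by the actual argument subtrees; nested definitions are
    expanded transitively.  Unknown names, arity mismatches and cyclic
    definitions raise :class:`ExpansionError`.
    """

    def expand(e: Expr, stack: tuple[str, ...]) -> Expr:
        if e.kind == CALL and e.name not in BUILTIN_FUNCTIONS:
            fd = defs.get(e.name)
            if fd is None:
                raise ExpansionError(f"unknown function {e.name!r}")
            if len(fd.parameters) != len(e.args):
                raise ExpansionError(
                    f"function {e.name!r} expects {len(fd.parameters)} "
                    f"argument(s), got {len(e.args)}"
                )
            if e.name in stack:
                raise ExpansionError(
                    f"cyclic function definitions: {' -> '.join(stack + (e.name,))}"
                )
            actuals = tuple(expand(a, stack) for a in e.args)
            body = substitute(fd.body, dict(zip(fd.parameters, actuals)))
            return expand(body, stack + (e.name,))
        if not e.args:
            return e
        return Expr(
            e.kind,
            args=tuple(expand(a, stack) for a in e.args),
            name=e.name,
            value=e.value,
        )

    return expand(expr, ())


# ---------------------------------------------------------------------------
# SBML writing (Level 3 Version 1)
# ---------------------------------------------------------------------------

_MATHML_BINARY = {SUB: "minus", DIV: "divide", POW: "power"}
_MATHML_NARY = {ADD: "plus", MUL: "times"}
_CALL_ELEMENTS = BUILTIN_FUNCTIONS - {"log10", "arcsin", "arccos", "arctan"}


def _mathml_from_expr(expr: Expr, parent: etree._Element) -> None:
    m = f"{{{MATHML_NS}}}"
    if expr.kind == NUM:
        v = expr.value
        el = etree.SubElement(parent, m + "cn")
        if isinstance(v, int) or (isinstance(v, float) and v.is_integer()):
            el.set("type", "integer")
            el.text = str(int(v))
        else:
            el.text = repr(float(v))
        return
    if expr.kind == SYM:
        if expr.name == "time":
            el = etree.SubElement(parent, m + "csymbol")
            el.set("encoding", "text")
            el.set("definitionURL", "http://www.sbml.org/sbml/symbols/time")
            el.text = "t"
            return
        el = etree.SubElement(parent, m + "ci")
        el.text = " " + expr.name + " "
        return
    if expr.kind == OPAQUE:
        raise SerializationError(f"cannot serialize opaque construct {expr.name!r}")
    apply_el = etree.SubElement(parent, m + "apply")
    if expr.kind == NEG:
        etree.SubElement(apply_el, m + "minus")
        _mathml_from_expr(expr.args[0], apply_el)
        return
    if expr.kind in _MATHML_BINARY:
        etree.SubElement(apply_el, m + _MATHML_BINARY[expr.kind])
    elif expr.kind in _MATHML_NARY:
        etree.SubElement(apply_el, m + _MATHML_NARY[expr.kind])
    elif expr.kind == CALL:
        if expr.name == "log10":
            etree.SubElement(apply_el, m + "log")
        elif expr.name in _CALL_ELEMENTS:
            etree.SubElement(apply_el, m + expr.name)
        else:
            ci = etree.SubElement(apply_el, m + "ci")
            ci.text = " " + expr.name + " "
    else:
        raise SerializationError(f"cannot serialize node kind {expr.kind!r}")
    for a in expr.args:
        _mathml_from_expr(a, apply_el)


def write_model(record: ModelRecord, path: str | Path) -> Path:
    """Serialize a model as SBML Level 3 Version 1.

    The document round-trips through :func:`load_model` to an equivalent
    record (same participant sets, roles and kinetic-law values).
    """
    path = Path(path)
    nsmap = {None: SBML_L3V1_NS}
    sbml = etree.Element(f"{{{SBML_L3V1_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "1")
    model = etree.SubElement(sbml, f"{{{SBML_L3V1_NS}}}model")
    model.set("id", record.model_id)

    compartments = record.compartments
    if not compartments and record.species:
        compartments = ("default_compartment",)

    if record.function_definitions:
        lofd = etree.SubElement(model, f"{{{SBML_L3V1_NS}}}listOfFunctionDefinitions")
        for fd in record.function_definitions.values():
            fd_el = etree.SubElement(lofd, f"{{{SBML_L3V1_NS}}}functionDefinition")
            fd_el.set("id", fd.name)
            math_el = etree.SubElement(fd_el, f"{{{MATHML_NS}}}math")
            lam = etree.SubElement(math_el, f"{{{MATHML_NS}}}lambda")
            for p in fd.parameters:
                bvar = etree.SubElement(lam, f"{{{MATHML_NS}}}bvar")
                ci = etree.SubElement(bvar, f"{{{MATHML_NS}}}ci")
                ci.text = " " + p + " "
            _mathml_from_expr(fd.body, lam)

    if compartments:
        loc = etree.SubElement(model, f"{{{SBML_L3V1_NS}}}listOfCompartments")
        for cid in compartments:
            c = etree.SubElement(loc, f"{{{SBML_L3V1_NS}}}compartment")
            c.set("id", cid)
            c.set("size", "1")
            c.set("constant", "true")
    if record.species:
        los = etree.SubElement(model, f"{{{SBML_L3V1_NS}}}listOfSpecies")
        for sid in record.species:
            s = etree.SubElement(los, f"{{{SBML_L3V1_NS}}}species")
            s.set("id", sid)
            s.set("compartment", compartments[0])
            s.set("initialConcentration", "1")
            s.set("hasOnlySubstanceUnits", "false")
            s.set("boundaryCondition", "false")
            s.set("constant", "false")
    if record.parameters:
        lop = etree.SubElement(model, f"{{{SBML_L3V1_NS}}}listOfParameters")
        for pid in record.parameters:
            p = etree.SubElement(lop, f"{{{SBML_L3V1_NS}}}parameter")
            p.set("id", pid)
            p.set("value", "1")
            p.set("constant", "true")

    if record.reactions:
        lor = etree.SubElement(model, f"{{{SBML_L3V1_NS}}}listOfReactions")
        for rx in record.reactions:
            r = etree.SubElement(lor, f"{{{SBML_L3V1_NS}}}reaction")
            r.set("id", rx.reaction_id)
            r.set("reversible", "true" if rx.reversible else "false")
            r.set("fast", "false")
            for list_name, members in (
                ("listOfReactants", rx.reactants),
                ("listOfProducts", rx.products),
            ):
                if members:
                    lo = etree.SubElement(r, f"{{{SBML_L3V1_NS}}}{list_name}")
                    for sid in sorted(members):
                        ref = etree.SubElement(
                            lo, f"{{{SBML_L3V1_NS}}}speciesReference"
                        )
                        ref.set("species", sid)
                        ref.set("stoichiometry", "1")
                        ref.set("constant", "true")
            if rx.modifiers:
                lo = etree.SubElement(r, f"{{{SBML_L3V1_NS}}}listOfModifiers")
                for sid in sorted(rx.modifiers):
                    ref = etree.SubElement(
                        lo, f"{{{SBML_L3V1_NS}}}modifierSpeciesReference"
                    )
                    ref.set("species", sid)
            if rx.kinetic_law is not None:
                kl = etree.SubElement(r, f"{{{SBML_L3V1_NS}}}kineticLaw")
                math_el = etree.SubElement(kl, f"{{{MATHML_NS}}}math")
                try:
                    _mathml_from_expr(rx.kinetic_law, math_el)
                except SerializationError as exc:
                    raise SerializationError(
                        f"reaction {rx.reaction_id}: {exc}"
                    ) from exc
                if rx.local_parameters:
                    lolp = etree.SubElement(
                        kl, f"{{{SBML_L3V1_NS}}}listOfLocalParameters"
                    )
                    for pid in sorted(rx.local_parameters):
                        lp = etree.SubElement(
                            lolp, f"{{{SBML_L3V1_NS}}}localParameter"
                        )
                        lp.set("id", pid)
                        lp.set("value", "1")

    path.parent.mkdir(parents=True, exist_ok=True)
    tree = etree.ElementTree(sbml)
    tree.write(
        str(path),
        pretty_print=True,
        xml_declaration=True,
        encoding="UTF-8",
    )
    return path
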