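"""Kinetics-type and reaction-type classification.

Each reaction's kinetic law is reduced to eight structural properties
(**K properties** a-h) and those feed a fixed decision table that assigns
exactly one of ten mutually exclusive **kinetics types**:

========  ==========================================================
ZERO      no species in the law (zeroth order)
UNDR      single product of terms, species = reactants (mass action)
UNMO      single product involving a non-reactant moderator
BIDR      difference of two products matching reactants/products
          (reversible mass action)
BIMO      difference of two products, not BIDR
MM        Michaelis-Menten shape, no explicit enzyme
MMCAT     Michaelis-Menten shape with an explicit enzyme factor
HILL      Hill equation shape
FR        any other fraction with a species in the denominator
NA        not classified
========  ==========================================================

The **reaction type** is independent of the law: the pair of distinct
reactant and product counts, each binned as 0, 1, 2 or >2 (16 cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .expr_algebra import (
    Expr,
    ExprError,
    as_two_term_difference,
    is_single_product,
    match_hill,
    match_michaelis_menten,
    species_in,
    species_in_denominator,
    symbols_of,
    to_infix,
)
from .sbml_io import (
    ExpansionError,
    FunctionDefinition,
    ModelRecord,
    ReactionRecord,
    SBMLError,
    effective_roles,
    expand_function_definitions,
)

__all__ = [
    "K_TYPES",
    "R_BINS",
    "R_TYPES",
    "KProperties",
    "RType",
    "ClassificationResult",
    "compute_k_properties",
    "classify_k_type",
    "classify_r_type",
    "classify_reaction",
    "classify_model",
    "classify_corpus",
]

logger = logging.getLogger("kinlaw")

#: canonical kinetics-type order (used everywhere: tables, CSVs, plots)
K_TYPES = ("ZERO", "UNDR", "UNMO", "BIDR", "BIMO", "MM", "MMCAT", "HILL", "FR", "NA")

#: distinct-count bins for reactants and products
R_BINS = ("0", "1", "2", ">2")


def _bin(n: int) -> str:
    return str(n) if n <= 2 else ">2"


@dataclass(frozen=True)
class RType:
    """Reaction type: binned distinct reactant and product counts."""

    reactant_bin: str
    product_bin: str

    @property
    def label(self) -> str:
        return f"R={self.reactant_bin},P={self.product_bin}"

    def __str__(self) -> str:
        return self.label


#: all 16 reaction types in canonical (reactant bin, product bin) order
R_TYPES = tuple(RType(r, p) for r in R_BINS for p in R_BINS)


@dataclass(frozen=True)
class KProperties:
    """The eight analyzed properties of one kinetic law.

    a: number of distinct species in the law
    b: the law is a single product of terms
    c: the law is a difference of exactly two products
    d: species/term-to-participant correspondence (for b: the law's
       species set equals the reactant set; for c: the positive term's
       species equal the reactants and the negative term's the products)
    e: Michaelis-Menten shape, single reactant in the numerator
    f: Michaelis-Menten shape with an explicit enzyme in the numerator
    g: Hill shape
    h: the rational form has at least one species in the denominator
    """

    a: int
    b: bool = False
    c: bool = False
    d: bool = False
    e: bool = False
    f: bool = False
    g: bool = False
    h: bool = False


@dataclass(frozen=True)
class ClassificationResult:
    model_id: str
    reaction_id: str
    reaction: str
    kinetic_law: str
    k_type: str
    r_type: RType
    properties: Optional[KProperties] = None
    diagnostic: str = ""


def compute_k_properties(
    reaction: ReactionRecord,
    roles: Mapping[str, str],
    expr: Optional[Expr] = None,
) -> KProperties:
    """Compute properties a-h for a reaction's (already expanded) law."""
    law = expr if expr is not None else reaction.kinetic_law
    if law is None:
        raise ValueError(f"reaction {reaction.reaction_id} has no kinetic law")
    a = len(species_in(law, roles))
    b = is_single_product(law, roles)
    diff = as_two_term_difference(law, roles)
    c = diff is not None
    if b:
        d = species_in(law, roles) == reaction.reactants
    elif c:
        pos, neg = diff
        d = (
            species_in(pos, roles) == reaction.reactants
            and species_in(neg, roles) == reaction.products
        )
    else:
        d = False
    mm = match_michaelis_menten(law, reaction.reactants, roles)
    g = match_hill(law, roles)
    h = species_in_denominator(law, roles)
    return KProperties(
        a=a, b=b, c=c, d=d, e=(mm == "MM"), f=(mm == "MMCAT"), g=g, h=h
    )


def classify_k_type(props: KProperties) -> str:
    """Apply the decision table, column by column; first match wins.

    Total and single-valued on every property combination (the h-gating
    of b/c inside the algebra layer makes the column order immaterial
    for real laws, but the order is fixed for determinism).
    """
    if props.a == 0:
        return "ZERO"
    if props.b and props.d:
        return "UNDR"
    if props.b and not props.d:
        return "UNMO"
    if props.c and props.d:
        return "BIDR"
    if props.c and not props.d:
        return "BIMO"
    if props.a == 1 and props.e and props.h:
        return "MM"
    if props.a == 2 and props.f and props.h:
        return "MMCAT"
    if props.a == 1 and props.g and props.h:
        return "HILL"
    if props.h:
        return "FR"
    return "NA"


def classify_r_type(reaction: ReactionRecord) -> RType:
    """Bin the distinct reactant and product counts (0, 1, 2, >2)."""
    return RType(_bin(len(reaction.reactants)), _bin(len(reaction.products)))


def render_reaction(reaction: ReactionRecord) -> str:
    lhs = " + ".join(sorted(reaction.reactants))
    rhs = " + ".join(sorted(reaction.products))
    return f"{lhs} -> {rhs}".strip()


def classify_reaction(
    reaction: ReactionRecord,
    roles: Mapping[str, str],
    defs: Mapping[str, FunctionDefinition],
    model_id: str = "",
) -> Optional[ClassificationResult]:
    """Expand, analyze and classify one reaction.

    Returns None for a reaction with no kinetic law at all (such
    reactions are excluded from every distribution and tallied
    separately).  An expansion or analysis failure degrades to NA with a
    logged diagnostic rather than aborting a corpus run.
    """
    if reaction.kinetic_law is None:
        return None
    r_type = classify_r_type(reaction)
    rendering = render_reaction(reaction)
    law_str = to_infix(reaction.kinetic_law)
    try:
        expanded = expand_function_definitions(reaction.kinetic_law, defs)
        props = compute_k_properties(reaction, roles, expanded)
        k_type = classify_k_type(props)
        diagnostic = ""
    except (SBMLError, ExprError) as exc:
        logger.warning(
            "model %s: reaction %s unclassifiable (%s)",
            model_id,
            reaction.reaction_id,
            exc,
        )
        props = None
        k_type = "NA"
        diagnostic = str(exc)
    return ClassificationResult(
        model_id=model_id,
        reaction_id=reaction.reaction_id,
        reaction=rendering,
        kinetic_law=law_str,
        k_type=k_type,
        r_type=r_type,
        properties=props,
        diagnostic=diagnostic,
    )


def classify_model(model: ModelRecord) -> list[ClassificationResult]:
    """Classify every reaction of a model that carries a kinetic law."""
    out: list[ClassificationResult] = []
    for rx in model.reactions:
        roles = effective_roles(model, rx)
        res = classify_reaction(
            rx, roles, model.function_definitions, model_id=model.model_id
        )
        if res is not None:
            out.append(res)
    return out


def classify_corpus(
    models: Iterable[ModelRecord],
) -> tuple[list[ClassificationResult], dict[str, int]]:
    """Classify a collection of models.

    Returns the flat result list and a tally: reactions classified,
    reactions skipped for missing kinetic laws, and laws that degraded
    to NA with a diagnostic.
    """
    results: list[ClassificationResult] = []
    tally = {"classified": 0, "no_law": 0, "diagnostic_na": 0}
    for model in models:
        n_before = len(results)
        results.extend(classify_model(model))
        classified = len(results) - n_before
        tally["classified"] += classified
        tally["no_law"] += sum(1 for rx in model.reactions if rx.kinetic_law is None)
        tally["diagnostic_na"] += sum(
            1 for r in results[n_before:] if r.diagnostic
        )
    return results, tally
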