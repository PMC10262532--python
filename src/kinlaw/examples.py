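"""In-repo toy models: one worked example per kinetics type, plus a
library of template rate-law expressions for algebra testing.

The ten worked examples are miniature single-reaction models whose
kinetic laws are classic published rate-law excerpts (cell-cycle mass
action, MAPK-cascade Michaelis-Menten, circadian Hill kinetics, ...),
each exercising exactly one kinetics type.  They double as the canonical
smoke-test corpus for the command-line pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

from .expr_algebra import Expr, parse_infix
from .sbml_io import ModelRecord, ReactionRecord

__all__ = ["WorkedExample", "worked_examples", "worked_example_models", "expression_templates"]


@dataclass(frozen=True)
class WorkedExample:
    name: str
    expected_k_type: str
    model: ModelRecord


def _model(
    name: str,
    law: str,
    *,
    reactants: tuple[str, ...] = (),
    products: tuple[str, ...] = (),
    modifiers: tuple[str, ...] = (),
    species: tuple[str, ...] = (),
    parameters: tuple[str, ...] = (),
    compartments: tuple[str, ...] = (),
) -> ModelRecord:
    return ModelRecord(
        model_id=f"example_{name.lower()}",
        species=species,
        parameters=parameters,
        compartments=compartments,
        reactions=[
            ReactionRecord(
                reaction_id="r1",
                reactants=frozenset(reactants),
                products=frozenset(products),
                modifiers=frozenset(modifiers),
                kinetic_law=parse_infix(law),
            )
        ],
    )


def worked_examples() -> list[WorkedExample]:
    """The ten single-reaction toy models, one per kinetics type."""
    return [
        WorkedExample(
            "ZERO",
            "ZERO",
            _model(
                "zero",
                "Cell*k1aa",
                products=("Y",),
                species=("Y",),
                parameters=("k1aa",),
                compartments=("Cell",),
            ),
        ),
        WorkedExample(
            "UNDR",
            "UNDR",
            _model(
                "undr",
                "Cell*CP*k9",
                reactants=("CP",),
                products=("C2",),
                species=("CP", "C2"),
                parameters=("k9",),
                compartments=("Cell",),
            ),
        ),
        WorkedExample(
            "UNMO",
            "UNMO",
            _model(
                "unmo",
                "k_tl*X",
                products=("PX",),
                modifiers=("X",),
                species=("X", "PX"),
                parameters=("k_tl",),
            ),
        ),
        WorkedExample(
            "BIDR",
            "BIDR",
            _model(
                "bidr",
                "Comp1*(kf_0*B - kr_0*BL)",
                reactants=("B",),
                products=("BL",),
                species=("B", "BL"),
                parameters=("kf_0", "kr_0"),
                compartments=("Comp1",),
            ),
        ),
        WorkedExample(
            "BIMO",
            "BIMO",
            _model(
                "bimo",
                "c1*g*s173*(s172 - s135)",
                reactants=("s172",),
                products=("s135",),
                modifiers=("s173",),
                species=("s172", "s135", "s173"),
                parameters=("g",),
                compartments=("c1",),
            ),
        ),
        WorkedExample(
            "MM",
            "MM",
            _model(
                "mm",
                "Cell*MI*V1*pow(K1 + MI, -1)",
                reactants=("MI",),
                products=("M",),
                species=("MI", "M"),
                parameters=("V1", "K1"),
                compartments=("Cell",),
            ),
        ),
        WorkedExample(
            "MMCAT",
            "MMCAT",
            _model(
                "mmcat",
                "uVol*k3*MKKK_P*MKK/(KK3 + MKK)",
                reactants=("MKK",),
                products=("MKK_P",),
                modifiers=("MKKK_P",),
                species=("MKK", "MKK_P", "MKKK_P"),
                parameters=("k3", "KK3"),
                compartments=("uVol",),
            ),
        ),
        WorkedExample(
            "HILL",
            "HILL",
            _model(
                "hill",
                "Compartment*(n1*pow(cXn, a)/(pow(g1, a) + pow(cXn, a)))",
                products=("cLm",),
                modifiers=("cXn",),
                species=("cXn", "cLm"),
                parameters=("n1", "a", "g1"),
                compartments=("Compartment",),
            ),
        ),
        WorkedExample(
            "FR",
            "FR",
            _model(
                "fr",
                "Cell*(1 + -1*M)*V1*pow(K1 + -1*M + 1, -1)",
                products=("M",),
                species=("M",),
                parameters=("V1", "K1"),
                compartments=("Cell",),
            ),
        ),
        WorkedExample(
            "NA",
            "NA",
            _model(
                "na",
                "WholeCell*((1 - pow(1 - prct, npt))*tccctimp"
                " + pow(1 - prct, npt)*tcdvpmt)*timp",
                products=("timm",),
                modifiers=("prct", "timp"),
                species=("prct", "timp", "timm"),
                parameters=("npt", "tccctimp", "tcdvpmt"),
                compartments=("WholeCell",),
            ),
        ),
    ]


def worked_example_models() -> list[ModelRecord]:
    return [ex.model for ex in worked_examples()]


def expression_templates() -> list[tuple[str, dict[str, str]]]:
    """A library of (infix law, symbol-role map) pairs spanning the
    structural variety the algebra layer must handle.

    Used by the value-preservation and oracle-equivalence tests; every
    template is a well-formed algebraic law (no opaque constructs).
    """
    S = "species"
    P = "parameter"
    C = "compartment"
    t: list[tuple[str, dict[str, str]]] = []

    def add(law: str, **roles: str) -> None:
        t.append((law, roles))

    # plain products / mass action
    add("Cell*k1aa", Cell=C, k1aa=P)
    add("Cell*CP*k9", Cell=C, CP=S, k9=P)
    add("k_tl*X", k_tl=P, X=S)
    add("k1*A*B", k1=P, A=S, B=S)
    add("k1*A*A", k1=P, A=S)
    add("k*pow(A, 2)*B", k=P, A=S, B=S)
    add("k*pow(A, n)", k=P, A=S, n=P)
    add("(k1 + k2)*A", k1=P, k2=P, A=S)
    add("A*k*1.5", k=P, A=S)
    add("2*A*B*k", A=S, B=S, k=P)
    add("k*A*B*C*D", k=P, A=S, B=S, C=S, D=S)
    add("exp(k*t)*V*A", k=P, t=P, V=P, A=S)
    # two-term differences
    add("Comp1*(kf_0*B - kr_0*BL)", Comp1=C, kf_0=P, kr_0=P, B=S, BL=S)
    add("c1*g*s173*(s172 - s135)", c1=C, g=P, s173=S, s172=S, s135=S)
    add("kf*A*B - kr*C", kf=P, kr=P, A=S, B=S, C=S)
    add("V*(A - B/Keq)", V=P, Keq=P, A=S, B=S)
    add("cell*(kf*A - kr*B)", cell=C, kf=P, kr=P, A=S, B=S)
    add("kf*pow(A, 2) - kr*B", kf=P, kr=P, A=S, B=S)
    add("-kr*B + kf*A", kf=P, kr=P, A=S, B=S)
    add("kf*A - kr*A", kf=P, kr=P, A=S)
    # three or more terms
    add("k1*A - k2*B + k3*A*B", k1=P, k2=P, k3=P, A=S, B=S)
    add("k1*A + k2*B", k1=P, k2=P, A=S, B=S)
    add("k1 + k2*A - k3*A - k4*A", k1=P, k2=P, k3=P, k4=P, A=S)
    # Michaelis-Menten family
    add("Cell*MI*V1*pow(K1 + MI, -1)", Cell=C, MI=S, V1=P, K1=P)
    add("V*S/(K + S)", V=P, K=P, S=S)
    add("V*S/(K1 + K2 + S)", V=P, K1=P, K2=P, S=S)
    add("uVol*k3*MKKK_P*MKK/(KK3 + MKK)", uVol=C, k3=P, KK3=P, MKKK_P=S, MKK=S)
    add("k*E*S*pow(Km + S, -1)", k=P, Km=P, E=S, S=S)
    add("V*S/((K1 + S)*(K2 + S))", V=P, K1=P, K2=P, S=S)
    add("V*S/(K + S + S*S/Ki)", V=P, K=P, Ki=P, S=S)
    add("Vf*A/Ka/(1 + A/Ka + B/Kb)", Vf=P, Ka=P, Kb=P, A=S, B=S)
    # Hill family
    add(
        "Compartment*(n1*pow(cXn, a)/(pow(g1, a) + pow(cXn, a)))",
        Compartment=C, n1=P, a=P, g1=P, cXn=S,
    )
    add("n1*pow(S, 2)/(pow(g1, 3) + pow(S, 2))", n1=P, g1=P, S=S)
    add("V*pow(S, h)/(pow(K, h) + pow(S, h))", V=P, h=P, K=P, S=S)
    add("V*pow(S, 4)/(Kd + pow(S, 4))", V=P, Kd=P, S=S)
    add("V*pow(S, h)/(pow(K, h) + pow(S, g))", V=P, h=P, g=P, K=P, S=S)
    add("V*pow(S, 2)/(K + S)", V=P, K=P, S=S)
    # general fractions
    add("Cell*(1 + -1*M)*V1*pow(K1 + -1*M + 1, -1)", Cell=C, M=S, V1=P, K1=P)
    add("k/(K + I)", k=P, K=P, I=S)
    add("k*A/(K + I)", k=P, K=P, A=S, I=S)
    add("(kf*A - kr*B)/(1 + A/Ka + B/Kb)", kf=P, kr=P, Ka=P, Kb=P, A=S, B=S)
    add("V/(1 + pow(I/Ki, 2))", V=P, Ki=P, I=S)
    add("k1/(k2 + k3*A/(k4 + A))", k1=P, k2=P, k3=P, k4=P, A=S)
    add("(a/b)/(c/d)", a=S, b=S, c=S, d=S)
    add("(a/b)/(c/d)", a=P, b=S, c=P, d=S)
    add("A/B", A=S, B=S)
    add("1/S", S=S)
    add("pow(K1 + MI, -2)*V", K1=P, MI=S, V=P)
    add("pow(S, -1)*V*S", S=S, V=P)
    # nested / unusual but algebraic
    add(
        "WholeCell*((1 - pow(1 - prct, npt))*tccctimp + pow(1 - prct, npt)*tcdvpmt)*timp",
        WholeCell=C, prct=S, npt=P, tccctimp=P, tcdvpmt=P, timp=S,
    )
    add("k*sqrt(A)", k=P, A=S)
    add("k*pow(A + B, 2)", k=P, A=S, B=S)
    add("k*(A + K1)*(B + K2)", k=P, K1=P, K2=P, A=S, B=S)
    add("(K1 + K2)/(K3 + K4)*A", K1=P, K2=P, K3=P, K4=P, A=S)
    add("k*A/(B*C)", k=P, A=S, B=S, C=S)
    add("5", )
    add("k1 + k2", k1=P, k2=P)
    add("time*k*A", k=P, A=S, **{"time": "time-like"})
    assert len(t) >= 50
    return t
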