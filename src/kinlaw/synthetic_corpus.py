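"""Seeded generator of SBML corpora with known kinetics-type labels.

Every emitted reaction is built from the template family of its target
kinetics type (the canonical worked-example shapes: mass-action
products, two-term differences, Michaelis-Menten and Hill fractions,
nested unclassifiable forms) with freshly named species and parameters,
then optionally obfuscated — wrapped in a function definition, multiplied
by a compartment, divisions rewritten as ``pow(x, -1)``, factor order
shuffled.  None of the obfuscations change the structural class, so the
generated labels are exact ground truth for classifier round-trips and
for distribution-recovery studies of random reaction networks.

The generator is deliberately not biologically realistic: no mass
conservation, no thermodynamics — its contract is label fidelity and
seeded determinism (one seed fully determines the output bytes).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .classifier import K_TYPES, R_BINS, R_TYPES, RType
from .expr_algebra import (
    Add,
    Call,
    Div,
    Expr,
    Mul,
    Num,
    Pow,
    Sub,
    Sym,
    symbols_of,
)
from .sbml_io import FunctionDefinition, ModelRecord, ReactionRecord, write_model

__all__ = [
    "ObfuscationOptions",
    "GeneratorConfig",
    "GeneratedReaction",
    "InfeasiblePairError",
    "ConfigError",
    "is_feasible",
    "feasible_pairs",
    "uniform_feasible_joint",
    "emit_reaction",
    "generate_models",
    "generate_corpus",
]

_BIN_COUNT = {"0": 0, "1": 1, "2": 2, ">2": 3}


class ConfigError(ValueError):
    pass


class InfeasiblePairError(ConfigError):
    pass


def is_feasible(k_type: str, r_type: RType) -> bool:
    """Can a reaction of this R type carry a law of this kinetics type?

    UNDR needs the species of a single product to equal a *nonempty*
    reactant set (the no-reactant case is ZERO territory); BIDR needs
    both sides nonempty; the Michaelis-Menten shapes need a reactant as
    substrate.  Everything else is unconstrained.
    """
    if k_type in ("UNDR", "MM", "MMCAT") and r_type.reactant_bin == "0":
        return False
    if k_type == "BIDR" and (
        r_type.reactant_bin == "0" or r_type.product_bin == "0"
    ):
        return False
    return True


def feasible_pairs() -> list[tuple[str, RType]]:
    return [(k, r) for k in K_TYPES for r in R_TYPES if is_feasible(k, r)]


def uniform_feasible_joint() -> dict[tuple[str, str], float]:
    pairs = feasible_pairs()
    p = 1.0 / len(pairs)
    return {(k, r.label): p for k, r in pairs}


@dataclass(frozen=True)
class ObfuscationOptions:
    """Independent probabilities for the label-preserving disguises."""

    wrap_in_function_definition: float = 0.3
    multiply_by_compartment: float = 0.5
    use_pow_minus_one_for_division: float = 0.5
    shuffle_factor_order: bool = True

    @classmethod
    def none(cls) -> "ObfuscationOptions":
        return cls(0.0, 0.0, 0.0, False)

    @classmethod
    def all(cls) -> "ObfuscationOptions":
        return cls(1.0, 1.0, 1.0, True)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``joint_distribution`` (keys ``(k_type, r_label)``) takes precedence;
    otherwise ``k_type_distribution`` x ``r_type_distribution`` is used
    and must place zero mass on infeasible pairs.  Distributions must sum
    to one within 1e-9.  The default is uniform over all feasible
    (kinetics type, reaction type) pairs.
    """

    n_models: int = 50
    reactions_per_model: tuple[int, int] = (3, 12)
    k_type_distribution: Optional[dict[str, float]] = None
    r_type_distribution: Optional[dict[str, float]] = None
    joint_distribution: Optional[dict[tuple[str, str], float]] = None
    seed: int = 0
    obfuscation: ObfuscationOptions = field(default_factory=ObfuscationOptions)

    def resolved_joint(self) -> dict[tuple[str, str], float]:
        if self.joint_distribution is not None:
            joint = dict(self.joint_distribution)
        elif self.k_type_distribution or self.r_type_distribution:
            kd = self.k_type_distribution or {
                k: 1.0 / len(K_TYPES) for k in K_TYPES
            }
            rd = self.r_type_distribution or {
                r.label: 1.0 / len(R_TYPES) for r in R_TYPES
            }
            _check_sum(kd, "k_type_distribution")
            _check_sum(rd, "r_type_distribution")
            joint = {
                (k, rl): pk * pr
                for k, pk in kd.items()
                for rl, pr in rd.items()
                if pk * pr > 0
            }
        else:
            joint = uniform_feasible_joint()
        _check_sum({str(k): v for k, v in joint.items()}, "joint distribution")
        by_label = {r.label: r for r in R_TYPES}
        for (k, rl), p in joint.items():
            if k not in K_TYPES:
                raise ConfigError(f"unknown kinetics type {k!r}")
            if rl not in by_label:
                raise ConfigError(f"unknown reaction type {rl!r}")
            if p > 0 and not is_feasible(k, by_label[rl]):
                raise InfeasiblePairError(
                    f"({k}, {rl}) is infeasible: {k} requires a nonempty "
                    f"{'reactant and product set' if k == 'BIDR' else 'reactant set'}"
                )
        return joint

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        raw = json.loads(Path(path).read_text())
        obf = ObfuscationOptions(**raw.get("obfuscation", {}))
        joint = raw.get("joint_distribution")
        if joint is not None:
            joint = {tuple(k.split("::")): v for k, v in joint.items()}
        rpm = raw.get("reactions_per_model", (3, 12))
        return cls(
            n_models=raw.get("n_models", 50),
            reactions_per_model=(int(rpm[0]), int(rpm[1])),
            k_type_distribution=raw.get("k_type_distribution"),
            r_type_distribution=raw.get("r_type_distribution"),
            joint_distribution=joint,
            seed=raw.get("seed", 0),
            obfuscation=obf,
        )


def _check_sum(dist: Mapping[str, float], name: str) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name} sums to {total!r}, expected 1")
    if any(p < 0 for p in dist.values()):
        raise ConfigError(f"{name} has a negative probability")


@dataclass
class GeneratedReaction:
    """One emitted reaction plus everything it introduced into the model."""

    reaction: ReactionRecord
    true_k_type: str
    true_r_type: RType
    species: tuple[str, ...]
    parameters: tuple[str, ...]
    function_definitions: tuple[FunctionDefinition, ...] = ()


class _Namer:
    """Fresh, deterministic identifiers within one model."""

    def __init__(self) -> None:
        self.counts: dict[str, int] = {}

    def fresh(self, prefix: str) -> str:
        n = self.counts.get(prefix, 0)
        self.counts[prefix] = n + 1
        return f"{prefix}{n}"


def _shuffled_product(factors: list[Expr], rng: random.Random, on: bool) -> Expr:
    fs = list(factors)
    if on and len(fs) > 1:
        rng.shuffle(fs)
    return fs[0] if len(fs) == 1 else Mul(*fs)


def emit_reaction(
    k_type: str,
    r_type: RType,
    rng: random.Random,
    namer: Optional[_Namer] = None,
    obfuscation: ObfuscationOptions = ObfuscationOptions.none(),
    compartment: str = "cell",
) -> GeneratedReaction:
    """Build one reaction whose law is guaranteed to classify as ``k_type``.

    Raises :class:`InfeasiblePairError` for incompatible (K, R) pairs.
    """
    if not is_feasible(k_type, r_type):
        raise InfeasiblePairError(f"({k_type}, {r_type.label}) is infeasible")
    namer = namer or _Namer()
    shuffle = obfuscation.shuffle_factor_order

    reactants = tuple(namer.fresh("S") for _ in range(_BIN_COUNT[r_type.reactant_bin]))
    products = tuple(namer.fresh("S") for _ in range(_BIN_COUNT[r_type.product_bin]))
    modifiers: list[str] = []
    params: list[str] = []
    species = list(reactants) + list(products)

    def param() -> Expr:
        p = namer.fresh("k")
        params.append(p)
        return Sym(p)

    def moderator() -> Expr:
        m = namer.fresh("S")
        modifiers.append(m)
        species.append(m)
        return Sym(m)

    def div(a: Expr, b: Expr) -> Expr:
        if rng.random() < obfuscation.use_pow_minus_one_for_division:
            return Mul(a, Pow(b, Num(-1)))
        return Div(a, b)

    r_syms = [Sym(s) for s in reactants]
    p_syms = [Sym(s) for s in products]

    if k_type == "ZERO":
        law = param()
    elif k_type == "UNDR":
        law = _shuffled_product([param()] + r_syms, rng, shuffle)
    elif k_type == "UNMO":
        law = _shuffled_product([param(), moderator()], rng, shuffle)
    elif k_type == "BIDR":
        fwd = _shuffled_product([param()] + r_syms, rng, shuffle)
        bwd = _shuffled_product([param()] + p_syms, rng, shuffle)
        law = Sub(fwd, bwd)
    elif k_type == "BIMO":
        fwd = _shuffled_product([param(), moderator()] + r_syms, rng, shuffle)
        bwd = _shuffled_product([param()] + p_syms, rng, shuffle)
        law = Sub(fwd, bwd)
    elif k_type == "MM":
        s = r_syms[0]
        law = div(_shuffled_product([param(), s], rng, shuffle), Add(param(), s))
    elif k_type == "MMCAT":
        s = r_syms[0]
        enzyme = moderator()
        law = div(
            _shuffled_product([param(), enzyme, s], rng, shuffle),
            Add(param(), s),
        )
    elif k_type == "HILL":
        s = r_syms[0] if r_syms else moderator()
        exponent = rng.choice([Num(2), Num(3), Num(4), param()])
        s_pow = Pow(s, exponent)
        law = div(
            _shuffled_product([param(), s_pow], rng, shuffle),
            Add(Pow(param(), exponent), s_pow),
        )
    elif k_type == "FR":
        if rng.random() < 0.5:
            law = div(param(), Add(param(), moderator()))
        else:
            law = div(
                _shuffled_product([param(), moderator()], rng, shuffle),
                Add(param(), moderator()),
            )
    elif k_type == "NA":
        if rng.random() < 0.5:
            # nested non-matching fraction/power structure
            m1, m2 = moderator(), moderator()
            blocked = Pow(Sub(Num(1), m1), param())
            law = Mul(
                Add(
                    Mul(Sub(Num(1), blocked), param()),
                    Mul(blocked, param()),
                ),
                m2,
            )
        else:
            # three additive terms: neither a product nor a difference
            m1, m2 = moderator(), moderator()
            law = Add(
                Mul(param(), m1),
                Mul(Num(-1), param(), m2),
                Mul(param(), m1, m2),
            )
    else:
        raise ConfigError(f"unknown kinetics type {k_type!r}")

    if rng.random() < obfuscation.multiply_by_compartment:
        law = Mul(Sym(compartment), law)

    funcdefs: tuple[FunctionDefinition, ...] = ()
    if rng.random() < obfuscation.wrap_in_function_definition:
        fname = namer.fresh("flux")
        args = sorted(symbols_of(law))
        formals = tuple(f"x{i}" for i in range(len(args)))
        body = _rename(law, dict(zip(args, formals)))
        funcdefs = (FunctionDefinition(fname, formals, body),)
        law = Call(fname, *(Sym(a) for a in args))

    reaction = ReactionRecord(
        reaction_id=namer.fresh("rx"),
        reactants=frozenset(reactants),
        products=frozenset(products),
        modifiers=frozenset(modifiers),
        reversible=bool(rng.random() < 0.2),
        kinetic_law=law,
    )
    return GeneratedReaction(
        reaction=reaction,
        true_k_type=k_type,
        true_r_type=r_type,
        species=tuple(species),
        parameters=tuple(params),
        function_definitions=funcdefs,
    )


def _rename(expr: Expr, mapping: Mapping[str, str]) -> Expr:
    from .expr_algebra import substitute

    return substitute(expr, {k: Sym(v) for k, v in mapping.items()})


def generate_models(
    config: GeneratorConfig,
) -> tuple[list[ModelRecord], pd.DataFrame]:
    """Generate the corpus in memory: models plus the ground-truth table."""
    joint = config.resolved_joint()
    rng = random.Random(config.seed)
    pairs = sorted(joint)  # deterministic order regardless of dict history
    weights = [joint[p] for p in pairs]
    by_label = {r.label: r for r in R_TYPES}

    models: list[ModelRecord] = []
    label_rows: list[dict] = []
    lo, hi = config.reactions_per_model
    if lo < 1 or hi < lo:
        raise ConfigError(f"invalid reactions_per_model range {config.reactions_per_model}")
    for i in range(config.n_models):
        model_id = f"synthetic_{i:04d}"
        namer = _Namer()
        n_rx = rng.randint(lo, hi)
        species: list[str] = []
        params: list[str] = []
        funcdefs: dict[str, FunctionDefinition] = {}
        reactions: list[ReactionRecord] = []
        for k, rl in rng.choices(pairs, weights=weights, k=n_rx):
            emitted = emit_reaction(
                k,
                by_label[rl],
                rng,
                namer=namer,
                obfuscation=config.obfuscation,
                compartment="cell",
            )
            species.extend(emitted.species)
            params.extend(emitted.parameters)
            for fd in emitted.function_definitions:
                funcdefs[fd.name] = fd
            reactions.append(emitted.reaction)
            label_rows.append(
                {
                    "model_id": model_id,
                    "reaction_id": emitted.reaction.reaction_id,
                    "true_k_type": emitted.true_k_type,
                    "true_r_type": emitted.true_r_type.label,
                }
            )
        models.append(
            ModelRecord(
                model_id=model_id,
                species=tuple(species),
                parameters=tuple(params),
                compartments=("cell",),
                function_definitions=funcdefs,
                reactions=reactions,
            )
        )
    labels = pd.DataFrame(
        label_rows, columns=["model_id", "reaction_id", "true_k_type", "true_r_type"]
    )
    return models, labels


def generate_corpus(
    config: GeneratorConfig, out_dir: str | Path
) -> tuple[list[Path], pd.DataFrame]:
    """Write the corpus as SBML files plus a ``labels.csv`` table.

    Identical configs (including the seed) produce byte-identical files.
    The joint distribution is validated before anything is written.
    """
    models, labels = generate_models(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for model in models:
        paths.append(write_model(model, out_dir / f"{model.model_id}.xml"))
    labels.to_csv(out_dir / "labels.csv", index=False)
    return paths, labels
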