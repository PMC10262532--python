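# Methods

## The classification model

`kinlaw` assigns every reaction a pair (kinetics type, reaction type). The
reaction type is purely structural: the numbers of *distinct* reactant and
product species (a species with stoichiometry 2, or listed twice, counts
once), each binned as 0, 1, 2 or >2. The kinetics type is a function of the
kinetic law's algebraic shape plus the reaction's participant sets, computed
in three stages.

**1. Expansion.** SBML kinetic laws may be written as calls to user-defined
functions (`f(S, V)` with `f(x, v) = v*x/(1 + x)` defined elsewhere in the
file). All calls are inlined, recursively, before analysis; unknown names,
arity mismatches and cyclic definitions are reported per reaction. Builtin
math functions (`exp`, `ln`, ...) are not definitions and stay as atomic
factors.

**2. Eight structural properties.** On the expanded law:

- **a** — the number of distinct species symbols anywhere in the law.
  Compartments and (local) parameters are never species, even when a
  compartment's size is variable: only the algebraic role matters, never
  parameter values or units.
- **h** — whether any species occurs in the denominator once all divisions
  and negative-literal-exponent powers (`pow(K + S, -1)`) are collected into
  one numerator/denominator pair. Symbolic exponents are never assumed
  negative; `S^n` stays in the numerator unless the exponent is explicitly
  negated or the base explicitly divided.
- **b** — the law is a *single product of terms*: no species inside any
  additive subexpression, species appearing only as bare symbols or positive
  powers of symbols. Species-free additive factors (`(k1 + k2)*A`) do not
  disqualify. b is defined false whenever h is true: a Michaelis–Menten law
  written multiplicatively with `pow(..., -1)` is literally a product, and
  without this gate the mass-action and fraction categories would overlap,
  breaking mutual exclusivity.
- **c** — the law, after distributing products over species-containing sums
  (species-free sums are kept intact), is exactly two terms of opposite sign,
  each itself a plain product. Gated by h like b. Common species-free
  prefactors (a compartment multiplying the difference) distribute into both
  terms.
- **d** — participant correspondence. For single products: the law's species
  set equals the reactant set (set equality; the category descriptions read
  both as "all species are reactants" and "all reactants appear", and
  equality satisfies both). For two-term differences: the positive term's
  species equal the reactants *and* the negative term's equal the products —
  the orientation is fixed by sign after normalization, so a law written
  `-k_r*P + k_f*S` still matches.
- **e / f** — Michaelis–Menten shape. The numerator must be a single product
  whose species content is exactly one substrate S (exponent 1, S a
  reactant) — or exactly {S, E} for the explicit-enzyme variant, E being any
  second species, declared modifier or not (annotation independence: the
  enzyme is recognizable only by its species role). The denominator, expanded
  to a sum, must have ≥ 2 terms, contain no species other than S, and contain
  S linearly in at least one term; E must not appear there. Accepting > 2
  denominator terms (e.g. `V*S/(K1 + K2 + S)`) is an interpretation choice;
  it also admits substrate-inhibition-like denominators, which we consider
  within the Michaelis–Menten family.
- **g** — Hill shape: numerator species content is a single power `S^p` with
  p symbolic or a literal ≠ 1; denominator is exactly two terms, one
  species-free and one whose species content is the *syntactically identical*
  `S^p` (identity after constant folding; no attempt to prove algebraic
  equality of distinct exponent expressions — decidable and deterministic).
  A literal exponent of 1 is rejected: it collapses to Michaelis–Menten
  shape. S need not be a reactant (gene-expression Hill inputs usually are
  not).

**3. Decision table.** Evaluated in fixed order, first match wins:
a=0 → ZERO; b∧d → UNDR; b∧¬d → UNMO; c∧d → BIDR; c∧¬d → BIMO;
a=1∧e∧h → MM; a=2∧f∧h → MMCAT; a=1∧g∧h → HILL; h → FR; else NA.
With the h-gating of b/c the order is provably immaterial for laws produced
by the algebra layer, but fixing it makes the function total and
deterministic on *every* property combination, which the test suite verifies
by exhaustive enumeration. The species-count guards on MM/MMCAT/HILL are
implied by the matchers (their conditions force a = 1, 2, 1 respectively); a
fraction-shaped law with extra species falls through to FR.

Reversibility flags are read but ignored — the scheme does not distinguish
reversible from irreversible kinetics. Reactions with *no* kinetic law are
excluded from all distributions and tallied separately; NA is reserved for
laws that exist but match no pattern.

**Non-algebraic constructs.** `piecewise`, `delay`, relational/boolean
operators and similar MathML make a law unanalyzable: every boolean property
returns false and classification falls through the table (NA when species
are present; a species-free piecewise law still lands in ZERO because the
species count fires first — the table is applied uniformly). The SBML time
symbol is treated as an ordinary non-species symbol: a law like `a*t + b` is
algebraic and classifies by the usual rules.

## SBML handling

Input: levels 1–3. Level 1 rate laws (infix `formula` strings) and level 2/3
content MathML are parsed into the same expression trees. Identifier roles are
resolved per model (species / parameter / compartment / function name), with
reaction-local parameters shadowing globals inside that reaction's law only.
Rate rules, assignment rules and events are outside the scheme's scope; their
presence is logged. Output is always SBML Level 3 Version 1, and writing then
re-loading preserves participant sets, roles and the numeric value of every
law (checked at random positive assignments, relative tolerance 1e-9).

The reader/writer is a purpose-built subset implementation on `lxml`,
covering exactly the constructs classification needs; it is not a general
SBML toolkit (no units, no annotations, no packages).

## Statistics

For an axis (K, R, or the 160-cell K×R product) with categories fixed in
canonical order (the K order used throughout; R by reactant-bin then
product-bin):

- pooled share: category count / total reactions, all models pooled;
- per-model mean: average over models of within-model shares;
- per-model SE: sample standard deviation across models (denominator M−1)
  divided by √M — the conventional standard-error estimator; with a single
  model the SE is reported as 0 and flagged degenerate.

Models with zero classified reactions are dropped from per-model averaging
(their share is 0/0) with a logged count. All categories are always reported,
zeros included, so pooled and mean shares each sum to one on fully classified
corpora, and K×R counts marginalize exactly (as integers) to the
one-dimensional tables. No hypothesis testing is attached to corpus
comparisons; they are descriptive (side-by-side shares, absolute differences,
top categories).

## Synthetic corpus generator

The generator's job is exact ground truth, not biological realism. Each
kinetics type has one template family — the canonical worked-example shapes:
`k` (ZERO), `k*∏R` (UNDR), `k*M` (UNMO), `k_f*∏R − k_r*∏P` (BIDR, plus a
moderator factor for BIMO), `V*S/(K + S)` (MM, with an enzyme factor for
MMCAT), `V*S^n/(K^n + S^n)` (HILL, n ∈ {2, 3, 4, symbolic}), species-bearing
denominators that match nothing (FR), and NA from either a nested
power/fraction structure or a three-term sum. All identifiers are fresh per
model. Label-preserving obfuscations are applied with configurable
probabilities: wrapping the law in a function definition, multiplying by the
compartment, writing divisions as `pow(x, -1)`, and shuffling factor order.
Piecewise-based NA fixtures are not generated because the writer emits only
algebraic MathML; the two algebraic NA families cover the fall-through path.

Defaults: 50 models, 3–12 reactions per model, the joint (K, R) distribution
uniform over the 141 feasible pairs, obfuscation probabilities
(wrap 0.3, compartment 0.5, pow-division 0.5, shuffle on). Infeasible pairs —
UNDR/MM/MMCAT with no reactants, BIDR with an empty side — are rejected with
an error rather than remapped, so configured distributions stay honest. One
integer seed determines the output byte-for-byte.

Because the generator emits exactly the template families the classifier
recognizes, a 100% round-trip recovery shows the pipeline (writer → reader →
expansion → algebra → decision table) is faithful under every disguise; it
does *not* show that real repository corpora contain only these shapes —
coverage on real corpora must be measured, not assumed, and NA rates there
will be nonzero.

## Numerical and design notes

- Constant folding evaluates purely numeric subtrees only; `1 + (-1)*M`
  keeps its additive structure because it contains a symbol.
- `sqrt(x)` normalizes to `x^0.5`, so a square-rooted species counts as a
  (positive) power of a symbol.
- Expression equality (e.g. Hill exponent identity) is structural equality of
  folded trees; no general simplification, factorization or exponent
  arithmetic beyond literal folding is attempted.
- Value preservation of every transformation (normalization, rational form,
  term expansion) is asserted at 20 random positive assignments per
  expression, relative tolerance 1e-9, over a ≥ 50 template library, and
  cross-checked against independent sympy-based re-derivations. Assignments
  are drawn inside (0, 1) so subtractive structures stay positive and
  fractional powers remain real.
- Test problem sizes (50-model and 200-model synthetic corpora, ~1,500
  reactions) were chosen to keep the full suite in the tens of seconds while
  leaving multinomial sampling error well inside the three-binomial-SE
  acceptance bands.

## Known limitations

- The SBML subset reader ignores rules, events, constraints and all package
  extensions; models whose kinetics depend on assignment rules will classify
  from the literal law only.
- MM/MMCAT/Hill matching is shape-based; algebraically equivalent but
  structurally different writings (e.g. a Hill law with the exponent
  expanded into a product of two symbolic factors in one place only) fall
  to FR or NA.
- Exponent handling is syntactic: `S^(2*n)` vs `S^(n*2)` are different
  exponents.
- Large-repository benchmarking (thousands of curated models) is supported
  through the same `classify` pipeline but requires the user to supply a
  local snapshot; no downloading is built in.
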