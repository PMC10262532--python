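# kinlaw

Annotation-independent classification of reaction kinetics in SBML models.

Mechanistic models in systems biology attach a *kinetic law* — an algebraic
rate expression — to every reaction, and choosing an appropriate law is one of
the harder modeling decisions. Existing recommendation tools lean on SBO/MIRIAM
annotations, which are missing or unreliable in much of public repositories
such as BioModels. `kinlaw` instead classifies each reaction purely from the
*structure* of its rate expression plus the reaction's participant lists, so it
works on any SBML file (levels 1–3), annotated or not. It is aimed at modelers
who want to know which rate laws a model collection actually uses, at curators
hunting for unusual kinetics, and at authors of random-network studies who need
realistic kinetics distributions to sample from.

## The classification scheme

Each reaction gets a two-dimensional label:

**Kinetics type (K type)** — ten mutually exclusive categories derived from
eight structural properties (a–h) of the kinetic law *v*:

| K type | shape (S, P species; k, K, n parameters) |
|--------|------------------------------------------|
| ZERO   | no species in *v* (e.g. `cell*k`) |
| UNDR   | single product, species(*v*) = reactants (`k*S1*S2`) |
| UNMO   | single product with a non-reactant moderator (`k*M`) |
| BIDR   | `k_f*∏reactants − k_r*∏products` |
| BIMO   | a two-term difference that is not BIDR |
| MM     | `V*S/(K + S)` with S a reactant |
| MMCAT  | `k*E*S/(K + S)` with an explicit enzyme species E |
| HILL   | `V*S^n/(K^n + S^n)`, n ≠ 1 |
| FR     | any other fraction with a species in the denominator |
| NA     | everything else (not classified) |

The properties are computed symbolically: the law is parsed into an expression
tree, user-defined SBML functions are inlined, divisions and `pow(x, −1)`
factors are collected into a single numerator/denominator pair, and products
are distributed over species-containing sums. A decision table then assigns
exactly one type (column by column, zeroth order first).

**Reaction type (R type)** — the pair (number of distinct reactants, number of
distinct products), each binned as 0, 1, 2 or >2: sixteen cells.

Corpus statistics report, per category, both the *pooled* share (fraction of
all reactions from all models) and the *per-model mean* share, with a standard
error across models (sample SD / √M), plus the kinetics distribution
conditioned on each reaction type and side-by-side comparisons of two corpora.

A seeded generator emits SBML corpora with known ground-truth labels (and
optional target distributions) for validation and for random-reaction-network
studies.

## Worked example

```python
>>> from kinlaw import load_model, classify_model, pooled_distribution
>>> from kinlaw.examples import worked_example_models
>>> from kinlaw.sbml_io import write_model
>>> import tempfile, pathlib
>>> d = pathlib.Path(tempfile.mkdtemp())
>>> for m in worked_example_models():
...     _ = write_model(m, d / f"{m.model_id}.xml")
>>> results = [classify_model(load_model(p))[0] for p in sorted(d.glob("*.xml"))]
>>> for r in results[:3]:
...     print(f"{r.model_id:16s} {r.reaction:12s} {r.kinetic_law:28s} {r.k_type:5s} {r.r_type}")
example_bidr     B -> BL      Comp1*(kf_0*B - kr_0*BL)     BIDR  R=1,P=1
example_bimo     s172 -> s135 c1*g*s173*(s172 - s135)      BIMO  R=1,P=1
example_fr       -> M         Cell*(1 + -1*M)*V1*(K1 + -1*M + 1)^(-1) FR    R=0,P=1
>>> table = pooled_distribution(results, "K")
>>> round(table.pooled["UNDR"], 2), table.n_reactions
(0.1, 10)
```

Each line shows a reaction, its rate law, its kinetics type and its reaction
type; the distribution table reports each type's share of the corpus (here one
reaction of each of the ten types, so every share is 0.1).

The same pipeline from a shell:

```sh
kinlaw classify --input models/ --output report/ --plots
kinlaw generate --config corpus.json --out synthetic/
kinlaw compare report/distribution_K.json other/distribution_K.json
```

`classify` writes `per_reaction.csv`, `per_model.csv`, distribution JSONs for
the K, R and K×R axes, bar-chart/panel plots, and a `manifest.json` run
record.

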