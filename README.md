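# farm — dilution-aware constraint-based metabolic modeling

`farm` is a toolkit for predicting growth phenotypes from genome-scale
metabolic models, built for the reconstruction workflow of organisms
like the filamentous fungus *Neurospora crassa*: predict knockout
viability, find which nutrient supplements rescue an auxotroph, screen
for synthetic-lethal gene pairs, prune reactions that can never carry
flux, and reconcile the model against observed growth/no-growth data.

Three optimization routines form the core:

* **limed-FBA** — flux balance analysis with **li**near **me**tabolite
  **d**ilution. Classic FBA (`max c^T v` s.t. `S v = 0, lb ≤ v ≤ ub`)
  lets internal cycles regenerate compounds with no input flux, which
  produces false viability calls for cycle-input enzymes. limed-FBA
  forces every active metabolite to be net-produced at a small rate
  `b = ε S^binary v`, i.e. it solves the same-size LP
  `max c^T v` s.t. `(S − ε S^binary) v = 0` on the irreversible model,
  with `ε` sized so no metabolite's dilution exceeds `d_max = 0.1` at
  `v_max = 1000 mmol/gDW/h`. Simple transport reactions (no chemical
  change) and biomass metabolites are exempt.
* **OnePrune** — finds *all* blocked reactions with one goal-programming
  LP, `max Σ t_i` s.t. `t_i ≤ v_i/δ, t_i ∈ [0,1]` over the limed
  constraints with unlimited nutrients, instead of one LP per reaction
  as in flux variability analysis (FVA). The test suite verifies the
  blocked set is identical to the FVA oracle's.
* **CROP** — evidence-weighted reconciliation. Each reaction gets a
  weight `w_r = −log(p_biochem · p_thermo · pathway_support)`; when the
  model wrongly predicts no-growth, an LP relaxation picks a
  minimum-weight set of database reactions to add; when it wrongly
  predicts growth, a covering MILP picks a minimum-weight set of
  non-curated reactions to remove. Every suggestion is re-verified to
  flip the growth call, and is ranked for manual review, never
  auto-applied.

A knockout is simulated by blocking reactions whose gene–protein–
reaction rule fails (AND = enzyme complex, OR = isozymes); a mutant is
viable when maximal biomass flux exceeds 0.02. Models are read and
written as COBRA-dialect SBML (Level 3 + fbc, plus legacy Notes), with
a lossless identifier codec (`[` ↔ `__91__`, digit-initial ids
prefixed with `_`).

## Worked example

The classic failure mode, on a five-reaction fixture: a metabolic
cycle whose carriers are only replenished by one input enzyme
(`g_input`), with biomass drawing on the cycle's by-product.

```python
from farm import fixtures as fx
from farm.model import apply_knockout
from farm.solve import fba, limed_fba

fix = fx.input_cycle()
no_input = apply_knockout(fix.model, {"g_input"})
print("FBA, cycle without input:   ", round(fba(no_input, fix.media).objective_value, 3))
print("limed-FBA, without input:   ", round(limed_fba(no_input, fix.media).objective_value, 3))
print("limed-FBA, input restored:  ", round(limed_fba(fix.model, fix.media).objective_value, 3))
```

```
FBA, cycle without input:    1000.0
limed-FBA, without input:    -0.0
limed-FBA, input restored:   999.8
```

FBA happily runs the input-free cycle at the flux cap and calls the
knockout viable; limed-FBA requires the cycle carriers to dilute, so
without the input enzyme no flux is possible — the gene is correctly
essential. With the input restored, growth resumes (fractionally below
FBA because a little flux feeds dilution).

Synthetic lethality on a two-route fixture (two ways to make an
essential metabolite, one gene each), including nutrient rescue of the
double mutant:

```python
from farm.phenotype import synthetic_lethal_screen, simulate_knockout
from farm.media import build_media

sl = fx.dual_route_sl()
for p in synthetic_lethal_screen(sl.model, sl.media, ["gA", "gB"]):
    print("synthetic lethal:", "+".join(sorted(p.genes)), "->", p.classification)
media = build_media(sl.media, ["G[e]"], model=sl.model)
res = simulate_knockout(sl.model, {"gA", "gB"}, media)
print("double mutant + G supplement, biomass:", round(res.biomass, 3), "viable:", res.viable)
```

```
synthetic lethal: gA+gB -> same_pathway
double mutant + G supplement, biomass: 3.0 viable: True
```

Each single knockout is viable, the double knockout is lethal, the
pair is classified as a common-pathway interaction, and supplementing
the downstream intermediate `G` at the 3 mmol/gDW/h supplement cap
rescues the double mutant.

## Command line

```sh
farm fixture dual_route_sl -o model.xml      # motif model + ground-truth sidecar
farm validate model.xml
farm limedfba model.xml --media media.tsv    # flux TSV + objective
farm prune model.xml -o pruned.xml --fva-check
farm essentiality model.xml --media media.tsv --truth truth.tsv
farm rescue model.xml --gene g1 --supplements list.txt --media media.tsv
farm synlethal model.xml --media media.tsv
farm crop model.xml --phenotypes phenotypes.tsv --database db.xml
```

Media TSVs have columns `metabolite_id`, `max_uptake`; the built-in
`vogels_sucrose` preset caps the carbon source at 1.5 mmol/gDW/h.

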