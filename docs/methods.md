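# Methods

## Scope

`farm` implements constraint-based growth prediction for genome-scale
metabolic models with three coupled pieces: flux balance analysis that
linearly accounts for metabolite dilution, a one-LP detector/pruner of
blocked reactions, and an evidence-weighted reconciler that edits a
model to match observed growth/no-growth phenotypes. On top of these it
provides the standard validation screens (gene essentiality, nutrient
rescue of auxotrophs, pairwise synthetic lethality) and COBRA-dialect
SBML I/O with a reversible identifier codec.

## Dilution-aware flux balance analysis

Classic FBA solves `max c^T v` subject to `S v = 0, lb ≤ v ≤ ub`. Its
well-known blind spot is metabolite dilution: a compound that takes
part in active reactions is diluted by growth and must be continuously
re-synthesized, but the steady-state constraint lets internal cycles
regenerate such compounds with no input flux at all. The symptom is
false viability calls for knockouts of cycle-input enzymes (the
acetylglutamate-synthase pattern in arginine biosynthesis is the
canonical example).

The linear fix used here works on the irreversible model (every
reversible reaction split into two non-negative children). Let
`S^binary` be the 0/1 sparsity pattern of `S`; because `v ≥ 0`, row `i`
of `S^binary v` is the summed absolute flux through metabolite `i` —
twice its turnover — and is positive exactly when the metabolite is
active. Requiring each metabolite to be net-produced at the rate

    b = ε S^binary v,        S v = b
    ⇔  (S − ε S^binary) v = 0        (written S_limed v = 0)

forces active metabolites to dilute, with `ε` a diagonal matrix of
small non-negative coefficients. The LP remains the same size as FBA;
the realized dilution `b` is recovered from `v` after the solve rather
than carried as extra variables.

### Choice of ε

With `k_i` the number of non-exempt reactions metabolite `i`
participates in,

    ε_ii = d_max / (k_i · v_max)

so the worst-case dilution `b_i ≤ ε_ii · k_i · v_max = d_max` is capped
by construction. Defaults: `d_max = 0.1` (flux units) and
`v_max = 1000 mmol/gDW/h`; both are parameters of
`dilution.compute_epsilon`. `d_max = 0.1` keeps dilution on the order
of typical growth-associated drains without materially perturbing
wild-type flux distributions; other normalizations that preserve the
cap (e.g. a constant factor) can be supplied through a custom
`DilutionSpec`.

### Exemptions

Two exemptions keep the construction honest:

* **Biomass metabolites** (`ε_ii = 0`): anything in the biomass
  reaction's stoichiometry already dilutes through the biomass equation
  itself; diluting it twice would double-count. The set is detected
  from the objective reaction and can be overridden.
* **Simple transport reactions** (columns zeroed in `S^binary`):
  reactions that move metabolites between compartments with no chemical
  change — detected structurally as a perfect pairing of consumed and
  produced species (same compartment-stripped identity, coefficient
  magnitude 1, no other participants; antiporters qualify,
  cofactor-driven pumps do not). Without this exemption the optimizer
  can "cheat": a by-product with no exporter can be granted arbitrary
  dilution capacity by running a high-flux 1:1 shuttle loop through it.
  The `transport_cheat` fixture demonstrates both directions: with the
  exemption growth is impossible (correct), without it the shuttle
  manufactures growth.

### Numerics

ε entries are 1e-4–1e-7, small enough to bother some LP algorithms.
Every solve walks a fallback chain — dual simplex, then interior
point, then HiGHS default — before reporting failure; feasibility
tolerances are the solver defaults (~1e-9). Infeasibility is reported
as biomass 0 (the all-zero flux is feasible whenever bounds admit it,
so genuine LP infeasibility only arises when extra constraints such as
a pinned biomass are added). Unbounded problems are an error: models
must carry `v_max` caps.

## One-LP blocked-reaction detection (goal program)

Blocked reactions — those that can carry no flux under any nutrient
condition — are classically found with flux variability analysis, one
or two LPs per reaction. The goal-programming alternative finds the
whole set at once:

    max Σ_i t_i   s.t.  S_limed v = 0,  0 ≤ v ≤ v_max,
                        0 ≤ t_i ≤ 1,   t_i ≤ v_i / δ

on the irreversible model with every exchange opened (all extracellular
metabolites treated as nutrients; the only limit is `v_max`). Once a
reaction reaches flux δ its goal saturates and the optimizer moves on,
so at the optimum the `t_i` are numerically binary and one solve
classifies every reaction. Using `S_limed` rather than `S` penalizes
the split-pair artifact (a disconnected `A↔B` would otherwise cycle
through its own two children).

δ is the operational definition of "can carry flux". The smallest
legitimate fluxes in a dilution-constrained model are disposals through
metabolite dilution, of order `d_max/k ≈ 1e-2`; the default `δ = 1e-4`
sits two orders of magnitude below that scale and three above solver
tolerance, which is what makes the one-LP classification agree with
per-reaction flux maximization (tolerance 1e-6) across the random-model
ensemble in the test suite. δ is configurable.

Known exception, by construction: an exempt simple-transport
self-cycle (e.g. a reversible compartment shuttle on an otherwise
disconnected metabolite) is not penalized in `S_limed` and survives the
goal LP. `prune(..., fva_check=True)` catches these with classical FVA
on the *reversible* plain stoichiometric matrix — the only region in
which such a cycle cannot carry flux — and unions the result.

Pruning removes a reversible parent only when both split directions are
blocked; a single blocked direction tightens the corresponding bound to
zero. Orphaned metabolites are dropped (optional). A blocked biomass
reaction is an error, not a removal: it means the model cannot grow on
any nutrient condition, which callers must see.

## Evidence-weighted reconciliation

When an observed phenotype contradicts the prediction, the reconciler
proposes the cheapest network edit that flips the in-silico call.
Edit costs come from per-reaction evidence on a probabilistic scale:

    w_r = −log(p_biochem · p_thermo · pathway_support)

with all factors in (0, 1]. The log makes independent evidence
additive, a fully supported reaction free, and the minimum-total-weight
edit a maximum-a-posteriori-flavored choice. A reaction without an
evidence record gets the uninformative `pathway_support = 0.5`
(weight ln 2). Manually curated reactions cost 0 to keep and are never
candidates for removal.

**Restoring growth** (observed viable, predicted no-growth): candidate
reactions from a database are merged into the model with their flux
gated by indicators, `v_r ≤ v_max · y_r`, `y_r ∈ [0, 1]`, biomass
pinned just above the viability threshold, and `min Σ w_r y_r` solved
as a single LP (the relaxation of the natural add-set MILP). Because
the gating ties indicators to flux, the relaxed optimum concentrates
weight on the cheapest adequate route; candidates are selected by
rounding *relative to the largest indicator* (default cut 0.5·max y —
an absolute cut is meaningless when indicators scale as
`flux/v_max ≈ 2e-5`), the selection is re-verified by an independent
simulation, and on failure the selected set is pinned and the LP
re-solved, lowering the relative cut if pinning stalls.

**Suppressing growth** (observed inviable, predicted growth): a binary
covering MILP over removable (non-curated, non-exchange, non-biomass)
reactions, solved by iterative cuts: simulate the edited model; if it
still grows, the flux support of that solution is a certificate that at
least one of its removable members must go, which becomes a covering
constraint; re-solve the master `min Σ w_r y_r` and repeat. The loop
ends with a verified minimum-weight cut set, or reports the phenotype
unresolvable when growth flows entirely through immutable reactions.
Ties among equal-weight solutions are broken lexicographically by
reaction id via an infinitesimal (1e-9) weight perturbation, for
reproducibility.

Suggestions are ranked and never auto-applied; accepting one is a
manual-review decision (`Reconciliation.accepted` is the hook).

## Phenotype screens

A knockout is simulated by setting both bounds of every reaction whose
GPR evaluates false to zero (AND = complex, all subunits required;
OR = isozymes, any suffices; the empty rule is gene-independent, and
unknown gene ids are ignored with a warning). Indices stay stable,
which keeps large screens cheap. A mutant is **viable** when its
maximal biomass flux exceeds 0.02 (configurable threshold).

Media are uptake caps on exchange reactions: the limiting carbon source
defaults to 1.5 mmol/gDW/h, supplements to 3 mmol/gDW/h, everything
else non-limiting. A Vogel's-style minimal-medium preset ships as a
data file; its non-carbon components are treated as non-limiting since
only the carbon cap is quantitatively constrained.

* **Essentiality**: one dilution-aware solve per gene; accuracy against
  a truth table is reported as sensitivity (experimentally viable
  predicted viable) and specificity (experimentally inviable predicted
  inviable).
* **Nutrient rescue**: defined only for mutants inviable on the base
  medium; each candidate supplement (or combination) is added at the
  supplement cap and the knockout re-simulated. A combination
  containing an already-rescuing single supplement is reported as
  implied without re-solving.
* **Synthetic lethality**: all unordered pairs of individually viable
  genes; a pair is synthetic-lethal when the double knockout falls
  below the threshold. An optional support-based shortcut skips pairs
  whose blocked reactions miss the wild-type optimal flux support; the
  exhaustive mode is the default and the shortcut is re-checked against
  it in the tests. Pairs are classified mechanistically: *isozyme* if
  the two genes appear in OR positions of one reaction's rule,
  *same pathway* if reactions unique to each gene share a pathway
  annotation, otherwise *interacting pathways*.
* A per-metabolite accumulation allowance (a bounded sink reaction) is
  available for compounds known to pile up in vivo, which the
  steady-state constraint otherwise forbids.

## SBML and identifiers

Models are written as SBML Level 3 + fbc (bounds, objective, gene
products, formulae, charges) plus classic COBRA Notes
(`GENE_ASSOCIATION`, `SUBSYSTEM`, evidence scores) so both modern and
legacy toolchains can read them. Reading prefers fbc and falls back to
kinetic-law `LOWER_BOUND`/`UPPER_BOUND` parameters and Notes. An
unparseable gene association degrades to the empty rule with a logged
warning; a missing objective is an error.

Identifiers pass through a reversible codec: every character outside
the SBML SId grammar is replaced by `__<ascii>__` (so `[` becomes
`__91__`) and a digit-initial result gets a leading underscore. The
naive substitution alone is not injective — a raw id that already
contains a token-shaped substring, or starts with `_<digit>`, would
decode to something else — so encoding falls back to also escaping
underscores (`__95__`) whenever the naive form would not round-trip.
`decode(encode(x)) = x` therefore holds on all printable ASCII
(property-tested).

## Synthetic fixtures: what they do and do not show

The fixture generator plants each pathology with known ground truth:
input-free cycles (catalytic carriers emitting a biomass precursor),
linear biosynthesis chains with per-step genes and supplement plumbing,
branch points, dual routes to an essential metabolite (tagged as one
pathway or two), isozyme pairs, the shuttle-cheat motif, dead ends, and
seeded random networks with small-integer coefficients so that subset
enumeration, truth tables and per-reaction LPs stay exact oracles.

These networks are deliberately tiny and idealized: integer
stoichiometry, no cofactor coupling, no compartmental proton/charge
bookkeeping, one-gene-one-reaction rules except where a motif needs
more, and a single-metabolite biomass drain. Passing the suite
demonstrates that the algorithms have the claimed semantics
(cycle starvation, dilution caps, FVA equivalence, minimal-weight
edits, screen logic); it does not certify prediction accuracy on a real
genome-scale reconstruction, which additionally depends on curation
quality, biomass composition and media fidelity. The genome-scale
reproduction hook in the acceptance tests runs the full protocol when a
published model and its phenotype tables are supplied under `data/`.

## Problem sizes and runtime

The shipped test and acceptance runs use motif fixtures of 5–20
reactions and a 100-model random ensemble (5–11 metabolites, 6–21
reactions before splitting), sizes at which every brute-force oracle is
exact and the whole suite completes in well under a minute on one CPU.
All sampling is seeded; the acceptance script derives every stream from
its `--seed` argument.

## Known limitations

* No kinetics, enzyme capacity, or regulation: phenotypes caused by
  condition-specific expression (glyoxysomal induction, subunit
  swapping) are out of reach by design.
* The one-LP pruner's δ trades a sharp "zero flux" notion for a
  "carries at least δ" notion; reactions whose maximal flux lies below
  δ are called blocked.
* The growth-restoration LP relaxation is exact on the fixture family
  (verified against enumeration) but carries no general optimality
  guarantee; the removal MILP is exact but its cut loop can take many
  simulate/solve rounds on highly redundant networks.
* The simple-transport detector keys on compartment-stripped metabolite
  identity; metabolite ids that encode the same species inconsistently
  across compartments will not pair.
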