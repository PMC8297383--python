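# Methods

## Model representation and conventions

A model is a list of reactions (stoichiometry over metabolite ids, flux
bounds in mmol/gDW/h, optional gene–protein–reaction rule), a list of
metabolites (compartment tag, optional chemical formula and/or explicit
carbon count), an objective reaction and a gene set. All listed metabolites
are balanced (`S v = 0`); the system boundary is expressed through exchange
reactions touching exactly one metabolite. Two boundary writing styles are
accepted: drains `met → ∅` (uptake = negative flux) and sources `∅ → met`
(uptake = positive flux). Uptake magnitudes are always reported
non-negative. An environment overlays uptake caps on the model bounds: a cap
of 1.15 on a drain-form glucose exchange becomes lower bound −1.15; on a
source it becomes upper bound +1.15; caps never widen model bounds.

Reaction kinds are derived structurally — exchange (one metabolite),
transport (same base metabolite id in two compartments), internal — and can
be overridden per reaction, since genome-scale annotations are inconsistent.
Carbon counts resolve in order: caller-supplied map, explicit metadata,
formula parsing (element-aware, so Cl/Ca/Cu are not carbon); polymeric
formulas (X/R residues) raise rather than silently count zero.

GPR rules are boolean trees over gene ids (case-insensitive `and`/`or`,
parentheses). A deletion set silences a reaction when the rule evaluates
false with deleted genes false; reactions without rules cannot be silenced
by gene deletions. Minimal gene cuts of a rule are computed by subset
enumeration over the rule's genes — rules in curated models are small
enough that this is exact and cheap.

Model edits (`add_reaction`, `remove_reaction`, `set_bounds`,
`set_reversibility`) round-trip through plain dicts so that model-specific
patch sets live in YAML/JSON config rather than code. I/O covers SBML L3
with the fbc package (via libsbml) and a versioned flat JSON dialect
(`chassiscraft-model-1`); both round-trip structurally.

## Phenotype prediction

All predictors are linear programs over `S v = 0`, `lb ≤ v ≤ ub`, solved
with HiGHS (scipy.optimize.linprog), which is deterministic for fixed input.
Solver feasibility tolerance is 1e-9; all post-hoc flux comparisons use
1e-6, appropriate to the mmol/gDW/h scale.

- **FBA** maximizes the objective flux and returns one optimal vertex.
- **pFBA** fixes the objective at its optimum (a relative slack of 1e-9 is
  left so the constraint is numerically safe while exact at the 1e-6
  comparison tolerance; a fraction parameter exists for sensitivity runs)
  and minimizes total absolute flux via forward/reverse splitting. Reported
  growth is the stage-1 optimum. The stage-2 LP can itself be degenerate, so
  fluxes are whatever vertex the solver returns; all growth-coupling claims
  are made through FVA minima, never through a single vertex.
- **lMOMA** minimizes the L1 distance to a reference distribution (default:
  wild-type pFBA) with auxiliary deviation variables; the achieved growth is
  read off the solution, not re-optimized. Reactions absent from the
  reference contribute |v − 0|. Notably, lMOMA can prefer a non-growing
  mutant state when total shutdown is a smaller adjustment than re-routing —
  on the T1 toy the g2 deletion yields distance 30 with zero growth, not the
  growing re-routed state at distance 40. Quadratic MOMA is not implemented.
- **FVA** minimizes and maximizes each requested flux with the objective
  held at a fraction of its optimum (default 1.0); with the fraction set to
  `None` it explores the whole feasible region, which is how blocked
  reactions are detected (|min|, |max| < 1e-9).

## Candidate filtering

Screens, in effect: (nearly) essential reactions — closure drops the FBA
optimum below 1% of wild type (one threshold covers both, as a single
criterion); reactions without gene association; drains and transport
reactions (categorical by default, configurable to blocked-only, since the
defining phrase is ambiguous about transporters); blocked reactions; fully
coupled groups collapsed to their lexicographically smallest member. Full
coupling is tested pairwise by FVA with one reaction fixed at zero, in both
directions, and groups are the transitive closure — O(n) FVA sweeps,
deterministic, acceptable at toy and genome scale.

Exclusions are recorded with one reason each. Because a reaction often
matches several screens, the ledger uses a fixed reason priority —
`drain_or_transport` > `non_gene` > `essential` > `blocked` — so structural
classifications outrank phenotype-derived ones; a drain here is an exchange
that can only remove mass (the objective and network-feeding sources are
exempt). The priority affects labels only, never membership: the candidate
list is identical under any ordering.

## Knockout search

The search is SPEA2 over variable-length sets of candidate reaction ids,
maximizing (pFBA growth, pFBA product flux). Canonical SPEA2 fitness:
strength = dominated count, raw fitness = summed strengths of dominators,
density = 1/(σ_k + 2) with k = √(population + archive). Environmental
selection keeps non-dominated individuals, truncating by iterated removal of
the most crowded (lexicographic k-nearest-distance comparison); when the
front is small the canonical fill step tops up the *mating pool* with the
best dominated individuals, but the reported archive contains only mutually
non-dominated solutions (asserted each generation). Defaults: population
100, archive 100, binary tournament mating, uniform set crossover at rate
0.8, exactly one mutation event per offspring (add/remove/replace a
reaction, 1/3 each), repair to 1 ≤ size ≤ max_deletions. Evaluations are
cached by deletion set; the budget counts individual evaluations per
generation. A master seed spawns per-run seeds as seed + run index.

Dead or infeasible phenotypes score (0, 0) and stay in the population so the
search can traverse them. Per-solution metrics: pFBA growth, substrate
uptake and product flux; the FVA product range at optimal growth (positive
minimum = growth-coupled); `CYIELD = (v_product·C_product)/(v_substrate·
C_substrate)`; `BPCY = growth·v_product/v_substrate` (the conventional
biomass-product coupled yield); `COST` = size of the smallest gene-level
implementation of the deletion set. When the environment caps a single
uptake that exchange is the substrate; otherwise the largest importer in
the flux distribution is used (deterministic tie-break on id).

Post-processing: simplification removes deletions whose removal leaves both
objectives equal within 1e-6 or better (so lethal supersets also shrink —
the weakest deterministic reading of "not directly contributing"; removals
proceed in sorted order to a fixpoint, making the operation idempotent and
never worsening an objective, and at least one deletion is kept).
Reaction-to-gene conversion cross-combines per-reaction minimal cuts,
keeps minimal combinations, and drops gene sets whose collateral reaction
closures change either objective by more than 1e-6 (falling back, with a
warning, to the combinatorial sets if all have side effects). Runs merge
into one solution set de-duplicated by primary (smallest) gene set.

## Chassis analysis

Gene frequencies are per-target containment fractions over the merged
solution sets. Clustering of gene rows and target columns uses Euclidean
distance with complete linkage; rows with maximum frequency below 20% are
dropped from the clustering display only — the gene score is computed on the
unfiltered matrix (the filter's published use is the heat map). Rows are
pre-sorted lexicographically so leaf order is independent of input order;
rendering the heat map itself is out of scope, linkages and leaf orders are
exported.

`gscore(g) = (Σ_t freq(g_t)) × #{t : freq(g_t) > 0}` — the indicator is 1
exactly when the frequency is positive. Chassis enumeration takes the
⌈30%⌉ top-scoring genes (boundary ties all included, so the cut is
order-independent) and emits every subset up to size 5. `cscore(c)` sums,
over targets, max CYIELD over min COST within `S_{t,c}` — the solutions
containing `c` whose CYIELD is at least 95% of the best CYIELD *identified*
in that target's merged set (not the theoretical maximum); an empty group
contributes 0. Ranking is by descending cscore, then fewer genes, then
lexicographic gene tuple. The score orders chassis for analysis; it excludes
nothing.

## Omics-constrained flux fitting

Fold changes with q-value below 0.1 are mapped to reactions through GPR
rules: AND-nodes take the minimum over measured children (scarcest subunit
limits a complex), OR-nodes the maximum (dominant isozyme), unmeasured genes
are ignored; when transcript and protein layers both cover a reaction the
protein value wins, being nearer to flux. All three rules are configurable
in code. Extracellular metabolite changes constrain the corresponding
exchange fluxes the same way.

The fit solves, on the (possibly knockout-perturbed) model: soft constraints
`v_r − f_r·v_ref,r = s⁺_r − s⁻_r` with `s± ≥ 0`, a hard bound
`v_obj ≥ growth_frac × reference optimum` (wild type = 1; `growth_frac`
comes from measured growth-rate ratios, never estimated internally), stage 1
minimizing Σ(s⁺+s⁻), stage 2 fixing that optimum (+1e-9) and minimizing
Σ|v|. A zero reference flux with a fold change degenerates to `v = 0` and is
flagged in the logs. This slack-minimizing formulation is this package's
own; it is validated by parameter recovery — for seeded synthetic cases
constructed so that a perturbed feasible vector satisfies every derived
constraint, the fit attains zero slack and reproduces the constrained fluxes
to 1e-4 — not by claimed equivalence to any external tool. Distances between
fitted distributions (the input to ordinations such as PCA) are Euclidean
over the union flux vector with missing ids as zero.

## Toy networks and what they do (not) show

`T1` is the canonical 6-reaction branched network: source `∅→A` (cap 10),
routes `A→C` (gene g2) and `A→B→C+P` (genes g1, g3), biomass drain on C,
product export for P, carbon metadata A = 6, P = 4 (the network is
deliberately not elementally balanced — carbon counts are metadata for the
yield formula). Deleting g2 growth-couples P. `T2` adds a second branch
`A→B2→C+Q` (g4, g5) and product Q, so both products couple through the
shared gene g2 — the minimal shape of a cross-product chassis. `random`
decorates the T1 skeleton, seeded, with product-co-producing chains
`A→Di→C+P` and carbon-wasting side drains, plus a jittered substrate cap;
deleting g2 remains a guaranteed growth-coupling knockout by construction.

These fixtures exercise every code path — alternate optima, co-sets, lethal
combinations, multi-target sharing — but they are tiny, acyclic and
elementally unbalanced: passing tests demonstrate correctness of the
algorithms and formulas, not that a genome-scale model of a real organism
will yield useful designs. Genome-scale behaviour additionally depends on
model curation (GPR completeness, compartment annotations, cofactor
balancing) that the toys do not emulate. Default problem sizes in the test
and acceptance runs (search budgets of 500–2,000 evaluations, populations of
10–20, subsets up to size 3) are chosen to keep exhaustive enumeration
available as an oracle; production settings (100,000 evaluations,
population/archive 100, up to 20 deletions, 10 runs) remain the package
defaults.

## Numerical choices and known limitations

- Objective-vector comparisons in the search round to 1e-9 so LP noise
  cannot flip domination decisions.
- FVA min/max pairs are clamped to their midpoint if solver noise inverts
  them (sub-1e-9 effect).
- Infeasible omics fits return a diagnostic naming the unreachable growth
  floor rather than raising.
- The search optimizes the optimistic pFBA product flux; a solution can sit
  on the Pareto front without being robustly coupled. The FVA minimum is
  reported per solution precisely so downstream analysis can tell the two
  apart. Simplification likewise tests the pFBA objectives, so under
  degenerate optima it may strip deletions that mattered only for
  robustness; this mirrors the optimistic fitness definition.
- Integer-programming formulations (OptKnock-style bilevel designs),
  regulatory constraints, thermodynamic feasibility and flux sampling are
  out of scope.
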