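# chassiscraft

Model-guided design of microbial *chassis* strains — hosts pre-optimized by
gene deletions to channel carbon toward precursors shared by several target
products — on constraint-based metabolic models.

Most industrially interesting compounds derive from a small set of precursor
metabolites, so a single knockout backbone can serve many products. The
difficulty is finding deletion sets that *growth-couple* production: network
states in which every growth-optimal flux distribution secretes the product,
so that adaptive evolution improves rather than erodes the titre.
`chassiscraft` implements the full in-silico workflow for this problem:

1. **Phenotype prediction** — FBA, parsimonious FBA (pFBA), linear MOMA
   (lMOMA) and flux variability analysis (FVA) over a stoichiometric model
   `S v = 0`, `lb ≤ v ≤ ub`, solved with HiGHS.
2. **Target filtering** — reduces the reaction list to admissible knockout
   candidates by removing (nearly) essential reactions (growth under 1% of
   wild type), gene-free reactions, drains/transporters, blocked reactions,
   and all but one representative of each fully coupled set.
3. **Knockout search** — a Strength Pareto Evolutionary Algorithm 2 (SPEA2)
   over variable-size deletion sets (default ≤ 20), maximizing the two
   conflicting objectives *biomass flux* and *product flux* under pFBA, with
   a 100-solution archive, multi-run merging, solution simplification and
   GPR-based conversion of reaction deletions to minimal gene deletions.
4. **Chassis analysis** — per-target gene frequencies, hierarchical
   clustering (Euclidean/complete), and two scores:

   - gene score  `gscore(g) = (Σ_t freq(g_t)) × #{t : freq(g_t) > 0}`
   - chassis score `cscore(c) = Σ_t max CYIELD(S_{t,c}) / min COST(S_{t,c})`

   where `S_{t,c}` holds the target-*t* solutions containing gene set *c*
   and passing a 95 %-of-best carbon-yield filter, with
   `CYIELD = (v_product × C_product)/(v_substrate × C_substrate)` and
   `COST` the number of deleted genes.
5. **Omics-constrained flux fitting** — significant transcript/protein fold
   changes (q < 0.1) mapped onto reactions through GPR rules (AND → min,
   OR → max) and imposed as soft constraints `v_r = f_r · v_ref,r`, with a
   hard growth bound `v_obj ≥ growth_frac × reference optimum`; a two-stage
   LP minimizes total constraint violation, then total flux.

Genome-scale models load from SBML Level 3 (fbc) or a small JSON dialect;
seeded toy-model generators (`make_toy_model`) provide branched networks
with known growth-coupling knockouts for testing and demonstration.

## Worked example

```python
from chassiscraft import (Environment, make_toy_model, simulate_knockout,
                          evaluate_solution, select_candidates)

t1 = make_toy_model("T1")          # A -> {B -> C + P | C}; biomass drains C
env = Environment()

wt = simulate_knockout(t1, env, set(), product_id="EX_P")
ko = simulate_knockout(t1, env, {"g2"}, product_id="EX_P")
print(f"wild type: growth {wt.growth:.1f}, product {wt.product_flux:.1f}")
print(f"del g2:    growth {ko.growth:.1f}, product {ko.product_flux:.1f}")

m = evaluate_solution(t1, env, {"R2"}, "EX_P")
print(f"FVA product range {m.fva_product_range[0]:.1f}-{m.fva_product_range[1]:.1f},"
      f" CYIELD {m.cyield:.3f}, BPCY {m.bpcy:.1f}, COST {m.cost}")
print("candidates:", select_candidates(t1, env).candidates)
```

prints

```
wild type: growth 10.0, product 0.0
del g2:    growth 10.0, product 10.0
FVA product range 10.0-10.0, CYIELD 0.667, BPCY 10.0, COST 1
candidates: ['R1', 'R2']
```

Deleting `g2` closes the direct route A→C, so the only remaining path to
the biomass precursor co-produces P: growth is unchanged but the FVA
minimum of the product export rises from 0 to 10 — production is now
growth-coupled. The carbon yield is (10×4 C)/(10×6 C) = 0.667 at the cost
of one gene. The same stages are available from the shell
(`chassiscraft make-toy | patch | simulate | filter-targets | optimize |
analyze-chassis | omics-fit`).

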