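"""Multi-objective gene-knockout search (SPEA2) and solution metrics.

The search explores variable-length sets of candidate reaction deletions
(up to a configurable maximum, default 20) with the Strength Pareto
Evolutionary Algorithm 2, maximizing two conflicting objectives: biomass
flux and target-product flux, both predicted with pFBA.  An archive keeps
the best solutions found (default 100).  Finished runs are post-processed:
deletions that do not contribute to either objective are dropped, the
reaction-level deletions are converted to their minimal gene-level
equivalents through the GPR rules, and the runs are merged into a single
de-duplicated solution set.

Each evaluated solution carries the metrics used downstream by the chassis
analysis:

* growth, substrate uptake and product flux under pFBA;
* the FVA range of product flux at optimal growth (a positive minimum
  diagnoses growth coupling — robustness is never claimed from a single
  pFBA vertex);
* BPCY, the biomass-product coupled yield, growth x product / substrate;
* CYIELD, the carbon yield: product flux x product carbons over substrate
  flux x substrate carbons;
* COST, the number of genes in the smallest gene-level implementation.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from itertools import combinations, product as iproduct
from typing import Iterable, Sequence

import numpy as np

from .model_core import (
    ChassiscraftError,
    MetabolicModel,
    carbon_content,
    reactions_silenced_by,
)
from .phenotype import Environment, FLUX_TOL, fva, pfba
from .target_filter import CandidateSet

logger = logging.getLogger("chassiscraft")


@dataclass(frozen=True)
class SolutionMetrics:
    growth: float
    substrate_uptake: float
    product_flux: float
    fva_product_range: tuple[float, float]
    bpcy: float
    cyield: float
    cost: int


@dataclass
class KnockoutSolution:
    """A deletion set with its evaluated metrics.

    ``reaction_deletions`` is the reaction-level set searched by the EA;
    ``gene_deletions`` is the primary (smallest) minimal gene set that
    implements it, with any alternative minimal sets in
    ``alternative_gene_sets``.
    """

    reaction_deletions: frozenset[str]
    metrics: SolutionMetrics
    gene_deletions: frozenset[str] = frozenset()
    alternative_gene_sets: tuple[frozenset[str], ...] = ()


@dataclass
class SearchConfig:
    product_id: str = ""
    substrate_id: str | None = None
    max_deletions: int = 20
    evaluations: int = 100_000
    archive_size: int = 100
    population_size: int = 100
    runs: int = 10
    seed: int = 0
    crossover_rate: float = 0.8
    objective_fraction: float = 1.0
    carbon_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.archive_size < 1 or self.population_size < 1:
            raise ChassiscraftError("archive and population sizes must be >= 1")
        if self.max_deletions < 1 or self.evaluations < 1 or self.runs < 1:
            raise ChassiscraftError("all search counts must be positive")


@dataclass
class SolutionSet:
    product_id: str
    solutions: list[KnockoutSolution]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

_ZERO_METRICS_FVA = (0.0, 0.0)


def _close_reactions(model: MetabolicModel, deletions: Iterable[str]) -> MetabolicModel:
    mutant = model.copy()
    for rid in deletions:
        rxn = mutant.reaction(rid)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return mutant


def minimal_cost(model: MetabolicModel, deletions: Iterable[str]) -> int:
    """Size of the smallest combined gene set silencing all deletions."""
    sets = _gene_set_combinations(model, deletions)
    return len(sets[0]) if sets else 0


def evaluate_solution(
    model: MetabolicModel,
    env: Environment,
    deletions: Iterable[str],
    product_id: str,
    substrate_id: str | None = None,
    carbon_map: dict[str, int] | None = None,
) -> SolutionMetrics:
    """Evaluate a reaction-deletion set against all solution metrics.

    Dead or infeasible phenotypes (growth ~ 0) score zero on every yield
    metric but are returned rather than raised, so the search can traverse
    them.
    """
    deletions = frozenset(deletions)
    product_rxn = model.reaction(product_id)
    if not product_rxn.is_exchange():
        raise ChassiscraftError(
            f"product id {product_id!r} is not an exchange/drain reaction"
        )
    mutant = _close_reactions(model, deletions)
    result = pfba(mutant, env, product_id=product_id, substrate_id=substrate_id)
    cost = minimal_cost(model, deletions)
    if result.status != "optimal" or result.growth <= FLUX_TOL:
        return SolutionMetrics(
            growth=0.0,
            substrate_uptake=0.0,
            product_flux=0.0,
            fva_product_range=_ZERO_METRICS_FVA,
            bpcy=0.0,
            cyield=0.0,
            cost=cost,
        )
    fva_range = fva(mutant, env, reactions=[product_id], objective_fraction=1.0)[
        product_id
    ]
    substrate = substrate_id
    if substrate is None:
        from .phenotype import infer_substrate_exchange

        substrate = infer_substrate_exchange(model, env, result.distribution)
    if substrate is None:
        raise ChassiscraftError(
            "cannot identify the substrate exchange; pass substrate_id"
        )
    uptake = result.substrate_uptake
    product_flux = result.product_flux
    if uptake <= FLUX_TOL:
        bpcy = cyield = 0.0
    else:
        product_met = next(iter(model.reaction(product_id).stoichiometry))
        substrate_met = next(iter(model.reaction(substrate).stoichiometry))
        c_product = carbon_content(model, product_met, carbon_map)
        c_substrate = carbon_content(model, substrate_met, carbon_map)
        if c_substrate == 0:
            raise ChassiscraftError(
                f"substrate {substrate_met!r} has zero carbon content"
            )
        cyield = (product_flux * c_product) / (uptake * c_substrate)
        bpcy = result.growth * product_flux / uptake
    return SolutionMetrics(
        growth=result.growth,
        substrate_uptake=uptake,
        product_flux=product_flux,
        fva_product_range=fva_range,
        bpcy=bpcy,
        cyield=cyield,
        cost=cost,
    )


class _Evaluator:
    """Caches metric evaluations by deletion set and counts EA evaluations."""

    def __init__(self, model, env, config: SearchConfig):
        self.model = model
        self.env = env
        self.config = config
        self.cache: dict[frozenset[str], SolutionMetrics] = {}
        self.evaluations = 0  # every individual evaluation, cached or not

    def __call__(self, deletions: frozenset[str]) -> SolutionMetrics:
        self.evaluations += 1
        if deletions not in self.cache:
            self.cache[deletions] = evaluate_solution(
                self.model,
                self.env,
                deletions,
                self.config.product_id,
                self.config.substrate_id,
                self.config.carbon_map or None,
            )
        return self.cache[deletions]


# ---------------------------------------------------------------------------
# SPEA2
# ---------------------------------------------------------------------------

def _objectives(metrics: SolutionMetrics) -> tuple[float, float]:
    # rounded so LP noise cannot flip domination decisions
    return (round(metrics.growth, 9), round(metrics.product_flux, 9))


def _dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] >= b[0] and a[1] >= b[1] and (a[0] > b[0] or a[1] > b[1])


def pareto_front(points: Iterable[tuple[float, float]]) -> set[tuple[float, float]]:
    """Non-dominated subset of objective vectors (maximization)."""
    pts = set(points)
    return {
        p for p in pts if not any(_dominates(q, p) for q in pts if q != p)
    }


def _spea2_fitness(objs: list[tuple[float, float]]) -> list[float]:
    n = len(objs)
    strength = [sum(1 for j in range(n) if _dominates(objs[i], objs[j])) for i in range(n)]
    raw = [
        sum(strength[j] for j in range(n) if _dominates(objs[j], objs[i]))
        for i in range(n)
    ]
    pts = np.asarray(objs, dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    k = max(1, int(round(np.sqrt(n))))
    sorted_dist = np.sort(dist, axis=1)
    kth = sorted_dist[:, min(k, n - 1) - 1] if n > 1 else np.zeros(n)
    density = 1.0 / (kth + 2.0)
    return [raw[i] + float(density[i]) for i in range(n)]


def _truncate(members: list, objs: list[tuple[float, float]], size: int) -> list[int]:
    """SPEA2 archive truncation: iteratively drop the most crowded member."""
    keep = list(range(len(members)))
    pts = np.asarray(objs, dtype=float)
    while len(keep) > size:
        sub = pts[keep]
        diff = sub[:, None, :] - sub[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(dist, np.inf)
        ordered = np.sort(dist, axis=1)
        # lexicographic comparison of sorted distance vectors
        worst = 0
        for i in range(1, len(keep)):
            for a, b in zip(ordered[i], ordered[worst]):
                if a < b - 1e-12:
                    worst = i
                    break
                if a > b + 1e-12:
                    break
        keep.pop(worst)
    return keep


def _random_individual(rng: random.Random, candidates, max_deletions) -> frozenset[str]:
    size = rng.randint(1, min(max_deletions, len(candidates)))
    return frozenset(rng.sample(candidates, size))


def _repair(
    genes: set[str], rng: random.Random, candidates, max_deletions
) -> frozenset[str]:
    genes = set(genes)
    while len(genes) > max_deletions:
        genes.remove(rng.choice(sorted(genes)))
    if not genes:
        genes.add(rng.choice(candidates))
    return frozenset(genes)


def _crossover(a, b, rng, candidates, max_deletions) -> frozenset[str]:
    # uniform set crossover: each element of the union kept with p = 1/2
    child = {g for g in sorted(a | b) if rng.random() < 0.5}
    return _repair(child, rng, candidates, max_deletions)


def _mutate(individual, rng, candidates, max_deletions) -> frozenset[str]:
    genes = set(individual)
    move = rng.random()
    pool = [c for c in candidates if c not in genes]
    if move < 1 / 3 and pool:  # add
        genes.add(rng.choice(pool))
    elif move < 2 / 3 and len(genes) > 1:  # remove
        genes.remove(rng.choice(sorted(genes)))
    else:  # replace
        if genes and pool:
            genes.remove(rng.choice(sorted(genes)))
            genes.add(rng.choice(pool))
    return _repair(genes, rng, candidates, max_deletions)


def spea2_search(
    model: MetabolicModel,
    env: Environment,
    candidates: CandidateSet | Sequence[str],
    config: SearchConfig,
) -> list[KnockoutSolution]:
    """Run one SPEA2 search and return the final archive.

    The archive contains only mutually non-dominated solutions (asserted
    each generation); the canonical SPEA2 fill step, which can admit
    dominated individuals when the front is small, only feeds the mating
    pool.  Fully reproducible from ``config.seed``.
    """
    pool = (
        list(candidates.candidates)
        if isinstance(candidates, CandidateSet)
        else list(candidates)
    )
    if not pool:
        raise ChassiscraftError("candidate list is empty")
    if config.evaluations < config.population_size:
        raise ChassiscraftError(
            "evaluation budget smaller than one generation "
            f"({config.evaluations} < population {config.population_size})"
        )
    rng = random.Random(config.seed)
    evaluator = _Evaluator(model, env, config)
    max_dels = min(config.max_deletions, len(pool))

    population = [
        _random_individual(rng, pool, max_dels)
        for _ in range(config.population_size)
    ]
    archive: list[frozenset[str]] = []

    while True:
        union: list[frozenset[str]] = []
        seen = set()
        for ind in population + archive:
            if ind not in seen:
                union.append(ind)
                seen.add(ind)
        metrics = [evaluator(ind) for ind in union]
        objs = [_objectives(m) for m in metrics]
        fitness = _spea2_fitness(objs)

        nondom_idx = [i for i, f in enumerate(fitness) if f < 1.0]
        if len(nondom_idx) > config.archive_size:
            kept = _truncate(
                [union[i] for i in nondom_idx],
                [objs[i] for i in nondom_idx],
                config.archive_size,
            )
            nondom_idx = [nondom_idx[i] for i in kept]
        archive = [union[i] for i in nondom_idx]
        front = pareto_front([objs[i] for i in nondom_idx])
        assert all(objs[i] in front for i in nondom_idx), (
            "archive contains a Pareto-dominated member"
        )

        # mating pool: archive topped up with the best dominated individuals
        mating_idx = list(nondom_idx)
        if len(mating_idx) < config.archive_size:
            dominated = sorted(
                (i for i in range(len(union)) if i not in set(nondom_idx)),
                key=lambda i: fitness[i],
            )
            mating_idx += dominated[: config.archive_size - len(mating_idx)]
        mating_pool = [union[i] for i in mating_idx]

        if evaluator.evaluations >= config.evaluations:
            break

        def tournament():
            i, j = rng.randrange(len(mating_idx)), rng.randrange(len(mating_idx))
            return mating_pool[i if fitness[mating_idx[i]] <= fitness[mating_idx[j]] else j]

        population = []
        for _ in range(config.population_size):
            if rng.random() < config.crossover_rate:
                child = _crossover(tournament(), tournament(), rng, pool, max_dels)
            else:
                child = tournament()
            child = _mutate(child, rng, pool, max_dels)
            population.append(child)

    return [
        KnockoutSolution(reaction_deletions=ind, metrics=evaluator.cache[ind])
        for ind in sorted(archive, key=lambda s: tuple(sorted(s)))
    ]


def brute_force_front(
    model: MetabolicModel,
    env: Environment,
    candidates: Sequence[str],
    config: SearchConfig,
    max_size: int | None = None,
) -> set[tuple[float, float]]:
    """Exhaustive Pareto front over all deletion subsets (oracle for tests)."""
    max_size = max_size or config.max_deletions
    points = []
    for size in range(1, max_size + 1):
        for combo in combinations(sorted(candidates), size):
            metrics = evaluate_solution(
                model,
                env,
                frozenset(combo),
                config.product_id,
                config.substrate_id,
                config.carbon_map or None,
            )
            points.append(_objectives(metrics))
    return pareto_front(points)


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def simplify_solution(
    model: MetabolicModel,
    env: Environment,
    solution: KnockoutSolution,
    product_id: str,
    substrate_id: str | None = None,
    carbon_map: dict[str, int] | None = None,
) -> KnockoutSolution:
    """Drop deletions that do not contribute to either objective.

    A deletion is removed when its removal leaves growth and product flux
    unchanged within 1e-6 or improves them; removals are attempted in
    sorted order until a fixpoint, so the operation is deterministic and
    idempotent and never worsens either objective.  At least one deletion is
    always kept.
    """
    current = set(solution.reaction_deletions)
    metrics = solution.metrics
    changed = True
    while changed and len(current) > 1:
        changed = False
        for rid in sorted(current):
            if len(current) == 1:
                break
            trial = frozenset(current - {rid})
            trial_metrics = evaluate_solution(
                model, env, trial, product_id, substrate_id, carbon_map
            )
            if (
                trial_metrics.growth >= metrics.growth - FLUX_TOL
                and trial_metrics.product_flux >= metrics.product_flux - FLUX_TOL
            ):
                current = set(trial)
                metrics = trial_metrics
                changed = True
    final = frozenset(current)
    if final != solution.reaction_deletions:
        metrics = evaluate_solution(
            model, env, final, product_id, substrate_id, carbon_map
        )
    return KnockoutSolution(reaction_deletions=final, metrics=metrics)


def _gene_set_combinations(
    model: MetabolicModel, deletions: Iterable[str]
) -> list[frozenset[str]]:
    """All minimal combined gene sets silencing every deleted reaction."""
    per_reaction: list[list[frozenset[str]]] = []
    for rid in sorted(deletions):
        rxn = model.reaction(rid)
        if rxn.gpr is None:
            raise ChassiscraftError(
                f"reaction {rid!r} has no gene association and cannot be "
                "deleted at gene level (it should have been filtered)"
            )
        per_reaction.append(rxn.gpr.minimal_knockout_sets())
    combos: set[frozenset[str]] = set()
    for parts in iproduct(*per_reaction):
        combined = frozenset().union(*parts)
        combos.add(combined)
    minimal = [
        c for c in combos if not any(other < c for other in combos)
    ]
    return sorted(minimal, key=lambda s: (len(s), tuple(sorted(s))))


def reactions_to_genes(
    model: MetabolicModel,
    deletions: Iterable[str],
    env: Environment | None = None,
    product_id: str | None = None,
    substrate_id: str | None = None,
    carbon_map: dict[str, int] | None = None,
) -> list[frozenset[str]]:
    """Minimal gene-deletion sets equivalent to a reaction-deletion set.

    When an environment and product are supplied, gene sets that silence
    additional reactions are kept only if the collateral closures leave both
    objectives unchanged within 1e-6 (side-effect check); without them the
    purely combinatorial minimal sets are returned.
    """
    deletions = frozenset(deletions)
    combos = _gene_set_combinations(model, deletions)
    if env is None or product_id is None:
        return combos
    base = evaluate_solution(
        model, env, deletions, product_id, substrate_id, carbon_map
    )
    kept = []
    for genes in combos:
        silenced = reactions_silenced_by(model, genes)
        if silenced == deletions:
            kept.append(genes)
            continue
        actual = evaluate_solution(
            model, env, silenced, product_id, substrate_id, carbon_map
        )
        if (
            abs(actual.growth - base.growth) <= FLUX_TOL
            and abs(actual.product_flux - base.product_flux) <= FLUX_TOL
        ):
            kept.append(genes)
    if not kept:
        logger.warning(
            "all gene conversions of %s have objective-changing side effects; "
            "keeping combinatorial minimal sets",
            sorted(deletions),
        )
        kept = combos
    return kept


def merge_runs(
    run_archives: Sequence[Sequence[KnockoutSolution]],
    model: MetabolicModel,
    env: Environment,
    product_id: str,
    substrate_id: str | None = None,
    carbon_map: dict[str, int] | None = None,
    simplify: bool = True,
    archive_products: Sequence[str] | None = None,
) -> SolutionSet:
    """Merge per-run archives into one simplified, gene-level solution set.

    Solutions are simplified, converted to gene-deletion sets and
    de-duplicated by their primary gene set; metrics (including COST, the
    size of the primary gene set) are retained.  ``archive_products``, when
    given, must all equal ``product_id`` — merging runs for different
    targets is an error.
    """
    if archive_products is not None:
        stray = {p for p in archive_products if p != product_id}
        if stray:
            raise ChassiscraftError(
                f"cannot merge archives for mixed products: {sorted(stray)} "
                f"vs {product_id!r}"
            )
    merged: dict[frozenset[str], KnockoutSolution] = {}
    for archive in run_archives:
        for solution in archive:
            if simplify:
                solution = simplify_solution(
                    model, env, solution, product_id, substrate_id, carbon_map
                )
            gene_sets = reactions_to_genes(
                model,
                solution.reaction_deletions,
                env,
                product_id,
                substrate_id,
                carbon_map,
            )
            primary = gene_sets[0]
            entry = KnockoutSolution(
                reaction_deletions=solution.reaction_deletions,
                metrics=SolutionMetrics(
                    growth=solution.metrics.growth,
                    substrate_uptake=solution.metrics.substrate_uptake,
                    product_flux=solution.metrics.product_flux,
                    fva_product_range=solution.metrics.fva_product_range,
                    bpcy=solution.metrics.bpcy,
                    cyield=solution.metrics.cyield,
                    cost=len(primary),
                ),
                gene_deletions=primary,
                alternative_gene_sets=tuple(gene_sets[1:]),
            )
            if primary not in merged:
                merged[primary] = entry
    ordered = sorted(
        merged.values(),
        key=lambda s: (len(s.gene_deletions), tuple(sorted(s.gene_deletions))),
    )
    return SolutionSet(product_id=product_id, solutions=ordered)
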