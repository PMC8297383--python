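"""Constraint-based phenotype prediction.

Implements the standard linear-programming phenotype predictors over a
:class:`~chassiscraft.model_core.MetabolicModel`:

* FBA — maximize the objective flux subject to steady state and bounds;
* pFBA — among growth-optimal solutions, minimize total absolute flux;
* lMOMA — minimize the L1 distance to a reference flux distribution;
* FVA — per-reaction flux min/max at (near-)optimal objective;
* gene-knockout simulation composing GPR-driven deletions with a predictor.

All LPs are solved with the HiGHS solver through
:func:`scipy.optimize.linprog`, which is deterministic for fixed input, so
identical inputs give identical outputs.  Solver feasibility tolerance is
1e-9; all post-hoc comparisons in this package use 1e-6, appropriate for
fluxes on the mmol/gDW/h scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model_core import (
    ChassiscraftError,
    MetabolicModel,
    apply_gene_deletions,
)

logger = logging.getLogger("chassiscraft")

#: solver feasibility tolerance passed to HiGHS
SOLVER_TOL = 1e-9
#: tolerance for all post-hoc flux comparisons
FLUX_TOL = 1e-6
#: relative slack left when fixing an objective at its optimum
OBJECTIVE_FIX_TOL = 1e-9


class SolverError(ChassiscraftError):
    """The LP solver failed in an unexpected way."""


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------

@dataclass
class Environment:
    """Growth-environment specification.

    ``uptake_limits`` maps an exchange-reaction id (or the id of the single
    metabolite it touches) to a maximum uptake magnitude in mmol/gDW/h;
    ``unrestricted`` lists exchange ids whose uptake is uncapped (e.g.
    oxygen).  Exchanges not named keep their model bounds.  The sign of the
    imposed bound follows the reaction's writing direction: a drain
    ``met -> ∅`` takes up at negative flux (lower bound −limit); a source
    ``∅ -> met`` takes up at positive flux (upper bound +limit).
    """

    uptake_limits: dict[str, float] = field(default_factory=dict)
    unrestricted: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for key, value in self.uptake_limits.items():
            if value < 0:
                raise ChassiscraftError(
                    f"uptake magnitude for {key!r} must be >= 0, got {value}"
                )

    def resolve(self, model: MetabolicModel, key: str) -> str:
        """Map an uptake key to an exchange reaction id."""
        if model.has_reaction(key):
            return key
        rid = model.exchange_for_metabolite(key)
        if rid is None:
            raise ChassiscraftError(
                f"no exchange reaction found for environment key {key!r}"
            )
        return rid

    def bounds_for(self, model: MetabolicModel) -> list[tuple[float, float]]:
        """Model bounds merged with the environment's uptake caps."""
        bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
        index = {r.id: i for i, r in enumerate(model.reactions)}
        for key, limit in self.uptake_limits.items():
            rid = self.resolve(model, key)
            rxn = model.reaction(rid)
            if not rxn.is_exchange():
                raise ChassiscraftError(
                    f"uptake limit target {rid!r} is not an exchange reaction"
                )
            coef = next(iter(rxn.stoichiometry.values()))
            lb, ub = bounds[index[rid]]
            if coef < 0:  # drain form: uptake is negative flux
                bounds[index[rid]] = (max(lb, -limit), ub)
            else:  # source form: uptake is positive flux
                bounds[index[rid]] = (lb, min(ub, limit))
        for key in self.unrestricted:
            rid = self.resolve(model, key)
            rxn = model.reaction(rid)
            coef = next(iter(rxn.stoichiometry.values()))
            lb, ub = bounds[index[rid]]
            if coef < 0:
                bounds[index[rid]] = (-np.inf, ub)
            else:
                bounds[index[rid]] = (lb, np.inf)
        return bounds

    @classmethod
    def from_dict(cls, data: Mapping) -> "Environment":
        return cls(
            uptake_limits={k: float(v) for k, v in (data.get("uptake_limits") or {}).items()},
            unrestricted=set(data.get("unrestricted") or []),
        )

    def to_dict(self) -> dict:
        return {
            "uptake_limits": dict(self.uptake_limits),
            "unrestricted": sorted(self.unrestricted),
        }


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class FluxDistribution:
    """One steady-state solution: reaction id -> flux, plus solver status."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rid: str) -> float:
        return self.fluxes.get(rid, 0.0)

    def get(self, rid: str, default: float = 0.0) -> float:
        return self.fluxes.get(rid, default)


@dataclass
class PhenotypeResult:
    """Growth, product and substrate summary of one phenotype prediction."""

    growth: float
    product_flux: float
    substrate_uptake: float  # magnitude, >= 0
    method: str  # fba | pfba | lmoma
    distribution: FluxDistribution
    l1_distance: float | None = None  # attached by lMOMA

    @property
    def status(self) -> str:
        return self.distribution.status


# ---------------------------------------------------------------------------
# LP scaffolding
# ---------------------------------------------------------------------------

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )
    if res.status not in _STATUS:
        raise SolverError(f"LP solver failure: {res.message}")
    return res


def _empty_distribution(status: str) -> FluxDistribution:
    return FluxDistribution(fluxes={}, objective_value=0.0, status=status)


def _uptake_magnitude(model: MetabolicModel, dist: FluxDistribution, rid: str) -> float:
    """Uptake magnitude of an exchange reaction, respecting its direction."""
    rxn = model.reaction(rid)
    coef = next(iter(rxn.stoichiometry.values()))
    v = dist.get(rid)
    return max(v, 0.0) if coef > 0 else max(-v, 0.0)


def infer_substrate_exchange(
    model: MetabolicModel, env: Environment, dist: FluxDistribution | None = None
) -> str | None:
    """Pick the substrate exchange reaction.

    If the environment caps exactly one uptake, that exchange is the
    substrate.  Otherwise the exchange importing the most flux in ``dist``
    is chosen (deterministic tie-break on reaction id).
    """
    if len(env.uptake_limits) == 1:
        return env.resolve(model, next(iter(env.uptake_limits)))
    if dist is None:
        return None
    best, best_flux = None, 0.0
    for rxn in sorted(model.reactions, key=lambda r: r.id):
        if not rxn.is_exchange():
            continue
        mag = _uptake_magnitude(model, dist, rxn.id)
        if mag > best_flux + FLUX_TOL:
            best, best_flux = rxn.id, mag
    return best


# ---------------------------------------------------------------------------
# Predictors
# ---------------------------------------------------------------------------

def fba(model: MetabolicModel, env: Environment | None = None) -> FluxDistribution:
    """Flux balance analysis: maximize the objective flux.

    Returns the optimum and one optimal vertex; alternate optima are not
    resolved here (use FVA for robustness claims).
    """
    env = env or Environment()
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    bounds = env.bounds_for(model)
    c = np.zeros(n)
    c[model.reaction_ids.index(model.objective_reaction)] = -1.0
    res = _solve(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds)
    status = _STATUS[res.status]
    if status != "optimal":
        return _empty_distribution(status)
    fluxes = dict(zip(model.reaction_ids, (float(x) + 0.0 for x in res.x)))
    return FluxDistribution(
        fluxes=fluxes,
        objective_value=float(-res.fun),
        status="optimal",
    )


def _split_bounds(bounds):
    """Forward/reverse non-negative bounds for |v| splitting v = f - r."""
    fwd, rev = [], []
    for lb, ub in bounds:
        fwd.append((max(lb, 0.0), max(ub, 0.0)))
        rev.append((max(-ub, 0.0), max(-lb, 0.0)))
    return fwd + rev


def pfba(
    model: MetabolicModel,
    env: Environment | None = None,
    product_id: str | None = None,
    substrate_id: str | None = None,
    objective_fraction: float = 1.0,
) -> PhenotypeResult:
    """Parsimonious FBA: fix growth at its optimum, minimize total |flux|.

    Stage 1 maximizes the objective; stage 2 constrains the objective to at
    least ``objective_fraction`` of that optimum (up to a relative slack of
    1e-9, so fixing is exact at the 1e-6 comparison tolerance) and minimizes
    the sum of absolute fluxes via splitting each flux
    into non-negative forward/reverse parts.  Reported growth equals the
    stage-1 optimum.
    """
    env = env or Environment()
    stage1 = fba(model, env)
    if stage1.status != "optimal":
        return PhenotypeResult(0.0, 0.0, 0.0, "pfba", stage1)
    opt = stage1.objective_value

    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    bounds = env.bounds_for(model)
    obj_idx = model.reaction_ids.index(model.objective_reaction)

    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    # objective >= fraction * optimum (relative tolerance 1e-6)
    floor = objective_fraction * opt
    floor -= OBJECTIVE_FIX_TOL * max(1.0, abs(floor))
    row = np.zeros(2 * n)
    row[obj_idx], row[n + obj_idx] = -1.0, 1.0
    res = _solve(
        c=np.ones(2 * n),
        A_ub=row[None, :],
        b_ub=np.array([-floor]),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=_split_bounds(bounds),
    )
    if _STATUS[res.status] != "optimal":
        raise SolverError(
            f"pFBA stage 2 unexpectedly {_STATUS[res.status]} on {model.id!r}"
        )
    v = res.x[:n] - res.x[n:]
    fluxes = dict(zip(model.reaction_ids, (float(x) + 0.0 for x in v)))
    dist = FluxDistribution(fluxes=fluxes, objective_value=opt, status="optimal")
    substrate = substrate_id or infer_substrate_exchange(model, env, dist)
    return PhenotypeResult(
        growth=opt,
        product_flux=dist.get(product_id) if product_id else 0.0,
        substrate_uptake=_uptake_magnitude(model, dist, substrate) if substrate else 0.0,
        method="pfba",
        distribution=dist,
    )


def lmoma(
    model: MetabolicModel,
    env: Environment | None = None,
    reference: FluxDistribution | None = None,
    product_id: str | None = None,
    substrate_id: str | None = None,
) -> PhenotypeResult:
    """Linear MOMA: minimize the L1 distance to a reference distribution.

    The achieved growth is read off the solution, not re-optimized.
    Reactions absent from the reference contribute |v - 0|.
    """
    env = env or Environment()
    if reference is None:
        raise ChassiscraftError("lMOMA requires a reference flux distribution")
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    bounds = env.bounds_for(model)
    ref = np.array([reference.get(rid) for rid in model.reaction_ids])

    # variables: [v, d]; d_j >= |v_j - ref_j|
    A_eq = np.hstack([S, np.zeros((S.shape[0], n))])
    b_eq = np.zeros(S.shape[0])
    eye = np.eye(n)
    A_ub = np.vstack(
        [np.hstack([eye, -eye]), np.hstack([-eye, -eye])]
    )
    b_ub = np.concatenate([ref, -ref])
    c = np.concatenate([np.zeros(n), np.ones(n)])
    var_bounds = list(bounds) + [(0.0, np.inf)] * n
    res = _solve(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=var_bounds)
    status = _STATUS[res.status]
    if status != "optimal":
        return PhenotypeResult(0.0, 0.0, 0.0, "lmoma", _empty_distribution(status))
    v = res.x[:n]
    fluxes = dict(zip(model.reaction_ids, (float(x) + 0.0 for x in v)))
    obj_idx = model.reaction_ids.index(model.objective_reaction)
    dist = FluxDistribution(
        fluxes=fluxes, objective_value=float(v[obj_idx]), status="optimal"
    )
    substrate = substrate_id or infer_substrate_exchange(model, env, dist)
    return PhenotypeResult(
        growth=float(v[obj_idx]),
        product_flux=dist.get(product_id) if product_id else 0.0,
        substrate_uptake=_uptake_magnitude(model, dist, substrate) if substrate else 0.0,
        method="lmoma",
        distribution=dist,
        l1_distance=float(res.fun),
    )


def fva(
    model: MetabolicModel,
    env: Environment | None = None,
    reactions: Sequence[str] | None = None,
    objective_fraction: float | None = 1.0,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis.

    For each listed reaction (default: all), minimize and maximize its flux
    with the objective constrained to at least ``objective_fraction`` of its
    optimum.  ``objective_fraction=None`` drops the objective constraint and
    explores the whole feasible region (used for blocked-reaction detection).
    """
    env = env or Environment()
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    bounds = env.bounds_for(model)
    rids = list(reactions) if reactions is not None else model.reaction_ids
    index = {rid: i for i, rid in enumerate(model.reaction_ids)}

    A_ub = None
    b_ub = None
    if objective_fraction is not None:
        base = fba(model, env)
        if base.status != "optimal":
            raise SolverError(
                f"FVA base problem is {base.status} on model {model.id!r}"
            )
        floor = objective_fraction * base.objective_value
        floor -= OBJECTIVE_FIX_TOL * max(1.0, abs(floor))
        row = np.zeros(n)
        row[index[model.objective_reaction]] = -1.0
        A_ub, b_ub = row[None, :], np.array([-floor])

    out: dict[str, tuple[float, float]] = {}
    b_eq = np.zeros(S.shape[0])
    for rid in rids:
        j = index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo = _solve(c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=b_eq, bounds=bounds)
        hi = _solve(-c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=b_eq, bounds=bounds)
        if _STATUS[lo.status] != "optimal" or _STATUS[hi.status] != "optimal":
            raise SolverError(f"FVA subproblem failed for reaction {rid!r}")
        vmin, vmax = float(lo.fun), float(-hi.fun)
        if vmin > vmax:  # solver noise on degenerate problems
            vmin = vmax = 0.5 * (vmin + vmax)
        out[rid] = (vmin, vmax)
    return out


def simulate_knockout(
    model: MetabolicModel,
    env: Environment | None = None,
    genes: Iterable[str] = (),
    method: str = "pfba",
    reference: FluxDistribution | None = None,
    product_id: str | None = None,
    substrate_id: str | None = None,
) -> PhenotypeResult:
    """Simulate a gene-deletion mutant with pFBA or lMOMA.

    For lMOMA the reference defaults to the pFBA distribution of the
    unmodified model, a documented package choice.
    """
    env = env or Environment()
    mutant = apply_gene_deletions(model, genes)
    if method == "pfba":
        return pfba(mutant, env, product_id=product_id, substrate_id=substrate_id)
    if method == "lmoma":
        if reference is None:
            reference = pfba(model, env).distribution
        return lmoma(
            mutant, env, reference, product_id=product_id, substrate_id=substrate_id
        )
    raise ChassiscraftError(f"unknown simulation method {method!r}")
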