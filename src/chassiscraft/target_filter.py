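"""Knockout-candidate selection.

Reduces the full reaction list of a model to the admissible deletion targets
for the strain-design optimizer by screening out:

* essential / nearly essential reactions — closing them drops the flux
  balance optimum below a fraction (default 1%) of wild-type growth;
* reactions without any gene association (spontaneous or unannotated) —
  they cannot be implemented as gene knockouts;
* boundary drains and inter-compartment transport reactions;
* blocked reactions — unable to carry any flux under the environment;
* fully coupled reaction groups (co-sets) — collapsed to one representative,
  since knocking out any member has the same effect.

Every excluded reaction is recorded in a ledger with a single reason tag.
When a reaction matches several screens the recorded reason follows a fixed
priority — drain_or_transport, then non_gene, then essential, then blocked —
so that structural reasons outrank phenotype-derived ones; the exclusion
itself happens regardless of the label.  Coupled-group members other than
the representative carry ``coupled_duplicate``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model_core import ChassiscraftError, MetabolicModel
from .phenotype import Environment, FLUX_TOL, fba, fva

logger = logging.getLogger("chassiscraft")

#: FVA magnitude below which a reaction counts as unable to carry flux
BLOCKED_TOL = 1e-9

EXCLUSION_REASONS = (
    "essential",
    "non_gene",
    "blocked",
    "drain_or_transport",
    "coupled_duplicate",
)


@dataclass
class FilterConfig:
    """Tunables of the candidate screens.

    ``essential_threshold`` is the wild-type growth fraction below which a
    single-reaction closure marks the reaction (nearly) essential.
    ``exclude_transport`` applies the drain/transport screen categorically;
    set False to exclude transporters only when blocked.  ``kind_overrides``
    force a reaction's exchange/transport/internal classification where a
    model's annotations defeat the structural heuristic.
    """

    essential_threshold: float = 0.01
    exclude_transport: bool = True
    kind_overrides: dict[str, str] = field(default_factory=dict)


@dataclass
class CandidateSet:
    """Outcome of the screens: candidates, exclusion ledger, co-sets."""

    candidates: list[str]
    exclusions: dict[str, str]  # reaction id -> reason tag
    coupled_groups: list[frozenset[str]]

    def reason(self, rid: str) -> str | None:
        return self.exclusions.get(rid)


def find_essential_reactions(
    model: MetabolicModel,
    env: Environment | None = None,
    threshold_fraction: float = 0.01,
) -> set[str]:
    """Reactions whose closure drops growth below a fraction of wild-type."""
    env = env or Environment()
    wildtype = fba(model, env)
    if wildtype.status != "optimal" or wildtype.objective_value <= FLUX_TOL:
        raise ChassiscraftError(
            f"model {model.id!r} cannot grow under this environment"
        )
    cutoff = threshold_fraction * wildtype.objective_value
    essential: set[str] = set()
    for rxn in model.reactions:
        closed = model.copy()
        target = closed.reaction(rxn.id)
        target.lower_bound = 0.0
        target.upper_bound = 0.0
        result = fba(closed, env)
        growth = result.objective_value if result.status == "optimal" else 0.0
        if growth < cutoff:
            essential.add(rxn.id)
    return essential


def find_blocked_reactions(
    model: MetabolicModel, env: Environment | None = None
) -> set[str]:
    """Reactions unable to carry flux anywhere in the feasible region."""
    env = env or Environment()
    ranges = fva(model, env, objective_fraction=None)
    return {
        rid
        for rid, (vmin, vmax) in ranges.items()
        if abs(vmin) < BLOCKED_TOL and abs(vmax) < BLOCKED_TOL
    }


def find_coupled_sets(
    model: MetabolicModel,
    env: Environment | None = None,
    candidates: list[str] | None = None,
) -> list[frozenset[str]]:
    """Partition candidates into fully coupled groups.

    Two reactions are fully coupled iff forcing either to zero forces the
    other to zero; the test runs FVA on the remaining candidates with one
    reaction's bounds fixed at zero, in both directions, and groups are the
    transitive closure of the pairwise relation.  O(n) FVA sweeps / O(n^2)
    LPs — deterministic and acceptable at both toy and genome scale.
    """
    env = env or Environment()
    candidates = list(candidates) if candidates is not None else model.reaction_ids
    forced: dict[str, set[str]] = {}
    for rid in candidates:
        closed = model.copy()
        target = closed.reaction(rid)
        target.lower_bound = 0.0
        target.upper_bound = 0.0
        others = [c for c in candidates if c != rid]
        ranges = fva(closed, env, reactions=others, objective_fraction=None)
        forced[rid] = {
            other
            for other, (vmin, vmax) in ranges.items()
            if abs(vmin) < BLOCKED_TOL and abs(vmax) < BLOCKED_TOL
        }
    # union-find over mutually forcing pairs
    parent = {rid: rid for rid in candidates}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in candidates:
        for b in forced[a]:
            if a in forced.get(b, ()):
                parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for rid in candidates:
        groups.setdefault(find(rid), set()).add(rid)
    return sorted(
        (frozenset(g) for g in groups.values()), key=lambda g: min(g)
    )


def _is_drain_or_transport(
    model: MetabolicModel, rid: str, config: FilterConfig
) -> bool:
    """Categorical drain/transport screen.

    A drain is an exchange that can only remove mass from the system (its
    bounds admit no uptake direction); the objective reaction is exempt, as
    are source exchanges that feed the network.  Transport reactions are
    excluded categorically when ``exclude_transport`` is set.
    """
    if rid == model.objective_reaction:
        return False
    kind = config.kind_overrides.get(rid) or model.reaction_kind(rid)
    if kind == "transport":
        return config.exclude_transport
    if kind != "exchange":
        return False
    rxn = model.reaction(rid)
    coef = next(iter(rxn.stoichiometry.values()))
    if coef < 0:  # met -> ∅ : outgoing unless lower bound admits uptake
        return rxn.lower_bound >= -BLOCKED_TOL
    return rxn.upper_bound <= BLOCKED_TOL  # ∅ -> met used in reverse only


def select_candidates(
    model: MetabolicModel,
    env: Environment | None = None,
    config: FilterConfig | None = None,
) -> CandidateSet:
    """Run all screens and return the admissible knockout targets."""
    env = env or Environment()
    config = config or FilterConfig()

    essential = find_essential_reactions(model, env, config.essential_threshold)
    non_gene = {r.id for r in model.reactions if r.gpr is None}
    drains = {
        r.id for r in model.reactions if _is_drain_or_transport(model, r.id, config)
    }
    blocked = find_blocked_reactions(model, env)

    exclusions: dict[str, str] = {}
    survivors: list[str] = []
    for rxn in model.reactions:
        rid = rxn.id
        if rid in drains:
            exclusions[rid] = "drain_or_transport"
        elif rid in non_gene:
            exclusions[rid] = "non_gene"
        elif rid in essential:
            exclusions[rid] = "essential"
        elif rid in blocked:
            exclusions[rid] = "blocked"
        else:
            survivors.append(rid)

    groups = find_coupled_sets(model, env, survivors) if survivors else []
    candidates: list[str] = []
    for group in groups:
        representative = min(group)  # lexicographically smallest id
        candidates.append(representative)
        for member in sorted(group - {representative}):
            exclusions[member] = "coupled_duplicate"
    candidates = [rid for rid in model.reaction_ids if rid in set(candidates)]
    if not candidates:
        logger.warning(
            "candidate screen on model %r left no admissible targets", model.id
        )
    return CandidateSet(
        candidates=candidates, exclusions=exclusions, coupled_groups=groups
    )
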