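"""Chassis analysis: cross-product gene frequencies, gscore and cscore.

Given a merged knockout-solution set per target product, this stage

1. computes, per gene and target, the fraction of that target's solutions
   whose gene-deletion set contains the gene (the frequency matrix);
2. hierarchically clusters gene rows and target columns (Euclidean
   distance, complete linkage) after dropping rows whose maximum frequency
   is below a threshold (default 20%) — the linkage and leaf orders are
   exported, drawing the heat map itself is presentation;
3. scores each gene: gscore(g) = (sum of its frequencies over targets) x
   (number of targets where its frequency is positive), promoting genes
   recurring across products;
4. enumerates candidate chassis as all gene-set combinations (up to a size
   cap, default 5) of the top-scoring genes (default top 30%, boundary ties
   included);
5. scores each chassis over the solutions that contain it and pass a
   carbon-yield filter (>= 95% of the best identified CYIELD for the
   target): cscore(c) = sum over targets of max CYIELD / min COST within
   the group, and ranks chassis by descending cscore.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .knockout_optimizer import KnockoutSolution, SolutionSet
from .model_core import ChassiscraftError

logger = logging.getLogger("chassiscraft")


@dataclass
class ClusterResult:
    """Agglomerative clustering of the frequency matrix."""

    row_labels: list[str]
    col_labels: list[str]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list[str]
    col_order: list[str]


@dataclass
class ChassisCandidate:
    genes: frozenset[str]
    cscore: float
    targets_covered: int
    per_target: dict[str, dict]  # target -> {n, max_cyield, min_cost, best}


@dataclass
class ChassisReport:
    ranked: list[ChassisCandidate]
    gscores: dict[str, float]
    frequencies: pd.DataFrame
    clustering: ClusterResult | None
    parameters: dict = field(default_factory=dict)


def gene_frequencies(
    solution_sets: Mapping[str, SolutionSet] | Mapping[str, Sequence[KnockoutSolution]],
) -> pd.DataFrame:
    """Gene x target frequency matrix.

    freq(g, t) = (# solutions of target t containing gene g) / (# solutions
    of t).  Genes appearing in no solution of any target are omitted; rows
    are sorted lexicographically, columns follow the mapping order.
    """
    targets = list(solution_sets)
    per_target_sols: dict[str, list[KnockoutSolution]] = {}
    for target in targets:
        entry = solution_sets[target]
        sols = list(entry.solutions if isinstance(entry, SolutionSet) else entry)
        if not sols:
            raise ChassiscraftError(
                f"target {target!r} has an empty solution set"
            )
        per_target_sols[target] = sols
    genes = sorted(
        {
            gene
            for sols in per_target_sols.values()
            for sol in sols
            for gene in sol.gene_deletions
        }
    )
    data = np.zeros((len(genes), len(targets)))
    for j, target in enumerate(targets):
        sols = per_target_sols[target]
        for i, gene in enumerate(genes):
            data[i, j] = sum(
                1 for sol in sols if gene in sol.gene_deletions
            ) / len(sols)
    return pd.DataFrame(data, index=genes, columns=targets)


def cluster_frequencies(
    matrix: pd.DataFrame, min_freq: float = 0.20
) -> ClusterResult:
    """Complete-linkage Euclidean clustering of gene rows and target columns.

    Rows whose maximum frequency is below ``min_freq`` are dropped before
    clustering.  Rows are pre-sorted lexicographically so the leaf order is
    invariant to the input row order.  With fewer than two rows (or
    columns) the corresponding linkage degenerates to the identity order.
    """
    kept = matrix.loc[matrix.max(axis=1) >= min_freq].sort_index()
    row_labels = list(kept.index)
    col_labels = list(kept.columns)
    row_linkage = col_linkage = None
    row_order, col_order = row_labels, col_labels
    if len(row_labels) >= 2:
        row_linkage = linkage(pdist(kept.values, metric="euclidean"), method="complete")
        row_order = [row_labels[i] for i in leaves_list(row_linkage)]
    else:
        logger.warning("fewer than 2 gene rows after the %.0f%% filter", 100 * min_freq)
    if len(col_labels) >= 2 and len(row_labels) >= 1:
        col_linkage = linkage(
            pdist(kept.values.T, metric="euclidean"), method="complete"
        )
        col_order = [col_labels[i] for i in leaves_list(col_linkage)]
    return ClusterResult(
        row_labels=row_labels,
        col_labels=col_labels,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
        row_order=row_order,
        col_order=col_order,
    )


def gene_score(matrix: pd.DataFrame) -> dict[str, float]:
    """gscore(g) = (Σ_t freq(g,t)) × #{t : freq(g,t) > 0}."""
    scores = {}
    for gene, row in matrix.iterrows():
        total = float(row.sum())
        present = int((row > 0).sum())
        scores[gene] = total * present
    return scores


def enumerate_chassis(
    gscores: Mapping[str, float],
    top_fraction: float = 0.30,
    max_size: int = 5,
) -> list[frozenset[str]]:
    """All gene-set combinations (size <= max_size) of the top-scoring genes.

    The cut keeps ceil(top_fraction x #genes) genes by descending gscore;
    genes tied with the score at the boundary are all included, so the
    outcome does not depend on tie order.
    """
    if not gscores:
        return []
    ordered = sorted(gscores.items(), key=lambda kv: (-kv[1], kv[0]))
    cut = math.ceil(top_fraction * len(ordered))
    cut = max(cut, 1)
    threshold = ordered[cut - 1][1]
    top = [g for g, s in ordered if s > threshold or math.isclose(s, threshold)]
    out: list[frozenset[str]] = []
    for size in range(1, min(max_size, len(top)) + 1):
        for combo in combinations(sorted(top), size):
            out.append(frozenset(combo))
    return out


def chassis_score(
    chassis: frozenset[str],
    solution_sets: Mapping[str, SolutionSet],
    cyield_fraction: float = 0.95,
) -> ChassisCandidate:
    """Score one chassis over all targets.

    Per target, the eligible group S contains the solutions whose gene set
    includes the chassis and whose CYIELD is at least ``cyield_fraction`` of
    the best CYIELD identified in that target's merged set.  The target
    contributes max(CYIELD of S) / min(COST of S); an empty group
    contributes 0.
    """
    total = 0.0
    covered = 0
    per_target: dict[str, dict] = {}
    for target, sset in solution_sets.items():
        sols = sset.solutions if isinstance(sset, SolutionSet) else list(sset)
        if not sols:
            continue
        max_identified = max(s.metrics.cyield for s in sols)
        group = [
            s
            for s in sols
            if chassis <= s.gene_deletions
            and s.metrics.cyield >= cyield_fraction * max_identified
        ]
        if not group:
            per_target[target] = {"n": 0}
            continue
        best_cyield = max(s.metrics.cyield for s in group)
        min_cost = min(s.metrics.cost for s in group)
        best = max(group, key=lambda s: (s.metrics.cyield, -s.metrics.cost))
        total += best_cyield / min_cost
        covered += 1
        per_target[target] = {
            "n": len(group),
            "max_cyield": best_cyield,
            "min_cost": min_cost,
            "best": best,
        }
    return ChassisCandidate(
        genes=chassis, cscore=total, targets_covered=covered, per_target=per_target
    )


def rank_chassis(
    candidates: Sequence[ChassisCandidate],
    gscores: Mapping[str, float] | None = None,
    frequencies: pd.DataFrame | None = None,
    clustering: ClusterResult | None = None,
    parameters: Mapping | None = None,
) -> ChassisReport:
    """Sort chassis by descending cscore (ties: fewer genes, then lexical)."""
    ranked = sorted(
        candidates,
        key=lambda c: (-c.cscore, len(c.genes), tuple(sorted(c.genes))),
    )
    return ChassisReport(
        ranked=ranked,
        gscores=dict(gscores or {}),
        frequencies=(
            frequencies if frequencies is not None else pd.DataFrame()
        ),
        clustering=clustering,
        parameters=dict(parameters or {}),
    )


def analyze_chassis(
    solution_sets: Mapping[str, SolutionSet],
    min_freq: float = 0.20,
    top_fraction: float = 0.30,
    max_size: int = 5,
    cyield_fraction: float = 0.95,
    cluster: bool = True,
) -> ChassisReport:
    """Full chassis-analysis stage over merged per-target solution sets.

    The frequency filter (``min_freq``) applies to the displayed clustering
    only; gscore is computed on the unfiltered matrix.
    """
    matrix = gene_frequencies(solution_sets)
    clustering = cluster_frequencies(matrix, min_freq) if cluster else None
    gscores = gene_score(matrix)
    chassis_list = enumerate_chassis(gscores, top_fraction, max_size)
    candidates = [
        chassis_score(c, solution_sets, cyield_fraction) for c in chassis_list
    ]
    return rank_chassis(
        candidates,
        gscores=gscores,
        frequencies=matrix,
        clustering=clustering,
        parameters={
            "min_freq": min_freq,
            "top_fraction": top_fraction,
            "max_size": max_size,
            "cyield_fraction": cyield_fraction,
        },
    )
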