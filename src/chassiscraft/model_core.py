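"""Data model for constraint-based metabolic networks.

Defines the in-memory representation used throughout the package — reactions
with flux bounds and gene-protein-reaction (GPR) rules, metabolites with
carbon counts, and the model container — plus model I/O (a versioned JSON
dialect and SBML Level 3 with the fbc package), model patching, and seeded
toy-model fixtures that emulate a branched network in which a single gene
knockout growth-couples product secretion.

Sign conventions
----------------
Boundary (exchange) reactions touch exactly one metabolite.  A drain written
``met -> ∅`` carries positive flux for secretion and negative flux for
uptake; a source written ``∅ -> met`` carries positive flux for uptake.
Both forms are supported and uptake magnitudes are always reported as
non-negative numbers.
"""

from __future__ import annotations

import copy
import json
import logging

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("chassiscraft")

#: schema tag written into (and required from) JSON model files
JSON_SCHEMA = "chassiscraft-model-1"

#: default large bound used where a fixture needs an effectively open flux
BIG = 1000.0


class ChassiscraftError(Exception):
    """Base class for all package errors."""


class ModelFormatError(ChassiscraftError):
    """A model file could not be parsed or violates the format contract."""


class ModelValidationError(ChassiscraftError):
    """A model object violates a structural invariant."""


class UnknownGeneError(ChassiscraftError):
    """An operation referenced a gene id absent from the model."""


class UnknownCarbonError(ChassiscraftError):
    """Carbon content of a metabolite could not be determined."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class GprRule:
    """Boolean expression over gene ids with AND/OR nodes.

    The expression is stored as a nested tuple tree: a leaf is a gene id
    string; an internal node is ``("and", children)`` or ``("or", children)``
    with two or more children.
    """

    __slots__ = ("expr",)

    def __init__(self, expr):
        self.expr = expr

    # -- parsing ----------------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "GprRule | None":
        """Parse a GPR string (case-insensitive and/or, parentheses).

        Returns ``None`` for an empty/blank rule.
        """
        tokens = _GPR_TOKEN.findall(text or "")
        if not tokens:
            return None
        pos = 0

        def peek():
            return tokens[pos] if pos < len(tokens) else None

        def parse_or():
            nonlocal pos
            terms = [parse_and()]
            while peek() is not None and peek().lower() == "or":
                pos += 1
                terms.append(parse_and())
            return terms[0] if len(terms) == 1 else ("or", tuple(terms))

        def parse_and():
            nonlocal pos
            terms = [parse_atom()]
            while peek() is not None and peek().lower() == "and":
                pos += 1
                terms.append(parse_atom())
            return terms[0] if len(terms) == 1 else ("and", tuple(terms))

        def parse_atom():
            nonlocal pos
            tok = peek()
            if tok is None:
                raise ModelFormatError("unexpected end of GPR expression")
            if tok == "(":
                pos += 1
                inner = parse_or()
                if peek() != ")":
                    raise ModelFormatError("unbalanced parenthesis in GPR")
                pos += 1
                return inner
            if tok == ")" or tok.lower() in ("and", "or"):
                raise ModelFormatError(f"unexpected token {tok!r} in GPR")
            pos += 1
            return tok

        expr = parse_or()
        if pos != len(tokens):
            raise ModelFormatError(
                f"trailing tokens in GPR expression: {tokens[pos:]}"
            )
        return cls(expr)

    # -- queries ----------------------------------------------------------
    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node):
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        walk(self.expr)
        return frozenset(out)

    def evaluate(self, deleted: Iterable[str]) -> bool:
        """Truth value with ``deleted`` genes false and all others true."""
        deleted = set(deleted)

        def walk(node):
            if isinstance(node, str):
                return node not in deleted
            op, children = node
            if op == "and":
                return all(walk(c) for c in children)
            return any(walk(c) for c in children)

        return walk(self.expr)

    def minimal_knockout_sets(self) -> list[frozenset[str]]:
        """Minimal gene sets whose deletion falsifies the rule.

        These are the minimal hitting sets over the rule's DNF terms, found
        here by subset enumeration over the rule's genes (rules in curated
        models are small).
        """
        genes = sorted(self.genes())
        found: list[frozenset[str]] = []
        for size in range(1, len(genes) + 1):
            for combo in combinations(genes, size):
                cand = frozenset(combo)
                if any(prev <= cand for prev in found):
                    continue
                if not self.evaluate(cand):
                    found.append(cand)
        return sorted(found, key=lambda s: (len(s), tuple(sorted(s))))

    def to_string(self) -> str:
        def walk(node, parent=None):
            if isinstance(node, str):
                return node
            op, children = node
            joined = f" {op} ".join(walk(c, op) for c in children)
            if parent is not None and parent != op:
                return f"({joined})"
            return joined

        return walk(self.expr)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"GprRule({self.to_string()!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, GprRule) and self.expr == other.expr

    def __hash__(self) -> int:
        return hash(self.expr)


def evaluate_gpr(rule: GprRule | None, deleted: Iterable[str]) -> bool:
    """Evaluate a GPR rule under a gene deletion set.

    An empty rule (``None``) returns True: the reaction has no gene
    association and cannot be silenced by gene deletions.
    """
    if rule is None:
        return True
    return rule.evaluate(deleted)


# ---------------------------------------------------------------------------
# Metabolites and reactions
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def carbon_atoms_from_formula(formula: str) -> int:
    """Count C atoms in a chemical formula string.

    Element parsing distinguishes C from Cl/Ca/Cu etc.  Formulas containing
    polymeric/undefined residues ("X", "R", "*") raise
    :class:`UnknownCarbonError`.
    """
    if not formula:
        raise UnknownCarbonError("empty formula")
    if any(ch in formula for ch in "XR*"):
        raise UnknownCarbonError(f"formula {formula!r} has undefined residues")
    consumed = 0
    count = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != consumed:
            raise UnknownCarbonError(f"unparsable formula {formula!r}")
        consumed = match.end()
        element, digits = match.groups()
        if element == "C":
            count += int(digits) if digits else 1
    if consumed != len(formula):
        raise UnknownCarbonError(f"unparsable formula {formula!r}")
    return count


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    carbon: int | None = None  # explicit count overrides formula parsing

    def base_id(self) -> str:
        """Metabolite id with a trailing compartment tag stripped."""
        if self.compartment and self.id.endswith(f"_{self.compartment}"):
            return self.id[: -(len(self.compartment) + 1)]
        return re.sub(r"\[[a-zA-Z0-9]+\]$", "", self.id)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -BIG
    upper_bound: float = BIG
    gpr: GprRule | None = None
    name: str = ""
    kind_override: str | None = None  # internal | exchange | transport

    def genes(self) -> frozenset[str]:
        return self.gpr.genes() if self.gpr is not None else frozenset()

    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1


@dataclass
class MetabolicModel:
    """Stoichiometry, bounds, GPR rules, carbon counts and objective."""

    id: str
    reactions: list[Reaction]
    metabolites: list[Metabolite]
    objective_reaction: str
    genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not isinstance(self.genes, frozenset):
            self.genes = frozenset(self.genes)

    # -- lookups ----------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id!r}")

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"no metabolite {mid!r} in model {self.id!r}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- derived structure -------------------------------------------------
    def reaction_kind(self, rid: str) -> str:
        """Classify a reaction as exchange / transport / internal.

        Heuristic (overridable per reaction via ``kind_override``): a
        reaction touching a single metabolite is an exchange; a reaction
        moving the same base metabolite between two compartments is a
        transport; everything else is internal.
        """
        rxn = self.reaction(rid)
        if rxn.kind_override is not None:
            return rxn.kind_override
        if rxn.is_exchange():
            return "exchange"
        mets = [self.metabolite(m) for m in rxn.stoichiometry]
        by_base: dict[str, set[str]] = {}
        for met in mets:
            by_base.setdefault(met.base_id(), set()).add(met.compartment)
        if any(len(comps) > 1 for comps in by_base.values()):
            return "transport"
        return "internal"

    def exchange_for_metabolite(self, mid: str) -> str | None:
        """Id of the exchange reaction touching a metabolite, if any."""
        for rxn in self.reactions:
            if rxn.is_exchange() and mid in rxn.stoichiometry:
                return rxn.id
        return None

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S matrix, metabolites x reactions, in model order."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                S[met_index[mid], j] = coef
        return S

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any broken invariant."""
        met_ids = set(self.metabolite_ids)
        if len(met_ids) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            missing = set(rxn.stoichiometry) - met_ids
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolites "
                    f"{sorted(missing)}"
                )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} has lower_bound > upper_bound"
                )
            stray = rxn.genes() - self.genes
            if stray:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} GPR references unknown genes "
                    f"{sorted(stray)}"
                )
        if not self.objective_reaction:
            raise ModelValidationError("model has no objective reaction")
        if self.objective_reaction not in seen:
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )


def carbon_content(
    model: MetabolicModel,
    metabolite_id: str,
    carbon_map: Mapping[str, int] | None = None,
) -> int:
    """Carbon atoms of a metabolite.

    Resolution order: caller-supplied ``carbon_map``, explicit metadata on
    the metabolite, then the count of C atoms parsed from its formula.
    """
    if carbon_map is not None and metabolite_id in carbon_map:
        return int(carbon_map[metabolite_id])
    met = model.metabolite(metabolite_id)
    if met.carbon is not None:
        return int(met.carbon)
    if met.formula:
        return carbon_atoms_from_formula(met.formula)
    raise UnknownCarbonError(
        f"unknown carbon content for {metabolite_id!r}: no metadata and no "
        "formula; supply a carbon map"
    )


# ---------------------------------------------------------------------------
# Gene deletions
# ---------------------------------------------------------------------------

def apply_gene_deletions(
    model: MetabolicModel, genes: Iterable[str]
) -> MetabolicModel:
    """Copy of the model with GPR-silenced reactions closed to [0, 0]."""
    genes = set(genes)
    unknown = genes - set(model.genes)
    if unknown:
        raise UnknownGeneError(
            f"unknown gene id(s): {sorted(unknown)}"
        )
    out = model.copy()
    for rxn in out.reactions:
        if rxn.gpr is not None and not rxn.gpr.evaluate(genes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def reactions_silenced_by(
    model: MetabolicModel, genes: Iterable[str]
) -> frozenset[str]:
    """Reaction ids whose GPR evaluates false under the deletion set."""
    genes = set(genes)
    return frozenset(
        r.id
        for r in model.reactions
        if r.gpr is not None and not r.gpr.evaluate(genes)
    )


# ---------------------------------------------------------------------------
# Model patching
# ---------------------------------------------------------------------------

@dataclass
class ModelEdit:
    """A single serializable model modification.

    ``operation`` is one of ``add_reaction``, ``remove_reaction``,
    ``set_bounds`` and ``set_reversibility``; ``payload`` carries the
    matching data.  Edit lists round-trip through plain dicts so that
    model-specific patch sets can live in YAML/JSON config files.
    """

    operation: str
    payload: dict

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelEdit":
        data = dict(data)
        op = data.pop("operation", None)
        if op is None:
            raise ModelFormatError("model edit missing 'operation'")
        payload = data.pop("payload", data)
        return cls(operation=op, payload=dict(payload))

    def to_dict(self) -> dict:
        return {"operation": self.operation, "payload": dict(self.payload)}


def _reaction_from_dict(data: Mapping) -> Reaction:
    gpr_text = data.get("gpr") or ""
    return Reaction(
        id=data["id"],
        name=data.get("name", ""),
        stoichiometry={k: float(v) for k, v in data["stoichiometry"].items()},
        lower_bound=float(data.get("lower_bound", -BIG)),
        upper_bound=float(data.get("upper_bound", BIG)),
        gpr=GprRule.parse(gpr_text),
        kind_override=data.get("kind"),
    )


def patch_model(
    model: MetabolicModel, edits: Sequence[ModelEdit | Mapping]
) -> MetabolicModel:
    """Apply a list of edits in order; returns a validated new model."""
    out = model.copy()
    for index, edit in enumerate(edits):
        if not isinstance(edit, ModelEdit):
            edit = ModelEdit.from_dict(edit)
        try:
            _apply_edit(out, edit)
        except (KeyError, ModelFormatError, ModelValidationError) as exc:
            raise ModelValidationError(
                f"edit {index} ({edit.operation}) failed: {exc}"
            ) from exc
    out.validate()
    return out


def _apply_edit(model: MetabolicModel, edit: ModelEdit) -> None:
    payload = edit.payload
    if edit.operation == "add_reaction":
        rxn = _reaction_from_dict(payload)
        if model.has_reaction(rxn.id):
            raise ModelValidationError(f"reaction {rxn.id!r} already exists")
        # unseen metabolites may be declared inline
        known = set(model.metabolite_ids)
        for mid in rxn.stoichiometry:
            if mid not in known:
                meta = (payload.get("metabolites") or {}).get(mid, {})
                model.metabolites.append(
                    Metabolite(
                        id=mid,
                        name=meta.get("name", ""),
                        compartment=meta.get("compartment", ""),
                        formula=meta.get("formula"),
                        carbon=meta.get("carbon"),
                    )
                )
        model.reactions.append(rxn)
        model.genes = frozenset(model.genes | rxn.genes())
    elif edit.operation == "remove_reaction":
        rid = payload["id"]
        model.reaction(rid)  # raises KeyError if absent
        model.reactions = [r for r in model.reactions if r.id != rid]
    elif edit.operation == "set_bounds":
        rxn = model.reaction(payload["id"])
        if "lower_bound" in payload:
            rxn.lower_bound = float(payload["lower_bound"])
        if "upper_bound" in payload:
            rxn.upper_bound = float(payload["upper_bound"])
    elif edit.operation == "set_reversibility":
        rxn = model.reaction(payload["id"])
        if bool(payload["reversible"]):
            if rxn.lower_bound >= 0:
                rxn.lower_bound = -abs(rxn.upper_bound) if rxn.upper_bound else -BIG
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    else:
        raise ModelFormatError(f"unknown edit operation {edit.operation!r}")


# ---------------------------------------------------------------------------
# JSON dialect I/O
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema": JSON_SCHEMA,
        "id": model.id,
        "objective": model.objective_reaction,
        "genes": sorted(model.genes),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "carbon": m.carbon,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string() if r.gpr is not None else "",
                "kind": r.kind_override,
            }
            for r in model.reactions
        ],
    }


def model_from_dict(data: Mapping) -> MetabolicModel:
    if data.get("schema") != JSON_SCHEMA:
        raise ModelFormatError(
            f"unsupported model schema {data.get('schema')!r}; "
            f"expected {JSON_SCHEMA!r}"
        )
    objective = data.get("objective")
    if not objective:
        raise ModelFormatError("no objective reaction declared in model file")
    try:
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", ""),
                formula=m.get("formula"),
                carbon=m.get("carbon"),
            )
            for m in data.get("metabolites", [])
        ]
        reactions = [_reaction_from_dict(r) for r in data.get("reactions", [])]
    except KeyError as exc:
        raise ModelFormatError(f"model element missing field {exc}") from exc
    genes = set(data.get("genes", []))
    for rxn in reactions:
        genes |= rxn.genes()
    model = MetabolicModel(
        id=data.get("id", "model"),
        reactions=reactions,
        metabolites=metabolites,
        objective_reaction=objective,
        genes=frozenset(genes),
    )
    model.validate()
    return model


def read_model(path, format: str | None = None) -> MetabolicModel:
    """Read a model from SBML L3 (fbc) or the package JSON dialect.

    ``format`` is inferred from the file suffix when not given
    (``.xml``/``.sbml`` -> sbml, ``.json`` -> json).
    """
    path = str(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"invalid JSON in {path}: {exc}") from exc
        model = model_from_dict(data)
    elif format == "sbml":
        model = _read_sbml(path)
    else:
        raise ModelFormatError(f"unknown model format {format!r}")
    model.validate()
    return model


def write_model(model: MetabolicModel, path, format: str | None = None) -> None:
    path = str(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ModelFormatError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# SBML L3 + fbc I/O (via libsbml)
# ---------------------------------------------------------------------------

def _read_sbml(path: str) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(
            f"SBML parse error in {path}: {err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"no model element in {path}")
    fbc = sbml_model.getPlugin("fbc")

    metabolites = []
    boundary = set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        formula = None
        carbon = None
        sfbc = sp.getPlugin("fbc")
        if sfbc is not None and sfbc.isSetChemicalFormula():
            formula = sfbc.getChemicalFormula()
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "",
                formula=formula,
                carbon=carbon,
            )
        )

    genes = set()
    label_by_gp = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            label_by_gp[gp.getId()] = label
            genes.add(label)

    def assoc_to_expr(assoc):
        import libsbml as _ls

        if isinstance(assoc, _ls.GeneProductRef):
            return label_by_gp.get(assoc.getGeneProduct(), assoc.getGeneProduct())
        if isinstance(assoc, _ls.FbcAnd):
            return (
                "and",
                tuple(
                    assoc_to_expr(assoc.getAssociation(i))
                    for i in range(assoc.getNumAssociations())
                ),
            )
        if isinstance(assoc, _ls.FbcOr):
            return (
                "or",
                tuple(
                    assoc_to_expr(assoc.getAssociation(i))
                    for i in range(assoc.getNumAssociations())
                ),
            )
        raise ModelFormatError(f"unsupported GPR association node {assoc!r}")

    def bound_value(rxn_fbc, getter, default):
        if rxn_fbc is None or getter is None:
            return default
        pid = getter()
        if not pid:
            return default
        param = sbml_model.getParameter(pid)
        if param is None:
            raise ModelFormatError(f"flux bound parameter {pid!r} missing")
        return param.getValue()

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rxn_fbc = rxn.getPlugin("fbc")
        rev_default = -BIG if rxn.getReversible() else 0.0
        lb = bound_value(rxn_fbc, rxn_fbc.getLowerFluxBound if rxn_fbc else None, rev_default)
        ub = bound_value(rxn_fbc, rxn_fbc.getUpperFluxBound if rxn_fbc else None, BIG)
        if lb > ub:
            raise ModelFormatError(
                f"reaction {rxn.getId()!r} has lower bound {lb} > upper bound {ub}"
            )
        gpr = None
        if rxn_fbc is not None and rxn_fbc.isSetGeneProductAssociation():
            expr = assoc_to_expr(
                rxn_fbc.getGeneProductAssociation().getAssociation()
            )
            gpr = GprRule(expr)
        reactions.append(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
            )
        )

    objective = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective = active.getFluxObjective(0).getReaction()
    if objective is None:
        raise ModelFormatError(
            f"no objective: {path} declares no active fbc objective"
        )

    model = MetabolicModel(
        id=sbml_model.getId() or "model",
        reactions=reactions,
        metabolites=metabolites,
        objective_reaction=objective,
        genes=frozenset(genes),
    )
    model.validate()
    return model


def _write_sbml(model: MetabolicModel, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(re.sub(r"\W", "_", model.id) or "model")
    mfbc = sm.getPlugin("fbc")
    mfbc.setStrict(True)

    compartments = sorted({m.compartment or "c" for m in model.metabolites}) or ["c"]
    for cid in compartments:
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment or "c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)

    gp_id = {}
    for gene in sorted(model.genes):
        gp = mfbc.createGeneProduct()
        gid = "G_" + re.sub(r"\W", "_", gene)
        gp.setId(gid)
        gp.setLabel(gene)
        gp_id[gene] = gid

    bound_params = {}

    def param_for(value: float) -> str:
        key = float(value)
        if key not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sm.createParameter()
            param.setId(pid)
            param.setValue(key)
            param.setConstant(True)
            bound_params[key] = pid
        return bound_params[key]

    def expr_to_assoc(node, parent):
        if isinstance(node, str):
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(gp_id[node])
            return
        op, children = node
        child = parent.createAnd() if op == "and" else parent.createOr()
        for sub in children:
            expr_to_assoc(sub, child)

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId(rxn.id)
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for mid, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rfbc = sr.getPlugin("fbc")
        rfbc.setLowerFluxBound(param_for(rxn.lower_bound))
        rfbc.setUpperFluxBound(param_for(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = rfbc.createGeneProductAssociation()
            expr_to_assoc(rxn.gpr.expr, gpa)

    objective = mfbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fo = objective.createFluxObjective()
    fo.setReaction(model.objective_reaction)
    fo.setCoefficient(1.0)
    mfbc.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, path)


# ---------------------------------------------------------------------------
# Toy-model fixtures
# ---------------------------------------------------------------------------

TOY_VARIANTS = ("T1", "T2", "random")


def make_toy_model(variant: str = "T1", seed: int = 0) -> MetabolicModel:
    """Seeded toy-model fixtures.

    ``T1``
        Canonical deterministic 6-reaction branched network: a carbon source
        A feeds a biomass precursor C either directly (gene ``g2``) or via an
        intermediate B whose conversion co-produces the product P (genes
        ``g1``, ``g3``).  Deleting ``g2`` growth-couples P secretion.  Carbon
        counts: A = 6, P = 4 (metadata; the toy network is deliberately not
        elementally balanced).

    ``T2``
        Deterministic dual-product variant of T1 with a second branch
        ``A -> B2 -> C + Q`` (genes ``g4``, ``g5``) and a second product Q.
        Deleting ``g2`` plus one branch gene growth-couples the product of
        the other branch, so the two products share the coupling gene
        ``g2`` — the shape of a cross-product chassis.

    ``random``
        Seeded random branched network built on the T1 skeleton with extra
        product-co-producing chains ``A -> Di -> C + P`` and carbon-wasting
        side drains ``C -> Wj -> ∅``.  Deleting ``g2`` is a guaranteed
        growth-coupling knockout: every surviving route to biomass
        co-produces P.
    """
    if variant == "T1":
        return _toy_t1()
    if variant == "T2":
        return _toy_t2()
    if variant == "random":
        return _toy_random(seed)
    raise ChassiscraftError(
        f"unknown toy-model variant {variant!r}; available: {TOY_VARIANTS}"
    )


def _toy_t1() -> MetabolicModel:
    metabolites = [
        Metabolite("A", "precursor A", "c", carbon=6),
        Metabolite("B", "intermediate B", "c"),
        Metabolite("C", "biomass precursor C", "c"),
        Metabolite("P", "product P", "c", carbon=4),
    ]
    reactions = [
        Reaction("UP", {"A": 1.0}, 0.0, 10.0, name="carbon source"),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, BIG, GprRule.parse("g1")),
        Reaction("R2", {"A": -1.0, "C": 1.0}, 0.0, BIG, GprRule.parse("g2")),
        Reaction("R3", {"B": -1.0, "C": 1.0, "P": 1.0}, 0.0, BIG, GprRule.parse("g3")),
        Reaction("BIO", {"C": -1.0}, 0.0, BIG, name="biomass drain"),
        Reaction("EX_P", {"P": -1.0}, 0.0, BIG, name="product export"),
    ]
    model = MetabolicModel(
        id="T1",
        reactions=reactions,
        metabolites=metabolites,
        objective_reaction="BIO",
        genes=frozenset({"g1", "g2", "g3"}),
    )
    model.validate()
    return model


def _toy_t2() -> MetabolicModel:
    metabolites = [
        Metabolite("A", "precursor A", "c", carbon=6),
        Metabolite("B", "intermediate B", "c"),
        Metabolite("B2", "intermediate B2", "c"),
        Metabolite("C", "biomass precursor C", "c"),
        Metabolite("P", "product P", "c", carbon=4),
        Metabolite("Q", "product Q", "c", carbon=3),
    ]
    reactions = [
        Reaction("UP", {"A": 1.0}, 0.0, 10.0, name="carbon source"),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, BIG, GprRule.parse("g1")),
        Reaction("R2", {"A": -1.0, "C": 1.0}, 0.0, BIG, GprRule.parse("g2")),
        Reaction("R3", {"B": -1.0, "C": 1.0, "P": 1.0}, 0.0, BIG, GprRule.parse("g3")),
        Reaction("R4", {"A": -1.0, "B2": 1.0}, 0.0, BIG, GprRule.parse("g4")),
        Reaction("R5", {"B2": -1.0, "C": 1.0, "Q": 1.0}, 0.0, BIG, GprRule.parse("g5")),
        Reaction("BIO", {"C": -1.0}, 0.0, BIG, name="biomass drain"),
        Reaction("EX_P", {"P": -1.0}, 0.0, BIG, name="product P export"),
        Reaction("EX_Q", {"Q": -1.0}, 0.0, BIG, name="product Q export"),
    ]
    model = MetabolicModel(
        id="T2",
        reactions=reactions,
        metabolites=metabolites,
        objective_reaction="BIO",
        genes=frozenset({"g1", "g2", "g3", "g4", "g5"}),
    )
    model.validate()
    return model


def _toy_random(seed: int) -> MetabolicModel:
    rng = np.random.default_rng(seed)
    model = _toy_t1().copy()
    model.id = f"random-{seed}"
    genes = set(model.genes)
    n_chains = int(rng.integers(0, 3))
    for i in range(n_chains):
        mid = f"D{i + 1}"
        g_in, g_out = f"ga{i + 1}", f"gd{i + 1}"
        model.metabolites.append(Metabolite(mid, f"chain metabolite {mid}", "c"))
        model.reactions.append(
            Reaction(f"RA{i + 1}", {"A": -1.0, mid: 1.0}, 0.0, BIG, GprRule.parse(g_in))
        )
        model.reactions.append(
            Reaction(
                f"RD{i + 1}",
                {mid: -1.0, "C": 1.0, "P": 1.0},
                0.0,
                BIG,
                GprRule.parse(g_out),
            )
        )
        genes.update({g_in, g_out})
    n_waste = int(rng.integers(0, 3))
    for j in range(n_waste):
        mid = f"W{j + 1}"
        gene = f"gw{j + 1}"
        model.metabolites.append(Metabolite(mid, f"waste metabolite {mid}", "c"))
        model.reactions.append(
            Reaction(f"RW{j + 1}", {"C": -1.0, mid: 1.0}, 0.0, BIG, GprRule.parse(gene))
        )
        model.reactions.append(
            Reaction(f"EX_W{j + 1}", {mid: -1.0}, 0.0, BIG)
        )
        genes.add(gene)
    # jitter the substrate cap so models differ beyond topology
    model.reaction("UP").upper_bound = float(rng.integers(5, 15))
    model.genes = frozenset(genes)
    model.validate()
    return model
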