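"""Model container, GPR logic, I/O round-trips and patching."""

import itertools
import random

import pytest

from chassiscraft import (
    GprRule,
    Metabolite,
    MetabolicModel,
    ModelFormatError,
    ModelValidationError,
    Reaction,
    UnknownCarbonError,
    UnknownGeneError,
    apply_gene_deletions,
    carbon_atoms_from_formula,
    carbon_content,
    evaluate_gpr,
    fba,
    make_toy_model,
    model_from_dict,
    model_to_dict,
    patch_model,
    read_model,
    write_model,
)


class TestGprRule:
    @pytest.mark.parametrize(
        "text,deleted,expected",
        [
            ("g1 or g2", {"g1"}, True),  # isozyme survives
            ("g1 and g2", {"g1"}, False),  # complex broken
            ("(g1 and g2) or g3", {"g1", "g3"}, False),
            ("(g1 and g2) or g3", {"g3"}, True),
            ("g1 AND (g2 OR g3)", {"g2"}, True),
            ("g1 AND (g2 OR g3)", {"g2", "g3"}, False),
        ],
    )
    def test_evaluation(self, text, deleted, expected):
        assert evaluate_gpr(GprRule.parse(text), deleted) is expected

    def test_empty_rule_is_always_true(self):
        assert evaluate_gpr(None, {"g1"}) is True

    def test_parse_rejects_malformed(self):
        for bad in ["g1 or", "(g1 and g2", "and g1", "g1 g2 or"]:
            with pytest.raises(ModelFormatError):
                GprRule.parse(bad)

    def test_roundtrip_through_string(self):
        rule = GprRule.parse("(g1 and g2) or (g3 and (g4 or g5))")
        assert GprRule.parse(rule.to_string()) == rule

    def test_agreement_with_truth_table_enumeration(self):
        """Random rules of <= 6 genes checked over all 2^6 deletion subsets.

        The oracle evaluates the rule by direct recursion over python's
        and/or on a dict of gene states, independently of GprRule.
        """
        genes = [f"g{i}" for i in range(6)]
        rng = random.Random(20240917)

        def random_expr(depth):
            if depth == 0 or rng.random() < 0.4:
                return rng.choice(genes)
            op = rng.choice(["and", "or"])
            return (op, tuple(random_expr(depth - 1) for _ in range(rng.randint(2, 3))))

        def oracle(expr, state):
            if isinstance(expr, str):
                return state[expr]
            op, children = expr
            results = [oracle(c, state) for c in children]
            return all(results) if op == "and" else any(results)

        for _ in range(25):
            expr = random_expr(3)
            rule = GprRule(expr)
            for bits in itertools.product([True, False], repeat=6):
                state = dict(zip(genes, bits))
                deleted = {g for g, alive in state.items() if not alive}
                assert rule.evaluate(deleted) == oracle(expr, state)

    def test_minimal_knockout_sets(self):
        assert GprRule.parse("g1 or g2").minimal_knockout_sets() == [
            frozenset({"g1", "g2"})
        ]
        assert GprRule.parse("g1 and g2").minimal_knockout_sets() == [
            frozenset({"g1"}),
            frozenset({"g2"}),
        ]
        # (g1 and g2) or g3: must break the complex AND remove the isozyme
        sets = GprRule.parse("(g1 and g2) or g3").minimal_knockout_sets()
        assert sets == [frozenset({"g1", "g3"}), frozenset({"g2", "g3"})]


class TestCarbonContent:
    @pytest.mark.parametrize(
        "formula,expected",
        [("C6H12O6", 6), ("CaCl2", 0), ("CH4", 1), ("C27H44O", 27), ("CuSO4", 0)],
    )
    def test_formula_parsing_distinguishes_elements(self, formula, expected):
        assert carbon_atoms_from_formula(formula) == expected

    def test_polymeric_formula_raises(self):
        with pytest.raises(UnknownCarbonError):
            carbon_atoms_from_formula("C10H16N5O13P3X")

    def test_metadata_overrides_and_errors(self, t1):
        assert carbon_content(t1, "A") == 6
        assert carbon_content(t1, "P") == 4
        with pytest.raises(UnknownCarbonError):
            carbon_content(t1, "B")  # no metadata, no formula
        assert carbon_content(t1, "B", carbon_map={"B": 3}) == 3


class TestToyModels:
    def test_t1_shape_and_determinism(self):
        m1, m2 = make_toy_model("T1", 1), make_toy_model("T1", 2)
        assert len(m1.reactions) == 6
        assert len(m1.metabolites) == 4
        assert m1.genes == {"g1", "g2", "g3"}
        assert model_to_dict(m1) == model_to_dict(m2)  # T1 ignores the seed
        assert fba(m1).objective_value == pytest.approx(10.0)

    def test_random_variant_is_seed_deterministic(self):
        a, b = make_toy_model("random", 7), make_toy_model("random", 7)
        assert model_to_dict(a) == model_to_dict(b)
        c = make_toy_model("random", 8)
        assert model_to_dict(a) != model_to_dict(c)

    def test_unknown_variant_lists_available(self):
        with pytest.raises(Exception, match="T1"):
            make_toy_model("nope")

    def test_random_variant_grows_and_validates(self):
        for seed in range(5):
            m = make_toy_model("random", seed)
            m.validate()
            assert fba(m).objective_value > 0


class TestGeneDeletions:
    def test_single_deletion_closes_only_its_reaction(self, t1):
        mutant = apply_gene_deletions(t1, {"g2"})
        assert (mutant.reaction("R2").lower_bound, mutant.reaction("R2").upper_bound) == (0, 0)
        assert mutant.reaction("R1").upper_bound > 0
        assert mutant.reaction("R3").upper_bound > 0
        # input untouched
        assert t1.reaction("R2").upper_bound > 0

    def test_empty_and_full_deletions(self, t1):
        assert model_to_dict(apply_gene_deletions(t1, set())) == model_to_dict(t1)
        all_closed = apply_gene_deletions(t1, {"g1", "g2", "g3"})
        for rid in ("R1", "R2", "R3"):
            assert all_closed.reaction(rid).upper_bound == 0

    def test_idempotence(self, t1):
        once = apply_gene_deletions(t1, {"g1", "g3"})
        twice = apply_gene_deletions(once, {"g1", "g3"})
        assert model_to_dict(once) == model_to_dict(twice)

    def test_unknown_gene_is_named(self, t1):
        with pytest.raises(UnknownGeneError, match="gX"):
            apply_gene_deletions(t1, {"gX"})


class TestPatchModel:
    def test_add_reaction_and_resolve(self, t1):
        patched = patch_model(
            t1,
            [
                {
                    "operation": "add_reaction",
                    "payload": {
                        "id": "R4",
                        "stoichiometry": {"C": -1, "P": 1},
                        "lower_bound": 0,
                        "upper_bound": 1000,
                        "gpr": "g4",
                    },
                }
            ],
        )
        assert len(patched.reactions) == 7
        assert "g4" in patched.genes

    def test_set_bounds_changes_optimum(self, t1):
        patched = patch_model(
            t1, [{"operation": "set_bounds", "payload": {"id": "UP", "upper_bound": 5}}]
        )
        assert fba(patched).objective_value == pytest.approx(5.0)

    def test_missing_id_reports_edit_index(self, t1):
        with pytest.raises(ModelValidationError, match="edit 0"):
            patch_model(t1, [{"operation": "remove_reaction", "payload": {"id": "nope"}}])

    def test_empty_edit_list_is_identity(self, t1):
        assert model_to_dict(patch_model(t1, [])) == model_to_dict(t1)


class TestModelIO:
    @pytest.mark.parametrize("fmt,suffix", [("json", ".json"), ("sbml", ".xml")])
    def test_roundtrip(self, t1, tmp_path, fmt, suffix):
        path = tmp_path / f"t1{suffix}"
        write_model(t1, path, format=fmt)
        back = read_model(path, format=fmt)
        assert back.reaction_ids == t1.reaction_ids
        assert back.objective_reaction == t1.objective_reaction
        assert back.genes == t1.genes
        for rid in t1.reaction_ids:
            a, b = t1.reaction(rid), back.reaction(rid)
            assert a.stoichiometry == b.stoichiometry
            assert a.lower_bound == pytest.approx(b.lower_bound)
            assert a.upper_bound == pytest.approx(b.upper_bound)
            assert (a.gpr is None) == (b.gpr is None)
            if a.gpr is not None:
                assert a.gpr.minimal_knockout_sets() == b.gpr.minimal_knockout_sets()

    def test_sbml_roundtrip_preserves_formula(self, tmp_path):
        m = make_toy_model("T1")
        m.metabolite("B").formula = "C3H4O3"
        path = tmp_path / "m.xml"
        write_model(m, path)
        assert read_model(path).metabolite("B").formula == "C3H4O3"

    def test_invalid_bounds_rejected(self, t1):
        data = model_to_dict(t1)
        data["reactions"][0]["lower_bound"] = 5
        data["reactions"][0]["upper_bound"] = 1
        with pytest.raises(ModelValidationError, match="lower_bound"):
            model_from_dict(data)

    def test_missing_objective_rejected(self, t1, tmp_path):
        data = model_to_dict(t1)
        data["objective"] = ""
        with pytest.raises(ModelFormatError, match="objective"):
            model_from_dict(data)

    def test_sbml_without_objective_rejected(self, tmp_path):
        import libsbml

        ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
        doc = libsbml.SBMLDocument(ns)
        doc.setPackageRequired("fbc", False)
        sm = doc.createModel()
        sm.setId("noobj")
        sm.getPlugin("fbc").setStrict(True)
        comp = sm.createCompartment()
        comp.setId("c")
        comp.setConstant(True)
        path = str(tmp_path / "noobj.xml")
        libsbml.writeSBMLToFile(doc, path)
        with pytest.raises(ModelFormatError, match="no objective"):
            read_model(path)

    def test_unparsable_json_names_problem(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelFormatError):
            read_model(path, format="json")


def test_reaction_kind_heuristic():
    model = MetabolicModel(
        id="kinds",
        metabolites=[
            Metabolite("glc_c", compartment="c"),
            Metabolite("glc_e", compartment="e"),
            Metabolite("pyr_c", compartment="c"),
        ],
        reactions=[
            Reaction("EX_glc", {"glc_e": -1.0}, -10, 0),
            Reaction("GLCt", {"glc_e": -1.0, "glc_c": 1.0}, 0, 10),
            Reaction("GLY", {"glc_c": -1.0, "pyr_c": 2.0}, 0, 10),
        ],
        objective_reaction="GLY",
    )
    assert model.reaction_kind("EX_glc") == "exchange"
    assert model.reaction_kind("GLCt") == "transport"
    assert model.reaction_kind("GLY") == "internal"
    model.reaction("GLCt").kind_override = "internal"
    assert model.reaction_kind("GLCt") == "internal"


# ---------------------------------------------------------------------------
# property-based checks
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402

_gene_names = st.sampled_from([f"g{i}" for i in range(6)])
_gpr_exprs = st.recursive(
    _gene_names,
    lambda children: st.tuples(
        st.sampled_from(["and", "or"]),
        st.lists(children, min_size=2, max_size=3).map(tuple),
    ),
    max_leaves=8,
)


@settings(derandomize=True, max_examples=60)
@given(expr=_gpr_exprs, deleted=st.sets(_gene_names), extra=_gene_names)
def test_gpr_evaluation_is_monotone_in_deletions(expr, deleted, extra):
    """Deleting more genes can only switch a rule from true to false."""
    rule = GprRule(expr)
    assert rule.evaluate(set()) is True  # all genes present
    assert rule.evaluate(rule.genes()) is False  # all genes deleted
    before = rule.evaluate(deleted)
    after = rule.evaluate(deleted | {extra})
    assert not (before is False and after is True)


@settings(derandomize=True, max_examples=40)
@given(expr=_gpr_exprs)
def test_minimal_knockout_sets_falsify_and_are_minimal(expr):
    rule = GprRule(expr)
    cuts = rule.minimal_knockout_sets()
    assert cuts  # every rule can be falsified by deleting all its genes
    for cut in cuts:
        assert rule.evaluate(cut) is False
        for gene in cut:  # dropping any member restores the rule
            assert rule.evaluate(cut - {gene}) is True
    for a in cuts:  # pairwise minimality
        for b in cuts:
            assert a == b or not (a < b)
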