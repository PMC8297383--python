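import pytest

from chassiscraft import Environment, make_toy_model


@pytest.fixture
def t1():
    return make_toy_model("T1")


@pytest.fixture
def t2():
    return make_toy_model("T2")


@pytest.fixture
def env():
    return Environment()


def to_cobra(model):
    """Convert a chassiscraft model to a cobra model (test oracle only)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    rxns = []
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        rxns.append(cr)
    cm.add_reactions(rxns)
    for rxn in model.reactions:
        cm.reactions.get_by_id(rxn.id).add_metabolites(
            {mets[mid]: coef for mid, coef in rxn.stoichiometry.items()}
        )
        if rxn.gpr is not None:
            cm.reactions.get_by_id(rxn.id).gene_reaction_rule = rxn.gpr.to_string()
    cm.objective = model.objective_reaction
    return cm
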