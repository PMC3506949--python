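"""Model loading, validation, and perturbation editing."""

import numpy as np
import pandas as pd
import pytest

from relatch.model import (
    MetabolicModel,
    ModelValidationError,
    PerturbationSpec,
    apply_environment,
    load_model,
    model_from_table,
    parse_reaction_equation,
)

TOY_TSV = """id\tequation\tlower_bound\tupper_bound\tgpr
U\t-> A\t0\t10\t
R1\tA -> B\t0\t100\tgR1
R2\tA -> B\t0\t100\tgR2
R3\tB ->\t0\t100\t
"""


@pytest.fixture
def toy_tsv(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text(TOY_TSV)
    return p


@pytest.fixture
def toy_sbml(tmp_path):
    import cobra
    from cobra import Metabolite, Reaction

    m = cobra.Model("toy")
    A = Metabolite("A", compartment="c")
    B = Metabolite("B", compartment="c")
    rxns = []
    for rid, mets, gpr in [
        ("U", {A: 1.0}, ""),
        ("R1", {A: -1.0, B: 1.0}, "gR1"),
        ("R2", {A: -1.0, B: 1.0}, "gR2"),
        ("R3", {B: -1.0}, ""),
    ]:
        r = Reaction(rid, lower_bound=0.0, upper_bound=10.0 if rid == "U" else 100.0)
        r.add_metabolites(mets)
        if gpr:
            r.gene_reaction_rule = gpr
        rxns.append(r)
    m.add_reactions(rxns)
    m.objective = "R3"
    path = tmp_path / "toy.xml"
    cobra.io.write_sbml_model(m, str(path))
    return path


def test_load_tabular_toy(toy_tsv):
    model = load_model(toy_tsv, dialect="tabular", biomass_id="R3")
    assert model.n_reactions == 4
    assert model.exchange_ids == {"U", "R3"}
    assert model.gpr_reactions == ("R1", "R2")
    assert model.genes == {"gR1", "gR2"}


def test_sbml_and_tabular_dialects_agree(toy_sbml, toy_tsv):
    a = load_model(toy_sbml, dialect="sbml")
    b = load_model(toy_tsv, dialect="tabular", biomass_id="R3")
    assert a.reaction_ids == b.reaction_ids
    assert a.exchange_ids == b.exchange_ids
    assert a.biomass_id == "R3"  # single-reaction SBML objective
    np.testing.assert_allclose(a.lower_bounds, b.lower_bounds)
    np.testing.assert_allclose(a.upper_bounds, b.upper_bounds)
    # same stoichiometry over shared metabolite labels
    for rid in a.reaction_ids:
        ja, jb = a.reaction_index[rid], b.reaction_index[rid]
        ca = {m: a.S[i, ja] for i, m in enumerate(a.metabolite_ids) if a.S[i, ja]}
        cb = {m: b.S[i, jb] for i, m in enumerate(b.metabolite_ids) if b.S[i, jb]}
        assert ca == cb
    assert a.associations["R1"].enzymes == b.associations["R1"].enzymes


def test_duplicate_reaction_ids_rejected(tmp_path):
    p = tmp_path / "dup.tsv"
    p.write_text("id\tequation\tlower_bound\tupper_bound\tgpr\n"
                 "R\tA -> B\t0\t1\t\nR\tB -> C\t0\t1\t\n")
    with pytest.raises(ModelValidationError, match="R"):
        load_model(p, dialect="tabular")


def test_bad_equation_names_reaction(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("id\tequation\tlower_bound\tupper_bound\tgpr\n"
                 "BROKEN\tno arrow here\t0\t1\t\n")
    with pytest.raises(ModelValidationError, match="BROKEN"):
        load_model(p, dialect="tabular")


def test_bounds_must_be_ordered(toy_tsv):
    df = pd.read_csv(toy_tsv, sep="\t")
    df.loc[0, "lower_bound"] = 50.0
    df.loc[0, "upper_bound"] = 5.0
    with pytest.raises(ModelValidationError, match="U"):
        model_from_table(df)


@pytest.mark.parametrize(
    "eq,expected",
    [
        ("A + 2 B -> C", {"A": -1, "B": -2, "C": 1}),
        ("A <-> B", {"A": -1, "B": 1}),
        ("-> A", {"A": 1}),
        ("A ->", {"A": -1}),
        ("B <- A", {"A": -1, "B": 1}),
        ("0.5 A -> B", {"A": -0.5, "B": 1}),
    ],
)
def test_equation_parsing(eq, expected):
    assert parse_reaction_equation(eq) == expected


# -- environmental perturbations ----------------------------------------

def test_carbon_source_switch(toy_tsv):
    model = load_model(toy_tsv, dialect="tabular", biomass_id="R3")
    spec = PerturbationSpec(medium={"U": (0.0, 0.0), "R3": (0.0, 50.0)})
    out = apply_environment(model, spec)
    j = out.reaction_index["U"]
    assert out.lower_bounds[j] == out.upper_bounds[j] == 0.0
    assert out.upper_bounds[out.reaction_index["R3"]] == 50.0
    # original untouched
    assert model.upper_bounds[model.reaction_index["U"]] == 10.0


def test_chemostat_growth_fixed(toy_tsv):
    model = load_model(toy_tsv, dialect="tabular", biomass_id="R3")
    out = apply_environment(model, PerturbationSpec(fixed_growth=0.2))
    j = out.reaction_index["R3"]
    assert out.lower_bounds[j] == out.upper_bounds[j] == 0.2


def test_empty_spec_is_identity(toy_tsv):
    model = load_model(toy_tsv, dialect="tabular", biomass_id="R3")
    out = apply_environment(model, PerturbationSpec())
    np.testing.assert_array_equal(out.lower_bounds, model.lower_bounds)
    np.testing.assert_array_equal(out.upper_bounds, model.upper_bounds)


def test_medium_edit_on_internal_reaction_rejected(toy_tsv):
    model = load_model(toy_tsv, dialect="tabular", biomass_id="R3")
    with pytest.raises(ValueError, match="non-exchange"):
        apply_environment(model, PerturbationSpec(medium={"R1": (0.0, 1.0)}))


def test_edit_then_revert_restores_bounds(toy_tsv):
    model = load_model(toy_tsv, dialect="tabular", biomass_id="R3")
    edited = apply_environment(model, PerturbationSpec(medium={"U": (0.0, 3.0)}))
    reverted = apply_environment(edited, PerturbationSpec(medium={"U": (0.0, 10.0)}))
    np.testing.assert_array_equal(reverted.lower_bounds, model.lower_bounds)
    np.testing.assert_array_equal(reverted.upper_bounds, model.upper_bounds)


def test_negative_fixed_growth_rejected():
    with pytest.raises(ValueError):
        PerturbationSpec(fixed_growth=-0.1)
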