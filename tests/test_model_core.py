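"""Model containers, readers/writers and the validation battery."""

import json

import pytest

from symbflux import (
    DissipationSpec,
    MetabolicModel,
    ModelError,
    check_mass_charge_balance,
    check_stoichiometric_consistency,
    detect_energy_generating_cycles,
    read_model,
    validate_model,
    write_model,
)
from symbflux.formulas import ElementalFormula, FormulaError
from symbflux.io import ModelIOError

from conftest import chain_model, met, rxn


# -- formulas -----------------------------------------------------------

@pytest.mark.parametrize(
    "text,counts",
    [
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("Fe", {"Fe": 1}),
        ("CHO2R", {"C": 1, "H": 1, "O": 2, "R": 1}),
        ("C3.5H7", {"C": 3.5, "H": 7}),
        ("", {}),
    ],
)
def test_formula_parse(text, counts):
    formula = ElementalFormula.parse(text)
    assert dict(formula.counts) == {k: float(v) for k, v in counts.items() if v}


def test_formula_rejects_garbage():
    with pytest.raises(FormulaError):
        ElementalFormula.parse("C6H12$O6")
    with pytest.raises(FormulaError):
        ElementalFormula({"Xx": 1})


def test_molecular_weight_glucose():
    # 180.156 g/mol -> 0.180156 g/mmol
    mw = ElementalFormula.parse("C6H12O6").molecular_weight()
    assert mw == pytest.approx(0.180156, abs=1e-6)


def test_r_group_is_massless_but_balances():
    assert ElementalFormula.parse("R").molecular_weight() == 0.0
    model = MetabolicModel(
        metabolites=[met("A", "C2R"), met("B", "C2")],
        reactions=[rxn("R1", {"A": -1, "B": 1})],
        objective_id=None,
    )
    report = check_mass_charge_balance(model)
    assert report.balances[0].element_residuals == {"R": -1.0}
    assert not report.balances[0].balanced


# -- structural invariants ---------------------------------------------

def test_dangling_metabolite_is_named():
    with pytest.raises(ModelError, match="'X'"):
        MetabolicModel(
            metabolites=[met("A")],
            reactions=[rxn("R1", {"A": -1, "X": 1})],
        )


def test_undeclared_gene_is_named():
    with pytest.raises(ModelError, match="'g9'"):
        MetabolicModel(
            metabolites=[met("A"), met("B")],
            reactions=[rxn("R1", {"A": -1, "B": 1}, gpr="g9")],
            genes=[],
        )


def test_exchange_must_touch_one_metabolite():
    with pytest.raises(ModelError):
        rxn("EX_bad", {"A": -1, "B": 1}, kind="exchange")


def test_bounds_ordering_enforced():
    with pytest.raises(ModelError):
        rxn("R1", {"A": -1}, lb=5.0, ub=1.0, kind="exchange")


# -- readers / writers --------------------------------------------------

TOY_JSON = {
    "id": "tiny",
    "metabolites": [
        {"id": "A", "compartment": "c", "formula": "CH4", "charge": 0},
        {"id": "B", "compartment": "c", "formula": "CH4", "charge": 0},
    ],
    "reactions": [
        {"id": "EX_A", "metabolites": {"A": -1}, "lower_bound": -10, "upper_bound": 0},
        {"id": "R", "metabolites": {"A": -1, "B": 1}, "lower_bound": 0,
         "upper_bound": 1000, "gene_reaction_rule": "g1",
         "objective_coefficient": 0},
        {"id": "EX_B", "metabolites": {"B": -1}, "lower_bound": 0,
         "upper_bound": 1000, "objective_coefficient": 1},
    ],
    "genes": [{"id": "g1"}],
}


def test_json_fixture_loads(tmp_path):
    path = tmp_path / "tiny.json"
    path.write_text(json.dumps(TOY_JSON))
    model = read_model(path, "json")
    assert len(model.reactions) == 3
    assert len(model.metabolites) == 2
    assert model.genes == ["g1"]
    assert model.objective_id == "EX_B"
    assert model.reaction("EX_A").kind == "exchange"  # inferred
    assert model.reaction("EX_A").lower_bound == -10


def test_json_missing_bounds_default(tmp_path):
    doc = json.loads(json.dumps(TOY_JSON))
    del doc["reactions"][1]["lower_bound"]
    del doc["reactions"][1]["upper_bound"]
    path = tmp_path / "tiny.json"
    path.write_text(json.dumps(doc))
    model = read_model(path, "json")
    assert model.reaction("R").bounds == (-1000.0, 1000.0)


def test_json_dangling_reference_names_culprit(tmp_path):
    doc = json.loads(json.dumps(TOY_JSON))
    doc["reactions"][1]["metabolites"] = {"A": -1, "X": 1}
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(ModelIOError, match="'X'"):
        read_model(path, "json")


def test_json_parse_failure_reports_position(tmp_path):
    path = tmp_path / "broken.json"
    path.write_text('{"id": "x", ')
    with pytest.raises(ModelIOError, match="line"):
        read_model(path, "json")


def test_missing_file_is_io_error():
    with pytest.raises(ModelIOError, match="does not exist"):
        read_model("/nonexistent/model.json", "json")


@pytest.mark.parametrize("fmt,ext", [("json", ".json"), ("sbml", ".xml")])
def test_round_trip_identity(toy, tmp_path, fmt, ext):
    """read(write(M)) equals M field-by-field, for both dialects."""
    model, _ = toy
    path = tmp_path / f"toy{ext}"
    write_model(model, path, fmt)
    assert model.equal(read_model(path, fmt))


def test_empty_gpr_not_emitted_in_json(tmp_path):
    model = chain_model()
    path = tmp_path / "chain.json"
    write_model(model, path, "json")
    doc = json.loads(path.read_text())
    assert all("gene_reaction_rule" not in entry for entry in doc["reactions"])
    assert {"metabolites", "reactions", "genes"} <= set(doc)


# -- mass / charge balance ---------------------------------------------

def test_identity_formula_balances():
    model = MetabolicModel(
        metabolites=[met("A", "CH4"), met("B", "CH4")],
        reactions=[rxn("R1", {"A": -1, "B": 1})],
    )
    bal = check_mass_charge_balance(model).balances[0]
    assert bal.balanced
    assert bal.element_residuals == {}


def test_hydrogen_residual_reported():
    model = MetabolicModel(
        metabolites=[met("A", "CH4"), met("B", "CH3")],
        reactions=[rxn("R1", {"A": -1, "B": 1})],
    )
    bal = check_mass_charge_balance(model).balances[0]
    assert not bal.balanced
    assert bal.element_residuals == {"H": -1.0}


def test_charge_residual_reported():
    model = MetabolicModel(
        metabolites=[met("A", "CH4", charge=1), met("B", "CH4", charge=0)],
        reactions=[rxn("R1", {"A": -1, "B": 1})],
    )
    bal = check_mass_charge_balance(model).balances[0]
    assert not bal.balanced
    assert bal.charge_residual == -1


def test_unknown_formula_marks_unchecked():
    model = MetabolicModel(
        metabolites=[met("A", "CH4"), met("B", "")],
        reactions=[rxn("R1", {"A": -1, "B": 1})],
    )
    report = check_mass_charge_balance(model)
    assert report.unchecked_reactions == ["R1"]
    assert not report.balances[0].balanced


def test_symbiosis_reaction_balanced_against_elemental_summation(toy):
    """The built symbiosis reaction balances; oracle: independent
    per-element summation over the composition table."""
    model, composition = toy
    symb = model.reaction("SYMBIOSIS")
    product = model.metabolite("symbiosis_product_c")
    # independent oracle: sum coefficient * element count per component
    for element in product.formula:
        total = 0.0
        for met_id, coeff in symb.stoichiometry.items():
            if coeff < 0:
                total += -coeff * model.metabolite(met_id).formula[element]
        assert total == pytest.approx(product.formula[element], rel=1e-12)
    report = check_mass_charge_balance(model)
    bal = {b.reaction_id: b for b in report.balances}["SYMBIOSIS"]
    assert bal.balanced


def test_balance_soundness_perturbation(toy):
    """Adding +1 to one coefficient of a balanced reaction unbalances
    exactly that reaction."""
    model, _ = toy
    perturbed = model.copy()
    target = perturbed.reaction("MDH")
    met_id = next(iter(target.stoichiometry))
    target.stoichiometry[met_id] += 1.0
    report = check_mass_charge_balance(perturbed)
    assert report.unbalanced_reactions == ["MDH"]


# -- stoichiometric consistency ----------------------------------------

def test_conserving_network_is_consistent():
    model = MetabolicModel(
        metabolites=[met("A"), met("B")],
        reactions=[rxn("R1", {"A": -1, "B": 1}, lb=-1000.0)],
    )
    consistent, witnesses = check_stoichiometric_consistency(model)
    assert consistent and witnesses == []


def test_mass_creation_flips_consistency_and_is_reversible():
    base = MetabolicModel(
        metabolites=[met("A"), met("B")],
        reactions=[rxn("R1", {"A": -1, "B": 1}, lb=-1000.0)],
    )
    assert check_stoichiometric_consistency(base)[0]
    bad = base.copy()
    bad.reactions.append(rxn("DUP", {"A": 1}))  # A -> 2A written as net +1 A
    bad.reactions[-1].stoichiometry = {"A": 1.0}
    bad.validate_structure()
    consistent, witnesses = check_stoichiometric_consistency(bad)
    assert not consistent
    assert "A" in witnesses
    # removing the offender restores consistency
    bad.reactions = [r for r in bad.reactions if r.id != "DUP"]
    bad.validate_structure()
    assert check_stoichiometric_consistency(bad)[0]


def test_empty_internal_network_trivially_consistent():
    model = MetabolicModel(
        metabolites=[met("A")],
        reactions=[rxn("EX_A", {"A": -1}, lb=-10.0, kind="exchange")],
    )
    report = validate_model(model)
    assert report.consistent
    assert report.warnings


def test_toy_is_stoichiometrically_consistent(toy):
    model, _ = toy
    consistent, witnesses = check_stoichiometric_consistency(model)
    assert consistent and witnesses == []


# -- energy-generating cycles ------------------------------------------

def _egc_fixture(reversible_synthase: bool) -> MetabolicModel:
    """An ATPase written in the hydrolysis direction plus an independent
    hydrolysis reaction.  When the ATPase is reversible its reverse flux
    regenerates ATP for free (the proton gradient it should consume is
    not modeled), closing an energy-generating loop with the dissipation
    probe; irreversible, no ATP source remains."""
    return MetabolicModel(
        metabolites=[
            met("atp_c", "C10H16N5O13P3"), met("adp_c", "C10H15N5O10P2"),
            met("pi_c", "H3PO4"), met("h2o_c", "H2O"),
        ],
        reactions=[
            rxn("ATPASE", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
                lb=-1000.0 if reversible_synthase else 0.0),
            rxn("HYDRO", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1}),
            rxn("EX_h2o", {"h2o_c": -1}, lb=-1000.0, kind="exchange"),
        ],
        objective_id=None,
        id="pump",
    )


def test_two_reaction_pump_detected():
    report = detect_energy_generating_cycles(_egc_fixture(True))
    assert report.detected
    assert "ATPASE" in report.witness_reactions


def test_irreversible_synthase_breaks_cycle():
    report = detect_energy_generating_cycles(_egc_fixture(False))
    assert not report.detected
    assert report.witness_reactions == []


def test_missing_energy_metabolite_is_error():
    model = chain_model()
    with pytest.raises(ModelError, match="atp"):
        detect_energy_generating_cycles(model, DissipationSpec())


def test_toy_has_no_egc(toy):
    model, _ = toy
    assert not detect_energy_generating_cycles(model).detected


@pytest.mark.parametrize("reversible", [True, False])
def test_egc_agrees_with_brute_force(reversible):
    """On a <=6-reaction network the detector agrees with vertex
    enumeration of the dissipation LP."""
    from conftest import brute_force_optimum

    model = _egc_fixture(reversible)
    report = detect_energy_generating_cycles(model)
    # replicate the probe: exchanges closed, dissipation added
    probe = model.copy()
    for r in probe.reactions:
        if r.kind == "exchange":
            r.lower_bound = r.upper_bound = 0.0
    probe.reactions.append(
        rxn("DISS", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1})
    )
    probe.objective_id = "DISS"
    probe.validate_structure()
    oracle = brute_force_optimum(probe)
    assert (oracle > 1e-6) == report.detected


# -- aggregate battery --------------------------------------------------

def test_toy_validation_battery_all_pass(toy, tmp_path):
    model, _ = toy
    report = validate_model(model)
    assert report.passed
    report.write_tsv(tmp_path / "residuals.tsv")
    report.write_summary_yaml(tmp_path / "summary.yaml")
    assert "passed: true" in (tmp_path / "summary.yaml").read_text()
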