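"""LP engine: FBA, duals, FVA, 1-norm fitting.

The independent oracle is brute-force vertex enumeration
(conftest.brute_force_optimum) on networks of <= 6 reactions; shadow
prices are additionally checked by finite differences; cobrapy + GLPK
serves as an external cross-check on the toy model.
"""

import numpy as np
import pytest

from symbflux import (
    MetabolicModel,
    ModelError,
    flux_variability,
    joint_min_norm_fluxes,
    min_norm_fluxes,
    shadow_prices,
    solve_fba,
)

from conftest import brute_force_optimum, chain_model, met, parallel_model, rxn


def diamond_model():
    """Split/rejoin: EX_S -> S -> (P1 cap 2 | P2 cap 5) -> P -> EX_P."""
    return MetabolicModel(
        metabolites=[met("S"), met("M1"), met("M2"), met("P")],
        reactions=[
            rxn("EX_S", {"S": -1}, lb=-6.0, ub=0.0, kind="exchange"),
            rxn("A1", {"S": -1, "M1": 1}, ub=2.0),
            rxn("A2", {"S": -1, "M2": 1}, ub=5.0),
            rxn("B1", {"M1": -1, "P": 1}),
            rxn("B2", {"M2": -1, "P": 1}),
            rxn("EX_P", {"P": -1}, lb=0.0, kind="exchange"),
        ],
        objective_id="EX_P",
        id="diamond",
    )


def cycle_model():
    """Chain plus a futile 2-cycle not needed at the optimum."""
    return MetabolicModel(
        metabolites=[met("A"), met("B")],
        reactions=[
            rxn("EX_A", {"A": -1}, lb=-5.0, ub=0.0, kind="exchange"),
            rxn("F", {"A": -1, "B": 1}),
            rxn("G", {"B": -1, "A": 1}),
            rxn("EX_B", {"B": -1}, lb=0.0, kind="exchange"),
        ],
        objective_id="EX_B",
        id="cycle",
    )


SMALL_MODELS = [chain_model, lambda: parallel_model(3, 4), diamond_model, cycle_model]


# -- FBA ----------------------------------------------------------------

def test_chain_single_path():
    solution = solve_fba(chain_model())
    assert solution.optimal
    assert solution.objective_value == pytest.approx(10.0, abs=1e-9)


def test_parallel_capacities_sum():
    solution = solve_fba(parallel_model(3, 4))
    assert solution.objective_value == pytest.approx(7.0, abs=1e-8)
    assert brute_force_optimum(parallel_model(3, 4)) == pytest.approx(7.0, abs=1e-8)


def test_closed_uptakes_zero_objective():
    model = chain_model()
    model.reaction("EX_A").lower_bound = 0.0
    solution = solve_fba(model)
    assert solution.optimal
    assert solution.objective_value == pytest.approx(0.0, abs=1e-9)


def test_bad_bounds_error_before_solve():
    model = chain_model()
    model.reaction("R").lower_bound = 5.0
    model.reaction("R").upper_bound = 1.0
    with pytest.raises(ModelError):
        solve_fba(model)


def test_unbounded_status_returned():
    model = MetabolicModel(
        metabolites=[met("A")],
        reactions=[
            rxn("EX_in", {"A": 1}, lb=0.0, ub=np.inf, kind="exchange"),
            rxn("EX_out", {"A": -1}, lb=0.0, ub=np.inf, kind="exchange"),
        ],
        objective_id="EX_out",
    )
    assert solve_fba(model).status == "unbounded"


def test_infeasible_status_returned():
    model = chain_model()
    model.reaction("EX_B").lower_bound = 20.0  # demand exceeds supply
    model.reaction("EX_B").upper_bound = 30.0
    assert solve_fba(model).status == "infeasible"


@pytest.mark.parametrize("factory", SMALL_MODELS)
def test_oracle_equivalence_on_small_networks(factory):
    """solve_fba matches vertex enumeration exactly on <=6-reaction nets."""
    model = factory()
    assert solve_fba(model).objective_value == pytest.approx(
        brute_force_optimum(model), abs=1e-8
    )


@pytest.mark.parametrize("factory", SMALL_MODELS)
def test_strong_duality_on_every_optimal_solve(factory):
    solution = solve_fba(factory())
    assert solution.optimal
    assert solution.objective_value == pytest.approx(
        solution.dual_objective, abs=1e-5
    )


def test_strong_duality_on_toy(toy_std):
    solution = solve_fba(toy_std)
    assert solution.objective_value == pytest.approx(
        solution.dual_objective, abs=1e-5
    )


def test_steady_state_and_bounds_satisfied(toy_std):
    solution = solve_fba(toy_std)
    S = toy_std.stoichiometric_matrix()
    v = np.array([solution.fluxes[r] for r in toy_std.reaction_ids])
    assert np.max(np.abs(S @ v)) < 1e-6
    lb, ub = toy_std.bounds_arrays()
    assert np.all(v >= lb - 1e-6) and np.all(v <= ub + 1e-6)


def test_repeated_solves_identical(toy_std):
    a = solve_fba(toy_std)
    b = solve_fba(toy_std)
    assert a.fluxes == b.fluxes


def test_bound_scaling_homogeneity():
    """Multiplying every bound by k multiplies the optimum by k."""
    model = diamond_model()
    base = solve_fba(model).objective_value
    k = 3.5
    for reaction in model.reactions:
        reaction.lower_bound *= k
        reaction.upper_bound *= k
    assert solve_fba(model).objective_value == pytest.approx(k * base, rel=1e-9)


# -- FVA ----------------------------------------------------------------

def test_fva_forced_chain_collapses():
    result = flux_variability(chain_model(), fraction_of_optimum=1.0)
    for rxn_id in ("EX_A", "R", "EX_B"):
        lo, hi = result[rxn_id]
        assert abs(abs(lo) - 10.0) < 1e-7 and abs(abs(hi) - 10.0) < 1e-7


def test_fva_redundant_paths_full_range():
    """Two redundant paths at fraction 0: each can carry 0..capacity;
    oracle: per-reaction vertex enumeration."""
    model = parallel_model(10.0, 10.0)
    model.reaction("EX_S").lower_bound = -10.0
    result = flux_variability(model, fraction_of_optimum=0.0)
    for path in ("P1", "P2"):
        lo, hi = result[path]
        assert lo == pytest.approx(0.0, abs=1e-8)
        assert hi == pytest.approx(10.0, abs=1e-8)
        assert hi == pytest.approx(
            brute_force_optimum(model, objective_id=path), abs=1e-8
        )


def test_fva_sandwich_property(toy_std):
    """Ranges at a higher fraction are contained in those at a lower one."""
    loose = flux_variability(toy_std, fraction_of_optimum=0.5)
    tight = flux_variability(toy_std, fraction_of_optimum=1.0)
    for rxn_id in toy_std.reaction_ids:
        assert tight[rxn_id][0] >= loose[rxn_id][0] - 1e-7
        assert tight[rxn_id][1] <= loose[rxn_id][1] + 1e-7


def test_fva_contains_fba_flux(toy_std):
    solution = solve_fba(toy_std)
    result = flux_variability(toy_std, fraction_of_optimum=1.0)
    for rxn_id, (lo, hi) in result.ranges.items():
        assert lo - 1e-6 <= solution.fluxes[rxn_id] <= hi + 1e-6


def test_tca_carries_flux_at_optimum(toy_std):
    """The oxidative TCA cycle runs during nitrogen fixation: its
    reactions have strictly positive minima at the optimum."""
    result = flux_variability(
        toy_std, fraction_of_optimum=1.0,
        reactions=["CS", "ICDH", "AKGDH", "SUCOAS", "PDH"],
    )
    for rxn_id, (lo, _) in result.ranges.items():
        assert lo > 1e-6, rxn_id


def test_fva_fraction_out_of_range():
    with pytest.raises(ValueError):
        flux_variability(chain_model(), fraction_of_optimum=1.5)


# -- shadow prices ------------------------------------------------------

def test_shadow_price_matches_finite_difference():
    """Chain limited by EX_A lb -10: price of A is 1 objective unit per
    unit of uptake; oracle: re-solve with the bound relaxed by 0.01."""
    model = chain_model()
    solution = solve_fba(model)
    assert solution.duals["A"] == pytest.approx(1.0, abs=1e-7)
    relaxed = model.copy()
    relaxed.reaction("EX_A").lower_bound = -10.01
    delta = solve_fba(relaxed).objective_value - solution.objective_value
    assert delta / 0.01 == pytest.approx(solution.duals["A"], abs=1e-6)


def test_nonlimiting_metabolite_price_zero():
    model = parallel_model(3, 4)  # supply 1000 >> capacity 7
    solution = solve_fba(model)
    assert solution.duals["S"] == pytest.approx(0.0, abs=1e-9)


def test_inositol_rate_limiting_in_toy(toy_std):
    """With a binding inositol uptake bound, inositol is reported as a
    rate-limiting substrate."""
    report = shadow_prices(toy_std)
    assert "inost_e" in report.rate_limiting
    assert "o2_e" in report.rate_limiting
    solution = solve_fba(toy_std)
    # oracle: finite difference on the inositol uptake bound
    relaxed = toy_std.copy()
    relaxed.reaction("EX_inost_e").lower_bound -= 0.01
    delta = solve_fba(relaxed).objective_value - solution.objective_value
    assert delta / 0.01 == pytest.approx(
        solution.duals["inost_e"], rel=0.05
    )


# -- 1-norm minimization ------------------------------------------------

def test_min_norm_kills_futile_cycle():
    model = cycle_model()
    solution = min_norm_fluxes(model)
    assert solution.objective_value == pytest.approx(5.0, abs=1e-7)
    assert solution.fluxes["G"] == pytest.approx(0.0, abs=1e-7)


def test_min_norm_never_exceeds_plain_fba_norm(toy_std):
    plain = solve_fba(toy_std)
    sparse = min_norm_fluxes(toy_std)
    norm_plain = sum(abs(v) for v in plain.fluxes.values())
    norm_sparse = sum(abs(v) for v in sparse.fluxes.values())
    assert norm_sparse <= norm_plain + 1e-6
    assert sparse.objective_value == pytest.approx(
        plain.objective_value, rel=1e-5
    )


def test_joint_identical_models_identical_fluxes():
    model = cycle_model()
    sol_a, sol_b = joint_min_norm_fluxes(model, model.copy())
    for rxn_id in model.reaction_ids:
        assert sol_a.fluxes[rxn_id] == pytest.approx(
            sol_b.fluxes[rxn_id], abs=1e-7
        )
    assert sol_a.fluxes["G"] == pytest.approx(0.0, abs=1e-7)


def test_joint_preserves_each_optimum(toy_std):
    other = toy_std.copy()
    other.reaction("EX_o2_e").lower_bound = -1.0  # poorer oxygen supply
    opt_a = solve_fba(toy_std).objective_value
    opt_b = solve_fba(other).objective_value
    sol_a, sol_b = joint_min_norm_fluxes(toy_std, other)
    assert sol_a.objective_value == pytest.approx(opt_a, rel=1e-5)
    assert sol_b.objective_value == pytest.approx(opt_b, rel=1e-5)


# -- external cross-check ----------------------------------------------

def test_fba_agrees_with_cobrapy(toy_std, tmp_path):
    """Independent route: the same model solved by cobrapy + GLPK."""
    cobra = pytest.importorskip("cobra")
    from symbflux import write_model

    path = tmp_path / "toy.xml"
    write_model(toy_std, path, "sbml")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cobra_model = cobra.io.read_sbml_model(str(path))
    cobra_model.solver = "glpk"
    external = cobra_model.optimize().objective_value
    ours = solve_fba(toy_std).objective_value
    assert ours == pytest.approx(external, rel=1e-6)
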