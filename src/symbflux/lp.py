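"""Linear-programming core.

Flux balance analysis maximizes (or minimizes) an objective reaction flux
subject to steady-state mass balance S.v = 0 and the flux bounds, solved
with the HiGHS simplex through :func:`scipy.optimize.linprog`.  Shadow
prices come from the duals of the metabolite balance rows; flux
variability re-solves per-reaction min/max LPs under an objective-fraction
constraint; the joint two-condition fit fixes each model at its own
optimum and minimizes the summed 1-norm of both flux vectors.

Variable order is always model file order, so repeated solves of the same
model return identical flux vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, ModelError

FEASIBILITY_TOL = 1e-9
ZERO_TOL = 1e-6


@dataclass
class FluxSolution:
    """Result of one FBA solve.

    ``duals`` maps each metabolite to its shadow price: the marginal change
    of the optimal objective per unit of external supply of the metabolite
    (positive = supplying more would raise the optimum).
    """

    status: str  # optimal | infeasible | unbounded
    objective_value: float = float("nan")
    fluxes: Dict[str, float] = field(default_factory=dict)
    duals: Dict[str, float] = field(default_factory=dict)
    dual_objective: float = float("nan")
    degenerate_duals: bool = False

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    ranges: Dict[str, Tuple[float, float]]
    fraction_of_optimum: float

    def __getitem__(self, rxn_id: str) -> Tuple[float, float]:
        return self.ranges[rxn_id]


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _check_bounds(model: MetabolicModel) -> None:
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelError(
                f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )


def _solve(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL,
        },
    )


def solve_fba(
    model: MetabolicModel,
    maximize: bool = True,
    objective_id: Optional[str] = None,
) -> FluxSolution:
    """Optimize the objective reaction flux at steady state.

    Infeasible and unbounded problems are returned as statuses, not raised;
    an inconsistent bound pair (lb > ub) is an error before solving.
    """
    _check_bounds(model)
    obj_id = objective_id or model.objective_id
    if obj_id is None:
        raise ModelError("model defines no objective reaction")
    rxn_ids = model.reaction_ids
    j_obj = rxn_ids.index(obj_id)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(rxn_ids))
    c[j_obj] = -1.0 if maximize else 1.0
    res = _solve(c, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        if status not in ("infeasible", "unbounded"):
            status = "infeasible"
        return FluxSolution(status=status)
    fluxes = dict(zip(rxn_ids, res.x))
    # scipy minimizes; for a maximization the metabolite-row marginals are
    # directly d(max objective)/d(unit external supply).
    marginals = np.asarray(res.eqlin.marginals)
    duals_vec = marginals if maximize else -marginals
    duals = dict(zip(model.metabolite_ids, duals_vec))
    objective_value = res.x[j_obj]
    # dual objective of the box-constrained LP: sum of bound marginals * bounds
    lower_marg = np.asarray(res.lower.marginals)
    upper_marg = np.asarray(res.upper.marginals)
    dual_obj = float(lower_marg @ lb + upper_marg @ ub)
    dual_objective = -dual_obj if maximize else dual_obj
    # non-unique duals show up as degenerate vertices: a basic variable at
    # its bound with zero reduced cost
    at_bound = (np.abs(res.x - lb) < 1e-9) | (np.abs(res.x - ub) < 1e-9)
    zero_rc = (np.abs(lower_marg) < 1e-12) & (np.abs(upper_marg) < 1e-12)
    degenerate = bool(np.any(at_bound & zero_rc))
    return FluxSolution(
        status="optimal",
        objective_value=float(objective_value),
        fluxes=fluxes,
        duals=duals,
        dual_objective=dual_objective,
        degenerate_duals=degenerate,
    )


def flux_variability(
    model: MetabolicModel,
    fraction_of_optimum: float = 0.0,
    reactions: Optional[List[str]] = None,
) -> FVAResult:
    """Per-reaction flux min/max with the objective held at a fraction of
    its optimum (fraction 0 releases the objective entirely)."""
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    wt = solve_fba(model)
    if not wt.optimal:
        raise ModelError(f"FVA requires an optimal base solve, got {wt.status}")
    rxn_ids = model.reaction_ids
    targets = rxn_ids if reactions is None else list(reactions)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    j_obj = rxn_ids.index(model.objective_id)
    # objective >= fraction * optimum  ->  -v_obj <= -fraction * optimum
    A_ub = np.zeros((1, len(rxn_ids)))
    A_ub[0, j_obj] = -1.0
    b_ub = np.array([-fraction_of_optimum * wt.objective_value])
    ranges: Dict[str, Tuple[float, float]] = {}
    bounds = list(zip(lb, ub))
    b_eq = np.zeros(S.shape[0])
    for rxn_id in targets:
        j = rxn_ids.index(rxn_id)
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        lo = _solve(c, S, b_eq, bounds, A_ub, b_ub)
        hi = _solve(-c, S, b_eq, bounds, A_ub, b_ub)
        if lo.status != 0 or hi.status != 0:
            raise ModelError(f"FVA subproblem for {rxn_id!r} not optimal")
        vmin, vmax = float(lo.x[j]), float(hi.x[j])
        if vmin > vmax:  # solver noise on forced fluxes
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rxn_id] = (vmin, vmax)
    return FVAResult(ranges=ranges, fraction_of_optimum=fraction_of_optimum)


@dataclass
class ShadowPriceReport:
    prices: Dict[str, float]
    rate_limiting: List[str]  # exchanged metabolites with nonzero price
    degenerate: bool


def shadow_prices(model: MetabolicModel, tolerance: float = ZERO_TOL) -> ShadowPriceReport:
    """Shadow prices at the FBA optimum, with the exchanged metabolites
    whose price is nonzero flagged as rate-limiting substrates/products."""
    solution = solve_fba(model)
    if not solution.optimal:
        raise ModelError(f"shadow prices require an optimal solve, got {solution.status}")
    exchanged = {
        next(iter(r.stoichiometry))
        for r in model.exchanges()
        if r.id != model.objective_id  # the objective sink's price is trivially 1
    }
    limiting = sorted(
        met for met in exchanged if abs(solution.duals.get(met, 0.0)) > tolerance
    )
    return ShadowPriceReport(
        prices=solution.duals,
        rate_limiting=limiting,
        degenerate=solution.degenerate_duals,
    )


def min_norm_fluxes(model: MetabolicModel, optimum: Optional[float] = None) -> FluxSolution:
    """Flux vector of minimal 1-norm among those attaining the optimum.

    The standard linearization introduces one auxiliary t_j >= |v_j| per
    reaction and minimizes sum(t).
    """
    wt = solve_fba(model) if optimum is None else None
    opt = wt.objective_value if optimum is None else optimum
    if wt is not None and not wt.optimal:
        return wt
    rxn_ids = model.reaction_ids
    n = len(rxn_ids)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    j_obj = rxn_ids.index(model.objective_id)
    # variables: [v (n), t (n)]; objective pinned at its optimum by an
    # extra equality row (the optimum is attainable by construction)
    A_eq = np.hstack([S, np.zeros_like(S)])
    pin = np.zeros(2 * n)
    pin[j_obj] = 1.0
    A_eq = np.vstack([A_eq, pin])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [opt]])
    rows = []
    rhs = []
    for j in range(n):
        row = np.zeros(2 * n)
        row[j], row[n + j] = 1.0, -1.0  # v - t <= 0
        rows.append(row)
        rhs.append(0.0)
        row = np.zeros(2 * n)
        row[j], row[n + j] = -1.0, -1.0  # -v - t <= 0
        rows.append(row)
        rhs.append(0.0)
    A_ub = np.vstack(rows)
    b_ub = np.array(rhs)
    c = np.concatenate([np.zeros(n), np.ones(n)])
    bounds = list(zip(lb, ub)) + [(0.0, None)] * n
    res = _solve(c, A_eq, b_eq, bounds, A_ub, b_ub)
    if res.status != 0:
        return FluxSolution(status=_STATUS.get(res.status, "infeasible"))
    fluxes = dict(zip(rxn_ids, res.x[:n]))
    return FluxSolution(
        status="optimal", objective_value=float(res.x[j_obj]), fluxes=fluxes
    )


def joint_min_norm_fluxes(
    model_a: MetabolicModel, model_b: MetabolicModel
) -> Tuple[FluxSolution, FluxSolution]:
    """Simultaneously fit two conditions: each model's objective is fixed at
    its own FBA optimum, then the summed 1-norm of both flux vectors is
    minimized in one joint LP.  Futile cycles not needed for either optimum
    are driven to zero, making the two flux distributions comparable."""
    opt_a = solve_fba(model_a)
    opt_b = solve_fba(model_b)
    for name, sol in (("first", opt_a), ("second", opt_b)):
        if not sol.optimal:
            raise ModelError(f"{name} model is {sol.status}; cannot fit jointly")
    na, nb = len(model_a.reactions), len(model_b.reactions)
    Sa = model_a.stoichiometric_matrix()
    Sb = model_b.stoichiometric_matrix()
    lba, uba = model_a.bounds_arrays()
    lbb, ubb = model_b.bounds_arrays()
    # variables: [vA, vB, tA, tB]
    ntot = 2 * (na + nb)
    A_eq = np.zeros((Sa.shape[0] + Sb.shape[0], ntot))
    A_eq[: Sa.shape[0], :na] = Sa
    A_eq[Sa.shape[0]:, na: na + nb] = Sb
    b_eq = np.zeros(A_eq.shape[0])
    rows, rhs = [], []

    def abs_rows(offset_v: int, offset_t: int, count: int) -> None:
        for j in range(count):
            row = np.zeros(ntot)
            row[offset_v + j], row[offset_t + j] = 1.0, -1.0
            rows.append(row)
            rhs.append(0.0)
            row = np.zeros(ntot)
            row[offset_v + j], row[offset_t + j] = -1.0, -1.0
            rows.append(row)
            rhs.append(0.0)

    abs_rows(0, na + nb, na)
    abs_rows(na, 2 * na + nb, nb)
    # pin each model's objective at its own optimum with equality rows
    pins = []
    pin_rhs = []
    for offset, model, opt in (
        (0, model_a, opt_a.objective_value),
        (na, model_b, opt_b.objective_value),
    ):
        row = np.zeros(ntot)
        row[offset + model.reaction_ids.index(model.objective_id)] = 1.0
        pins.append(row)
        pin_rhs.append(opt)
    A_eq = np.vstack([A_eq] + pins)
    b_eq = np.concatenate([b_eq, pin_rhs])
    A_ub = np.vstack(rows)
    b_ub = np.array(rhs)
    c = np.concatenate([np.zeros(na + nb), np.ones(na + nb)])
    bounds = (
        list(zip(lba, uba))
        + list(zip(lbb, ubb))
        + [(0.0, None)] * (na + nb)
    )
    res = _solve(c, A_eq, b_eq, bounds, A_ub, b_ub)
    if res.status != 0:
        raise ModelError(f"joint 1-norm fit failed: {_STATUS.get(res.status)}")
    va = res.x[:na]
    vb = res.x[na: na + nb]
    sol_a = FluxSolution(
        status="optimal",
        objective_value=float(va[model_a.reaction_ids.index(model_a.objective_id)]),
        fluxes=dict(zip(model_a.reaction_ids, va)),
    )
    sol_b = FluxSolution(
        status="optimal",
        objective_value=float(vb[model_b.reaction_ids.index(model_b.objective_id)]),
        fluxes=dict(zip(model_b.reaction_ids, vb)),
    )
    return sol_a, sol_b
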