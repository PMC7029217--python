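"""Shared fixtures: tiny hand-built networks, the toy bacteroid, and an
independent brute-force LP oracle (vertex enumeration) used to cross-check
the simplex-based solver on small networks."""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest

from symbflux import (
    MetabolicModel,
    MetaboliteRecord,
    ReactionRecord,
    apply_standard_condition,
    generate_toy_bacteroid_model,
    make_exchange,
)
from symbflux.formulas import ElementalFormula


def met(mid: str, formula: str = "", charge: int = 0, compartment: str = "c"):
    return MetaboliteRecord(
        id=mid, name=mid, formula=ElementalFormula.parse(formula),
        charge=charge, compartment=compartment,
    )


def rxn(rid: str, stoich: Dict[str, float], lb: float = 0.0, ub: float = 1000.0,
        gpr: str = "", kind: str = "internal"):
    return ReactionRecord(id=rid, name=rid, stoichiometry=stoich,
                          lower_bound=lb, upper_bound=ub, gpr=gpr, kind=kind)


def chain_model() -> MetabolicModel:
    """EX_A (lb -10) -> A -> B -> EX_B; optimum of EX_B is 10."""
    return MetabolicModel(
        metabolites=[met("A"), met("B")],
        reactions=[
            make_exchange("A", lb=-10.0, ub=0.0, rxn_id="EX_A"),
            rxn("R", {"A": -1, "B": 1}),
            make_exchange("B", lb=0.0, ub=1000.0, rxn_id="EX_B"),
        ],
        genes=[],
        objective_id="EX_B",
        id="chain",
    )


def parallel_model(cap1: float = 3.0, cap2: float = 4.0,
                   gpr1: str = "", gpr2: str = "",
                   genes: Optional[List[str]] = None) -> MetabolicModel:
    """Two parallel paths of capacities cap1/cap2 feeding one sink."""
    return MetabolicModel(
        metabolites=[met("S"), met("P")],
        reactions=[
            make_exchange("S", lb=-1000.0, ub=0.0, rxn_id="EX_S"),
            rxn("P1", {"S": -1, "P": 1}, ub=cap1, gpr=gpr1),
            rxn("P2", {"S": -1, "P": 1}, ub=cap2, gpr=gpr2),
            make_exchange("P", lb=0.0, ub=1000.0, rxn_id="EX_P"),
        ],
        genes=genes or [],
        objective_id="EX_P",
        id="parallel",
    )


def brute_force_optimum(model: MetabolicModel, maximize: bool = True,
                        objective_id: Optional[str] = None) -> Optional[float]:
    """LP optimum by vertex enumeration.

    For S v = 0 with box bounds, any bounded optimum is attained at a
    vertex where at least n - rank(S) variables sit on a bound.  Enumerate
    all bound assignments of every variable subset of that size, solve the
    remaining square-ish system by least squares, keep feasible points.
    Exponential, so only for networks with <= ~7 reactions.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    j_obj = model.reaction_ids.index(objective_id or model.objective_id)
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - rank
    best = None
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        for values in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            for j, val in zip(fixed, values):
                v[j] = val
            if free:
                rhs = -S[:, list(fixed)] @ np.array(values)
                sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            value = v[j_obj]
            if best is None:
                best = value
            elif maximize:
                best = max(best, value)
            else:
                best = min(best, value)
    return best


@pytest.fixture(scope="session")
def toy():
    """The default toy bacteroid model and its composition."""
    model, composition = generate_toy_bacteroid_model()
    return model, composition


@pytest.fixture(scope="session")
def toy_std(toy):
    """Toy bacteroid under the standard nitrogen-fixation condition."""
    model, _ = toy
    return apply_standard_condition(model)
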