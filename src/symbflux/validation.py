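"""Model-quality validation battery.

Three checks mirror the consistency section of the community model test
suites:

* **mass / charge balance** — per internal reaction, the net elemental and
  charge residuals must vanish; generic side groups (pseudo-element ``R``)
  must cancel like any other element;
* **stoichiometric consistency** — a strictly positive metabolite mass
  vector ``m`` with ``S_int' m = 0`` must exist (solved as a linear
  feasibility problem with ``m >= 1``); when it does not, a maximal
  conserved subset is found and its complement reported as the unconserved
  witness set;
* **energy-generating cycles (EGC)** — with every exchange closed, an added
  ATP dissipation reaction must not be able to carry flux; a nonzero
  optimum exposes an internal loop that creates energy from nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import yaml
from scipy.optimize import linprog

from .formulas import ElementalFormula
from .model import MetabolicModel, ModelError, ReactionRecord

ZERO_TOL = 1e-6


@dataclass
class ReactionBalance:
    reaction_id: str
    element_residuals: Dict[str, float]
    charge_residual: float
    checked: bool  # False when a participant formula is unknown

    @property
    def balanced(self) -> bool:
        if not self.checked:
            return False
        if abs(self.charge_residual) > ZERO_TOL:
            return False
        return all(abs(r) <= ZERO_TOL for r in self.element_residuals.values())


@dataclass
class EGCReport:
    detected: bool
    dissipation_flux: float
    witness_reactions: List[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    balances: List[ReactionBalance] = field(default_factory=list)
    consistent: Optional[bool] = None
    unconserved_metabolites: List[str] = field(default_factory=list)
    egc: Optional[EGCReport] = None
    warnings: List[str] = field(default_factory=list)

    @property
    def unbalanced_reactions(self) -> List[str]:
        return [b.reaction_id for b in self.balances if b.checked and not b.balanced]

    @property
    def unchecked_reactions(self) -> List[str]:
        return [b.reaction_id for b in self.balances if not b.checked]

    @property
    def passed(self) -> bool:
        if self.unbalanced_reactions:
            return False
        if self.consistent is False:
            return False
        if self.egc is not None and self.egc.detected:
            return False
        return True

    def residuals_table(self) -> List[Tuple[str, str, float]]:
        rows = []
        for bal in self.balances:
            for element, residual in sorted(bal.element_residuals.items()):
                if abs(residual) > ZERO_TOL:
                    rows.append((bal.reaction_id, element, residual))
            if abs(bal.charge_residual) > ZERO_TOL:
                rows.append((bal.reaction_id, "charge", bal.charge_residual))
        return rows

    def write_tsv(self, path: Union[str, Path]) -> None:
        lines = ["reaction_id\telement\tresidual"]
        for rxn, element, residual in self.residuals_table():
            lines.append(f"{rxn}\t{element}\t{residual:.6g}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_summary_yaml(self, path: Union[str, Path]) -> None:
        doc = {
            "balanced": not self.unbalanced_reactions,
            "unbalanced_reactions": self.unbalanced_reactions,
            "unchecked_reactions": self.unchecked_reactions,
            "stoichiometrically_consistent": self.consistent,
            "unconserved_metabolites": self.unconserved_metabolites,
            "egc_detected": None if self.egc is None else self.egc.detected,
            "egc_witness": [] if self.egc is None else self.egc.witness_reactions,
            "warnings": self.warnings,
            "passed": self.passed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _is_balance_exempt(model: MetabolicModel, rxn: ReactionRecord) -> bool:
    # exchanges (and the objective sink) move mass across the system
    # boundary and are not expected to balance
    return rxn.kind == "exchange" or rxn.id == model.objective_id and len(rxn.stoichiometry) == 1


def check_mass_charge_balance(model: MetabolicModel) -> ValidationReport:
    """Elemental and charge residuals of every internal reaction.

    A reaction touching a metabolite with unknown formula is marked
    unchecked (not balanced); exchange reactions and single-metabolite
    sinks are exempt.
    """
    report = ValidationReport()
    for rxn in model.reactions:
        if _is_balance_exempt(model, rxn):
            continue
        mets = [model.metabolite(m) for m in rxn.stoichiometry]
        if any(m.formula.is_unknown for m in mets):
            report.balances.append(
                ReactionBalance(rxn.id, {}, 0.0, checked=False)
            )
            continue
        residuals: Dict[str, float] = {}
        charge = 0.0
        for met in mets:
            coeff = rxn.stoichiometry[met.id]
            charge += coeff * met.charge
            for element, count in met.formula.counts.items():
                residuals[element] = residuals.get(element, 0.0) + coeff * count
        residuals = {el: r for el, r in residuals.items() if abs(r) > 1e-12}
        report.balances.append(
            ReactionBalance(rxn.id, residuals, charge, checked=True)
        )
    return report


def check_stoichiometric_consistency(
    model: MetabolicModel,
) -> Tuple[bool, List[str]]:
    """Existence of a strictly positive conserved mass vector.

    Internal reactions only (exchanges and single-metabolite sinks
    excluded).  Feasibility of ``S' m = 0, m >= 1`` is scale-invariant and
    closed; on failure, an auxiliary LP maximizes the number of conserved
    metabolites (``max sum k, k <= m, 0 <= k <= 1, m >= 0``) and returns
    the minimal complement as the unconserved witness set.
    """
    internal = [
        r for r in model.reactions if not _is_balance_exempt(model, r)
    ]
    if not internal:
        return True, []
    S = model.stoichiometric_matrix([r.id for r in internal])
    n_mets = S.shape[0]
    # feasibility: S^T m = 0, m >= 1
    res = linprog(
        np.zeros(n_mets),
        A_eq=S.T,
        b_eq=np.zeros(S.shape[1]),
        bounds=[(1.0, None)] * n_mets,
        method="highs",
    )
    if res.status == 0:
        return True, []
    # witness: maximize number of conserved metabolites
    # variables [m (n), k (n)]; k - m <= 0; maximize sum k
    A_ub = np.hstack([-np.eye(n_mets), np.eye(n_mets)])
    b_ub = np.zeros(n_mets)
    A_eq = np.hstack([S.T, np.zeros((S.shape[1], n_mets))])
    res2 = linprog(
        np.concatenate([np.zeros(n_mets), -np.ones(n_mets)]),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[1]),
        bounds=[(0.0, None)] * n_mets + [(0.0, 1.0)] * n_mets,
        method="highs",
    )
    met_ids = model.metabolite_ids
    if res2.status != 0:
        return False, list(met_ids)
    m = res2.x[:n_mets]
    witnesses = [met_ids[i] for i in range(n_mets) if m[i] < ZERO_TOL]
    return False, witnesses


@dataclass
class DissipationSpec:
    """Names of the energy-couple metabolites for EGC detection.

    The default is the ATP couple: ATP + H2O -> ADP + Pi (an explicit
    proton id may be supplied for charged-formula models).
    """

    atp: str = "atp_c"
    adp: str = "adp_c"
    h2o: str = "h2o_c"
    pi: str = "pi_c"
    h: Optional[str] = None


def detect_energy_generating_cycles(
    model: MetabolicModel, dissipation: Optional[DissipationSpec] = None
) -> EGCReport:
    """Probe for internal loops that generate ATP with all exchanges closed.

    Adds the dissipation reaction, closes every exchange to [0, 0], and
    maximizes dissipation flux; any optimum above tolerance is an EGC and
    the nonzero-flux reactions are returned as the witness cycle.
    """
    spec = dissipation or DissipationSpec()
    probe = model.copy()
    for name in ("atp", "adp", "h2o", "pi"):
        met_id = getattr(spec, name)
        if not probe.has_metabolite(met_id):
            raise ModelError(
                f"EGC dissipation metabolite {met_id!r} ({name}) absent from model"
            )
    stoich = {spec.atp: -1.0, spec.h2o: -1.0, spec.adp: 1.0, spec.pi: 1.0}
    if spec.h is not None:
        stoich[spec.h] = stoich.get(spec.h, 0.0) + 1.0
    for rxn in probe.reactions:
        if rxn.kind == "exchange":
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    dissipation_id = "EGC_DISSIPATION_PROBE"
    probe.reactions.append(
        ReactionRecord(
            id=dissipation_id,
            name="ATP dissipation probe",
            stoichiometry=stoich,
            lower_bound=0.0,
            upper_bound=1000.0,
            kind="internal",
        )
    )
    probe.objective_id = dissipation_id
    probe.validate_structure()
    from .lp import solve_fba

    solution = solve_fba(probe)
    if not solution.optimal:
        raise ModelError(f"EGC probe LP was {solution.status}")
    detected = solution.objective_value > ZERO_TOL
    witness = (
        sorted(
            r
            for r, v in solution.fluxes.items()
            if abs(v) > ZERO_TOL and r != dissipation_id
        )
        if detected
        else []
    )
    return EGCReport(
        detected=detected,
        dissipation_flux=float(solution.objective_value),
        witness_reactions=witness,
    )


def validate_model(
    model: MetabolicModel, dissipation: Optional[DissipationSpec] = None
) -> ValidationReport:
    """Run the full battery and aggregate one report."""
    report = check_mass_charge_balance(model)
    internal = [r for r in model.reactions if not _is_balance_exempt(model, r)]
    if internal:
        report.consistent, report.unconserved_metabolites = (
            check_stoichiometric_consistency(model)
        )
    else:
        report.consistent = True
        report.warnings.append("no internal reactions; trivially consistent")
    try:
        report.egc = detect_energy_generating_cycles(model, dissipation)
    except ModelError as exc:
        report.warnings.append(f"EGC check skipped: {exc}")
    return report
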