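"""Stoichiometric model containers.

A :class:`MetabolicModel` is the in-memory form of a genome-scale (or toy)
reconstruction: metabolites with formulas and charges, reactions with
bounds and gene-protein-reaction (GPR) strings, and an objective reaction.
It is the single source of the stoichiometric matrix used by every solver
in this package.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formulas import ElementalFormula

DEFAULT_BOUND = 1000.0

REACTION_KINDS = ("internal", "transport", "exchange", "objective")


class ModelError(ValueError):
    """Raised when a model violates its structural invariants."""


@dataclass
class MetaboliteRecord:
    id: str
    name: str = ""
    formula: ElementalFormula = field(default_factory=ElementalFormula)
    charge: int = 0
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class ReactionRecord:
    """One reaction: stoichiometry, flux bounds and a GPR rule.

    Negative stoichiometric coefficients are consumed, positive produced.
    Bounds are in mmol gDW^-1 h^-1.
    """

    id: str
    stoichiometry: Dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    kind: str = "internal"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.kind not in REACTION_KINDS:
            raise ModelError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "exchange" and len(self.stoichiometry) != 1:
            raise ModelError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite"
            )

    @property
    def bounds(self) -> Tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """A full stoichiometric model.

    Invariants (enforced by :meth:`validate_structure`, called on
    construction): every stoichiometry key resolves to a metabolite, every
    gene named in a GPR appears in ``genes``, and ``objective_id`` resolves
    to a reaction.
    """

    metabolites: List[MetaboliteRecord] = field(default_factory=list)
    reactions: List[ReactionRecord] = field(default_factory=list)
    genes: List[str] = field(default_factory=list)
    objective_id: Optional[str] = None
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate_structure()

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> MetaboliteRecord:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise ModelError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> ReactionRecord:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise ModelError(f"unknown reaction {rxn_id!r}") from None

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @property
    def objective(self) -> ReactionRecord:
        if self.objective_id is None:
            raise ModelError("model has no objective reaction")
        return self.reaction(self.objective_id)

    # -- structure -------------------------------------------------------
    def validate_structure(self) -> None:
        from .gpr import parse_gpr  # deferred: gpr imports nothing from here

        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelError(f"duplicate reaction ids: {dupes}")
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        gene_set = set(self.genes)
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                    )
            if rxn.gpr:
                for gene in parse_gpr(rxn.gpr).genes():
                    if gene not in gene_set:
                        raise ModelError(
                            f"reaction {rxn.id!r} GPR references undeclared gene {gene!r}"
                        )
        if self.objective_id is not None and self.objective_id not in self._rxn_index:
            raise ModelError(f"objective {self.objective_id!r} is not a reaction")

    # -- matrix ----------------------------------------------------------
    def stoichiometric_matrix(
        self, reactions: Optional[Sequence[str]] = None
    ) -> np.ndarray:
        """Dense S (metabolites x reactions), columns in model file order."""
        rxns = (
            self.reactions
            if reactions is None
            else [self.reaction(r) for r in reactions]
        )
        met_pos = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(rxns)))
        for j, rxn in enumerate(rxns):
            for met_id, coeff in rxn.stoichiometry.items():
                S[met_pos[met_id], j] = coeff
        return S

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    # -- convenience -----------------------------------------------------
    def exchanges(self) -> List[ReactionRecord]:
        return [r for r in self.reactions if r.kind == "exchange"]

    def internal_reactions(self) -> List[ReactionRecord]:
        """Reactions participating in internal mass balance (non-exchange)."""
        return [r for r in self.reactions if r.kind != "exchange"]

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def with_bounds(self, bounds: Dict[str, Tuple[float, float]]) -> "MetabolicModel":
        """Copy with the given reactions' bounds replaced."""
        new = self.copy()
        for rxn_id, (lb, ub) in bounds.items():
            rxn = new.reaction(rxn_id)
            if lb > ub:
                raise ModelError(f"reaction {rxn_id!r}: lb {lb} > ub {ub}")
            rxn.lower_bound = lb
            rxn.upper_bound = ub
        return new

    def equal(self, other: "MetabolicModel") -> bool:
        """Field-by-field equality (used by round-trip tests)."""
        if self.id != other.id or self.objective_id != other.objective_id:
            return False
        if sorted(self.genes) != sorted(other.genes):
            return False
        if [m.id for m in self.metabolites] != [m.id for m in other.metabolites]:
            return False
        if [r.id for r in self.reactions] != [r.id for r in other.reactions]:
            return False
        for a, b in zip(self.metabolites, other.metabolites):
            if (a.name, a.charge, a.compartment) != (b.name, b.charge, b.compartment):
                return False
            if str(a.formula) != str(b.formula):
                return False
        from .gpr import parse_gpr

        for a, b in zip(self.reactions, other.reactions):
            if (a.name, a.kind) != (b.name, b.kind):
                return False
            if parse_gpr(a.gpr).to_string() != parse_gpr(b.gpr).to_string():
                return False
            if abs(a.lower_bound - b.lower_bound) > 1e-9:
                return False
            if abs(a.upper_bound - b.upper_bound) > 1e-9:
                return False
            if set(a.stoichiometry) != set(b.stoichiometry):
                return False
            for met, coeff in a.stoichiometry.items():
                if abs(coeff - b.stoichiometry[met]) > 1e-9:
                    return False
        return True


def make_exchange(met_id: str, lb: float = -DEFAULT_BOUND, ub: float = DEFAULT_BOUND,
                  rxn_id: Optional[str] = None) -> ReactionRecord:
    """Exchange written as ``met ->`` so uptake is a negative flux."""
    return ReactionRecord(
        id=rxn_id or f"EX_{met_id}",
        name=f"{met_id} exchange",
        stoichiometry={met_id: -1.0},
        lower_bound=lb,
        upper_bound=ub,
        kind="exchange",
    )
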