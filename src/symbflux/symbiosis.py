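"""Symbiosis objective reaction and yield accounting.

Nitrogen-fixing bacteroids do not grow, so the usual biomass objective is
replaced by a *symbiosis reaction*: a pseudo-reaction consuming, in fixed
proportion, everything an effective symbiosis demands of the bacteroid
(carbon-storage polymers, exported amino acids, fixed ammonia, cofactors).
The composition is given in mmol of component per g of symbiosis product
and is rescaled so the pseudo-product has a molecular weight of exactly
1 g/mmol — one flux unit through the objective then equals one gram of
symbiotic output per gDW per hour, which makes yields comparable across
reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

from .formulas import ElementalFormula, weighted_sum
from .lp import FluxSolution
from .model import MetabolicModel, ModelError, ReactionRecord

SYMBIOSIS_PRODUCT_ID = "symbiosis_product_c"
SYMBIOSIS_REACTION_ID = "SYMBIOSIS"
SYMBIOSIS_SINK_ID = "SK_symbiosis_product"


class CompositionError(ValueError):
    """Raised for invalid symbiosis compositions."""


@dataclass
class SymbiosisComposition:
    """Component id -> mmol per g of symbiosis product, with formulas.

    ``coefficients`` are strictly positive; component formulas must be
    known so the product's molecular weight is computable.
    """

    coefficients: Dict[str, float]
    formulas: Dict[str, ElementalFormula]
    charges: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise CompositionError("composition must have at least one component")
        for comp, coeff in self.coefficients.items():
            if coeff <= 0:
                raise CompositionError(f"component {comp!r} coefficient must be > 0")
            if comp not in self.formulas:
                raise CompositionError(f"component {comp!r} has no formula")

    def product_molecular_weight(self) -> float:
        """Sum of coefficient x component MW, in g/mmol."""
        for comp, formula in self.formulas.items():
            if comp in self.coefficients and formula.is_unknown:
                raise CompositionError(f"component {comp!r} formula unknown")
        return sum(
            coeff * self.formulas[comp].molecular_weight()
            for comp, coeff in self.coefficients.items()
        )

    def product_formula(self) -> ElementalFormula:
        return weighted_sum(
            (self.formulas[comp], coeff) for comp, coeff in self.coefficients.items()
        )

    def product_charge(self) -> float:
        return sum(
            coeff * self.charges.get(comp, 0)
            for comp, coeff in self.coefficients.items()
        )

    # -- TSV interface ---------------------------------------------------
    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "SymbiosisComposition":
        """Read ``component_id  coefficient_mmol_per_g  formula  charge``."""
        coeffs: Dict[str, float] = {}
        formulas: Dict[str, ElementalFormula] = {}
        charges: Dict[str, int] = {}
        lines = Path(path).read_text().splitlines()
        for i, line in enumerate(lines):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if i == 0 and fields[0] == "component_id":
                continue
            if len(fields) < 3:
                raise CompositionError(f"{path}:{i + 1}: expected >= 3 columns")
            comp = fields[0]
            coeffs[comp] = float(fields[1])
            formulas[comp] = ElementalFormula.parse(fields[2])
            charges[comp] = int(fields[3]) if len(fields) > 3 and fields[3] else 0
        return cls(coefficients=coeffs, formulas=formulas, charges=charges)

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = ["component_id\tcoefficient_mmol_per_g\tformula\tcharge"]
        for comp in self.coefficients:
            lines.append(
                f"{comp}\t{self.coefficients[comp]:.10g}\t"
                f"{self.formulas[comp]}\t{self.charges.get(comp, 0)}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def scale_to_unit_molecular_weight(
    composition: SymbiosisComposition,
) -> SymbiosisComposition:
    """Rescale all coefficients by one scalar so the product MW is exactly
    1 g/mmol; relative proportions are preserved."""
    mw = composition.product_molecular_weight()
    if mw <= 0:
        raise CompositionError("composition has zero molecular weight")
    factor = 1.0 / mw
    return SymbiosisComposition(
        coefficients={c: v * factor for c, v in composition.coefficients.items()},
        formulas=dict(composition.formulas),
        charges=dict(composition.charges),
    )


def build_symbiosis_reaction(
    model: MetabolicModel,
    composition: SymbiosisComposition,
    scale: bool = True,
) -> MetabolicModel:
    """Attach the symbiosis objective to a model.

    Adds the pseudo-metabolite ``symbiosis_product_c`` carrying the
    coefficient-weighted elemental sum of the components, the symbiosis
    reaction (components -> 1 product) and the product sink, then sets the
    sink as the model objective.  The reaction is elementally balanced by
    construction.
    """
    if scale:
        composition = scale_to_unit_molecular_weight(composition)
    missing = [c for c in composition.coefficients if not model.has_metabolite(c)]
    if missing:
        raise ModelError(f"composition components absent from model: {missing}")
    new = model.copy()
    from .model import MetaboliteRecord

    new.metabolites.append(
        MetaboliteRecord(
            id=SYMBIOSIS_PRODUCT_ID,
            name="symbiosis product",
            formula=composition.product_formula(),
            charge=int(round(composition.product_charge())),
            compartment="c",
        )
    )
    stoich = {c: -v for c, v in composition.coefficients.items()}
    stoich[SYMBIOSIS_PRODUCT_ID] = 1.0
    new.reactions.append(
        ReactionRecord(
            id=SYMBIOSIS_REACTION_ID,
            name="symbiosis objective reaction",
            stoichiometry=stoich,
            lower_bound=0.0,
            upper_bound=1000.0,
            kind="internal",
        )
    )
    new.reactions.append(
        ReactionRecord(
            id=SYMBIOSIS_SINK_ID,
            name="symbiosis product sink",
            stoichiometry={SYMBIOSIS_PRODUCT_ID: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            kind="exchange",
        )
    )
    new.objective_id = SYMBIOSIS_SINK_ID
    new.validate_structure()
    return new


def rescale_for_cross_model_comparison(
    models: List[MetabolicModel],
) -> List[MetabolicModel]:
    """Rescale each model's symbiosis reaction so one flux unit moves the
    same total mass (1 g) in every model, making yields comparable."""
    out = []
    for model in models:
        if not model.has_reaction(SYMBIOSIS_REACTION_ID):
            raise ModelError(f"model {model.id!r} lacks a symbiosis reaction")
        new = model.copy()
        rxn = new.reaction(SYMBIOSIS_REACTION_ID)
        mass = 0.0
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff >= 0:
                continue
            formula = new.metabolite(met_id).formula
            if formula.is_unknown:
                raise ModelError(
                    f"model {model.id!r}: component {met_id!r} formula unknown"
                )
            mass += -coeff * formula.molecular_weight()
        if mass <= 0:
            raise ModelError(f"model {model.id!r}: symbiosis reaction moves no mass")
        factor = 1.0 / mass
        rxn.stoichiometry = {
            m: (c * factor if c < 0 else c) for m, c in rxn.stoichiometry.items()
        }
        product_ids = [m for m, c in rxn.stoichiometry.items() if c > 0]
        for met_id in product_ids:
            met = new.metabolite(met_id)
            met.formula = met.formula.scaled(factor)
        out.append(new)
    return out


@dataclass
class YieldSummary:
    """Symbiosis yields on carbon and nitrogen bases.

    ``carbon_yield``: g product per mmol of carbon taken up;
    ``nitrogen_yield``: g product per mmol of nitrogen taken up;
    ``c_to_n``: their ratio (dimensionless);
    ``fixed_nh3_export``: net ammonia flux to the plant, mmol gDW^-1 h^-1.
    """

    carbon_yield: float
    nitrogen_yield: float
    c_to_n: float
    carbon_uptake: float
    nitrogen_uptake: float
    objective_flux: float
    fixed_nh3_export: float = float("nan")


def fixed_nitrogen_export(
    model: MetabolicModel,
    solution: FluxSolution,
    nh3_metabolite: str = "nh3_c",
    nh3_exchange_id: str = "EX_nh3_e",
) -> float:
    """Ammonia delivered to the plant, mmol gDW^-1 h^-1.

    Counts both routes: ammonia consumed as a symbiosis-product component
    and free ammonia secreted through the exchange.
    """
    total = 0.0
    if model.has_reaction(SYMBIOSIS_REACTION_ID):
        symb = model.reaction(SYMBIOSIS_REACTION_ID)
        coeff = symb.stoichiometry.get(nh3_metabolite, 0.0)
        if coeff < 0:
            total += -coeff * solution.fluxes.get(SYMBIOSIS_REACTION_ID, 0.0)
    if model.has_reaction(nh3_exchange_id):
        total += max(solution.fluxes.get(nh3_exchange_id, 0.0), 0.0)
    return total


def compute_symbiosis_yields(
    model: MetabolicModel,
    solution: FluxSolution,
    nh3_exchange_id: Optional[str] = None,
) -> YieldSummary:
    """Yields from an optimal flux solution.

    Uptakes are exchange reactions with negative flux; the carbon (or
    nitrogen) basis is the summed |flux| x atom count over all uptakes.
    Secreted carbon is deliberately not subtracted from the basis: the
    yield is per mmol taken up.
    """
    if not solution.optimal:
        raise ModelError(f"yields require an optimal solution, got {solution.status}")
    carbon = 0.0
    nitrogen = 0.0
    for rxn in model.exchanges():
        flux = solution.fluxes.get(rxn.id, 0.0)
        if flux >= -1e-9:
            continue
        met = model.metabolite(next(iter(rxn.stoichiometry)))
        if met.formula.is_unknown:
            raise ModelError(
                f"uptake {rxn.id!r}: metabolite {met.id!r} formula unknown"
            )
        carbon += -flux * met.formula["C"]
        nitrogen += -flux * met.formula["N"]
    if carbon <= 1e-9:
        raise ModelError("undefined yield: zero carbon uptake")
    if nitrogen <= 1e-9:
        raise ModelError("undefined yield: zero nitrogen uptake")
    obj = solution.objective_value
    carbon_yield = obj / carbon
    nitrogen_yield = obj / nitrogen
    nh3_export = float("nan")
    if nh3_exchange_id is not None and model.has_reaction(nh3_exchange_id):
        nh3_export = solution.fluxes.get(nh3_exchange_id, 0.0)
    return YieldSummary(
        carbon_yield=carbon_yield,
        nitrogen_yield=nitrogen_yield,
        c_to_n=carbon_yield / nitrogen_yield,
        carbon_uptake=carbon,
        nitrogen_uptake=nitrogen,
        objective_flux=obj,
        fixed_nh3_export=nh3_export,
    )
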