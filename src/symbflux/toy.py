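"""Synthetic toy bacteroid network and two-condition expression profiles.

The generator emits a small (~45-reaction) but fully mass- and
charge-balanced bacteroid model with the canonical architecture of
rhizobial symbiosis: C4-dicarboxylates (malate, succinate) from the host
plant feed the TCA cycle; oxidative phosphorylation under microaerobic
conditions and succinyl-CoA synthetase supply ATP; nitrogenase reduces N2
to ammonia at a configurable ATP cost; PHB and glycogen act as
carbon-storage sinks; ammonia, alanine and aspartate can be exported to
the plant; and a balanced symbiosis pseudo-reaction aggregates the
symbiotic demands.  Every enzymatic reaction carries a GPR over synthetic
gene ids of the form ``<pathway>__<gene>``, including configurable
isozyme (OR) pairs and fixed enzyme-complex (AND) groups.

All metabolites use neutral whole-molecule formulas (charge 0), so
elemental balance implies charge balance; the oxidative-phosphorylation
and nitrogenase reactions are lumped couples, each balanced exactly.  The
network is a test fixture for the analysis pipeline, not a biological
claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
import yaml

from .formulas import ElementalFormula
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    MetaboliteRecord,
    ModelError,
    ReactionRecord,
    make_exchange,
)
from .symbiosis import SymbiosisComposition, build_symbiosis_reaction

# -- network tables ----------------------------------------------------

_FORMULAS = {
    "mal__L": "C4H6O5",
    "succ": "C4H6O4",
    "glu__L": "C5H9NO4",
    "inost": "C6H12O6",
    "o2": "O2",
    "n2": "N2",
    "nh3": "NH3",
    "ala__L": "C3H7NO2",
    "asp__L": "C4H7NO4",
    "co2": "CO2",
    "h2o": "H2O",
    "h2": "H2",
    "pi": "H3PO4",
    "atp": "C10H16N5O13P3",
    "adp": "C10H15N5O10P2",
    "nad": "C21H27N7O14P2",
    "nadh": "C21H29N7O14P2",
    "coa": "C21H36N7O16P3S",
    "accoa": "C23H38N7O17P3S",
    "oaa": "C4H4O5",
    "pyr": "C3H4O3",
    "cit": "C6H8O7",
    "akg": "C5H6O5",
    "succoa": "C25H40N7O19P3S",
    "fum": "C4H4O4",
    "phb": "C4H6O2",
    "glycogen": "C6H10O5",
}

# species that exist in the extracellular / plant-interface compartment
_EXTERNAL = [
    "mal__L", "succ", "glu__L", "inost", "o2", "n2",
    "nh3", "ala__L", "asp__L", "co2", "h2o", "h2", "pi",
]

REACTION_PATHWAY = {
    "MALt": "transport", "SUCCt": "transport", "GLUt": "transport",
    "INOSTt": "transport", "O2t": "transport", "N2t": "transport",
    "NH3t": "transport", "ALAt": "transport", "ASPt": "transport",
    "CO2t": "transport", "H2Ot": "transport", "H2t": "transport",
    "PIt": "transport",
    "MDH": "tca", "ME": "tca", "PDH": "tca", "CS": "tca", "ICDH": "tca",
    "AKGDH": "tca", "SUCOAS": "tca", "SDH": "tca", "FUM": "tca",
    "CYTOX": "oxphos", "NITROGENASE": "nitrogenase", "ATPM": "maintenance",
    "HYD": "ferm",
    "PHBS": "storage", "GLYCS": "storage",
    "ALAS": "amino", "ASPTA": "amino", "GDH": "amino",
    "INOSD": "inositol",
}

# reactions eligible for an additional isozyme (OR) partner, in order
_ISOZYME_CANDIDATES = ["ME", "PHBS", "GLYCS", "ALAS", "GDH"]

# toy symbiosis composition: mmol component per g product, pre-scaling.
# PHB and glycogen are the bacteroid storage polymers, glutamate the
# amino-acid demand, ammonia the fixed nitrogen delivered to the plant,
# phosphate a proxy for the cofactor/ion demand.
TOY_COMPOSITION_RAW = {
    "phb_c": 4.0,
    "glycogen_c": 1.5,
    "glu__L_c": 0.8,
    "nh3_c": 8.0,
    "pi_c": 0.3,
}


@dataclass
class ToyBacteroidParams:
    """Knobs of the toy generator.

    ``nitrogenase_atp_per_n2`` is the ATP cost of one N2 reduction (the
    canonical nitrogenase stoichiometry spends 16); ``capacities`` multiply
    the default upper bound of whole pathways; ``n_isozyme_pairs`` adds an
    OR-partner gene to that many eligible reactions.
    """

    include_inositol_pathway: bool = True
    n_isozyme_pairs: int = 2
    nitrogenase_atp_per_n2: float = 16.0
    capacities: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nitrogenase_atp_per_n2 <= 0:
            raise ValueError("nitrogenase_atp_per_n2 must be > 0")
        if not 0 <= self.n_isozyme_pairs <= len(_ISOZYME_CANDIDATES):
            raise ValueError(
                f"n_isozyme_pairs must be in [0, {len(_ISOZYME_CANDIDATES)}]"
            )
        for pathway, scalar in self.capacities.items():
            if scalar <= 0:
                raise ValueError(f"capacity scalar for {pathway!r} must be > 0")


@dataclass
class StandardCondition:
    """The standard microaerobic nitrogen-fixation condition.

    Uptake rates in mmol gDW^-1 h^-1: malate 1.44 and succinate 1.38
    (the C4-dicarboxylate supply from the host), oxygen capped at 1.26 to
    mimic the microaerobic nodule interior, non-growth ATP maintenance
    fixed at 4, and unlimited uptake (bound 1000) for the free cofactor
    and ion exchanges.  Glutamate and inositol uptakes are secondary
    carbon/nitrogen sources whose literature values are configuration
    inputs.
    """

    malate_uptake: float = 1.44
    succinate_uptake: float = 1.38
    o2_uptake: float = 1.26
    glutamate_uptake: float = 0.18
    inositol_uptake: float = 0.05
    atp_maintenance: Optional[float] = 4.0
    unlimited_uptake: float = DEFAULT_BOUND
    free_uptake_exchanges: Tuple[str, ...] = ("EX_n2_e", "EX_pi_e", "EX_h2o_e")
    export_only_exchanges: Tuple[str, ...] = (
        "EX_nh3_e", "EX_ala__L_e", "EX_asp__L_e", "EX_co2_e", "EX_h2_e",
    )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "StandardCondition":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in (
            "malate_uptake", "succinate_uptake", "o2_uptake",
            "glutamate_uptake", "inositol_uptake", "atp_maintenance",
            "unlimited_uptake",
        ):
            if key in doc:
                kwargs[key] = doc[key]
        for key in ("free_uptake_exchanges", "export_only_exchanges"):
            if key in doc:
                kwargs[key] = tuple(doc[key])
        return cls(**kwargs)

    def to_yaml(self, path: Union[str, Path]) -> None:
        doc = {
            "malate_uptake": self.malate_uptake,
            "succinate_uptake": self.succinate_uptake,
            "o2_uptake": self.o2_uptake,
            "glutamate_uptake": self.glutamate_uptake,
            "inositol_uptake": self.inositol_uptake,
            "atp_maintenance": self.atp_maintenance,
            "unlimited_uptake": self.unlimited_uptake,
            "free_uptake_exchanges": list(self.free_uptake_exchanges),
            "export_only_exchanges": list(self.export_only_exchanges),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _met(short: str, compartment: str) -> MetaboliteRecord:
    return MetaboliteRecord(
        id=f"{short}_{compartment}",
        name=short,
        formula=ElementalFormula.parse(_FORMULAS[short]),
        charge=0,
        compartment=compartment,
    )


def toy_composition() -> SymbiosisComposition:
    """The documented toy symbiosis composition (unscaled)."""
    return SymbiosisComposition(
        coefficients=dict(TOY_COMPOSITION_RAW),
        formulas={
            comp: ElementalFormula.parse(_FORMULAS[comp.rsplit("_", 1)[0]])
            for comp in TOY_COMPOSITION_RAW
        },
        charges={comp: 0 for comp in TOY_COMPOSITION_RAW},
    )


def generate_toy_bacteroid_model(
    params: Optional[ToyBacteroidParams] = None,
    check: bool = True,
) -> Tuple[MetabolicModel, SymbiosisComposition]:
    """Build the toy bacteroid model with its symbiosis objective attached.

    With ``check`` (the default) the standard condition is applied to a
    copy and solved; a non-positive optimum raises with a diagnosis, so a
    bad parameter combination fails at generation time rather than deep in
    an analysis.
    """
    params = params or ToyBacteroidParams()
    p = params.nitrogenase_atp_per_n2

    cytosol = sorted(set(_FORMULAS))
    metabolites = [_met(s, "c") for s in cytosol if s not in ("phb", "glycogen")]
    metabolites += [_met(s, "c") for s in ("phb", "glycogen")]
    metabolites += [_met(s, "e") for s in _EXTERNAL]

    def rxn(rid, stoich, gpr="", lb=0.0, ub=DEFAULT_BOUND, kind="internal", name=""):
        return ReactionRecord(
            id=rid, name=name or rid, stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gpr=gpr, kind=kind,
        )

    reactions: List[ReactionRecord] = []
    # -- transport (uptake written e -> c, export c -> e) ---------------
    uptake = [
        ("MALt", "mal__L", "transport__dctA"),
        ("SUCCt", "succ", "transport__dctA"),
        ("GLUt", "glu__L", "transport__gltJ"),
        ("O2t", "o2", ""),
        ("N2t", "n2", ""),
        ("PIt", "pi", "transport__pstA and transport__pstC"),
    ]
    if params.include_inositol_pathway:
        uptake.append(("INOSTt", "inost", "transport__iolT"))
    for rid, short, gpr in uptake:
        reactions.append(
            rxn(rid, {f"{short}_e": -1.0, f"{short}_c": 1.0}, gpr, kind="transport")
        )
    export = [
        ("NH3t", "nh3", "transport__amtB"),
        ("ALAt", "ala__L", "transport__alaE"),
        ("ASPt", "asp__L", "transport__aspT"),
        ("CO2t", "co2", ""),
        ("H2t", "h2", ""),
    ]
    for rid, short, gpr in export:
        reactions.append(
            rxn(rid, {f"{short}_c": -1.0, f"{short}_e": 1.0}, gpr, kind="transport")
        )
    reactions.append(
        rxn("H2Ot", {"h2o_c": -1.0, "h2o_e": 1.0}, lb=-DEFAULT_BOUND, kind="transport")
    )

    # -- central carbon metabolism --------------------------------------
    reactions += [
        rxn("MDH", {"mal__L_c": -1, "nad_c": -1, "oaa_c": 1, "nadh_c": 1},
            "tca__mdh", name="malate dehydrogenase"),
        rxn("ME", {"mal__L_c": -1, "nad_c": -1, "pyr_c": 1, "co2_c": 1, "nadh_c": 1},
            "tca__maeB", name="malic enzyme"),
        rxn("PDH", {"pyr_c": -1, "coa_c": -1, "nad_c": -1,
                    "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
            "tca__pdhA and tca__pdhB", name="pyruvate dehydrogenase"),
        rxn("CS", {"oaa_c": -1, "accoa_c": -1, "h2o_c": -1, "cit_c": 1, "coa_c": 1},
            "tca__gltA", name="citrate synthase"),
        rxn("ICDH", {"cit_c": -1, "nad_c": -1, "akg_c": 1, "co2_c": 1, "nadh_c": 1},
            "tca__icd", name="isocitrate dehydrogenase (lumped with aconitase)"),
        rxn("AKGDH", {"akg_c": -1, "coa_c": -1, "nad_c": -1,
                      "succoa_c": 1, "co2_c": 1, "nadh_c": 1},
            "tca__sucA and tca__sucB", name="2-oxoglutarate dehydrogenase"),
        rxn("SUCOAS", {"succoa_c": -1, "adp_c": -1, "pi_c": -1,
                       "succ_c": 1, "atp_c": 1, "coa_c": 1},
            "tca__sucC and tca__sucD", name="succinyl-CoA synthetase"),
        rxn("SDH", {"succ_c": -1, "nad_c": -1, "fum_c": 1, "nadh_c": 1},
            "tca__sdhA and tca__sdhB", name="succinate dehydrogenase (lumped)"),
        rxn("FUM", {"fum_c": -1, "h2o_c": -1, "mal__L_c": 1},
            "tca__fumC", name="fumarase"),
    ]
    # -- energy ----------------------------------------------------------
    reactions += [
        rxn("CYTOX", {"nadh_c": -1, "o2_c": -0.5, "adp_c": -3, "pi_c": -3,
                      "nad_c": 1, "h2o_c": 4, "atp_c": 3},
            "oxphos__ctaC and oxphos__ctaD",
            name="cytochrome oxidase (lumped oxidative phosphorylation, "
                 "cbb3-type P/O 3)"),
        rxn("NITROGENASE",
            {"n2_c": -1, "nadh_c": -4, "atp_c": -p, "h2o_c": -p,
             "nh3_c": 2, "h2_c": 1, "nad_c": 4, "adp_c": p, "pi_c": p},
            "nitrogenase__nifH and nitrogenase__nifD and nitrogenase__nifK",
            name=f"nitrogenase ({p:g} ATP per N2)"),
        rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
            name="non-growth ATP maintenance"),
        rxn("HYD", {"nadh_c": -1, "nad_c": 1, "h2_c": 1},
            "ferm__hoxG",
            name="NADH-dependent hydrogen evolution (fermentative electron valve)"),
    ]
    # -- storage and amino acids -----------------------------------------
    reactions += [
        rxn("PHBS", {"accoa_c": -2, "nadh_c": -1, "phb_c": 1, "coa_c": 2, "nad_c": 1},
            "storage__phbB", name="PHB synthesis (per monomer)"),
        rxn("GLYCS", {"pyr_c": -2, "nadh_c": -2, "atp_c": -4, "h2o_c": -3,
                      "glycogen_c": 1, "nad_c": 2, "adp_c": 4, "pi_c": 4},
            "storage__glgA", name="glycogen synthesis (lumped gluconeogenesis)"),
        rxn("ALAS", {"pyr_c": -1, "nh3_c": -1, "nadh_c": -1,
                     "ala__L_c": 1, "h2o_c": 1, "nad_c": 1},
            "amino__alaD", name="alanine dehydrogenase"),
        rxn("ASPTA", {"oaa_c": -1, "glu__L_c": -1, "asp__L_c": 1, "akg_c": 1},
            "amino__aspC", name="aspartate transaminase"),
        rxn("GDH", {"akg_c": -1, "nh3_c": -1, "nadh_c": -1,
                    "glu__L_c": 1, "h2o_c": 1, "nad_c": 1},
            "amino__gdhA", name="glutamate dehydrogenase"),
    ]
    if params.include_inositol_pathway:
        reactions.append(
            rxn("INOSD", {"inost_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
                          "pyr_c": 2, "atp_c": 2, "nadh_c": 2, "h2o_c": 2},
                "inositol__iolD",
                name="myo-inositol catabolism (lumped to pyruvate)")
        )

    # -- exchanges --------------------------------------------------------
    external = [s for s in _EXTERNAL if params.include_inositol_pathway or s != "inost"]
    if not params.include_inositol_pathway:
        metabolites = [
            m for m in metabolites if m.id.rsplit("_", 1)[0] != "inost"
        ]
    for short in external:
        reactions.append(make_exchange(f"{short}_e"))

    # isozyme OR-pairs
    iso_genes = []
    for rid in _ISOZYME_CANDIDATES[: params.n_isozyme_pairs]:
        for reaction in reactions:
            if reaction.id == rid:
                partner = f"{reaction.gpr}_iso"
                iso_genes.append(partner)
                reaction.gpr = f"{reaction.gpr} or {partner}"

    # pathway capacity scalars
    for reaction in reactions:
        pathway = REACTION_PATHWAY.get(reaction.id)
        scalar = params.capacities.get(pathway)
        if scalar is not None:
            reaction.upper_bound *= scalar
            if reaction.lower_bound < 0:
                reaction.lower_bound *= scalar

    from .gpr import parse_gpr

    genes = sorted(
        {g for r in reactions if r.gpr for g in parse_gpr(r.gpr).genes()}
    )
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective_id=None,
        id="toy_bacteroid",
    )
    composition = toy_composition()
    model = build_symbiosis_reaction(model, composition)

    if check:
        probe = apply_standard_condition(model, StandardCondition())
        from .lp import solve_fba

        solution = solve_fba(probe)
        if not solution.optimal or solution.objective_value <= 1e-9:
            raise ModelError(
                "toy bacteroid infeasible under the standard condition "
                f"(status {solution.status}, objective "
                f"{solution.objective_value if solution.optimal else 'n/a'}); "
                "check capacity scalars and the nitrogenase ATP coefficient"
            )
    return model, composition


def apply_standard_condition(
    model: MetabolicModel, condition: Optional[StandardCondition] = None
) -> MetabolicModel:
    """Copy of the model with the standard-condition exchange bounds.

    Uptakes are lower bounds on exchange fluxes (negative flux = uptake);
    the ATP maintenance flux, when given, is fixed (lb = ub).
    """
    condition = condition or StandardCondition()
    new = model.copy()
    named = {
        "EX_mal__L_e": condition.malate_uptake,
        "EX_succ_e": condition.succinate_uptake,
        "EX_o2_e": condition.o2_uptake,
        "EX_glu__L_e": condition.glutamate_uptake,
    }
    if model.has_reaction("EX_inost_e"):
        named["EX_inost_e"] = condition.inositol_uptake
    missing = [r for r in named if not new.has_reaction(r)]
    missing += [
        r
        for r in condition.free_uptake_exchanges + condition.export_only_exchanges
        if not new.has_reaction(r)
    ]
    if missing:
        raise ModelError(f"standard condition: exchanges absent from model: {missing}")
    for rxn_id, rate in named.items():
        rxn = new.reaction(rxn_id)
        rxn.lower_bound = -abs(rate)
        rxn.upper_bound = DEFAULT_BOUND
    for rxn_id in condition.free_uptake_exchanges:
        rxn = new.reaction(rxn_id)
        rxn.lower_bound = -condition.unlimited_uptake
        rxn.upper_bound = DEFAULT_BOUND
    for rxn_id in condition.export_only_exchanges:
        rxn = new.reaction(rxn_id)
        rxn.lower_bound = 0.0
        rxn.upper_bound = DEFAULT_BOUND
    if condition.atp_maintenance is not None and new.has_reaction("ATPM"):
        atpm = new.reaction("ATPM")
        atpm.lower_bound = condition.atp_maintenance
        atpm.upper_bound = condition.atp_maintenance
    return new


# ----------------------------------------------------------------------
# expression scenarios
# ----------------------------------------------------------------------

# per-pathway baseline expression (RPKM-like scale); nif genes dominate
# bacteroid transcriptomes, with the energy and carbon backbone close behind
PATHWAY_BASELINE = {
    "transport": 600.0,
    "tca": 700.0,
    "oxphos": 800.0,
    "nitrogenase": 900.0,
    "storage": 300.0,
    "amino": 250.0,
    "inositol": 200.0,
    "ferm": 300.0,
}

# the host-shift scenario used as the default two-condition experiment:
# condition B (the poorer host) down-regulates the oxidase and the
# inositol pathway
HOST_SHIFT_FOLDS = {"oxphos": 0.5, "inositol": 0.4}


@dataclass
class ExpressionScenario:
    """Two-condition expression generator settings.

    ``fold_changes`` multiplies the targeted pathways' mean expression in
    condition B; ``sigma`` is the lognormal noise (log-space standard
    deviation) drawn independently per gene and condition;
    ``missing_fraction`` of genes get the sentinel -1 in both profiles.
    """

    fold_changes: Dict[str, float] = field(default_factory=dict)
    sigma: float = 0.2
    missing_fraction: float = 0.1
    seed: int = 0
    condition_names: Tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        for pathway, fold in self.fold_changes.items():
            if fold <= 0:
                raise ValueError(f"fold change for {pathway!r} must be > 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def gene_pathway(gene: str) -> str:
    """Pathway of a synthetic toy gene (the prefix before ``__``)."""
    return gene.split("__", 1)[0]


def generate_expression_profiles(
    model: MetabolicModel, scenario: Optional[ExpressionScenario] = None
):
    """Two deterministic (per seed) expression profiles for the toy genes.

    Returns ``(profile_a, profile_b)``; condition B applies the scenario's
    per-pathway fold changes.
    """
    from .eflux import ExpressionProfile

    scenario = scenario or ExpressionScenario()
    rng = np.random.default_rng(scenario.seed)
    name_a, name_b = scenario.condition_names
    values_a: Dict[str, float] = {}
    values_b: Dict[str, float] = {}
    for gene in model.genes:
        pathway = gene_pathway(gene)
        mu = float(np.log(PATHWAY_BASELINE.get(pathway, 100.0)))
        fold = scenario.fold_changes.get(pathway, 1.0)
        if rng.uniform() < scenario.missing_fraction:
            values_a[gene] = -1.0
            values_b[gene] = -1.0
            continue
        noise_a = rng.normal(0.0, scenario.sigma) if scenario.sigma else 0.0
        noise_b = rng.normal(0.0, scenario.sigma) if scenario.sigma else 0.0
        values_a[gene] = float(np.exp(mu + noise_a))
        values_b[gene] = float(np.exp(mu + np.log(fold) + noise_b))
    return (
        ExpressionProfile(condition=name_a, values=values_a),
        ExpressionProfile(condition=name_b, values=values_b),
    )
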