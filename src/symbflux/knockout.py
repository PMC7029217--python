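"""Single-gene deletion screen and symbiotic-gene classification.

Each gene is deleted in turn; reactions whose GPR evaluates false with
that gene removed get their bounds set to [0, 0]; the mutant optimum is
re-solved and the *symbiotic rate ratio* (mutant / wild-type objective)
recorded.  Genes with ratio below the essentiality cutoff are essential
symbiotic genes; genes with any other detectable reduction have a partial
effect; the rest are nonessential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import yaml

from .gpr import evaluate_gpr, parse_gpr
from .lp import solve_fba
from .model import MetabolicModel, ModelError

ESSENTIAL_CUTOFF = 0.05
PARTIAL_TOLERANCE = 0.01
LP_NOISE = 1e-6


@dataclass
class KnockoutResult:
    gene: str
    ratio: float
    affected_reactions: List[str] = field(default_factory=list)
    label: Optional[str] = None  # essential | partial | nonessential
    in_model_scope: bool = True  # False for genes appearing in no GPR


def single_gene_deletion(
    model: MetabolicModel, genes: Optional[List[str]] = None
) -> List[KnockoutResult]:
    """Symbiotic rate ratio for every gene (or the given subset).

    The model is restored between deletions; ratios are clipped into
    [0, 1] only for LP round-off (a deletion can never enlarge the
    feasible set).
    """
    wild_type = solve_fba(model)
    if not wild_type.optimal or wild_type.objective_value <= LP_NOISE:
        raise ModelError(
            "ratios undefined: wild-type objective is zero or not optimal"
        )
    wt_opt = wild_type.objective_value
    asts = {rxn.id: parse_gpr(rxn.gpr) for rxn in model.reactions if rxn.gpr}
    results: List[KnockoutResult] = []
    for gene in genes if genes is not None else model.genes:
        affected = [
            rxn_id
            for rxn_id, ast in asts.items()
            if gene in ast.genes() and not evaluate_gpr(ast, {gene})
        ]
        if not affected:
            in_scope = any(gene in ast.genes() for ast in asts.values())
            results.append(
                KnockoutResult(gene=gene, ratio=1.0, affected_reactions=[],
                               in_model_scope=in_scope)
            )
            continue
        saved = {
            rxn_id: model.reaction(rxn_id).bounds for rxn_id in affected
        }
        try:
            for rxn_id in affected:
                rxn = model.reaction(rxn_id)
                rxn.lower_bound = 0.0
                rxn.upper_bound = 0.0
            mutant = solve_fba(model)
            ratio = (
                mutant.objective_value / wt_opt if mutant.optimal else 0.0
            )
        finally:
            for rxn_id, (lb, ub) in saved.items():
                rxn = model.reaction(rxn_id)
                rxn.lower_bound = lb
                rxn.upper_bound = ub
        ratio = min(max(ratio, 0.0), 1.0)
        results.append(
            KnockoutResult(gene=gene, ratio=ratio, affected_reactions=affected)
        )
    return results


def classify_symbiotic_genes(
    results: List[KnockoutResult],
    essential_cutoff: float = ESSENTIAL_CUTOFF,
    partial_tolerance: float = PARTIAL_TOLERANCE,
) -> Tuple[List[KnockoutResult], Dict[str, int]]:
    """Label each knockout result and count the classes.

    essential: ratio < essential_cutoff; partial: any other reduction
    beyond ``partial_tolerance`` (which guards against LP noise);
    nonessential otherwise.  ``symbiotic`` counts essential + partial.
    """
    labeled = []
    counts = {"essential": 0, "partial": 0, "nonessential": 0, "symbiotic": 0}
    for result in results:
        if result.ratio < essential_cutoff:
            label = "essential"
        elif result.ratio < 1.0 - partial_tolerance:
            label = "partial"
        else:
            label = "nonessential"
        result.label = label
        counts[label] += 1
        labeled.append(result)
    counts["symbiotic"] = counts["essential"] + counts["partial"]
    return labeled, counts


def write_knockout_tsv(results: List[KnockoutResult], path: Union[str, Path]) -> None:
    lines = ["gene_id\tratio\tlabel\treactions_disabled"]
    for result in results:
        lines.append(
            f"{result.gene}\t{result.ratio:.4g}\t{result.label or ''}\t"
            + ";".join(result.affected_reactions)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_classification_yaml(counts: Dict[str, int], path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(dict(counts), sort_keys=False))
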