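"""E-Flux integration of expression data into flux bounds.

The E-Flux idea: a reaction's maximal capacity is proportional to the
expression of the genes encoding it.  Per-gene normalized expression
values (two conditions) are mapped onto reactions through the GPR rules
(complex = min of subunits, isozymes = sum), reaction scores are divided
by the maximum score across *both* conditions so the two condition models
stay on one common scale, and each reaction's flux-variability envelope
(computed on the unconstrained model at fraction-of-optimum 0) is shrunk
toward zero by that relative activity.

The sentinel ``-1`` marks genes or reactions without expression data;
such reactions keep their original bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple, Union

from .gpr import MISSING, parse_gpr, score_gpr
from .lp import FVAResult, flux_variability
from .model import MetabolicModel, ModelError


class ExpressionError(ValueError):
    """Raised for malformed expression data."""


@dataclass
class ExpressionProfile:
    """One condition's normalized per-gene expression.

    Values are >= 0, or exactly -1 for missing data; NaN is rejected.
    """

    condition: str
    values: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, value in self.values.items():
            if value != value:  # NaN
                raise ExpressionError(f"gene {gene!r}: expression is NaN")
            if value < 0 and value != MISSING:
                raise ExpressionError(
                    f"gene {gene!r}: negative expression {value} (only -1 allowed)"
                )

    @classmethod
    def from_tsv(cls, path: Union[str, Path], condition: Optional[str] = None) -> "ExpressionProfile":
        """Read ``gene_id <tab> value`` (optional header)."""
        path = Path(path)
        values: Dict[str, float] = {}
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if i == 0 and fields[0] in ("gene_id", "gene"):
                continue
            if len(fields) < 2:
                raise ExpressionError(f"{path}:{i + 1}: expected 2 columns")
            values[fields[0]] = float(fields[1])
        return cls(condition=condition or path.stem, values=values)

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = ["gene_id\tvalue"]
        for gene, value in self.values.items():
            lines.append(f"{gene}\t{value:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ConditionBounds:
    """Reaction id -> (lb, ub) after expression scaling for one condition.

    Reactions absent from the map keep their original bounds (missing
    expression, sentinel -1).
    """

    condition: str
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rxn_id, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ExpressionError(f"reaction {rxn_id!r}: lb {lb} > ub {ub}")

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = ["reaction_id\tlb\tub"]
        for rxn_id, (lb, ub) in self.bounds.items():
            lines.append(f"{rxn_id}\t{lb:.10g}\t{ub:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path], condition: Optional[str] = None) -> "ConditionBounds":
        path = Path(path)
        bounds: Dict[str, Tuple[float, float]] = {}
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if i == 0 and fields[0] == "reaction_id":
                continue
            bounds[fields[0]] = (float(fields[1]), float(fields[2]))
        return cls(condition=condition or path.stem, bounds=bounds)


def reaction_expression_scores(
    model: MetabolicModel, profile: ExpressionProfile
) -> Dict[str, float]:
    """Map gene expression onto per-reaction activity scores via the GPRs.

    Orphan reactions (no GPR) score -1.
    """
    scores: Dict[str, float] = {}
    for rxn in model.reactions:
        ast = parse_gpr(rxn.gpr)
        scores[rxn.id] = score_gpr(ast, profile.values)
    return scores


def eflux_bounds(
    model: MetabolicModel,
    scores_by_condition: Mapping[str, Mapping[str, float]],
    baseline: Optional[FVAResult] = None,
    normalization: str = "cross_condition",
) -> Dict[str, ConditionBounds]:
    """Expression-scaled bounds per condition.

    Per reaction and condition, a relative activity r in (0, 1] scales the
    baseline FVA envelope toward zero (both bounds multiplied by r, so the
    side ordering is preserved).  Three normalizations are offered:

    * ``cross_condition`` (default): r = score / max score *of that
      reaction across the conditions* — the condition with the higher
      expression keeps the full envelope and the other is scaled down by
      the between-condition expression ratio;
    * ``global``: r = score / max finite score over all reactions and
      conditions;
    * ``per_condition``: r = score / max finite score within the
      condition (breaks cross-condition comparability; for sensitivity
      checks only).

    Sentinel scores (-1) leave the reaction at its original bounds; a
    zero score closes the reaction ([0, 0]).
    """
    if normalization not in ("cross_condition", "global", "per_condition"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if baseline is None:
        baseline = flux_variability(model, fraction_of_optimum=0.0)
    finite_all = [
        s
        for scores in scores_by_condition.values()
        for s in scores.values()
        if s != MISSING
    ]
    if not finite_all:
        raise ExpressionError("no constraining information: all scores are -1")
    if max(finite_all) <= 0:
        raise ExpressionError("no constraining information: all finite scores are 0")
    global_max = max(finite_all)
    out: Dict[str, ConditionBounds] = {}
    for condition, scores in scores_by_condition.items():
        if normalization == "per_condition":
            finite = [s for s in scores.values() if s != MISSING]
            if not finite or max(finite) <= 0:
                raise ExpressionError(
                    f"condition {condition!r}: no constraining information"
                )
        bounds: Dict[str, Tuple[float, float]] = {}
        for rxn_id, score in scores.items():
            if score == MISSING:
                continue
            if normalization == "global":
                normalizer = global_max
            elif normalization == "per_condition":
                normalizer = max(
                    s for s in scores.values() if s != MISSING
                )
            else:
                peers = [
                    other.get(rxn_id, MISSING)
                    for other in scores_by_condition.values()
                ]
                finite_peers = [s for s in peers if s != MISSING]
                normalizer = max(finite_peers)
            if normalizer <= 0:
                r = 0.0
            else:
                r = min(score / normalizer, 1.0)
            base_lo, base_hi = baseline.ranges[rxn_id]
            bounds[rxn_id] = (base_lo * r, base_hi * r)
        out[condition] = ConditionBounds(condition=condition, bounds=bounds)
    return out


def build_condition_model(
    model: MetabolicModel, bounds: ConditionBounds
) -> MetabolicModel:
    """Copy of ``model`` with the condition bounds substituted.

    Exchange bounds (the nutrient condition) are retained unless the
    exchange itself was expression-scaled through a transporter GPR
    attached to it.
    """
    for rxn_id in bounds.bounds:
        if not model.has_reaction(rxn_id):
            raise ModelError(f"condition bounds reference unknown reaction {rxn_id!r}")
    applied = {
        rxn_id: pair
        for rxn_id, pair in bounds.bounds.items()
        if model.reaction(rxn_id).kind != "exchange" or model.reaction(rxn_id).gpr
    }
    new = model.with_bounds(applied)
    new.id = f"{model.id}__{bounds.condition}"
    return new
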