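"""Evolutionary bound-adoption sensitivity analysis.

Starting from the low-yield condition's bounds, each iteration picks one
reaction uniformly at random and moves its bounds a random fraction of the
way toward the high-yield condition's bounds; the move is kept only if the
optimal symbiosis flux strictly improves, otherwise reverted.  A run stops
once the objective reaches the high-condition optimum or a stall limit of
consecutive rejected proposals is hit.  Reactions whose adoption is
accepted in nearly every run are the *determinants* of the between-
condition yield difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .eflux import ConditionBounds, build_condition_model
from .lp import solve_fba
from .model import MetabolicModel, ModelError

IMPROVEMENT_TOL = 1e-6


@dataclass
class MoveRecord:
    iteration: int
    reaction: str
    proposed_bounds: Tuple[float, float]
    accepted: bool
    objective_after: float


@dataclass
class SensitivityRun:
    seed: int
    moves: List[MoveRecord] = field(default_factory=list)
    start_objective: float = float("nan")
    final_objective: float = float("nan")
    iterations: int = 0
    converged: bool = False  # reached the high-condition optimum

    def accepted_reactions(self) -> List[str]:
        return [m.reaction for m in self.moves if m.accepted]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "start_objective": self.start_objective,
                "final_objective": self.final_objective,
                "iterations": self.iterations,
                "converged": self.converged,
                "moves": [
                    {
                        "iteration": m.iteration,
                        "reaction": m.reaction,
                        "bounds": list(m.proposed_bounds),
                        "accepted": m.accepted,
                        "objective": m.objective_after,
                    }
                    for m in self.moves
                ],
            }
        )


@dataclass
class DeterminantReport:
    frequencies: Dict[str, float]
    mean_gain: Dict[str, float]
    determinants: List[str]
    frequency_threshold: float

    def write_tsv(self, path: Union[str, Path]) -> None:
        lines = ["reaction_id\tfrequency\tmean_gain"]
        for rxn in sorted(
            self.frequencies, key=lambda r: -self.frequencies[r]
        ):
            lines.append(
                f"{rxn}\t{self.frequencies[rxn]:.4g}\t{self.mean_gain.get(rxn, 0.0):.4g}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def _differing_reactions(
    model: MetabolicModel, low: ConditionBounds, high: ConditionBounds
) -> List[str]:
    rxn_ids = set(low.bounds) | set(high.bounds)
    out = []
    for rxn_id in model.reaction_ids:
        if rxn_id not in rxn_ids:
            continue
        base = model.reaction(rxn_id).bounds
        lo = low.bounds.get(rxn_id, base)
        hi = high.bounds.get(rxn_id, base)
        if abs(lo[0] - hi[0]) > 1e-12 or abs(lo[1] - hi[1]) > 1e-12:
            out.append(rxn_id)
    return out


def evolutionary_sensitivity(
    model: MetabolicModel,
    bounds_low: ConditionBounds,
    bounds_high: ConditionBounds,
    n_runs: int = 10000,
    seed: int = 0,
    stall_limit: Optional[int] = None,
    full_replacement: bool = False,
) -> List[SensitivityRun]:
    """Randomized greedy adoption of high-condition bounds.

    Per iteration a candidate reaction is drawn uniformly from the
    reactions whose bounds differ between conditions, and both of its
    bounds are interpolated a fraction lambda ~ U(0,1) toward the
    high-condition values (``full_replacement`` adopts them outright).
    Moves are accepted only on strict objective improvement.  The master
    seed spawns per-run seeds deterministically (seed, run index), so runs
    are reproducible and parallel-safe.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if stall_limit is not None and stall_limit < 1:
        raise ValueError("stall_limit must be >= 1")
    low_model = build_condition_model(model, bounds_low)
    high_model = build_condition_model(model, bounds_high)
    low_opt = solve_fba(low_model)
    high_opt = solve_fba(high_model)
    if not (low_opt.optimal and high_opt.optimal):
        raise ModelError("both condition models must solve to optimality")
    target = high_opt.objective_value
    candidates = _differing_reactions(model, bounds_low, bounds_high)
    if stall_limit is None:
        stall_limit = max(1, 50 * len(candidates))
    runs: List[SensitivityRun] = []
    base_bounds = {r.id: r.bounds for r in low_model.reactions}
    high_bounds = {r.id: r.bounds for r in high_model.reactions}
    for run_idx in range(n_runs):
        rng = np.random.default_rng([seed, run_idx])
        run = SensitivityRun(seed=run_idx)
        work = low_model.copy()
        current = solve_fba(work).objective_value
        run.start_objective = current
        stall = 0
        iteration = 0
        while candidates and stall < stall_limit and (
            current < target - IMPROVEMENT_TOL
        ):
            iteration += 1
            rxn_id = candidates[int(rng.integers(len(candidates)))]
            rxn = work.reaction(rxn_id)
            lb, ub = rxn.bounds
            hi_lb, hi_ub = high_bounds[rxn_id]
            if full_replacement:
                new_lb, new_ub = hi_lb, hi_ub
            else:
                lam = float(rng.uniform())
                new_lb = lb + lam * (hi_lb - lb)
                new_ub = ub + lam * (hi_ub - ub)
            rxn.lower_bound, rxn.upper_bound = new_lb, new_ub
            trial = solve_fba(work)
            improved = (
                trial.optimal
                and trial.objective_value > current + IMPROVEMENT_TOL
            )
            if improved:
                current = trial.objective_value
                stall = 0
            else:
                rxn.lower_bound, rxn.upper_bound = lb, ub
                stall += 1
            run.moves.append(
                MoveRecord(
                    iteration=iteration,
                    reaction=rxn_id,
                    proposed_bounds=(new_lb, new_ub),
                    accepted=improved,
                    objective_after=current,
                )
            )
        run.iterations = iteration
        run.final_objective = current
        run.converged = current >= target - IMPROVEMENT_TOL
        runs.append(run)
    return runs


def summarize_determinants(
    runs: List[SensitivityRun], frequency_threshold: float = 0.9
) -> DeterminantReport:
    """Per-reaction acceptance frequency across runs, with the mean
    objective increment credited to each reaction at acceptance."""
    if not runs:
        raise ValueError("at least one run required")
    counts: Dict[str, int] = {}
    gains: Dict[str, List[float]] = {}
    for run in runs:
        seen = set()
        objective = run.start_objective
        for move in run.moves:
            if not move.accepted:
                continue
            if move.reaction not in seen:
                counts[move.reaction] = counts.get(move.reaction, 0) + 1
                seen.add(move.reaction)
            gains.setdefault(move.reaction, []).append(
                move.objective_after - objective
            )
            objective = move.objective_after
    n = len(runs)
    frequencies = {rxn: c / n for rxn, c in counts.items()}
    mean_gain = {rxn: float(np.mean(v)) for rxn, v in gains.items()}
    determinants = sorted(
        [r for r, f in frequencies.items() if f >= frequency_threshold],
        key=lambda r: -frequencies[r],
    )
    return DeterminantReport(
        frequencies=frequencies,
        mean_gain=mean_gain,
        determinants=determinants,
        frequency_threshold=frequency_threshold,
    )


def write_runs_jsonl(runs: List[SensitivityRun], path: Union[str, Path]) -> None:
    Path(path).write_text("\n".join(run.to_json() for run in runs) + "\n")
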