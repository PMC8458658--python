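"""Iterative score-model search: cut-off escalation and greedy refinement.

The original score models were explored by hand in a spreadsheet; this
module formalises that exploration as a deterministic procedure with the
same stated objectives.  For one disease class at a time, the score is a
weighted sum of binary features and a patient is called positive when the
score reaches a cut-off.  Cut-offs are escalated until either specificity
reaches 1.00 or sensitivity drops below 0.50; candidate models are then
refined greedily — single-feature removals and single-step weight
increments — accepting a proposal only if it does not reduce specificity
and keeps sensitivity at or above the floor, preferring higher specificity
and then higher sensitivity, with ties broken by feature order.  The final
combination searches a ratio grid for the rule
"NMOSD when NMOSD score x ratio > MS score", maximising weighted precision.

The whole search is in-sample by design, as in the original analysis; the
optimism this induces is demonstrated (not corrected) by re-evaluating the
selected model on a freshly generated cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classifiers import ScoreModel, load_default_score_model, score_classify
from .cohort import FeatureMatrix
from .evaluate import confusion, weighted_metrics

__all__ = [
    "SearchConfig",
    "OperatingPoint",
    "escalate_cutoffs",
    "refine_model",
    "search_combined",
]


def _default_candidates() -> tuple[dict[str, int], dict[str, int]]:
    model = load_default_score_model()
    return dict(model.nmosd_features), dict(model.ms_features)


@dataclass
class SearchConfig:
    """Grids, floors and goals steering the search."""

    candidate_nmosd: dict[str, int] = field(default_factory=lambda: _default_candidates()[0])
    candidate_ms: dict[str, int] = field(default_factory=lambda: _default_candidates()[1])
    weight_grid: tuple[int, ...] = (1, 2, 3)
    specificity_stop: float = 1.00
    sensitivity_floor: float = 0.50
    specificity_goal: float = 0.90
    ratio_grid: tuple[float, ...] = tuple(np.round(np.arange(0.5, 10.0 + 1e-9, 0.5), 2))
    max_models: int = 5000
    which: str = "ever"

    def validate(self) -> "SearchConfig":
        for name in ("specificity_stop", "sensitivity_floor", "specificity_goal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.weight_grid or not self.ratio_grid:
            raise ValueError("weight and ratio grids must be non-empty")
        if any(r <= 0 for r in self.ratio_grid):
            raise ValueError("ratios must be positive")
        return self


@dataclass(frozen=True)
class OperatingPoint:
    cutoff: int
    sensitivity: float
    specificity: float


def _class_scores(
    matrix: FeatureMatrix, weights: Mapping[str, int], which: str
) -> pd.Series:
    """Per-patient weighted score; NaN when all the features are missing."""
    cols = getattr(matrix, which)[list(weights)]
    w = pd.Series(dict(weights), dtype=float)
    all_missing = cols.isna().all(axis=1)
    scores = cols.fillna(0.0).mul(w, axis=1).sum(axis=1)
    scores[all_missing] = np.nan
    return scores


def escalate_cutoffs(
    weights: Mapping[str, int],
    matrix: FeatureMatrix,
    config: SearchConfig,
    target: str = "NMOSD",
) -> list[OperatingPoint]:
    """Sweep strictly increasing cut-offs on a single-class score.

    The trajectory stops at the first cut-off where specificity reaches the
    configured stop (default 1.00) or sensitivity falls below the floor
    (default 0.50); the terminating point is included for audit.
    """
    config.validate()
    if target not in ("NMOSD", "MS"):
        raise ValueError("target must be NMOSD or MS")
    scores = _class_scores(matrix, weights, config.which).dropna()
    if scores.empty:
        raise ValueError("no classifiable records")
    truth = matrix.diagnosis[scores.index]
    pos = scores[truth == target]
    neg = scores[truth != target]
    if pos.empty or neg.empty:
        raise ValueError("both classes must be present")
    max_cut = int(sum(weights.values()))
    trajectory: list[OperatingPoint] = []
    for cutoff in range(1, max_cut + 1):
        sens = float((pos >= cutoff).mean())
        spec = float((neg < cutoff).mean())
        trajectory.append(OperatingPoint(cutoff, sens, spec))
        if spec >= config.specificity_stop or sens < config.sensitivity_floor:
            break
    return trajectory


def _best_point(
    trajectory: list[OperatingPoint], floor: float
) -> OperatingPoint:
    feasible = [p for p in trajectory if p.sensitivity >= floor]
    if not feasible:
        return trajectory[0]
    return max(feasible, key=lambda p: (p.specificity, p.sensitivity, -p.cutoff))


def refine_model(
    weights: Mapping[str, int],
    matrix: FeatureMatrix,
    config: SearchConfig,
    target: str = "NMOSD",
) -> tuple[dict[str, int], OperatingPoint, int]:
    """Greedy single-class refinement.

    Proposes every single-feature removal (in feature order), then every
    single-step weight increment along the weight grid; accepts the first
    proposal in that order that strictly improves (specificity, sensitivity)
    lexicographically without dropping sensitivity below the floor, and
    repeats until no proposal is accepted or the model budget is exhausted.
    Returns the refined weights, the operating point, and the number of
    models evaluated.
    """
    config.validate()
    current = dict(weights)
    n_evaluated = 1
    current_pt = _best_point(escalate_cutoffs(current, matrix, config, target), config.sensitivity_floor)
    grid = sorted(config.weight_grid)

    improved = True
    while improved and n_evaluated < config.max_models:
        improved = False
        proposals: list[dict[str, int]] = []
        if len(current) > 1:
            for fid in current:
                proposals.append({k: v for k, v in current.items() if k != fid})
        for fid, w in current.items():
            higher = [g for g in grid if g > w]
            if higher:
                prop = dict(current)
                prop[fid] = higher[0]
                proposals.append(prop)
        for prop in proposals:
            if n_evaluated >= config.max_models:
                break
            pt = _best_point(escalate_cutoffs(prop, matrix, config, target), config.sensitivity_floor)
            n_evaluated += 1
            if pt.sensitivity < config.sensitivity_floor:
                continue
            if (pt.specificity, pt.sensitivity) > (current_pt.specificity, current_pt.sensitivity):
                current, current_pt = prop, pt
                improved = True
                break  # restart proposal enumeration from the new model
    return current, current_pt, n_evaluated


def search_combined(
    matrix: FeatureMatrix, config: SearchConfig | None = None
) -> tuple[ScoreModel, float, dict]:
    """Full search: refine both class scores, then pick the combination ratio.

    Returns the combined :class:`ScoreModel` (with the selected ratio), the
    achieved in-sample weighted precision, and a detail dict with the
    per-class operating points and model counts.  The ratio is the grid
    value maximising weighted precision of the combined rule, ties going to
    the smaller ratio.
    """
    config = (config or SearchConfig()).validate()
    labels = set(matrix.diagnosis)
    if labels != {"NMOSD", "MS"}:
        raise ValueError("data must contain both diagnosis classes")

    nmosd_w, nmosd_pt, n_eval_n = refine_model(config.candidate_nmosd, matrix, config, "NMOSD")
    ms_w, ms_pt, n_eval_m = refine_model(config.candidate_ms, matrix, config, "MS")

    best_ratio, best_prec = None, -1.0
    for ratio in config.ratio_grid:
        model = ScoreModel(nmosd_features=nmosd_w, ms_features=ms_w, combination_ratio=float(ratio))
        prec = _combined_precision(model, matrix, config.which)
        if prec > best_prec + 1e-12:
            best_ratio, best_prec = float(ratio), prec
    model = ScoreModel(nmosd_features=nmosd_w, ms_features=ms_w, combination_ratio=best_ratio)
    detail = {
        "nmosd_point": nmosd_pt,
        "ms_point": ms_pt,
        "models_evaluated": n_eval_n + n_eval_m + len(config.ratio_grid),
    }
    return model, best_prec, detail


def _combined_precision(model: ScoreModel, matrix: FeatureMatrix, which: str) -> float:
    truths, preds = [], []
    for pid in matrix.patient_ids:
        label, _, _ = score_classify(matrix.features_of(pid, which), model)
        if label is None:
            continue
        truths.append(matrix.diagnosis[pid])
        preds.append(label)
    if not truths or len(set(truths)) < 2:
        return float("nan")
    report = weighted_metrics(confusion(truths, preds))
    return report.weighted.precision
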