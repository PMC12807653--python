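"""Recover penalty weights and the classification cutoff from labeled reviews.

A labeled unit is a translation unit plus a human accept/reject verdict on
the professional translation.  Candidate configurations are evaluated by
scoring every unit and comparing the automatic pass/fail outcome with the
verdict; the grid search minimizes (false positives, false negatives)
lexicographically — a false positive (auto-passed but human-rejected) is the
costlier error and dominates the objective.  A weighted-sum objective is
available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from . import _tsv
from .scoring import (
    CATEGORY_PENDING,
    UNIT_COLUMNS,
    ScoreConfig,
    TranslationUnit,
    score_translation_unit,
)

VERDICTS = ("accept", "reject")


class EmptyGridError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledUnit:
    unit: TranslationUnit
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"verdict must be accept|reject, got {self.verdict!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    true_positives: int = 0
    false_positives: int = 0
    true_negatives: int = 0
    false_negatives: int = 0

    @property
    def total(self) -> int:
        return (
            self.true_positives
            + self.false_positives
            + self.true_negatives
            + self.false_negatives
        )


@dataclass(frozen=True)
class GridPoint:
    config: ScoreConfig
    counts: ConfusionCounts


@dataclass(frozen=True)
class CalibrationResult:
    best: ScoreConfig
    counts: ConfusionCounts
    trace: tuple[GridPoint, ...]


def evaluate_config(
    units: Sequence[LabeledUnit], config: ScoreConfig
) -> ConfusionCounts:
    """Score every unit under ``config`` and tally the confusion counts.

    Auto-positive means category exact or passed (above-cutoff); the human
    verdict is the reference.
    """
    if not units:
        raise ValueError("at least one labeled unit is required")
    tp = fp = tn = fn = 0
    for lu in units:
        classified = score_translation_unit(lu.unit, config)
        auto_positive = classified.category != CATEGORY_PENDING
        human_positive = lu.verdict == "accept"
        if auto_positive and human_positive:
            tp += 1
        elif auto_positive and not human_positive:
            fp += 1
        elif not auto_positive and human_positive:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _final_scores(units: Sequence[LabeledUnit], config: ScoreConfig) -> list[float]:
    return [score_translation_unit(lu.unit, config).final_score for lu in units]


def _counts_from_scores(
    scores: Sequence[float], units: Sequence[LabeledUnit], cutoff: float
) -> ConfusionCounts:
    tp = fp = tn = fn = 0
    for s, lu in zip(scores, units):
        auto_positive = s > cutoff
        if auto_positive and lu.verdict == "accept":
            tp += 1
        elif auto_positive:
            fp += 1
        elif lu.verdict == "accept":
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def grid_search(
    units: Sequence[LabeledUnit],
    weight_grid: Sequence[tuple[float, float, float]] | None = None,
    cutoff_grid: Sequence[float] | None = None,
    base_config: ScoreConfig | None = None,
    fp_weight: float | None = None,
) -> CalibrationResult:
    """Search (C_wt, W_wt, t) weight triples crossed with cutoffs.

    Default grids bracket the published operating point: C_wt 0.01–0.05,
    W_wt 0.02–0.10 (step 0.01 each), t 0.05–0.30 (step 0.05), cutoff
    0.50–0.95 (step 0.05).

    The objective is lexicographic (false positives, then false negatives)
    unless ``fp_weight`` is given, in which case ``fp_weight*FP + FN`` is
    minimized.  Ties break toward the smaller cutoff, then smaller C_wt,
    W_wt and t in that order.
    """
    if not units:
        raise ValueError("at least one labeled unit is required")
    if weight_grid is None:
        weight_grid = [
            (round(c, 2), round(w, 2), round(t, 2))
            for c in [0.01, 0.02, 0.03, 0.04, 0.05]
            for w in [0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.10]
            for t in [0.05, 0.10, 0.15, 0.20, 0.25, 0.30]
        ]
    if cutoff_grid is None:
        cutoff_grid = [round(0.50 + 0.05 * i, 2) for i in range(10)]
    if not weight_grid or not cutoff_grid:
        raise EmptyGridError("weight and cutoff grids must be non-empty")
    base = base_config if base_config is not None else ScoreConfig()

    trace: list[GridPoint] = []
    best_point: GridPoint | None = None
    best_key: tuple | None = None
    for c_wt, w_wt, t in weight_grid:
        config_w = replace(base, C_wt=c_wt, W_wt=w_wt, t_penalty=t)
        # Final scores do not depend on the cutoff; compute once per weight triple.
        scores = _final_scores(units, config_w)
        for cutoff in cutoff_grid:
            config = replace(config_w, cutoff=cutoff)
            counts = _counts_from_scores(scores, units, cutoff)
            point = GridPoint(config=config, counts=counts)
            trace.append(point)
            if fp_weight is None:
                objective = (counts.false_positives, counts.false_negatives)
            else:
                objective = (
                    fp_weight * counts.false_positives + counts.false_negatives,
                )
            key = (objective, cutoff, c_wt, w_wt, t)
            if best_key is None or key < best_key:
                best_key = key
                best_point = point
    assert best_point is not None
    return CalibrationResult(
        best=best_point.config, counts=best_point.counts, trace=tuple(trace)
    )


LABELED_COLUMNS = UNIT_COLUMNS + ("verdict",)


def read_labeled_units(path: str) -> list[LabeledUnit]:
    """Read the labeled-unit TSV (unit columns plus an accept|reject verdict)."""
    _, rows = _tsv.read_rows(path, required_columns=LABELED_COLUMNS)
    return [
        LabeledUnit(
            unit=TranslationUnit(**{c: row[c] for c in UNIT_COLUMNS}),
            verdict=row["verdict"],
        )
        for row in rows
    ]


def write_labeled_units(units: Iterable[LabeledUnit], path: str) -> None:
    _tsv.write_rows(
        path,
        LABELED_COLUMNS,
        [[getattr(lu.unit, c) for c in UNIT_COLUMNS] + [lu.verdict] for lu in units],
    )


def calibration_rows(result: CalibrationResult) -> tuple[list[str], list[list[str]]]:
    """Grid-trace table for the calibration report TSV."""
    header = ["C_wt", "W_wt", "t_penalty", "cutoff", "TP", "FP", "TN", "FN"]
    rows = [
        [
            f"{p.config.C_wt:.2f}",
            f"{p.config.W_wt:.2f}",
            f"{p.config.t_penalty:.2f}",
            f"{p.config.cutoff:.2f}",
            str(p.counts.true_positives),
            str(p.counts.false_positives),
            str(p.counts.true_negatives),
            str(p.counts.false_negatives),
        ]
        for p in result.trace
    ]
    return header, rows
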