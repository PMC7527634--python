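"""Performance metrics, ROC/AUC, cross-validation and the hyper-parameter grid.

Metrics follow the intuitive "error-fraction" formulation common in the
sequence-prediction literature.  With H+ hotspots and H- coldspots in truth,
H-+ hotspots mispredicted as coldspots and H+- coldspots mispredicted as
hotspots:

    ACC = 1 - (H-+ + H+-) / (H+ + H-)
    SN  = 1 - H-+ / H+
    SP  = 1 - H+- / H-
    MCC = (1 - H-+/H+ - H+-/H-) /
          sqrt((1 + (H+- - H-+)/H+) * (1 + (H-+ - H+-)/H-))

These are algebraically identical to the standard TP/TN/FP/FN formulas
(tested exhaustively).  A zero factor under the MCC square root yields
MCC = 0 by convention (logged), never NaN.

Cross-validation is stratified k-fold (k = 10 by default) with seeded
shuffling.  Under the default ``fold-internal-selection`` mode the SVM-RFE
rankings and feature standardization are re-fit inside each training fold;
``whole-dataset-selection`` ranks once on the full dataset before splitting,
mimicking protocols that select features up front (optimistic, provided for
replication).  Reported metrics are pooled over the union of held-out
predictions; per-fold values are kept alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateMetricError, ParameterError

logger = logging.getLogger(__name__)

LeakageMode = Literal["fold-internal-selection", "whole-dataset-selection"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Class totals and the two error counts (positive class = hotspot = 0)."""

    h_pos: int
    h_neg: int
    pos_as_neg: int  # hotspots predicted coldspot
    neg_as_pos: int  # coldspots predicted hotspot

    def __post_init__(self) -> None:
        if not (0 <= self.pos_as_neg <= self.h_pos and 0 <= self.neg_as_pos <= self.h_neg):
            raise ParameterError("error counts exceed class totals")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.h_pos + other.h_pos,
            self.h_neg + other.h_neg,
            self.pos_as_neg + other.pos_as_neg,
            self.neg_as_pos + other.neg_as_pos,
        )

    @property
    def tp(self) -> int:
        return self.h_pos - self.pos_as_neg

    @property
    def tn(self) -> int:
        return self.h_neg - self.neg_as_pos

    @property
    def fp(self) -> int:
        return self.neg_as_pos

    @property
    def fn(self) -> int:
        return self.pos_as_neg


@dataclass(frozen=True)
class Metrics:
    acc: float
    sn: float
    sp: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "sn": self.sn, "sp": self.sp, "mcc": self.mcc}


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionCounts:
    """Tally the four confusion quantities (labels in {0, 1}, 0 = hotspot)."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ParameterError("label vectors have different lengths")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ParameterError("labels must be 0 (hotspot) or 1 (coldspot)")
    return ConfusionCounts(
        h_pos=int((t == 0).sum()),
        h_neg=int((t == 1).sum()),
        pos_as_neg=int(((t == 0) & (p == 1)).sum()),
        neg_as_pos=int(((t == 1) & (p == 0)).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """ACC / SN / SP / MCC from confusion counts (formulas in module docstring)."""
    if c.h_pos == 0 or c.h_neg == 0:
        raise DegenerateMetricError("both classes must be present to compute metrics")
    acc = 1.0 - (c.pos_as_neg + c.neg_as_pos) / (c.h_pos + c.h_neg)
    sn = 1.0 - c.pos_as_neg / c.h_pos
    sp = 1.0 - c.neg_as_pos / c.h_neg
    f1 = 1.0 + (c.neg_as_pos - c.pos_as_neg) / c.h_pos
    f2 = 1.0 + (c.pos_as_neg - c.neg_as_pos) / c.h_neg
    if f1 <= 0 or f2 <= 0 or math.isclose(f1 * f2, 0.0):
        logger.info("degenerate MCC denominator; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (1.0 - c.pos_as_neg / c.h_pos - c.neg_as_pos / c.h_neg) / math.sqrt(f1 * f2)
    return Metrics(acc=acc, sn=sn, sp=sp, mcc=mcc)


@dataclass
class RocCurve:
    """Threshold-sweep ROC points (FPR, TPR) from (0,0) to (1,1), with AUC."""

    points: list[tuple[float, float]]
    auc: float


def roc_auc(scores: Sequence[float], true_labels: Sequence[int]) -> RocCurve:
    """ROC curve for hotspot-probability scores; AUC by the trapezoid rule.

    *scores* are P(hotspot); the positive class is label 0.  Tied scores are
    grouped into a single threshold step, so the AUC equals the normalized
    Mann-Whitney U statistic with the usual half-credit for ties.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels, dtype=int)
    if s.shape != t.shape:
        raise ParameterError("scores and labels have different lengths")
    if not np.isfinite(s).all():
        raise ParameterError("scores must be finite")
    pos = t == 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes must be present for a ROC curve")
    order = np.argsort(-s, kind="stable")
    s_sorted, pos_sorted = s[order], pos[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:  # group ties in one step
            j += 1
        tp += int(pos_sorted[i:j].sum())
        fp += (j - i) - int(pos_sorted[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    xs, ys = zip(*points)
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points=points, auc=auc)


@dataclass
class CvReport:
    """Per-fold and pooled cross-validation results."""

    fold_metrics: list[Metrics]
    pooled: Metrics
    pooled_confusion: ConfusionCounts
    fold_assignment: np.ndarray  # fold index per sample
    leakage_mode: LeakageMode
    roc: Optional[RocCurve] = None
    k: int = 10
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "leakage_mode": self.leakage_mode,
            "pooled": self.pooled.as_dict(),
            "auc": self.roc.auc if self.roc else None,
            "folds": [m.as_dict() for m in self.fold_metrics],
        }


def stratified_folds(
    y: Sequence[int], k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified train/test index splits; class counts must be >= k."""
    y = np.asarray(y, dtype=int)
    if min(np.bincount(y)) < k:
        raise ParameterError(
            f"smallest class has fewer than k={k} samples; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate(
    dataset,
    pipeline_spec,
    k: int = 10,
    seed: int = 0,
    leakage_mode: LeakageMode = "fold-internal-selection",
) -> CvReport:
    """Stratified k-fold evaluation of the full pipeline on a labeled dataset.

    Feature extraction is per-sequence and runs once; ranking, selection,
    standardization and classifier training happen per training fold (or once
    up front under ``whole-dataset-selection``).  Pooled metrics come from
    the union of held-out predictions; the pooled confusion equals the sum of
    the per-fold confusions by construction.
    """
    from . import pipeline as _pipeline  # runtime import to avoid a module cycle

    return _pipeline._cross_validate_impl(dataset, pipeline_spec, k, seed, leakage_mode)


@dataclass
class GridSearchResult:
    """Accuracy per (learning rate, activation) cell and the winning cell."""

    cells: dict[tuple[float, str], float]
    best_cell: tuple[float, str]
    reports: dict[tuple[float, str], CvReport] = field(default_factory=dict)


_ACTIVATION_ORDER = ("tanh", "relu", "sigmoid")


def grid_search(
    dataset,
    rates: Sequence[float],
    activations: Sequence[str],
    base_config,
    pipeline_spec=None,
    k: int = 10,
    seed: int = 0,
    leakage_mode: LeakageMode = "fold-internal-selection",
) -> GridSearchResult:
    """Evaluate every (learning rate, activation) cell by cross-validation.

    The best cell maximizes pooled accuracy; ties resolve to the lowest
    learning rate, then activation order tanh, relu, sigmoid.
    """
    from dataclasses import replace

    from . import pipeline as _pipeline

    if not rates or not activations:
        raise ParameterError("rates and activations must be nonempty")
    if pipeline_spec is None:
        raise ParameterError("a pipeline_spec is required")
    cells: dict[tuple[float, str], float] = {}
    reports: dict[tuple[float, str], CvReport] = {}
    for rate in rates:
        for act in activations:
            cfg = replace(base_config, learning_rate=rate, hidden_activation=act)
            spec = replace(pipeline_spec, classifier=cfg)
            try:
                report = _pipeline._cross_validate_impl(
                    dataset, spec, k, seed, leakage_mode
                )
                acc = report.pooled.acc
                reports[(rate, act)] = report
            except Exception as exc:  # a diverging cell scores 0, not a crash
                logger.warning("grid cell (%s, %s) failed: %s", rate, act, exc)
                acc = 0.0
            cells[(rate, act)] = acc

    def sort_key(cell: tuple[float, str]):
        rate, act = cell
        act_rank = _ACTIVATION_ORDER.index(act) if act in _ACTIVATION_ORDER else 99
        return (-cells[cell], rate, act_rank)

    best = min(cells, key=sort_key)
    return GridSearchResult(cells=cells, best_cell=best, reports=reports)
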