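"""SVM-RFE feature ranking and top-n selection.

Recursive feature elimination with a linear max-margin classifier: fit a
linear SVM on the surviving features, score each by its squared weight,
eliminate the lowest-scoring batch, repeat until none remain.  The ranking is
the reverse of the elimination order.  The loop is written here so that the
elimination trace and the deterministic tie rule (ties in squared weight are
broken by original column order, earlier columns ranking better) are explicit;
the per-iteration linear SVM fits delegate to scikit-learn.

Step schedule: one feature per iteration for blocks of at most 200 features,
10% of the surviving set (rounded up) for larger blocks.  Columns are
standardized (zero mean, unit variance) before ranking by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import ParameterError, ValidationError
from .features import FeatureMatrix
from .sequences import LABEL_CODES

_STEP_THRESHOLD = 200
_STEP_FRACTION = 0.10


@dataclass
class FeatureRanking:
    """Ranked feature names (best first) with the per-iteration removal trace."""

    ordered_names: list[str]
    elimination_trace: list[list[str]]
    params_used: dict

    def __len__(self) -> int:
        return len(self.ordered_names)


@dataclass(frozen=True)
class SelectionSpec:
    """How many features to keep per block: 5 GDC, 12 RCC, all 66 PseTNC, 425 bank."""

    g: int = 5
    r: int = 12
    p: int = 66
    h: int = 425

    def size_for(self, tag: str) -> int:
        return {"G": self.g, "R": self.r, "P": self.p, "H": self.h}[tag]


def _labels_to_int(labels: Sequence) -> np.ndarray:
    arr = np.asarray(
        [LABEL_CODES.get(l, l) if isinstance(l, str) else l for l in labels]
    )
    return arr.astype(int)


def svm_rfe_rank(
    matrix: FeatureMatrix,
    labels: Optional[Sequence] = None,
    step: Optional[int | float] = None,
    C: float = 1.0,
    standardize: bool = True,
) -> FeatureRanking:
    """Rank features by recursive elimination under a linear SVM.

    Parameters
    ----------
    labels
        Class labels (0/1 or hotspot/coldspot strings); taken from the matrix
        if omitted.  Both classes must be present with >= 2 samples each.
    step
        Features removed per iteration: an int count, a float fraction of the
        surviving set, or None for the default schedule.
    """
    if labels is None:
        if matrix.labels is None:
            raise ParameterError("matrix carries no labels and none were given")
        labels = matrix.labels
    y = _labels_to_int(labels)
    if len(y) != matrix.shape[0]:
        raise ParameterError("label count does not match sample count")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("labels contain a single class")
    if counts.min() < 2:
        raise ParameterError("need at least 2 samples per class")
    X = matrix.values
    if not np.isfinite(X).all():
        raise ValidationError("feature matrix contains non-finite values")

    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        X = (X - mu) / sd

    n_total = X.shape[1]
    remaining = list(range(n_total))
    trace: list[list[str]] = []
    while remaining:
        if len(remaining) == 1:
            trace.append([matrix.feature_names[remaining[0]]])
            break
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[:, remaining], y)
        w2 = np.asarray(clf.coef_).ravel() ** 2
        if step is None:
            s = 1 if n_total <= _STEP_THRESHOLD else max(
                1, math.ceil(_STEP_FRACTION * len(remaining))
            )
        elif isinstance(step, float) and 0 < step < 1:
            s = max(1, math.ceil(step * len(remaining)))
        else:
            s = max(1, int(step))
        s = min(s, len(remaining) - 1) if len(remaining) > s else len(remaining)
        # eliminate the s lowest |w|^2; among ties the later original column
        # goes first (so earlier columns end up ranked better)
        order = sorted(
            range(len(remaining)), key=lambda i: (w2[i], -remaining[i])
        )
        drop = order[:s]
        # absorb exact ties straddling the cut (e.g. duplicated columns), so
        # tied features leave in the same batch and end up adjacent in rank
        if s < len(remaining):
            cut = w2[order[s - 1]]
            for i in order[s:]:
                if len(drop) >= len(remaining) - 1 or not np.isclose(
                    w2[i], cut, rtol=1e-9, atol=1e-15
                ):
                    break
                drop.append(i)
        trace.append([matrix.feature_names[remaining[i]] for i in drop])
        kept = set(range(len(remaining))) - set(drop)
        remaining = [remaining[i] for i in sorted(kept)]

    ordered = [name for batch in reversed(trace) for name in reversed(batch)]
    return FeatureRanking(
        ordered_names=ordered,
        elimination_trace=trace,
        params_used={"C": C, "step": step, "standardize": standardize},
    )


def select_top(ranking: FeatureRanking, n: int) -> list[str]:
    """First *n* names of the ranking, order preserved."""
    if not 0 <= n <= len(ranking):
        raise ParameterError(f"n={n} out of range [0, {len(ranking)}]")
    return list(ranking.ordered_names[:n])
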