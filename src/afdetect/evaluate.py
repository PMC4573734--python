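"""Beat-level evaluation: confusion counts, Se/Sp/PPV/ACC, ROC sweep.

Metrics follow the usual screening conventions with AF as the positive
class:

    Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP),
    ACC = (TP+TN)/(TP+TN+FP+FN).

A metric whose denominator is zero is reported as undefined (None), not
as 0 — e.g. Se on a reference set that contains no AF beats.

The ROC sweep tests thresholds on a fixed grid (default 0.0 to 1.0 in
steps of 0.001), computes the confusion metrics at each, integrates the
area under the (1-Sp, Se) curve by the trapezoidal rule, and selects the
operating point closest (Euclidean distance) to the ideal corner (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detector import BeatDecision, decide
from .symbolic import AF, NONAF, WARMUP

__all__ = ["ConfusionCounts", "Metrics", "RocCurve", "confusion", "metrics", "roc_sweep"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """Se/Sp/PPV/ACC; a field is None when its denominator is zero."""

    se: float | None
    sp: float | None
    ppv: float | None
    acc: float | None


def _labels_of(decisions: Sequence) -> list[str]:
    return [d.label if isinstance(d, BeatDecision) else d for d in decisions]


def confusion(decisions: Sequence, reference: Sequence[str]) -> ConfusionCounts:
    """Tally TP/TN/FP/FN over beats; WARMUP decisions are excluded.

    ``decisions`` may be :class:`~afdetect.detector.BeatDecision` objects
    or plain label strings; ``reference`` gives the per-beat ground
    truth.  Lengths must match.
    """
    pred = _labels_of(decisions)
    if len(pred) != len(reference):
        raise ValueError(
            f"length mismatch: {len(pred)} decisions vs {len(reference)} reference labels"
        )
    tp = tn = fp = fn = 0
    for p, r in zip(pred, reference):
        if p == WARMUP:
            continue
        if r == AF:
            if p == AF:
                tp += 1
            else:
                fn += 1
        elif r == NONAF:
            if p == AF:
                fp += 1
            else:
                tn += 1
        else:
            raise ValueError(f"reference label {r!r} is neither AF nor NONAF")
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> Metrics:
    """Se/Sp/PPV/ACC from a confusion tally (None on zero denominator).

    PPV is also not-applicable when the reference holds no positive
    beats (tp+fn == 0): with nothing to detect, a predictive value for
    the positive class is meaningless even if false alarms occurred.
    """
    if c.total == 0:
        raise ValueError("no evaluated beats")
    no_positives = c.tp + c.fn == 0
    return Metrics(
        se=_ratio(c.tp, c.tp + c.fn),
        sp=_ratio(c.tn, c.tn + c.fp),
        ppv=None if no_positives else _ratio(c.tp, c.tp + c.fp),
        acc=_ratio(c.tp + c.tn, c.total),
    )


@dataclass
class RocCurve:
    """Threshold sweep result.

    ``points`` has one row per threshold with columns threshold, se, sp,
    one_minus_sp, ppv, acc (ppv is NaN where no beat is called AF);
    ``auc`` is the trapezoidal area under (1-Sp, Se); ``best_threshold``
    minimises the distance to the ideal corner, smallest threshold on
    ties.
    """

    points: pd.DataFrame
    auc: float
    best_threshold: float
    best_distance: float


def roc_sweep(
    h_values: Sequence[float],
    reference: Sequence[str],
    lo: float = 0.0,
    hi: float = 1.0,
    step: float = 0.001,
) -> RocCurve:
    """Sweep the decision threshold over a grid and build the ROC curve.

    At each threshold t a beat is called AF iff its entropy h >= t
    (matching :func:`~afdetect.detector.decide`).  Requires both classes
    in the reference; a single-class reference leaves the ROC undefined.
    """
    h = np.asarray(h_values, dtype=float)
    ref = np.asarray(reference, dtype=object)
    if len(h) != len(ref):
        raise ValueError("h_values and reference must have equal length")
    if not np.all(np.isfinite(h)) or h.min() < 0 or h.max() > 1:
        raise ValueError("h values must be finite and in [0, 1]")
    is_af = ref == AF
    n_pos = int(is_af.sum())
    n_neg = int(len(ref) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: reference contains a single class")

    n_steps = int(round((hi - lo) / step))
    thresholds = lo + step * np.arange(n_steps + 1)
    pos_sorted = np.sort(h[is_af])
    neg_sorted = np.sort(h[~is_af])
    # beats with h >= t are called AF; searchsorted('left') counts h < t
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    fn = n_pos - tp
    tn = n_neg - fp
    se = tp / n_pos
    sp = tn / n_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
    acc = (tp + tn) / (n_pos + n_neg)
    points = pd.DataFrame(
        {
            "threshold": thresholds,
            "se": se,
            "sp": sp,
            "one_minus_sp": 1.0 - sp,
            "ppv": ppv,
            "acc": acc,
        }
    )

    x = 1.0 - sp
    y = se
    # endpoints for the integral; the sweep itself may not reach them
    if not np.any((x == 0.0) & (y == 0.0)):
        x = np.append(x, 0.0)
        y = np.append(y, 0.0)
    if not np.any((x == 1.0) & (y == 1.0)):
        x = np.append(x, 1.0)
        y = np.append(y, 1.0)
    order = np.lexsort((y, x))
    auc = float(np.trapezoid(y[order], x[order]))

    dist = np.hypot(1.0 - sp, 1.0 - se)
    best = int(np.argmin(dist))  # first minimum = smallest threshold
    return RocCurve(
        points=points,
        auc=auc,
        best_threshold=float(thresholds[best]),
        best_distance=float(dist[best]),
    )
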