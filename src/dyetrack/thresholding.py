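"""ROC-based derivation of stained/unstained fluorescence thresholds.

Monoculture controls provide dye-channel intensities with known class
membership. Sweeping a decision threshold over the observed intensity range
and classifying each cell as stained (intensity >= threshold) or unstained
(< threshold) traces an ROC curve; the operating point closest to the
top-left corner (FPR = 0, TPR = 1), or alternatively the one maximising
balanced accuracy (TPR + TNR) / 2, defines the optimal threshold.

Only observed intensity values (plus one sentinel above the maximum) need to
be tried: any threshold strictly between two consecutive observed values
produces the same confusion counts, so the observed set exhausts all
distinct classifiers. Ties between equally good operating points are broken
toward lower FPR, then toward the higher threshold — i.e. toward not
over-calling stained cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "RocCurve",
    "Metrics",
    "ThresholdReport",
    "ThresholdComparison",
    "build_roc",
    "select_threshold",
    "evaluate_threshold",
    "pooled_threshold",
    "compare_threshold_strategies",
    "retention_curve",
]

logger = logging.getLogger(__name__)

CRITERIA = ("closest_topleft", "balanced_accuracy")


def _as_intensities(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name} intensity sample must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} intensities must be finite")
    return arr


@dataclass
class RocCurve:
    """Candidate-threshold sweep over two labelled intensity samples.

    ``thresholds`` is descending; entry 0 is a sentinel above the observed
    maximum (the all-unstained operating point). ``tpr[i]``/``fpr[i]`` are the
    fractions of stained/unstained cells with intensity >= ``thresholds[i]``.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    n_stained: int
    n_unstained: int

    def points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )


@dataclass
class Metrics:
    """Confusion-derived rates of one operating point."""

    tpr: float
    tnr: float
    fpr: float
    accuracy: float
    average: float

    def to_dict(self) -> dict:
        return dict(tpr=self.tpr, tnr=self.tnr, fpr=self.fpr,
                    accuracy=self.accuracy, average=self.average)


@dataclass
class ThresholdReport:
    """Selected optimal threshold with its performance metrics.

    ``accuracy`` is the proportion of correctly classified cells given the
    class sizes of the ROC; ``average`` is (TPR + TNR) / 2. ``validation``
    optionally holds the same metrics re-evaluated on a hold-out control
    pair.
    """

    threshold: float
    criterion: str
    tpr: float
    tnr: float
    fpr: float
    accuracy: float
    average: float
    n_stained: int
    n_unstained: int
    validation: Optional[Metrics] = None

    def with_validation(self, stained, unstained) -> "ThresholdReport":
        return replace(
            self, validation=evaluate_threshold(self.threshold, stained, unstained)
        )

    def to_dict(self) -> dict:
        d = dict(
            threshold=self.threshold, criterion=self.criterion, tpr=self.tpr,
            tnr=self.tnr, fpr=self.fpr, accuracy=self.accuracy,
            average=self.average, n_stained=self.n_stained,
            n_unstained=self.n_unstained,
        )
        if self.validation is not None:
            d["validation"] = self.validation.to_dict()
        return d


def build_roc(stained, unstained) -> RocCurve:
    """Sweep all distinct observed intensities as candidate thresholds.

    Candidates are the unique values pooled over both samples, descending,
    preceded by a sentinel above the maximum so the (FPR, TPR) = (0, 0)
    operating point exists. The classification rule is inclusive:
    stained iff intensity >= threshold.
    """
    s = _as_intensities(stained, "stained")
    u = _as_intensities(unstained, "unstained")
    values = np.unique(np.concatenate([s, u]))  # ascending, deduplicated
    thresholds = np.concatenate([[values[-1] + 1.0], values[::-1]])
    s_sorted = np.sort(s)
    u_sorted = np.sort(u)
    # count of observations >= t via sorted rank
    tpr = (s.size - np.searchsorted(s_sorted, thresholds, side="left")) / s.size
    fpr = (u.size - np.searchsorted(u_sorted, thresholds, side="left")) / u.size
    return RocCurve(
        thresholds=thresholds, tpr=tpr, fpr=fpr,
        n_stained=int(s.size), n_unstained=int(u.size),
    )


def select_threshold(roc: RocCurve, criterion: str = "closest_topleft") -> ThresholdReport:
    """Pick the optimal operating point of an ROC curve.

    ``closest_topleft`` minimises the Euclidean distance
    sqrt(FPR^2 + (1 - TPR)^2); ``balanced_accuracy`` maximises
    (TPR + TNR) / 2. Ties go to the point with lower FPR, then to the higher
    threshold.
    """
    if criterion not in CRITERIA:
        raise ValidationError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    tnr = 1.0 - roc.fpr
    if criterion == "closest_topleft":
        score = np.hypot(roc.fpr, 1.0 - roc.tpr)
    else:
        score = -(roc.tpr + tnr) / 2.0
    # lexsort: last key is primary
    order = np.lexsort((-roc.thresholds, roc.fpr, score))
    i = order[0]
    n_s, n_u = roc.n_stained, roc.n_unstained
    accuracy = (roc.tpr[i] * n_s + tnr[i] * n_u) / (n_s + n_u)
    return ThresholdReport(
        threshold=float(roc.thresholds[i]),
        criterion=criterion,
        tpr=float(roc.tpr[i]),
        tnr=float(tnr[i]),
        fpr=float(roc.fpr[i]),
        accuracy=float(accuracy),
        average=float((roc.tpr[i] + tnr[i]) / 2.0),
        n_stained=n_s,
        n_unstained=n_u,
    )


def evaluate_threshold(threshold: float, stained, unstained) -> Metrics:
    """Confusion metrics of a fixed threshold on a labelled control pair."""
    s = _as_intensities(stained, "stained")
    u = _as_intensities(unstained, "unstained")
    tp = int(np.count_nonzero(s >= threshold))
    tn = int(np.count_nonzero(u < threshold))
    tpr = tp / s.size
    tnr = tn / u.size
    return Metrics(
        tpr=tpr,
        tnr=tnr,
        fpr=1.0 - tnr,
        accuracy=(tp + tn) / (s.size + u.size),
        average=(tpr + tnr) / 2.0,
    )


def pooled_threshold(
    samples: Mapping[float, tuple],
    mode: str = "general",
    criterion: str = "closest_topleft",
):
    """Derive thresholds from per-time-point monoculture control pairs.

    ``samples`` maps time (h) to a ``(stained, unstained)`` intensity pair.
    ``general`` pools all stained and all unstained intensities across time
    points before the ROC sweep and returns one :class:`ThresholdReport`;
    ``per_timepoint`` returns ``{time_h: ThresholdReport}``.
    """
    if len(samples) == 0:
        raise ValidationError("at least one time point is required")
    if mode == "general":
        stained = np.concatenate([_as_intensities(s, "stained") for s, _ in samples.values()])
        unstained = np.concatenate([_as_intensities(u, "unstained") for _, u in samples.values()])
        return select_threshold(build_roc(stained, unstained), criterion)
    if mode == "per_timepoint":
        return {
            t: select_threshold(build_roc(s, u), criterion)
            for t, (s, u) in sorted(samples.items())
        }
    raise ValidationError(f"mode must be 'general' or 'per_timepoint', got {mode!r}")


@dataclass
class ThresholdComparison:
    """Competitor-specific versus unified threshold strategies.

    ``separate`` holds one report per stained competitor (each derived
    against the unstained control of its competitor); ``unified`` is the
    single threshold from the pooled pairs. Mean accuracies are computed over
    the two control pairs under each strategy.
    """

    separate: tuple
    unified: ThresholdReport
    separate_mean_accuracy: float
    unified_mean_accuracy: float


def compare_threshold_strategies(
    stained_a,
    unstained_a,
    stained_b,
    unstained_b,
    criterion: str = "closest_topleft",
) -> ThresholdComparison:
    """Compare per-competitor thresholds with one unified threshold.

    When competitor A is stained its coculture partner contributes the
    unstained background, so the separate threshold for A is derived from
    (stained A, unstained B) and vice versa. The unified threshold pools both
    pairs and is evaluated on each pair.
    """
    pair_a = (_as_intensities(stained_a, "stained_a"), _as_intensities(unstained_b, "unstained_b"))
    pair_b = (_as_intensities(stained_b, "stained_b"), _as_intensities(unstained_a, "unstained_a"))
    rep_a = select_threshold(build_roc(*pair_a), criterion)
    rep_b = select_threshold(build_roc(*pair_b), criterion)
    unified = select_threshold(
        build_roc(
            np.concatenate([pair_a[0], pair_b[0]]),
            np.concatenate([pair_a[1], pair_b[1]]),
        ),
        criterion,
    )
    unified_acc = np.mean(
        [evaluate_threshold(unified.threshold, *pair).accuracy for pair in (pair_a, pair_b)]
    )
    return ThresholdComparison(
        separate=(rep_a, rep_b),
        unified=unified,
        separate_mean_accuracy=float((rep_a.accuracy + rep_b.accuracy) / 2.0),
        unified_mean_accuracy=float(unified_acc),
    )


def retention_curve(samples_by_time: Mapping[float, Sequence[float]]) -> pd.DataFrame:
    """Per-time-point location/scale summary of stained-cell dye intensity.

    A transient dye is split between daughter cells, so the mean intensity of
    a growing stained population halves once per division; this summary is
    the standard diagnostic for that decay. Empty time points are omitted
    and logged.
    """
    if len(samples_by_time) == 0:
        raise ValidationError("at least one time point is required")
    rows = []
    for t in sorted(samples_by_time):
        arr = np.asarray(samples_by_time[t], dtype=float).ravel()
        if arr.size == 0:
            logger.warning("retention_curve: no stained events at t=%s h, point omitted", t)
            continue
        rows.append(
            {
                "time_h": t,
                "n": int(arr.size),
                "mean": float(arr.mean()),
                "median": float(np.median(arr)),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["time_h", "n", "mean", "median", "sd"])
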