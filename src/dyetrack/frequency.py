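"""Competitor relative abundances from thresholded events and plate counts.

The stained fraction of gated coculture events is the fluorescence-based
frequency estimate; serial-dilution colony counts give the independent
plate-based estimate. Both are binomial proportions and carry a 95% Wilson
score interval (chosen over the Wald interval for its behaviour at 0 and 1).
An optional Rogan-Gladen correction, (p_obs - FPR) / (TPR - FPR), converts
the observed stained fraction into a misclassification-corrected prevalence;
it is reported alongside, never instead of, the raw classified fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError
from .events_io import EventTable, PlateSeries, SampleMeta

__all__ = [
    "FrequencyEstimate",
    "CorrelationResult",
    "CorrelationComparison",
    "classify_events",
    "estimate_frequency",
    "correct_frequency",
    "plate_frequency",
    "correlate_methods",
    "compare_correlations",
]

logger = logging.getLogger(__name__)

#: Inclusive colony-count window for an evaluable plate.
COLONY_MIN, COLONY_MAX = 30, 300


@dataclass
class FrequencyEstimate:
    """Relative abundance of the stained (or focal) competitor in one sample.

    For ``method="plate"`` the "stained" fields refer to the focal morphotype
    on the rule-selected plate. ``valid`` is False when no plate qualified
    under the 30-300 colony rule; the numeric fields are then NaN.
    """

    meta: Optional[SampleMeta]
    n_gated: int
    n_stained: int
    freq_stained: float
    ci_low: float
    ci_high: float
    method: str = "fluorescence"
    freq_corrected: Optional[float] = None
    valid: bool = True

    def __post_init__(self) -> None:
        if not self.valid:
            return
        if not 0 <= self.n_stained <= self.n_gated:
            raise ValidationError("n_stained must lie in [0, n_gated]")
        if not (self.ci_low <= self.freq_stained <= self.ci_high):
            raise ValidationError("confidence interval must bracket the estimate")


def classify_events(events: EventTable, threshold: float) -> tuple[int, int]:
    """Count stained (intensity >= threshold) and unstained gated events."""
    if len(events) == 0:
        raise ValidationError("cannot classify an empty event table")
    x = events.intensity_dye
    n_stained = int(np.count_nonzero(x >= threshold))
    return n_stained, int(x.size) - n_stained


def estimate_frequency(
    n_stained: int,
    n_gated: int,
    meta: Optional[SampleMeta] = None,
    method: str = "fluorescence",
) -> FrequencyEstimate:
    """Binomial proportion with a 95% Wilson score interval."""
    if n_gated < 1:
        raise ValidationError("frequency undefined for n_gated < 1")
    if not 0 <= n_stained <= n_gated:
        raise ValidationError("n_stained must lie in [0, n_gated]")
    low, high = proportion_confint(n_stained, n_gated, alpha=0.05, method="wilson")
    freq = n_stained / n_gated
    return FrequencyEstimate(
        meta=meta,
        n_gated=int(n_gated),
        n_stained=int(n_stained),
        freq_stained=freq,
        # guard against the endpoints rounding just inside the estimate
        ci_low=min(float(low), freq),
        ci_high=max(float(high), freq),
        method=method,
    )


def correct_frequency(freq_observed: float, tpr: float, fpr: float) -> float:
    """Rogan-Gladen misclassification-corrected prevalence, clipped to [0, 1]."""
    if not tpr > fpr:
        raise ValidationError(
            f"threshold uninformative: TPR ({tpr}) must exceed FPR ({fpr})"
        )
    return float(min(1.0, max(0.0, (freq_observed - fpr) / (tpr - fpr))))


def plate_frequency(series: PlateSeries, focal: str) -> FrequencyEstimate:
    """Focal-morphotype frequency from the rule-selected evaluable plate.

    Plates whose total colony count lies in the closed window [30, 300] are
    evaluable; among them the plate with the highest total is used (ties, if
    dilutions produced equal totals, go to the lower dilution exponent). If
    no plate qualifies a flagged empty estimate is returned, never an
    exception.
    """
    if focal not in series.morphotypes:
        raise ValidationError(
            f"unknown focal morphotype {focal!r}; have {series.morphotypes}"
        )
    df = series.plates
    totals = df[series.morphotypes].sum(axis=1).to_numpy(float)
    ok = (totals >= COLONY_MIN) & (totals <= COLONY_MAX)
    if not ok.any():
        sid = series.meta.sample_id if series.meta else "<unknown>"
        logger.warning(
            "plate_frequency: no plate with %d-%d colonies in sample %s",
            COLONY_MIN, COLONY_MAX, sid,
        )
        return FrequencyEstimate(
            meta=series.meta, n_gated=0, n_stained=0,
            freq_stained=math.nan, ci_low=math.nan, ci_high=math.nan,
            method="plate", valid=False,
        )
    idx = np.flatnonzero(ok)
    dil = df["dilution_exponent"].to_numpy(float)
    # highest total wins; deterministic tie-break on the lower dilution
    best = idx[np.lexsort((dil[idx], -totals[idx]))[0]]
    total = int(totals[best])
    count = int(df[focal].iloc[best])
    return estimate_frequency(count, total, meta=series.meta, method="plate")


@dataclass
class CorrelationResult:
    """Agreement between fluorescence- and plate-based frequencies."""

    r: float
    n: int
    p_value: float
    slope: float
    intercept: float

    def to_dict(self) -> dict:
        return dict(r=self.r, n=self.n, p_value=self.p_value,
                    slope=self.slope, intercept=self.intercept)


def correlate_methods(pairs: Sequence[tuple]) -> CorrelationResult:
    """Pearson correlation and least-squares fit between two frequency estimates.

    ``pairs`` is a sequence of (fluorescence frequency, plate frequency).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("correlate_methods needs >= 3 (x, y) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("frequency pairs must be finite")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: zero variance in a coordinate")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(r), n=len(x), p_value=float(p),
        slope=float(fit.slope), intercept=float(fit.intercept),
    )


@dataclass
class CorrelationComparison:
    z_difference: float
    p_value: float


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Fisher r-to-z comparison of two independent Pearson correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p.
    """
    if n1 < 4 or n2 < 4:
        raise ValidationError("compare_correlations requires n >= 4 in both groups")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValidationError("|r| must be < 1 (Fisher transform diverges)")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(z_difference=float(z), p_value=float(p))
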