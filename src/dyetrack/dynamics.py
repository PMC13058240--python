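"""Competition outcome statistics: frequency trends and carrying capacity.

The competitive hierarchy of two types shows up as a temporal trend in the
focal type's relative abundance. Two per-replicate estimators are provided:
the ordinary least-squares slope of frequency versus time (the scale on
which the trajectories are usually plotted) and the slope of
ln(f / (1 - f)) versus time, ``s_logit``, the standard selection-rate
statistic — under discrete selection with relative fitness w per generation,
logit(f) is exactly linear in generations with slope ln(w). Converting
``s_logit`` (per hour) into ln(w) (per generation) requires the
generations-per-hour rate, which the caller must supply; it is never
inferred silently.

Replicate slopes are aggregated per condition by their mean, SE = sd/sqrt(k)
and a two-sided normal z-test against zero. This deliberately replaces a
random-intercept mixed model: the scientific quantity is the per-condition
temporal trend, and per-replicate OLS plus across-replicate aggregation
delivers it without off-the-shelf mixed-model machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .events_io import ODSeries

__all__ = [
    "Trajectory",
    "TrendEstimate",
    "fit_frequency_trend",
    "aggregate_trends",
    "carrying_capacity",
]

LOGIT_CLIP = 1e-3


@dataclass
class Trajectory:
    """Frequency of the focal competitor over time in one replicate culture.

    ``n_stained``/``n_gated`` are optional per-point counts of the focal
    competitor; when present, logit slopes use the Haldane-Anscombe
    pseudo-count (x + 0.5) / (n + 1) instead of clipping.
    """

    condition: tuple
    replicate: int
    time_h: np.ndarray
    freq: np.ndarray
    n_focal: Optional[np.ndarray] = None
    n_total: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, float)
        self.freq = np.asarray(self.freq, float)
        if self.time_h.shape != self.freq.shape:
            raise ValidationError("time and frequency arrays must align")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValidationError("time_h must be strictly increasing")
        if np.any((self.freq < 0) | (self.freq > 1)):
            raise ValidationError("frequencies must lie in [0, 1]")
        if (self.n_focal is None) != (self.n_total is None):
            raise ValidationError("n_focal and n_total must be given together")
        if self.n_focal is not None:
            self.n_focal = np.asarray(self.n_focal, float)
            self.n_total = np.asarray(self.n_total, float)


@dataclass
class TrendEstimate:
    """Per-replicate temporal trend on the linear and logit scales (per hour)."""

    slope: float
    slope_se: float
    s_logit: float
    s_logit_se: float
    n_points: int
    condition: Optional[tuple] = None
    replicate: Optional[int] = None


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    if n > 2:
        resid = y - (ym + slope * (x - xm))
        se = math.sqrt(float(np.sum(resid**2)) / (n - 2) / sxx)
    else:
        se = math.nan
    return slope, se


def fit_frequency_trend(traj: Trajectory) -> TrendEstimate:
    """OLS slopes of frequency and logit-frequency versus time.

    Boundary frequencies (0 or 1) are handled by the pseudo-count adjustment
    when counts are available, otherwise by clipping to
    [1e-3, 1 - 1e-3] before the logit.
    """
    if traj.time_h.size < 2:
        raise ValidationError("trend estimation requires >= 2 time points")
    slope, slope_se = _ols(traj.time_h, traj.freq)
    if traj.n_focal is not None:
        f = (traj.n_focal + 0.5) / (traj.n_total + 1.0)
    else:
        f = np.clip(traj.freq, LOGIT_CLIP, 1.0 - LOGIT_CLIP)
    s_logit, s_logit_se = _ols(traj.time_h, np.log(f / (1.0 - f)))
    return TrendEstimate(
        slope=slope, slope_se=slope_se,
        s_logit=s_logit, s_logit_se=s_logit_se,
        n_points=int(traj.time_h.size),
        condition=traj.condition, replicate=traj.replicate,
    )


def aggregate_trends(
    estimates_by_condition: Mapping[tuple, Sequence[TrendEstimate]],
    statistic: str = "s_logit",
) -> pd.DataFrame:
    """Per-condition mean replicate slope, SE and z-test against zero.

    Conditions with a single replicate report the mean with an undefined SE
    and are flagged. ``statistic`` selects ``"s_logit"`` or ``"slope"``.
    """
    if statistic not in ("s_logit", "slope"):
        raise ValidationError("statistic must be 's_logit' or 'slope'")
    rows = []
    for condition, ests in estimates_by_condition.items():
        slopes = np.array([getattr(e, statistic) for e in ests], float)
        k = slopes.size
        mean = float(slopes.mean())
        if k >= 2:
            se = float(slopes.std(ddof=1) / math.sqrt(k))
            z = mean / se if se > 0 else math.copysign(math.inf, mean) if mean else 0.0
            p = float(2.0 * stats.norm.sf(abs(z)))
            flagged = False
        else:
            se, z, p, flagged = math.nan, math.nan, math.nan, True
        rows.append(
            {
                "condition": condition,
                "statistic": statistic,
                "mean": mean,
                "se": se,
                "z": z,
                "p_value": p,
                "k_replicates": int(k),
                "flagged_single_replicate": flagged,
            }
        )
    return pd.DataFrame(rows)


def carrying_capacity(series: Sequence[ODSeries]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Maximum OD per culture and its mean across replicates per condition.

    Returns ``(per_culture, per_condition)`` frames; the carrying capacity of
    a culture is simply the highest OD value it reached during the assay.
    """
    if len(series) == 0:
        raise ValidationError("carrying_capacity requires >= 1 OD series")
    rows = []
    for s in series:
        if len(s.points) < 1:
            raise ValidationError("each OD series needs >= 1 point")
        meta = s.meta
        rows.append(
            {
                "sample_id": meta.sample_id if meta else "",
                "condition": meta.condition if meta else None,
                "replicate": meta.replicate if meta else None,
                "max_od": float(s.points["od600"].max()),
            }
        )
    per_culture = pd.DataFrame(rows)
    per_condition = (
        per_culture.groupby("condition", sort=False)["max_od"]
        .agg(mean_max_od="mean", k_replicates="count")
        .reset_index()
    )
    return per_culture, per_condition
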