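"""Time-depth-recorder processing: zero-offset correction, dive detection,
and trip-level dive summaries.

Depth records come from archival tags sampling every 5 or 10 s at 1 m
resolution.  Pressure sensors drift, so the raw trace is first zero-offset
corrected against a slowly varying surface baseline; dives are then maximal
runs of samples strictly deeper than a threshold (3 m by default — samples
at exactly the threshold count as surface).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthSeries",
    "Dive",
    "TripDiveSummary",
    "zero_offset_correct",
    "detect_dives",
    "trip_summary",
]

DIVE_THRESHOLD_M = 3.0


@dataclass(frozen=True)
class DepthSeries:
    """Regularly sampled depth trace for one trip (positive down, metres)."""

    seal_id: str
    t0: float  # start time, decimal days
    dt: float  # sampling interval, seconds
    depth: np.ndarray

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("sampling interval must be positive")
        object.__setattr__(self, "depth", np.asarray(self.depth, dtype=float))

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds from t0."""
        return np.arange(len(self.depth)) * self.dt


@dataclass(frozen=True)
class Dive:
    """One detected dive: bounding sample times (seconds from series t0)."""

    start_s: float
    end_s: float
    max_depth: float
    duration_s: float

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass(frozen=True)
class TripDiveSummary:
    n_dives: int
    mean_max_depth: float  # nan when no dives
    pct_time_diving: float
    pct_dives_night: float | None = None


def zero_offset_correct(
    series: DepthSeries,
    window_s: float = 7200.0,
    percentile: float = 10.0,
) -> DepthSeries:
    """Remove slow surface drift so that surface samples read ~0 m.

    The baseline is a centred rolling lower percentile of the trace (the
    animal surfaces often, so the lower envelope tracks the sensor offset),
    median-smoothed over the same window so it changes slowly, then
    subtracted.  Corrected depths are floored at -1 m (one unit of sensor
    resolution below zero).
    """
    n = len(series.depth)
    win = max(int(round(window_s / series.dt)), 10)
    if win < 10:
        raise ValueError("window must span at least 10 samples")
    if n == 0:
        return series
    if np.ptp(series.depth) == 0:
        warnings.warn("all-constant depth series; zeroing it", RuntimeWarning, stacklevel=2)
        return replace(series, depth=np.zeros_like(series.depth))
    s = pd.Series(series.depth)
    base = s.rolling(win, center=True, min_periods=1).quantile(percentile / 100.0)
    base = base.rolling(win, center=True, min_periods=1).median()
    corrected = np.maximum(series.depth - base.to_numpy(), -1.0)
    return replace(series, depth=corrected)


def detect_dives(series: DepthSeries, threshold: float = DIVE_THRESHOLD_M) -> list[Dive]:
    """Detect dives as maximal runs of samples with depth strictly > threshold.

    Start/end are the first/last supra-threshold samples of the run (no
    interpolation across the crossing, consistent with 1 m / 5 s resolution);
    duration counts the run's samples times the sampling interval.
    """
    deep = series.depth > threshold
    if not deep.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], deep, [False])).astype(int)))
    starts, ends = edges[::2], edges[1::2]  # end exclusive
    dives = []
    for i0, i1 in zip(starts, ends):
        dives.append(
            Dive(
                start_s=i0 * series.dt,
                end_s=(i1 - 1) * series.dt + series.dt,
                max_depth=float(series.depth[i0:i1].max()),
                duration_s=(i1 - i0) * series.dt,
            )
        )
    return dives


def _in_windows(t: float, windows: Sequence[tuple[float, float]]) -> bool:
    return any(a <= t < b for a, b in windows)


def trip_summary(
    dives: Sequence[Dive],
    trip_duration_days: float,
    night_windows_s: Sequence[tuple[float, float]] | None = None,
) -> TripDiveSummary:
    """Trip-level dive metrics.

    ``pct_time_diving`` is total dive time over trip time; ``mean_max_depth``
    averages per-dive maximum depths (nan with no dives).  When night windows
    (seconds from series start) are supplied, ``pct_dives_night`` is the
    percentage of dives whose midpoint falls inside a window.
    """
    if trip_duration_days <= 0:
        raise ValueError("trip duration must be positive")
    trip_s = trip_duration_days * 86_400.0
    total_dive_s = float(sum(d.duration_s for d in dives))
    pct_night = None
    if night_windows_s is not None and dives:
        n_night = sum(_in_windows(d.midpoint_s, night_windows_s) for d in dives)
        pct_night = 100.0 * n_night / len(dives)
    return TripDiveSummary(
        n_dives=len(dives),
        mean_max_depth=float(np.mean([d.max_depth for d in dives])) if dives else float("nan"),
        pct_time_diving=100.0 * total_dive_s / trip_s,
        pct_dives_night=pct_night,
    )
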