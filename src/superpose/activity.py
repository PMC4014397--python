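"""Promoter-activity and growth-rate curves from OD/GFP time series.

Promoter activity is the sliding-window regression slope of background-
subtracted GFP fluorescence divided by the mean OD over the same window
(default window: 17 samples at the ~8-minute sampling cadence).  Growth
rate is the same window regression applied to ln OD.  Curves are then
placed on a *generation axis* — log2 of the OD fold-change since the
start of the series — so that conditions with different growth rates can
be compared and combined pointwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .plate import ConditionSet, PlateSeries

__all__ = [
    "ActivityCurve",
    "GrowthRateCurve",
    "promoter_activity",
    "growth_rate",
    "to_generation_axis",
    "resample_to_common_grid",
    "DEFAULT_WINDOW",
    "DEFAULT_GRID_POINTS",
]

DEFAULT_WINDOW = 17
DEFAULT_GRID_POINTS = 100


@dataclass
class ActivityCurve:
    """A promoter's activity (fluorescence · OD⁻¹ · min⁻¹) for one well.

    ``generations`` is None until :func:`to_generation_axis` assigns it.
    """

    promoter: str
    condition_set: ConditionSet
    replicate_day: int
    activity: np.ndarray
    time_min: np.ndarray
    generations: np.ndarray | None = None

    @property
    def values(self) -> np.ndarray:
        return self.activity

    def with_values(self, v, time_min=None, generations=None) -> "ActivityCurve":
        return dataclasses.replace(
            self,
            activity=np.asarray(v, dtype=float),
            time_min=self.time_min if time_min is None else time_min,
            generations=self.generations if generations is None else generations,
        )

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.time_min = np.asarray(self.time_min, dtype=float)
        if self.activity.size != self.time_min.size:
            raise ValueError("activity and time_min lengths differ")
        if self.generations is not None:
            self.generations = np.asarray(self.generations, dtype=float)
            if self.generations.size != self.activity.size:
                raise ValueError("generations and activity lengths differ")
            ok = np.isfinite(self.generations)
            if np.any(np.diff(self.generations[ok]) < 0):
                raise ValueError("generations must be non-decreasing")

    def __len__(self) -> int:
        return self.activity.size


@dataclass
class GrowthRateCurve:
    """Instantaneous growth rate (1/min) on the same axes as ActivityCurve."""

    promoter: str
    condition_set: ConditionSet
    replicate_day: int
    rate: np.ndarray
    time_min: np.ndarray
    generations: np.ndarray | None = None

    @property
    def values(self) -> np.ndarray:
        return self.rate

    def with_values(self, v, time_min=None, generations=None) -> "GrowthRateCurve":
        return dataclasses.replace(
            self,
            rate=np.asarray(v, dtype=float),
            time_min=self.time_min if time_min is None else time_min,
            generations=self.generations if generations is None else generations,
        )

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        self.time_min = np.asarray(self.time_min, dtype=float)
        if self.generations is not None:
            self.generations = np.asarray(self.generations, dtype=float)

    def __len__(self) -> int:
        return self.rate.size


def _check_window(window: int, n: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if window > n:
        raise ValueError(f"series of length {n} shorter than window {window}")


def _window_slopes(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """OLS slope of y against t in each length-`window` sliding window.

    Handles non-uniform sampling; NaNs in y propagate to their windows.
    """
    tw = sliding_window_view(t, window)
    yw = sliding_window_view(y, window)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", tc, tc)
    return np.einsum("ij,ij->i", tc, yc) / denom


def _window_fitted_center(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Regression-fitted value of y at each window's center time."""
    half = window // 2
    tw = sliding_window_view(t, window)
    yw = sliding_window_view(y, window)
    tbar = tw.mean(axis=1)
    ybar = yw.mean(axis=1)
    slopes = _window_slopes(t, y, window)
    return ybar + slopes * (t[half : t.size - half] - tbar)


def promoter_activity(series: PlateSeries, window: int = DEFAULT_WINDOW) -> ActivityCurve:
    """Time derivative of GFP per unit OD, by sliding-window regression.

    Each retained point is the least-squares slope of fluorescence over a
    centered window divided by the mean OD over that window.  Endpoints
    where a full window does not fit are dropped.  Background must already
    be subtracted (see :func:`superpose.plate.subtract_background`).
    """
    n = len(series)
    _check_window(window, n)
    half = window // 2
    slopes = _window_slopes(series.time_min, series.fluo, window)
    od_mean = sliding_window_view(series.od, window).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        act = np.where(od_mean > 0, slopes / od_mean, np.nan)
    return ActivityCurve(
        promoter=series.promoter,
        condition_set=series.condition_set,
        replicate_day=series.replicate_day,
        activity=act,
        time_min=series.time_min[half : n - half],
    )


def growth_rate(series: PlateSeries, window: int = DEFAULT_WINDOW) -> GrowthRateCurve:
    """Instantaneous growth rate d ln(OD)/dt by sliding-window regression.

    Windows containing non-positive OD yield NaN (missing) points.
    """
    n = len(series)
    _check_window(window, n)
    half = window // 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ln_od = np.where(series.od > 0, np.log(series.od), np.nan)
    rate = _window_slopes(series.time_min, ln_od, window)
    return GrowthRateCurve(
        promoter=series.promoter,
        condition_set=series.condition_set,
        replicate_day=series.replicate_day,
        rate=rate,
        time_min=series.time_min[half : n - half],
    )


def to_generation_axis(curve, series: PlateSeries, window: int | None = None):
    """Assign generations(t) = log2(OD(t) / OD(t0)) to a curve.

    OD is smoothed in the log domain — the window regression of ln OD,
    fitted at each window center — because batch-growth OD is locally
    exponential, so log-domain smoothing is unbiased where arithmetic
    window means would overshoot.  The origin OD(t0) is the first-window
    ln-OD fit evaluated at the very first sample, and a cumulative
    maximum enforces the monotone axis interpolation requires.  The axis
    is invariant to the OD unit.
    """
    n = len(series)
    if window is None:
        # infer the window from how many endpoint samples the curve dropped
        window = n - len(curve) + 1
    _check_window(window, n)
    half = window // 2
    if len(curve) != n - 2 * half:
        raise ValueError("curve length inconsistent with series and window")
    with np.errstate(divide="ignore", invalid="ignore"):
        ln_od = np.where(series.od > 0, np.log(series.od), np.nan)
    ln_fit = _window_fitted_center(series.time_min, ln_od, window)
    # origin: first-window regression extrapolated to the first sample
    t0, tw = series.time_min[0], series.time_min[:window]
    lw = ln_od[:window]
    if np.all(np.isfinite(lw)):
        tbar, lbar = tw.mean(), lw.mean()
        slope0 = ((tw - tbar) @ (lw - lbar)) / ((tw - tbar) @ (tw - tbar))
        ln_od0 = lbar + slope0 * (t0 - tbar)
    else:
        pos = ln_od[np.isfinite(ln_od)]
        if pos.size == 0:
            raise ValueError(f"well {series.well_id}: no positive OD values")
        ln_od0 = pos[0]
    gen = (ln_fit - ln_od0) / np.log(2.0)
    gen = np.fmax.accumulate(gen)
    return dataclasses.replace(curve, generations=gen)


def resample_to_common_grid(curves: Sequence, n_points: int = DEFAULT_GRID_POINTS) -> list:
    """Interpolate curves onto one shared uniform generation grid.

    The grid spans the *intersection* of all curves' generation ranges so
    no extrapolation is ever performed; missing (NaN) points are dropped
    before linear interpolation.
    """
    if not curves:
        raise ValueError("no curves to resample")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    ranges = []
    for c in curves:
        if c.generations is None:
            raise ValueError("curve lacks a generation axis; run to_generation_axis first")
        ok = np.isfinite(c.generations) & np.isfinite(c.values)
        if ok.sum() < 2:
            raise ValueError(f"curve {c.promoter}/{c.condition_set} has <2 valid points")
        g = c.generations[ok]
        ranges.append((g[0], g[-1]))
    lo = max(r[0] for r in ranges)
    hi = min(r[1] for r in ranges)
    if not lo < hi:
        bad = [
            f"{c.promoter}/{c.condition_set}/day{c.replicate_day} [{r[0]:.3g},{r[1]:.3g}]"
            for c, r in zip(curves, ranges)
        ]
        raise ValueError("empty generation-range intersection among curves: " + "; ".join(bad))
    grid = np.linspace(lo, hi, n_points)
    out = []
    for c in curves:
        ok = np.isfinite(c.generations) & np.isfinite(c.values)
        g, v, t = c.generations[ok], c.values[ok], c.time_min[ok]
        out.append(
            c.with_values(
                np.interp(grid, g, v),
                time_min=np.interp(grid, g, t),
                generations=grid.copy(),
            )
        )
    return out
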