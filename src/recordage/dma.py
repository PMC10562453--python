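"""Detrending Moving Average (DMA) estimation of the walk dimension.

The fluctuation of a series around its backward moving average of window
length ell scales as F(ell) ~ ell^{1/d_w} for a walk of dimension d_w,
insensitively to level offsets and slowly varying trends.  This is the
estimator used to assign a walk dimension to arbitrary one-dimensional
time series (tracer tracks, climate series, DNA walks, ...).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulators import Trajectory

__all__ = [
    "DMAResult",
    "default_windows",
    "dma_fluctuation",
    "fit_walk_dimension",
    "dma_walk_dimension",
    "StationarityReport",
    "stationarity_check",
]


@dataclass
class DMAResult:
    """Fluctuation function with its fitted scaling exponent 1/d_w."""

    ell: np.ndarray
    F: np.ndarray
    inv_d_w: float
    stderr: float
    d_w: float
    fit_window: tuple[float, float]
    residuals: np.ndarray


def default_windows(n_points: int) -> np.ndarray:
    """Powers of 2 from 8 up to n_points/10."""
    ell_max = n_points // 10
    if ell_max < 8:
        raise ValueError(f"series of {n_points} points too short for DMA (need >= 80)")
    exps = np.arange(3, int(np.floor(np.log2(ell_max))) + 1)
    return 2 ** exps


def _as_positions(series) -> np.ndarray:
    if isinstance(series, Trajectory):
        return np.asarray(series.positions, dtype=float)
    return np.asarray(series, dtype=float)


def dma_fluctuation(
    series, ell_list: Sequence[int] | None = None, ell_max: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Backward-moving-average fluctuation F(ell) for each window length.

    For each ell the detrended residual is X_t - mean(X_{t-ell+1..t}), and
    F(ell) is its root mean square over t = ell_max..N so that every window
    size is evaluated on the same sample range.  A list of series gives the
    ensemble-averaged fluctuation (root of the mean squared fluctuation
    across series).

    A linear series X_t = c*t has residual c*(ell-1)/2 exactly, so
    F(ell) = |c|*(ell-1)/2 -- the closed form used to validate the
    implementation.
    """
    many = isinstance(series, (list, tuple)) or (
        isinstance(series, np.ndarray) and series.ndim == 2
    )
    series_list = [_as_positions(s) for s in series] if many else [_as_positions(series)]
    n = min(len(s) for s in series_list)
    if ell_list is None:
        ell_list = default_windows(n)
    ell_list = np.asarray(ell_list, dtype=int)
    if ell_max is None:
        ell_max = int(ell_list.max())
    if np.any(ell_list < 2):
        raise ValueError("window lengths must be >= 2")
    if n <= ell_max:
        raise ValueError(f"series length {n} must exceed ell_max = {ell_max}")
    if ell_max < ell_list.max():
        raise ValueError("ell_max smaller than the largest requested window")

    msq = np.zeros(len(ell_list))
    for x in series_list:
        c = np.concatenate([[0.0], np.cumsum(x)])
        for j, ell in enumerate(ell_list):
            # backward window mean at t: (S_{t+1} - S_{t+1-ell})/ell
            t = np.arange(ell_max, len(x))
            ma = (c[t + 1] - c[t + 1 - ell]) / ell
            resid = x[t] - ma
            msq[j] += np.mean(resid**2)
    F = np.sqrt(msq / len(series_list))
    return ell_list, F


def _middle_decades_window(ell: np.ndarray, decades: float = 2.0) -> tuple[float, float]:
    lo, hi = np.log10(ell.min()), np.log10(ell.max())
    if hi - lo <= decades:
        return float(ell.min()), float(ell.max())
    mid = 0.5 * (lo + hi)
    return float(10 ** (mid - decades / 2)), float(10 ** (mid + decades / 2))


def fit_walk_dimension(
    ell: np.ndarray, F: np.ndarray, fit_window: tuple[float, float] | None = None
) -> DMAResult:
    """OLS of log F on log ell; the slope is 1/d_w.

    The default window is the middle two decades of available ell, guarding
    against small-window discreteness and large-window noise.  Zero
    fluctuation values are excluded with a warning.
    """
    ell = np.asarray(ell, dtype=float)
    F = np.asarray(F, dtype=float)
    if fit_window is None:
        fit_window = _middle_decades_window(ell)
    sel = (ell >= fit_window[0]) & (ell <= fit_window[1])
    zero = sel & (F <= 0)
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero fluctuation values from the fit")
        sel &= F > 0
    if sel.sum() < 5:
        raise ValueError(f"only {int(sel.sum())} windows inside fit window {fit_window}; need 5")
    lx, ly = np.log(ell[sel]), np.log(F[sel])
    import statsmodels.api as sm

    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    slope = float(res.params[1])
    if not np.isfinite(slope):
        raise ValueError("non-finite fitted exponent")
    return DMAResult(
        ell=ell,
        F=F,
        inv_d_w=slope,
        stderr=float(res.bse[1]),
        d_w=1.0 / slope,
        fit_window=fit_window,
        residuals=np.asarray(res.resid),
    )


def dma_walk_dimension(
    series,
    ell_list: Sequence[int] | None = None,
    ell_max: int | None = None,
    fit_window: tuple[float, float] | None = None,
) -> DMAResult:
    """Convenience: fluctuation function plus exponent fit in one call."""
    ell, F = dma_fluctuation(series, ell_list, ell_max)
    return fit_walk_dimension(ell, F, fit_window)


@dataclass
class StationarityReport:
    """Increment MSD computed from starts in the first vs last quarter of
    the series; a ratio near 1 across lags indicates stationary increments
    (no aging)."""

    lags: np.ndarray
    msd_first: np.ndarray
    msd_last: np.ndarray
    ratio: np.ndarray
    max_ratio: float
    min_ratio: float
    stationary: bool


def stationarity_check(
    series, lags: Sequence[int] | None = None, band: tuple[float, float] = (0.5, 2.0)
) -> StationarityReport:
    """Aging diagnostic: compare MSD(t) of increments X_{T+t} - X_T with
    start points T in the first quarter of the data against starts in the
    last quarter.  Slowing-down (aging) processes show last-quarter MSD
    systematically below the first-quarter one; the verdict is 'stationary'
    when the ratio stays inside ``band`` at every probed lag."""
    x = _as_positions(series)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 points")
    if lags is None:
        # lags beyond ~N/32 have too few independent increments per quarter
        max_lag = max(1, n // 32)
        lags = np.unique(np.clip(2 ** np.arange(0, int(np.log2(max_lag)) + 1), 1, max_lag))
    lags = np.asarray(lags, dtype=int)
    q = n // 4
    msd_first = np.empty(len(lags))
    msd_last = np.empty(len(lags))
    for j, t in enumerate(lags):
        starts_first = np.arange(0, q)
        starts_first = starts_first[starts_first + t < n]
        d = x[starts_first + t] - x[starts_first]
        msd_first[j] = np.mean(d**2)
        starts_last = np.arange(3 * q, n - t)
        if len(starts_last) == 0:
            msd_last[j] = np.nan
            continue
        d = x[starts_last + t] - x[starts_last]
        msd_last[j] = np.mean(d**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = msd_last / msd_first
    finite = np.isfinite(ratio)
    stationary = bool(np.all((ratio[finite] >= band[0]) & (ratio[finite] <= band[1])))
    return StationarityReport(
        lags=lags,
        msd_first=msd_first,
        msd_last=msd_last,
        ratio=ratio,
        max_ratio=float(np.nanmax(ratio)),
        min_ratio=float(np.nanmin(ratio)),
        stationary=stationary,
    )
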