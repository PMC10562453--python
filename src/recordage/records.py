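"""Record extraction and censoring-aware survival estimation.

A record occurs at time t when X_t strictly exceeds every earlier value;
the initial observation is record n = 0 at T_0 = 0.  The record age
tau_n = T_{n+1} - T_n is the waiting time between the n-th and (n+1)-st
records; the age that is still open when the observation window closes is
only bounded below (censored) and is treated as such throughout.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .simulators import Trajectory

__all__ = [
    "RecordSeries",
    "SurvivalEstimate",
    "extract_records",
    "collect_records",
    "survival_estimate",
    "pooled_record_tail",
    "record_count_curve",
    "first_passage_times",
    "FirstPassageSample",
    "subtrajectory_sampler",
    "log_grid",
]


@dataclass
class RecordSeries:
    """Record times/values of one trajectory plus its censoring horizon.

    ``record_times[n]`` is T_n (physical time); completed ages are
    ``np.diff(record_times)``; the age of the last record is censored at
    ``horizon - record_times[-1]``.
    """

    record_times: np.ndarray
    record_values: np.ndarray
    horizon: float

    @property
    def n_records(self) -> int:
        return len(self.record_times)

    @property
    def ages(self) -> np.ndarray:
        """Completed record ages tau_0 .. tau_{n-2}."""
        return np.diff(self.record_times)

    @property
    def censored_age(self) -> float:
        """Lower bound on the age of the last record."""
        return float(self.horizon - self.record_times[-1])

    @property
    def last_age_censored(self) -> bool:
        return True  # the age open at the horizon is never observed complete


@dataclass
class SurvivalEstimate:
    """Empirical tail S(n, tau) = P(tau_n >= tau) on a tau grid.

    ``S`` is NaN where no trajectory was at risk; ``at_risk`` carries the
    denominator counts so fits can weight points by their precision.
    """

    n: int
    tau: np.ndarray
    S: np.ndarray
    at_risk: np.ndarray


def log_grid(lo: float, hi: float, points_per_decade: int = 20) -> np.ndarray:
    """Logarithmically spaced grid (default 20 points per decade)."""
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    n = max(2, int(np.ceil(np.log10(hi / lo) * points_per_decade)) + 1)
    return np.geomspace(lo, hi, n)


def extract_records(traj: Trajectory) -> RecordSeries:
    """Strict running-maximum records of one trajectory.

    Re-touching the running maximum is not a record; record times are the
    trajectory's physical times (relevant for scaled Brownian motion, whose
    clock is nonlinear in the step count).
    """
    x = np.asarray(traj.positions)
    if len(x) == 0:
        raise ValueError("empty trajectory")
    cm = np.maximum.accumulate(x)
    idx = np.flatnonzero(x[1:] > cm[:-1]) + 1
    idx = np.concatenate([[0], idx])
    return RecordSeries(
        record_times=np.asarray(traj.times, dtype=float)[idx],
        record_values=x[idx].astype(float),
        horizon=traj.horizon,
    )


def collect_records(trajectories: Iterable[Trajectory]) -> list[RecordSeries]:
    """Extract records from an iterable of trajectories (streaming-safe)."""
    return [extract_records(t) for t in trajectories]


def _nth_record_arrays(ensemble: Sequence[RecordSeries], n: int):
    """Per-trajectory (T_n, age_n, completed, horizon) for trajectories in
    which record n occurred; ``age_n`` is the censored elapsed time when
    record n+1 did not occur."""
    t_n, age, completed, horizon = [], [], [], []
    for rs in ensemble:
        if rs.n_records <= n:
            continue
        t_n.append(rs.record_times[n])
        horizon.append(rs.horizon)
        if rs.n_records > n + 1:
            age.append(rs.record_times[n + 1] - rs.record_times[n])
            completed.append(True)
        else:
            age.append(rs.horizon - rs.record_times[n])
            completed.append(False)
    return (np.asarray(t_n), np.asarray(age), np.asarray(completed, bool), np.asarray(horizon))


def survival_estimate(
    ensemble: Sequence[RecordSeries], n: int, tau_grid: np.ndarray | None = None
) -> SurvivalEstimate:
    """Censoring-aware estimate of S(n, tau) = P(tau_n >= tau).

    A trajectory is *at risk* at tau if its n-th record happened early
    enough (T_n <= horizon - tau) for an age >= tau to have been
    observable.  Among those, completed ages count in the numerator when
    tau_n >= tau; censored ages always do (their elapsed time
    horizon - T_n >= tau whenever the trajectory is at risk), so censored
    records enter as lower bounds instead of being discarded.
    """
    t_n, age, _completed, horizon = _nth_record_arrays(ensemble, n)
    if len(t_n) == 0:
        raise ValueError(f"record {n} never occurred in the ensemble")
    if tau_grid is None:
        tau_grid = log_grid(1.0, max(horizon.max(), 2.0))
    tau_grid = np.asarray(tau_grid, dtype=float)

    at_risk = np.empty(len(tau_grid), dtype=np.int64)
    surv = np.empty(len(tau_grid))
    for j, tau in enumerate(tau_grid):
        risk = t_n <= horizon - tau
        at_risk[j] = int(risk.sum())
        if at_risk[j] == 0:
            surv[j] = np.nan
        else:
            surv[j] = np.count_nonzero(risk & (age >= tau)) / at_risk[j]
    return SurvivalEstimate(n=n, tau=tau_grid, S=surv, at_risk=at_risk)


def pooled_record_tail(
    ensemble: Sequence[RecordSeries], tau_grid: np.ndarray | None = None
) -> SurvivalEstimate:
    """Survival of record ages pooled over all record indices n.

    Uses the same censoring-aware estimator as :func:`survival_estimate`
    with every record of every trajectory contributing one (possibly
    censored) age.  Useful on real data where per-n statistics are sparse.
    """
    t_all, age_all, horizon_all = [], [], []
    for rs in ensemble:
        t_all.append(rs.record_times)
        age_all.append(np.append(rs.ages, rs.censored_age))
        horizon_all.append(np.full(rs.n_records, rs.horizon))
    t_n = np.concatenate(t_all)
    age = np.concatenate(age_all)
    horizon = np.concatenate(horizon_all)
    if tau_grid is None:
        tau_grid = log_grid(1.0, max(horizon.max(), 2.0))
    tau_grid = np.asarray(tau_grid, dtype=float)

    at_risk = np.empty(len(tau_grid), dtype=np.int64)
    surv = np.empty(len(tau_grid))
    for j, tau in enumerate(tau_grid):
        risk = t_n <= horizon - tau
        at_risk[j] = int(risk.sum())
        surv[j] = np.count_nonzero(risk & (age >= tau)) / at_risk[j] if at_risk[j] else np.nan
    return SurvivalEstimate(n=-1, tau=tau_grid, S=surv, at_risk=at_risk)


def record_count_curve(
    ensemble: Sequence[RecordSeries], t_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean number of records achieved by time t, with the log-log slope
    fitted over the last decade of the grid.

    For a walk of dimension d_w the count grows as n(t) ~ t^(1/d_w) in a
    single regime, unlike the two-regime record-age tail.
    """
    horizons = np.array([rs.horizon for rs in ensemble])
    if t_grid is None:
        t_grid = log_grid(1.0, horizons.min())
    t_grid = np.asarray(t_grid, dtype=float)
    counts = np.zeros(len(t_grid))
    for rs in ensemble:
        counts += np.searchsorted(rs.record_times, t_grid, side="right")
    mean_n = counts / len(ensemble)
    sel = t_grid >= t_grid[-1] / 10.0
    slope = float(np.polyfit(np.log(t_grid[sel]), np.log(mean_n[sel]), 1)[0])
    return t_grid, mean_n, slope


@dataclass
class FirstPassageSample:
    """First-return times from many subinterval starts.

    ``windows[i]`` is the observable duration of start i; ``censored[i]``
    marks starts whose return had not happened by the subinterval end (for
    those ``times[i] == windows[i]`` is only a lower bound).
    """

    times: np.ndarray
    censored: np.ndarray
    windows: np.ndarray

    def survival(self, tau_grid: np.ndarray | None = None) -> SurvivalEstimate:
        """P(T_return >= tau); a start is at risk at tau only if its
        observation window is at least tau, so censored samples enter as
        lower bounds without biasing the tail."""
        if tau_grid is None:
            tau_grid = log_grid(1.0, max(self.times.max(), 2.0))
        tau_grid = np.asarray(tau_grid, dtype=float)
        at_risk = np.empty(len(tau_grid), dtype=np.int64)
        surv = np.empty(len(tau_grid))
        for j, tau in enumerate(tau_grid):
            risk = self.windows >= tau
            at_risk[j] = int(risk.sum())
            surv[j] = (
                np.count_nonzero(risk & (self.times >= tau)) / at_risk[j] if at_risk[j] else np.nan
            )
        return SurvivalEstimate(n=-1, tau=tau_grid, S=surv, at_risk=at_risk)


def _is_lattice(x: np.ndarray) -> bool:
    return np.issubdtype(x.dtype, np.integer) or bool(np.all(x == np.round(x)))


def first_passage_times(
    traj: Trajectory, starts: Sequence[int] | None = None, spacing: int = 200, lattice: bool | None = None
) -> FirstPassageSample:
    """First time to return to the value held at each subinterval start.

    For lattice (integer-valued) series a return is an exact revisit of the
    starting value; for continuous series it is the first sign change of
    X_{T+t} - X_T.  Starts default to every ``spacing`` steps; a start whose
    return has not occurred by the end of the series yields a censored
    sample equal to the remaining duration.
    """
    x = np.asarray(traj.positions)
    if starts is None:
        starts = _subtraj_starts(len(x), spacing)
    if lattice is None:
        lattice = _is_lattice(x)
    times, cens, windows = [], [], []
    for s in starts:
        d = x[s + 1 :] - x[s]
        if len(d) == 0:
            continue
        if lattice:
            hits = np.flatnonzero(d == 0)
        else:
            s0 = np.sign(d[np.flatnonzero(d)[0]]) if np.any(d) else 0.0
            hits = np.flatnonzero(np.sign(d) != s0) if s0 != 0 else np.array([0])
        windows.append(len(d))
        if len(hits):
            times.append(hits[0] + 1)
            cens.append(False)
        else:
            times.append(len(d))
            cens.append(True)
    return FirstPassageSample(
        np.asarray(times, dtype=float),
        np.asarray(cens, dtype=bool),
        np.asarray(windows, dtype=float),
    )


def _subtraj_starts(n_points: int, spacing: int) -> np.ndarray:
    if n_points <= spacing:
        raise ValueError(f"series of {n_points} points is shorter than the spacing {spacing}")
    return np.arange(0, n_points - 1, spacing)


def subtrajectory_sampler(
    traj: Trajectory, spacing: int = 200, count: int | None = None
) -> list[Trajectory]:
    """Overlapping subtrajectories with equally spaced starts, each
    re-zeroed (value at the start subtracted) so record extraction treats
    it as a fresh walk.  The default spacing of 200 steps keeps successive
    starts weakly dependent."""
    x = np.asarray(traj.positions)
    t = np.asarray(traj.times, dtype=float)
    starts = _subtraj_starts(len(x), spacing)
    if count is not None:
        starts = starts[:count]
    return [Trajectory(t[s:] - t[s], x[s:] - x[s], traj.spec) for s in starts]
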