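"""The two-regime scaling law for record ages and its exponent algebra.

For an asymptotically scale-invariant walk of dimension d_w (X_t ~ t^{1/d_w}),
with aged increments X_{T+t} - X_T ~ t^{1/d_w0} T^{alpha/2} defining the
short-time walk dimension d_w0 = (1/d_w - alpha/2)^{-1}, the tail
S(n, tau) = P(tau_n >= tau) of the n-th record age obeys

    S(n, tau) ~ (1/n) (n^{d_w} / tau)^{1/d_w0}   for n^{d_w - d_w0} << tau << n^{d_w}
    S(n, tau) ~ (1/n) (n^{d_w} / tau)^{theta}    for tau >> n^{d_w}

with theta the persistence exponent (theta = 1 - 1/d_w for stationary
increments).  For Markovian walks d_w = d_w0 = 2 and theta = 1/2, so the two
branches merge into the single Sparre-Andersen tau^{-1/2} law.

This module provides the exponent bookkeeping, the piecewise prediction,
weighted log-log tail fitting, and a quantitative check of the
effective-independence product formula
P(T_n <= T) ~ prod_{k<n} (1 - S(k, T)).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .records import RecordSeries, SurvivalEstimate, log_grid, survival_estimate

__all__ = [
    "ExponentSet",
    "RegimePrediction",
    "effective_walk_dimension",
    "solve_alpha",
    "predicted_tail",
    "regime_windows",
    "TailFit",
    "fit_tail_exponent",
    "collapse_curves",
    "ProductFormulaReport",
    "product_formula_check",
    "collapsed_tail_fit",
    "model_registry",
    "get_exponents",
]


def effective_walk_dimension(d_w: float, alpha: float) -> float:
    """Short-time walk dimension d_w0 = (1/d_w - alpha/2)^{-1}."""
    arg = 1.0 / d_w - alpha / 2.0
    if arg <= 0:
        raise ValueError(
            f"1/d_w - alpha/2 = {arg:.4g} <= 0: process outside the theory's domain"
        )
    return 1.0 / arg


def solve_alpha(d_w: float, d_w0: float) -> float:
    """Aging exponent implied by the pair (d_w, d_w0)."""
    return 2.0 * (1.0 / d_w - 1.0 / d_w0)


@dataclass(frozen=True)
class ExponentSet:
    """(d_w, d_w0, theta, alpha) with the defining constraint
    d_w0 = (1/d_w - alpha/2)^{-1} enforced at construction."""

    d_w: float
    d_w0: float
    theta: float
    alpha: float

    def __post_init__(self) -> None:
        if self.d_w <= 1:
            raise ValueError("d_w must exceed 1")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        expected = effective_walk_dimension(self.d_w, self.alpha)
        if not np.isclose(expected, self.d_w0, rtol=1e-10, atol=1e-12):
            raise ValueError(
                f"inconsistent exponents: d_w0={self.d_w0} but (1/d_w - alpha/2)^-1={expected}"
            )

    @classmethod
    def from_alpha(cls, d_w: float, theta: float, alpha: float = 0.0) -> "ExponentSet":
        return cls(d_w, effective_walk_dimension(d_w, alpha), theta, alpha)

    @classmethod
    def from_d_w0(cls, d_w: float, theta: float, d_w0: float) -> "ExponentSet":
        return cls(d_w, d_w0, theta, solve_alpha(d_w, d_w0))

    @classmethod
    def stationary(cls, d_w: float) -> "ExponentSet":
        """Stationary increments: alpha = 0, d_w0 = d_w, theta = 1 - 1/d_w."""
        return cls(d_w, d_w, 1.0 - 1.0 / d_w, 0.0)

    @property
    def regime1_exponent(self) -> float:
        return 1.0 / self.d_w0

    @property
    def regime2_exponent(self) -> float:
        return self.theta


@dataclass(frozen=True)
class RegimePrediction:
    """Crossover scales and branch exponents of the tail law at record index n."""

    n: int
    lower_crossover: float  # n^(d_w - d_w0): onset of the scale-invariant tail
    upper_crossover: float  # n^(d_w): typical T_n, switch to persistence decay
    regime1_exponent: float
    regime2_exponent: float
    regime1_prefactor_scaling: float  # S grows with n as n^(-1 + d_w/d_w0)
    regime2_prefactor_scaling: float  # ... and as n^(-1 + d_w*theta)


def regime_prediction(n: int, exponents: ExponentSet) -> RegimePrediction:
    e = exponents
    return RegimePrediction(
        n=n,
        lower_crossover=float(n) ** (e.d_w - e.d_w0),
        upper_crossover=float(n) ** e.d_w,
        regime1_exponent=1.0 / e.d_w0,
        regime2_exponent=e.theta,
        regime1_prefactor_scaling=-1.0 + e.d_w / e.d_w0,
        regime2_prefactor_scaling=-1.0 + e.d_w * e.theta,
    )


def predicted_tail(
    n: int,
    tau: np.ndarray,
    exponents: ExponentSet,
    amplitude1: float = 1.0,
    amplitude2: float | None = None,
) -> np.ndarray:
    """Piecewise power-law tail S(n, tau), amplitudes tied by continuity at
    the crossover tau = n^{d_w} unless ``amplitude2`` is given."""
    if n < 1:
        raise ValueError("n must be >= 1")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    e = exponents
    cross = float(n) ** e.d_w
    if amplitude2 is None:
        amplitude2 = amplitude1  # continuous matching: both branches equal A/n at the crossover
    ratio = cross / tau
    s1 = (amplitude1 / n) * ratio ** (1.0 / e.d_w0)
    s2 = (amplitude2 / n) * ratio ** e.theta
    return np.where(tau < cross, s1, s2)


def regime_windows(
    n: int, exponents: ExponentSet, horizon: float, guard: float = 10.0
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Default fit windows with one-decade guard bands against crossover
    contamination: regime 1 in [guard*n^{d_w-d_w0}, n^{d_w}/guard], regime 2
    in [guard*n^{d_w}, horizon/guard]."""
    e = exponents
    lo = float(n) ** (e.d_w - e.d_w0)
    hi = float(n) ** e.d_w
    return (guard * lo, hi / guard), (guard * hi, horizon / guard)


@dataclass
class TailFit:
    """Weighted log-log fit of a survival tail: S ~ tau^-exponent."""

    exponent: float
    stderr: float
    r_squared: float
    n_points: int
    window: tuple[float, float]


def fit_tail_exponent(
    surv: SurvivalEstimate,
    window: tuple[float, float],
    min_at_risk: int = 10,
    min_points: int = 5,
) -> TailFit:
    """Weighted least squares of log S on log tau inside ``window``.

    Points are weighted by sqrt(at_risk); undefined points (no trajectory
    at risk, or S = 0) are excluded.  Returns minus the slope, so a
    tau^{-1/2} tail yields exponent 0.5.
    """
    tau, S, at_risk = surv.tau, surv.S, surv.at_risk
    sel = (
        (tau >= window[0])
        & (tau <= window[1])
        & np.isfinite(S)
        & (S > 0)
        & (at_risk >= min_at_risk)
    )
    if sel.sum() < min_points:
        raise ValueError(
            f"only {int(sel.sum())} usable grid points in window {window}; need {min_points}"
        )
    import statsmodels.api as sm

    x = sm.add_constant(np.log(tau[sel]))
    res = sm.WLS(np.log(S[sel]), x, weights=np.sqrt(at_risk[sel])).fit()
    return TailFit(
        exponent=-float(res.params[1]),
        stderr=float(res.bse[1]),
        r_squared=float(res.rsquared),
        n_points=int(sel.sum()),
        window=window,
    )


def collapse_curves(
    ensemble: Sequence[RecordSeries],
    n_values: Sequence[int],
    d_w: float,
    tau_grid: np.ndarray | None = None,
) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Rescaled curves (tau/n^{d_w}, n*S(n,tau), at_risk) for each n.

    Under the scaling law these collapse onto the single master curve psi,
    which is the data-collapse diagnostic used to validate an exponent set.
    """
    out = {}
    for n in n_values:
        est = survival_estimate(ensemble, n, tau_grid)
        xi = est.tau / float(n) ** d_w
        out[n] = (xi, n * est.S, est.at_risk)
    return out


def collapse_sup_distance(
    curves: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]],
    xi_window: tuple[float, float],
    n_bins: int = 12,
    min_at_risk: int = 50,
) -> float:
    """Sup distance between binned rescaled curves over a common window of
    the scaling variable xi = tau/n^{d_w} (log-spaced geometric-mean bins)."""
    edges = np.geomspace(xi_window[0], xi_window[1], n_bins + 1)
    binned = []
    for xi, y, at_risk in curves.values():
        ok = np.isfinite(y) & (at_risk >= min_at_risk)
        vals = np.full(n_bins, np.nan)
        idx = np.digitize(xi[ok], edges) - 1
        for b in range(n_bins):
            sel = idx == b
            if sel.any():
                vals[b] = np.exp(np.mean(np.log(np.maximum(y[ok][sel], 1e-300))))
        binned.append(vals)
    binned = np.array(binned)
    common = np.all(np.isfinite(binned), axis=0)
    if not common.any():
        raise ValueError("no common bins across curves")
    return float(np.nanmax(binned[:, common].max(axis=0) - binned[:, common].min(axis=0)))


def collapsed_tail_fit(
    ensemble: Sequence[RecordSeries],
    n_values: Sequence[int],
    d_w: float,
    xi_window: tuple[float, float],
    tau_grid: np.ndarray | None = None,
    min_at_risk: int = 10,
    min_points: int = 5,
    estimates: dict[int, SurvivalEstimate] | None = None,
) -> TailFit:
    """Regime exponent from several record indices at once: common log-log
    slope of S(n, tau) vs the scaling variable xi = tau/n^{d_w}, with one
    free intercept per n.

    Per-curve intercepts absorb the finite-n amplitude corrections that
    would otherwise tilt a naively stacked fit, while sharing the slope
    multiplies the effective tail statistics -- the deep tail of a single
    record index is a staircase with very few completed ages.  Points are
    weighted by their approximate inverse variance on the log scale,
    S*at_risk/(1-S) (the expected number of ages exceeding tau), which is
    what controls the precision of an empirical log-survival value.
    Precomputed per-n ``estimates`` may be supplied instead of an ensemble.
    """
    xs, ys, ws, grp = [], [], [], []
    for gi, n in enumerate(n_values):
        est = estimates[n] if estimates is not None else survival_estimate(ensemble, n, tau_grid)
        xi = est.tau / float(n) ** d_w
        sel = (
            (xi >= xi_window[0])
            & (xi <= xi_window[1])
            & np.isfinite(est.S)
            & (est.S > 0)
            & (est.S < 1)
            & (est.at_risk >= min_at_risk)
        )
        xs.append(np.log(xi[sel]))
        ys.append(np.log(est.S[sel]))
        ws.append(est.S[sel] * est.at_risk[sel] / (1.0 - est.S[sel]))
        grp.append(np.full(int(sel.sum()), gi))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    w = np.concatenate(ws)
    grp = np.concatenate(grp)
    if len(x) < min_points:
        raise ValueError(f"only {len(x)} usable points in xi window {xi_window}")
    import statsmodels.api as sm

    used = np.unique(grp)
    dummies = (grp[:, None] == used[None, :]).astype(float)
    design = np.column_stack([dummies, x])
    res = sm.WLS(y, design, weights=w).fit()
    return TailFit(
        exponent=-float(res.params[-1]),
        stderr=float(res.bse[-1]),
        r_squared=float(res.rsquared),
        n_points=len(x),
        window=xi_window,
    )


@dataclass
class ProductFormulaReport:
    """Comparison of the measured distribution of T_n with the product
    prediction built from per-k record-age tails (effective independence)."""

    n: int
    time_grid: np.ndarray
    empirical_cdf: np.ndarray
    product_cdf: np.ndarray
    sup_distance: float


def product_formula_check(
    ensemble: Sequence[RecordSeries], n: int, time_grid: np.ndarray | None = None
) -> ProductFormulaReport:
    """Test the effective-independence product formula
    P(T_n <= T) ~ prod_{k=0}^{n-1} (1 - S(k, T)).

    Both sides are estimated from the same ensemble; the report's sup
    distance quantifies how far the record ages are from independent.  For
    n = 1 the product reduces to 1 - S(0, T) and the distance is zero by
    construction (up to censoring effects).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    t_n = np.array([rs.record_times[n] for rs in ensemble if rs.n_records > n])
    if len(t_n) == 0:
        raise ValueError(f"record {n} never occurred")
    n_total = len(ensemble)
    if time_grid is None:
        time_grid = log_grid(max(1.0, np.percentile(t_n, 1)), np.percentile(t_n, 99.5))
    time_grid = np.asarray(time_grid, dtype=float)

    # strict inequality: P(T_n < T) matches prod_k P(tau_k < T) at the atoms
    # of lattice-time records (tau takes integer values)
    emp = np.searchsorted(np.sort(t_n), time_grid, side="left") / n_total
    prod = np.ones(len(time_grid))
    for k in range(n):
        sk = survival_estimate(ensemble, k, time_grid)
        prod *= 1.0 - np.nan_to_num(sk.S, nan=1.0)
    ok = np.isfinite(emp) & np.isfinite(prod)
    sup = float(np.max(np.abs(emp[ok] - prod[ok])))
    return ProductFormulaReport(n, time_grid, emp, prod, sup)


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

def model_registry() -> list[dict]:
    """Reference exponent sets for the packaged models (parsed JSON)."""
    text = resources.files("recordage.data").joinpath("model_registry.json").read_text()
    return json.loads(text)["entries"]


def get_exponents(model: str, **params) -> ExponentSet:
    """Look up the reference ExponentSet for a model at its canonical
    parameters; unspecified parameters match the registry defaults."""
    for entry in model_registry():
        if entry["model"] != model:
            continue
        if all(
            np.isclose(entry["params"].get(k, np.nan), v, rtol=1e-9)
            for k, v in params.items()
        ):
            return ExponentSet(entry["d_w"], entry["d_w0"], entry["theta"], entry["alpha"])
    raise KeyError(f"no registry entry for model={model!r} params={params}")
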