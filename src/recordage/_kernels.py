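"""Numba step kernels for the lattice walk models.

Each kernel consumes a pre-drawn array of uniforms (one per step, drawn from
the per-trajectory generator) so that trajectories are bit-reproducible and
independent of execution order.  Kernels return the position series
``x[0..n_steps]`` with ``x[0] = 0``.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def elephant_steps(u_pick: np.ndarray, u_flip: np.ndarray, beta: float) -> np.ndarray:
    """Elephant random walk positions.

    The step at time t is a uniformly chosen earlier step, reversed with
    probability ``beta``; the first step is +/-1 equiprobably.
    """
    n = u_pick.shape[0]
    x = np.empty(n + 1, dtype=np.int64)
    x[0] = 0
    n_plus = 0  # number of previous +1 steps
    for t in range(n):
        if t == 0:
            step = 1 if u_pick[0] < 0.5 else -1
        else:
            # picking a uniform earlier step == +1 with prob n_plus/t
            step = 1 if u_pick[t] < n_plus / t else -1
            if u_flip[t] < beta:
                step = -step
        if step == 1:
            n_plus += 1
        x[t + 1] = x[t] + step
    return x


@njit(cache=True)
def satw_positions(u: np.ndarray, beta: float) -> np.ndarray:
    """Self-attractive walk: jump probabilities depend on whether the
    neighbouring sites were ever visited (exp(-beta) weight for a visited
    site, weight 1 for a virgin one)."""
    n = u.shape[0]
    x = np.empty(n + 1, dtype=np.int64)
    x[0] = 0
    counts = np.zeros(2 * n + 3, dtype=np.int32)  # calloc: lazily zeroed pages
    off = n + 1
    counts[off] = 1  # origin counts as visited once
    w = np.exp(-beta)
    # p(right) for (left visited?, right visited?)
    p_vv = 0.5
    p_00 = 0.5
    p_v0 = 1.0 / (1.0 + w)      # left visited, right virgin
    p_0v = w / (1.0 + w)        # right visited, left virgin
    pos = 0
    for t in range(n):
        lv = counts[off + pos - 1] > 0
        rv = counts[off + pos + 1] > 0
        if lv:
            p_right = p_vv if rv else p_v0
        else:
            p_right = p_0v if rv else p_00
        if u[t] < p_right:
            pos += 1
        else:
            pos -= 1
        counts[off + pos] += 1
        x[t + 1] = pos
    return x


@njit(cache=True)
def sesrw_positions(u: np.ndarray, beta: float, kappa: float) -> np.ndarray:
    """Sub-exponentially self-repelling walk (kappa=1: true self-avoiding
    walk).  Site weights exp(-beta * n^kappa) with n the visit count;
    probabilities are computed from the weight difference to avoid overflow."""
    n = u.shape[0]
    x = np.empty(n + 1, dtype=np.int64)
    x[0] = 0
    counts = np.zeros(2 * n + 3, dtype=np.int32)
    off = n + 1
    counts[off] = 1
    pos = 0
    for t in range(n):
        nl = counts[off + pos - 1]
        nr = counts[off + pos + 1]
        if nl == nr:
            p_right = 0.5
        else:
            if kappa == 1.0:
                d = float(nr - nl)
            else:
                d = float(nr) ** kappa - float(nl) ** kappa
            # p_right = w_r / (w_l + w_r) = 1 / (1 + exp(beta * d))
            p_right = 1.0 / (1.0 + np.exp(beta * d))
        if u[t] < p_right:
            pos += 1
        else:
            pos -= 1
        counts[off + pos] += 1
        x[t + 1] = pos
    return x


@njit(cache=True)
def all_positions(u: np.ndarray, trans: np.ndarray, first_dir: int) -> np.ndarray:
    """Average Levy Lorentz gas walk.

    ``trans[|x|]`` is the probability of keeping the current direction at
    site x; with probability 1-trans the direction is reversed.  The sub- and
    superdiffusive variants differ only in the table passed in.
    """
    n = u.shape[0]
    x = np.empty(n + 1, dtype=np.int64)
    x[0] = 0
    pos = 0
    d = first_dir
    for t in range(n):
        a = pos if pos >= 0 else -pos
        if u[t] >= trans[a]:
            d = -d
        pos += d
        x[t + 1] = pos
    return x


@njit(cache=True)
def record_times_int(x: np.ndarray) -> np.ndarray:
    """Indices of strict running-maximum records (index 0 included)."""
    n = x.shape[0]
    out = np.empty(n, dtype=np.int64)
    out[0] = 0
    k = 1
    m = x[0]
    for t in range(1, n):
        if x[t] > m:
            m = x[t]
            out[k] = t
            k += 1
    return out[:k]
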