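"""Trajectory generators for scale-invariant random walks with memory.

Nine models are provided, covering the three routes to non-Markovian
dynamics in one dimension:

* long-range step correlations — fractional Brownian motion (:func:`simulate_fbm`),
  its quenched-initial-condition interface analogue (:func:`simulate_qfbm`),
  and the elephant random walk (:func:`simulate_erw`);
* interaction with the visited territory — the self-attractive walk
  (:func:`simulate_satw`), the sub-exponential self-repelling walk and the
  true self-avoiding walk (:func:`simulate_sesrw`);
* explicit space/time dependence — the averaged Levy-Lorentz gas in its
  sub- and superdiffusive variants (:func:`simulate_all`) and scaled
  Brownian motion (:func:`simulate_sbm`).

The simple symmetric random walk (:func:`simulate_simple_rw`) is the
Markovian baseline and exact oracle.

Reproducibility contract: every trajectory is generated from its own
``numpy`` PCG64 generator seeded with ``SeedSequence([seed, traj_index])``,
so an ensemble is order-independent and a (model, params, n_steps, seed)
tuple reproduces a trajectory bit-for-bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np

from . import _kernels

__all__ = [
    "ModelSpec",
    "Trajectory",
    "simulate_fbm",
    "simulate_qfbm",
    "simulate_erw",
    "simulate_satw",
    "simulate_sesrw",
    "simulate_tsaw",
    "simulate_all",
    "simulate_sbm",
    "simulate_simple_rw",
    "simulate",
    "iter_trajectories",
    "MODEL_NAMES",
]

MODEL_NAMES = (
    "fbm",
    "qfbm",
    "erw",
    "satw",
    "sesrw",
    "tsaw",
    "sub_all",
    "sup_all",
    "sbm",
    "simple_rw",
)


@dataclass(frozen=True)
class ModelSpec:
    """Complete description of one simulated trajectory."""

    model: str
    params: tuple  # sorted (name, value) pairs
    n_steps: int
    seed: int
    traj_index: int = 0

    @staticmethod
    def make(model: str, params: dict, n_steps: int, seed: int, traj_index: int = 0) -> "ModelSpec":
        return ModelSpec(model, tuple(sorted(params.items())), int(n_steps), int(seed), int(traj_index))

    def params_dict(self) -> dict:
        return dict(self.params)


@dataclass
class Trajectory:
    """One realisation: positions X_t at (physical) times, X_0 = 0 at t = 0."""

    times: np.ndarray
    positions: np.ndarray
    spec: ModelSpec | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions)
        if self.times.shape != self.positions.shape:
            raise ValueError("times and positions must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def horizon(self) -> float:
        return float(self.times[-1])


def _rng(seed: int, traj_index: int = 0) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), int(traj_index)])))


# ---------------------------------------------------------------------------
# fractional Brownian motion
# ---------------------------------------------------------------------------

def _fgn_autocov(H: float, n: int) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    return 0.5 * (np.abs(k + 1) ** (2 * H) + np.abs(k - 1) ** (2 * H) - 2 * k ** (2 * H))


@lru_cache(maxsize=8)
def _dh_sqrt_eigs(H: float, n: int) -> np.ndarray | None:
    """Square roots of the circulant-embedding eigenvalues, or None when the
    embedding is not positive semi-definite and the dense fallback applies."""
    g = _fgn_autocov(H, n)
    row = np.concatenate([g, g[-2:0:-1]])  # length 2n
    eigs = np.fft.fft(row).real
    if eigs.min() < -1e-8 * max(1.0, eigs.max()):
        return None
    return np.sqrt(np.clip(eigs, 0.0, None))


@lru_cache(maxsize=4)
def _fgn_chol(H: float, n: int) -> np.ndarray:
    g = _fgn_autocov(H, n)
    from scipy.linalg import cholesky, toeplitz

    return cholesky(toeplitz(g[:n]), lower=True)


def _sample_fgn(H: float, n: int, rng: np.random.Generator) -> np.ndarray:
    sq = _dh_sqrt_eigs(float(H), int(n))
    if sq is None:  # rare: fall back to dense factorisation
        return _fgn_chol(float(H), int(n)) @ rng.standard_normal(n)
    m = 2 * n
    w = np.empty(m, dtype=complex)
    z = rng.standard_normal(m)
    w[0] = sq[0] * z[0]
    w[n] = sq[n] * z[1]
    a = z[2 : n + 1]
    b = z[n + 1 :]
    half = sq[1:n] / np.sqrt(2.0)
    w[1:n] = half * (a + 1j * b)
    w[n + 1 :] = np.conj(w[1:n][::-1])
    return (np.fft.fft(w).real / np.sqrt(m))[:n]


def simulate_fbm(H: float, n_steps: int, seed: int, traj_index: int = 0) -> Trajectory:
    """Fractional Brownian motion with Cov(X_t, X_s) = (t^2H + s^2H - |t-s|^2H)/2.

    Exact sampling of the fractional Gaussian noise by Davies-Harte
    circulant embedding, with a dense Cholesky fallback if the embedding
    fails to be positive semi-definite.
    """
    if not 0.0 < H < 1.0:
        raise ValueError(f"Hurst exponent must lie in (0, 1), got {H}")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = _rng(seed, traj_index)
    fgn = _sample_fgn(H, n_steps, rng)
    x = np.concatenate([[0.0], np.cumsum(fgn)])
    spec = ModelSpec.make("fbm", {"H": H}, n_steps, seed, traj_index)
    return Trajectory(np.arange(n_steps + 1, dtype=float), x, spec)


# ---------------------------------------------------------------------------
# quenched fBm: tagged-site height of an initially flat interface
# ---------------------------------------------------------------------------

def simulate_qfbm(
    z: float = 2.0,
    n_steps: int = 1024,
    L: int = 256,
    dt: float = 0.1,
    seed: int = 0,
    noise_amp: float = 1.0,
    traj_index: int = 0,
) -> Trajectory:
    """Height X_t = h(0, t) of an interface governed by
    dh/dt = -(-Laplacian)^{z/2} h + white noise, started flat (h = 0).

    Integrated mode-by-mode in Fourier space with the exact
    Ornstein-Uhlenbeck update over each substep of length ``dt``
    (unconditionally stable for any z and dt).  For z = 2 this is the
    Edwards-Wilkinson interface; the tagged-site process then has Hurst
    exponent 1/4 with aging (quenched) increments at early times.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if L != 1 and (L < 64 or L % 2):
        raise ValueError("L must be even and >= 64 (or exactly 1)")
    rng = _rng(seed, traj_index)
    sub = max(1, round(1.0 / dt))
    spec = ModelSpec.make("qfbm", {"z": z, "L": L, "dt": dt, "noise_amp": noise_amp}, n_steps, seed, traj_index)
    times = np.arange(n_steps + 1, dtype=float)

    if L == 1:  # Laplacian absent: pure integrated noise
        incr = noise_amp * np.sqrt(dt) * rng.standard_normal(n_steps * sub)
        x = np.concatenate([[0.0], np.cumsum(incr)[sub - 1 :: sub]])
        return Trajectory(times, x, spec)

    k = np.arange(L // 2 + 1)
    lam = (2.0 - 2.0 * np.cos(2.0 * np.pi * k / L)) ** (z / 2.0)
    decay = np.exp(-lam * dt)
    # variance of the exact OU noise term per mode ((1-e^{-2 lam dt})/(2 lam))
    var = np.where(lam > 0, -np.expm1(-2.0 * lam * dt) / np.where(lam > 0, 2.0 * lam, 1.0), dt)
    amp = noise_amp * np.sqrt(var)

    hq = np.zeros(L // 2 + 1, dtype=complex)
    x = np.empty(n_steps + 1)
    x[0] = 0.0
    for t in range(n_steps):
        for _ in range(sub):
            noise = np.fft.rfft(rng.standard_normal(L))
            hq = hq * decay + amp * noise
        x[t + 1] = np.fft.irfft(hq, L)[0]
    return Trajectory(times, x, spec)


# ---------------------------------------------------------------------------
# lattice models with memory
# ---------------------------------------------------------------------------

def simulate_erw(beta: float, n_steps: int, seed: int, traj_index: int = 0) -> Trajectory:
    """Elephant random walk: each step copies a uniformly chosen earlier
    step and is reversed with probability ``beta`` (first step +/-1
    equiprobably)."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = _rng(seed, traj_index)
    u_pick = rng.random(n_steps)
    u_flip = rng.random(n_steps)
    x = _kernels.elephant_steps(u_pick, u_flip, float(beta))
    spec = ModelSpec.make("erw", {"beta": beta}, n_steps, seed, traj_index)
    return Trajectory(np.arange(n_steps + 1, dtype=float), x, spec)


def simulate_satw(beta: float, n_steps: int, seed: int, traj_index: int = 0) -> Trajectory:
    """Self-attractive walk: jump to neighbour j with probability
    proportional to exp(-beta * H(n_j)), H(0) = 0 and H(n>0) = 1, where n_j
    counts previous visits to j.  The origin starts visited once and the
    landing site's count is incremented after each jump."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = _rng(seed, traj_index)
    x = _kernels.satw_positions(rng.random(n_steps), float(beta))
    spec = ModelSpec.make("satw", {"beta": beta}, n_steps, seed, traj_index)
    return Trajectory(np.arange(n_steps + 1, dtype=float), x, spec)


def simulate_sesrw(beta: float, kappa: float, n_steps: int, seed: int, traj_index: int = 0) -> Trajectory:
    """Sub-exponential self-repelling walk: neighbour weights
    exp(-beta * n_j^kappa).  kappa = 1 is the true self-avoiding walk,
    kappa = 0.5 the sub-exponential variant."""
    if beta < 0 or kappa <= 0:
        raise ValueError("require beta >= 0 and kappa > 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = _rng(seed, traj_index)
    x = _kernels.sesrw_positions(rng.random(n_steps), float(beta), float(kappa))
    spec = ModelSpec.make("sesrw", {"beta": beta, "kappa": kappa}, n_steps, seed, traj_index)
    return Trajectory(np.arange(n_steps + 1, dtype=float), x, spec)


def simulate_tsaw(beta: float, n_steps: int, seed: int, traj_index: int = 0) -> Trajectory:
    """True self-avoiding walk: the kappa = 1 special case of the SESRW."""
    t = simulate_sesrw(beta, 1.0, n_steps, seed, traj_index)
    t.spec = ModelSpec.make("tsaw", {"beta": beta}, n_steps, seed, traj_index)
    return t


@lru_cache(maxsize=8)
def _all_trans_table(a: float, mode: str, size: int) -> np.ndarray:
    xs = np.arange(size, dtype=float)
    with np.errstate(divide="ignore"):
        alg = np.minimum(1.0, xs ** (a - 1.0))
    if mode == "sub":
        trans = alg
        trans[0] = 1.0  # always transmit at the origin
    elif mode == "super":
        # reflection coefficient |x|^{a-1}/2; the 1/2 keeps site |x|=1 from
        # being perfectly reflecting (which would trap the walker near 0)
        trans = 1.0 - 0.5 * alg
        trans[0] = 0.5
    else:
        raise ValueError("mode must be 'sub' or 'super'")
    return trans


def simulate_all(a: float, mode: str, n_steps: int, seed: int, traj_index: int = 0) -> Trajectory:
    """Averaged Levy-Lorentz gas: a persistent lattice walk whose
    transmission (mode='sub') or reflection (mode='super') coefficient
    decays as |x|^{a-1} with the distance to the origin."""
    if not 0.0 < a < 1.0:
        raise ValueError("a must lie in (0, 1)")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = _rng(seed, traj_index)
    trans = _all_trans_table(float(a), mode, n_steps + 2)
    u = rng.random(n_steps + 1)
    first_dir = 1 if u[0] < 0.5 else -1
    x = _kernels.all_positions(u[1:], trans, first_dir)
    spec = ModelSpec.make(f"{mode}_all", {"a": a}, n_steps, seed, traj_index)
    return Trajectory(np.arange(n_steps + 1, dtype=float), x, spec)


def simulate_sbm(beta_sbm: float, n_ops: int, seed: int, traj_index: int = 0) -> Trajectory:
    """Scaled Brownian motion with MSD growing as t^beta_sbm.

    Realised exactly as a time-changed simple walk: unit +/-1 steps at
    operational times u = 1..n_ops reported at physical times
    t = u^(1/beta_sbm), equivalent in law to a jump rate decaying (or
    growing) algebraically in time; walk dimension d_w = 2/beta_sbm with
    short-time increment dimension 2.
    """
    if not 0.0 < beta_sbm < 2.0:
        raise ValueError("beta_sbm must lie in (0, 2)")
    if n_ops < 1:
        raise ValueError("n_ops must be >= 1")
    rng = _rng(seed, traj_index)
    steps = 2 * (rng.random(n_ops) < 0.5).astype(np.int64) - 1
    x = np.concatenate([[0], np.cumsum(steps)])
    times = np.arange(n_ops + 1, dtype=float) ** (1.0 / beta_sbm)
    spec = ModelSpec.make("sbm", {"beta_sbm": beta_sbm}, n_ops, seed, traj_index)
    return Trajectory(times, x, spec)


def simulate_simple_rw(n_steps: int, seed: int, traj_index: int = 0) -> Trajectory:
    """Simple symmetric +/-1 random walk (the Markovian baseline)."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = _rng(seed, traj_index)
    steps = 2 * (rng.random(n_steps) < 0.5).astype(np.int64) - 1
    x = np.concatenate([[0], np.cumsum(steps)])
    spec = ModelSpec.make("simple_rw", {}, n_steps, seed, traj_index)
    return Trajectory(np.arange(n_steps + 1, dtype=float), x, spec)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_SIMULATORS = {
    "fbm": lambda n, s, i, p: simulate_fbm(p["H"], n, s, i),
    "qfbm": lambda n, s, i, p: simulate_qfbm(
        p.get("z", 2.0), n, p.get("L", 256), p.get("dt", 0.1), s, p.get("noise_amp", 1.0), i
    ),
    "erw": lambda n, s, i, p: simulate_erw(p["beta"], n, s, i),
    "satw": lambda n, s, i, p: simulate_satw(p["beta"], n, s, i),
    "sesrw": lambda n, s, i, p: simulate_sesrw(p["beta"], p["kappa"], n, s, i),
    "tsaw": lambda n, s, i, p: simulate_tsaw(p["beta"], n, s, i),
    "sub_all": lambda n, s, i, p: simulate_all(p["a"], "sub", n, s, i),
    "sup_all": lambda n, s, i, p: simulate_all(p["a"], "super", n, s, i),
    "sbm": lambda n, s, i, p: simulate_sbm(p["beta_sbm"], n, s, i),
    "simple_rw": lambda n, s, i, p: simulate_simple_rw(n, s, i),
}


def iter_trajectories(model: str, n_steps: int, n_traj: int, seed: int, **params) -> Iterator[Trajectory]:
    """Yield ``n_traj`` independent trajectories one at a time (memory-safe
    for large ensembles); trajectory i uses SeedSequence([seed, i])."""
    if model not in _SIMULATORS:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    fn = _SIMULATORS[model]
    for i in range(n_traj):
        yield fn(n_steps, seed, i, params)


def simulate(model: str, n_steps: int, n_traj: int = 1, seed: int = 0, **params) -> list[Trajectory]:
    """Materialised ensemble; see :func:`iter_trajectories`."""
    return list(iter_trajectories(model, n_steps, n_traj, seed, **params))
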