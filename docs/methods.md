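# Methods

This note documents the models, estimators and numerical choices behind
`recordage`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the packaged tests do and do not demonstrate.

## Scope and model class

The package addresses record ages of one-dimensional, continuous (no
broad-tailed jumps), non-smooth, asymptotically scale-invariant random
walks. Three quantities organise everything:

* walk dimension d_w: X_t ∝ t^{1/d_w};
* effective short-time walk dimension d_w⁰ with aging exponent α:
  X_{T+t} − X_T ∝ t^{1/d_w⁰} T^{α/2}, d_w⁰ ≡ (1/d_w − α/2)^{−1};
* persistence exponent θ: first-passage survival ∝ τ^{−θ}
  (θ = 1 − 1/d_w when increments are stationary).

The record-age tail S(n, τ) = P(τ_n ≥ τ) then follows the two-regime law
(regime 1 exponent 1/d_w⁰ for n^{d_w−d_w⁰} ≪ τ ≪ n^{d_w}; regime 2
exponent θ beyond, with prefactors n^{−1+d_w/d_w⁰} and n^{−1+d_w·θ}).
Lévy flights (discontinuous) and smooth processes such as the random
acceleration process are outside the model class and the package makes no
claims about them.

## Simulators

All lattice kernels are Numba-compiled and consume pre-drawn uniforms from
a per-trajectory PCG64 generator seeded with `SeedSequence([seed, index])`,
making ensembles order-independent and bit-reproducible.

**fBm.** Exact sampling of fractional Gaussian noise by Davies–Harte
circulant embedding; if the embedding is not positive semi-definite
(possible only for extreme parameter/size combinations) a dense Cholesky
factorisation of the Toeplitz covariance is used instead. Covariance is
Cov(X_t, X_s) = (t^{2H} + s^{2H} − |t−s|^{2H})/2; tests verify the full
covariance matrix entrywise against 10⁴ sampled paths.

**qfBm.** Tagged-site height h(0, t) of an interface obeying
∂_t h = −(−Δ)^{z/2} h + η with spatially white Gaussian noise, flat start,
Δx = 1, periodic lattice of L sites (default z = 2, L = 256, dt = 0.1).
Each Fourier mode is an Ornstein–Uhlenbeck process and is advanced with its
exact exponential update, which is unconditionally stable in dt — a
stability error cannot arise, so the integration-accuracy contract reduces
to parameter validation. For z = 2 the tagged site grows with Hurst
exponent 1/4.

**eRW.** Drawing a uniform past step reduces to a Bernoulli draw with
probability n₊/t, where n₊ counts previous up-steps; the drawn step is
reversed with probability β. First step ±1 equiprobable. β = 0.25 is the
marginal point between diffusion and superdiffusion; logarithmic
corrections are expected and visible as a drifting DMA slope at large
windows.

**SATW / SESRW / TSAW.** Nearest-neighbour jump weights exp[−βH(n_j)] with
H(0) = 0, H(n>0) = 1 (SATW) or exp[−β n_j^κ] (SESRW; κ = 1 is the TSAW).
The origin counts as visited once and the landing site's count is
incremented after each jump. Probabilities are computed from weight
*differences*, so no overflow occurs at large visit counts. The SATW
weight convention is implemented exactly as written (visited sites carry
weight e^{−β}, i.e. the walk avoids its past range); an empirical check of
the record-age tail at β = 1 — the regime-2 exponent approaches e^{−1}/2 ≈
0.184 — confirms this convention reproduces the reference value, while the
sign-flipped (range-attracting) variant produces a qualitatively different
tail (exponent near 1) and a much smaller diffusivity. Visit-count
arrays are allocated as full-range zero pages, so memory cost is governed
by the territory actually visited.

**Averaged Lévy–Lorentz gas.** A persistent walk with direction state; at
site x the current direction is kept with probability t(x) and reversed
with r(x) = 1 − t(x). Subdiffusive variant: t(x) = min(1, |x|^{a−1}),
t(0) = 1. Superdiffusive variant: r(x) = |x|^{a−1}/2 for x ≠ 0 and
r(0) = 1/2. The ½ prefactor in the superdiffusive case is a deliberate
regularisation: with unit coefficient the sites |x| = 1 would reflect with
probability one and trap the walker in {−1, 0, 1} forever. Asymptotic
exponents are insensitive to the near-origin coefficient; only the
large-|x| decay matters.

**sBm.** Realised exactly as a deterministic time change of the unit-rate
simple walk: ±1 steps at operational times u = 1…n, reported at physical
times t = u^{1/β}. This is equal in law to a jump rate decaying as an
algebraic function of time, gives MSD ∝ t^{β} exactly, and doubles as an
exact oracle: record ages of the sBm are the time-changed record ages of
the underlying walk, which the tests verify by a two-sample KS comparison.

## Record extraction and survival estimation

A record requires *strictly* exceeding the running maximum (re-touching
does not count); the initial observation is record n = 0 at T_0 = 0.
Record times are physical times, which matters only for the sBm.

The survival estimator is censoring-aware: at lag τ a trajectory is *at
risk* for record n if T_n ≤ horizon − τ; among at-risk trajectories, the
numerator counts completed ages ≥ τ and all still-open (censored) ages,
which necessarily exceed τ when the trajectory is at risk. Censored ages
are therefore used as lower bounds rather than discarded — discarding them
would systematically deplete exactly the tails the scaling law describes.
Points with an empty at-risk set are reported as NaN, never as zero. The
estimator's denominator varies with τ, so tiny non-monotonicities
(≲ 0.01) can appear near the horizon; they are sampling artifacts, not
ordering violations of the underlying distribution. Kaplan–Meier-style
machinery is intentionally out of scope.

## Fitting tail exponents

`fit_tail_exponent` is a weighted least-squares fit of log S on log τ
(weights √at-risk, per the module contract). For deep tails this is
statistically inefficient: the variance of log Ŝ is ≈ (1−S)/(S·n_at-risk),
i.e. controlled by the expected number of *ages exceeding τ*, which decays
with τ even when the at-risk count does not. `collapsed_tail_fit` is the
recommended estimator for regime exponents: it pools several record
indices on the scaling variable ξ = τ/n^{d_w}, fits a common slope with
one free intercept per n (absorbing finite-n amplitude corrections that
would tilt a naively stacked fit), and weights each point by its
approximate inverse variance S·n_at-risk/(1−S). Pooling multiplies the
effective number of tail events several-fold, which is what makes the deep
tails estimable at desk-scale ensembles; single-index deep-tail fits rest
on a handful of completed ages and fluctuate far beyond their nominal
standard errors.

Default per-index fit windows keep one decade of guard band on each side
of the crossovers (regime 1 in [10·n^{d_w−d_w⁰}, n^{d_w}/10]; regime 2 in
[10·n^{d_w}, horizon/10]); for aging models with d_w⁰ > d_w the regime-1
window only opens up at large n.

## Product-formula (independence) check

`product_formula_check` compares the measured distribution of T_n with
∏_{k<n}(1 − S(k, T)). Two approximations enter: effective independence of
record ages, and the replacement of the sum of ages by its largest member.
The second is an asymptotic (large-T) statement, so the sup distance over
the bulk of the distribution contains an O(0.1) finite-n contribution even
for exactly independent ages; restricted to the upper tail (≳ 90th
percentile of T_n) the distance drops below 0.01 for the Markov baseline.
The empirical CDF uses the strict inequality P(T_n < T) so that the n = 1
case reduces to the identity 1 − S(0, T) exactly, atoms included.

## DMA estimator

The fluctuation function uses the backward (causal) window mean
x̄_t^ℓ = (1/ℓ)Σ_{i<ℓ} X_{t−i}, with the sum over t starting at ℓ_max for
every ℓ so all windows share one sample range. F(ℓ) is the root *mean*
square residual (the divisor equals the number of summed terms, which
makes the exact closed form for a linear series, F(ℓ) = |c|(ℓ−1)/2, hold
to machine precision — the packaged validation uses it). Multi-trajectory
input pools mean squares before the root. Defaults: windows are powers of
2 from 8 to N/10; the fit uses the middle two decades of available ℓ,
guarding against lattice discreteness at small ℓ and against noise and
local-drift contamination at ℓ approaching the series length. For
processes with genuinely aging increments DMA tracks the short-time
increment scaling; the first/last-quarter increment-MSD diagnostic
(`stationarity_check`, default band [0.5, 2], default lags up to N/32)
should be consulted before interpreting a single exponent.

## Synthetic data and what the tests show

The generator defaults are the study conditions: model parameters are the
canonical ones of the registry (H = 0.25; eRW β = 0.25; SATW β = 1; SESRW
β = 1, κ = 0.5; TSAW β = 1; gas a = 0.25/0.5; sBm β = 0.75). The
synthetic DNA fixture thresholds fractional Gaussian noise (H = 0.67) to
±1 steps — sign-clipping a Gaussian preserves the correlation-decay
exponent, so the resulting walk has a known target d_w; it emulates the
long-range compositional correlations of genomic walks but none of their
biology (no codon structure, GC skew, repeats), so passing pipelines on it
demonstrates the machinery, not genomics.

Ensemble sizes in `scripts/acceptance.py` were chosen to keep every fitted
tail supported by at least tens of completed ages per pooled index while
the full run stays in the ~15-minute range on one core: 100 × 2^15 steps
(fBm DMA), 2·10⁴ × 10⁴ (simple walk), 2·10⁴ × 2·10⁵ (TSAW), 8·10³ × 10⁶
(SATW, sBm, supALL), 5·10³ × 10⁶ (subALL), 200 × 10⁴ (eRW DMA), 20 × 10⁶
(SESRW DMA). The test suite repeats the same protocols, scaled down where
the tolerance allows it; the two tightest tolerances (SATW, subALL) keep
the full ensemble sizes because seed-to-seed scatter at smaller sizes is
comparable to the acceptance band.

## Known finite-time behaviour

The regime-2 exponent converges slowly and not always monotonically in
ξ = τ/n^{d_w}:

* TSAW approaches 1/3 from below (≈ 0.32 at ξ ≲ 500 with 2·10⁵-step
  horizons);
* sBm approaches 3/8 from above (≈ 0.40 over ξ ∈ [20, 600]); the
  time-change construction broadens the crossover because the operational
  record time T_n^{op} is itself heavy-tailed;
* the superdiffusive gas has the longest transient: ≈ 0.28 even at
  ξ ∈ [300, 8000], still ~0.05 below the asymptotic 1/3;
* the subdiffusive gas and SATW land within ~0.02 of their values
  (7/11 and e^{−1}/2) at the packaged sizes;
* the critical eRW carries logarithmic corrections: its DMA slope has a
  shallow plateau (≈ 0.52–0.54 over ℓ ∈ [32, 512]) before drifting upward
  at window sizes approaching the series length, so the fit window is
  pinned to the plateau;
* SESRW reaches its asymptotic slope 0.6 only at small windows of long
  series (the fit uses ℓ ∈ [8, 256] of 10⁶-step trajectories); at
  intermediate scales the apparent slope rises toward 0.7 before the
  asymptotic regime takes over.

These transients are properties of the models at finite horizon, not of
the estimators; enlarging horizons and ensembles moves every listed value
toward its asymptote.

## Limitations

One-dimensional series only (components of higher-dimensional tracks must
be analysed separately); no Lévy flights or smooth processes; the survival
estimator is the declared at-risk/lower-bound scheme, not Kaplan–Meier;
DMA is first-order (no higher-order detrending, no DFA/wavelet
alternatives); exponents for arbitrary parameter values are not derived —
the registry stores reference values at the canonical parameters.
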