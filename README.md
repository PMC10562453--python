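# recordage

Record-age statistics of random walks with memory.

## The problem

A *record* is broken at time *t* when an observable X_t exceeds every
earlier value; the *record age* τ_n is the waiting time between the n-th
and (n+1)-st records. For independent observations and for Markovian
random walks, record ages are classical: the Sparre-Andersen theorem gives
a universal τ^(−1/2) tail for any symmetric memoryless walk. Real series —
tracer trajectories in viscoelastic media, river discharge, cumulative
temperature anomalies, DNA composition walks, network traffic — have
long-range memory, and their record ages behave qualitatively differently.

For a walk that is asymptotically scale-invariant with walk dimension
d_w (X_t ∝ t^{1/d_w}) and aged increments
X_{T+t} − X_T ∝ t^{1/d_w⁰} T^{α/2}, where d_w⁰ = (1/d_w − α/2)^{−1} is the
effective short-time walk dimension, the tail S(n, τ) = P(τ_n ≥ τ) obeys a
two-regime scaling law:

    S(n, τ) ∝ (1/n) (n^{d_w}/τ)^{1/d_w⁰}   for n^{d_w − d_w⁰} ≪ τ ≪ n^{d_w}
    S(n, τ) ∝ (1/n) (n^{d_w}/τ)^{θ}        for τ ≫ n^{d_w}

with θ the persistence exponent (θ = 1 − 1/d_w for stationary increments).
Record statistics therefore *age*: what you observe depends strongly on
the number n of records already broken. For Markovian walks
(d_w = d_w⁰ = 2, θ = 1/2) the two regimes merge and the classical single
power law is recovered.

This package provides everything needed to explore, test and apply that
law:

* **simulators** — nine scale-invariant walk models with memory:
  fractional Brownian motion (fBm, exact circulant embedding), its
  quenched-interface variant (qfBm), the elephant random walk (eRW), the
  self-attractive walk (SATW), sub-exponential self-repelling walk
  (SESRW), true self-avoiding walk (TSAW), the averaged Lévy-Lorentz gas
  (sub- and superdiffusive), scaled Brownian motion (sBm, exact
  time-change construction), and the simple symmetric walk as baseline.
* **records** — record extraction, censoring-aware survival estimation
  S(n, τ), pooled tails, record-count curves, first-return times,
  subtrajectory sampling for single long series.
* **scaling_theory** — exponent algebra (d_w, d_w⁰, θ, α), piecewise tail
  predictions, weighted log-log tail fits, pooled multi-n fits, the
  record-independence product check, and a registry of reference exponent
  sets per model.
* **dma** — Detrending Moving Average estimation of 1/d_w from any 1-D
  series, plus a first/last-quarter increment-MSD stationarity diagnostic.
* **series_io** — trajectory CSV round-trips, FASTA → ±1 DNA walks
  (A/T up, C/G down), deterministic synthetic fixtures.
* **cli** — a `recordage` command wiring the above into reproducible runs.

## Worked example

Measure the regime-2 record-age exponent of scaled Brownian motion with
MSD exponent 0.75 (d_w = 8/3, θ = 3/8), pooling record indices around 25:

```python
import recordage as ra
from recordage import records, scaling_theory as st

ens = ra.collect_records(
    ra.iter_trajectories("sbm", n_steps=100_000, n_traj=4000, seed=2, beta_sbm=0.75)
)
grid = records.log_grid(1.0, max(r.horizon for r in ens), 16)

es = ra.get_exponents("sbm", beta_sbm=0.75)
fit = st.collapsed_tail_fit(ens, [12, 16, 21, 28, 37, 50], es.d_w, (20, 600), grid)
print(fit.exponent, fit.stderr)
```

This prints `0.432 0.007` at these ensemble sizes (the estimate drifts
toward the asymptotic 3/8 = 0.375 as the horizon grows; at 10^6
operational steps it reads ≈ 0.40). The same pipeline run on the Markov
baseline returns ≈ 0.5 in every regime, and the DMA estimator applied to
100 fBm paths of 2^15 steps with H = 0.25 returns 1/d_w ≈ 0.26.

From the shell:

```bash
recordage simulate --model tsaw --beta 1 --steps 100000 --n-traj 1000 --seed 7 --out traj.csv
recordage survival --in traj.csv --n 25 --n 50 --out surv.csv
recordage theory --model satw --beta 1
recordage dnawalk --in genome.fasta --out walk.csv
```

`examples/` contains one short narrative script per capability.

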