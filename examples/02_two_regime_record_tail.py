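"""The two-regime record-age tail of a walk with memory.

For a non-Markovian walk the tail S(n, tau) = P(tau_n >= tau) of the n-th
record age decays with two successive exponents: 1/d_w0, set by the
short-time increments, up to tau ~ n^{d_w}, then the persistence exponent
theta beyond.  Scaled Brownian motion with MSD exponent 3/4 separates the
two cleanly: d_w = 8/3, d_w0 = 2, theta = 3/8.
"""
import recordage as ra
from recordage import records, scaling_theory as st

es = ra.get_exponents("sbm", beta_sbm=0.75)
print(f"registry: d_w={es.d_w:.3f}  d_w0={es.d_w0}  theta={es.theta}  alpha={es.alpha}")

ens = ra.collect_records(ra.iter_trajectories("sbm", n_steps=100_000, n_traj=4000, seed=2, beta_sbm=0.75))
horizon = max(rs.horizon for rs in ens)
grid = records.log_grid(1.0, horizon, 16)

n = 25
est = ra.survival_estimate(ens, n, grid)
r1, r2 = st.regime_windows(n, es, horizon)
fit1 = ra.fit_tail_exponent(est, r1)
print(f"regime 1 fit at n={n} (tau in {r1[0]:.0f}..{r1[1]:.0f}): exponent {fit1.exponent:.3f}  (theory 1/d_w0 = {1/es.d_w0})")

fit2 = st.collapsed_tail_fit(ens, [12, 16, 21, 28, 37, 50], es.d_w, (20, 600), grid)
print(f"regime 2 pooled fit over record indices 12..50: exponent {fit2.exponent:.3f} +- {fit2.stderr:.3f}  (theory theta = {es.theta})")
print("the regime-2 estimate sits slightly above 3/8 at these horizons and drifts toward it as tau/n^d_w grows")
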