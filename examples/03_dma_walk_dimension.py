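"""Estimate a walk dimension from a bare time series with DMA.

The Detrending Moving Average fluctuation F(ell) of a series around its
ell-point moving average scales as ell^{1/d_w}.  Here we recover the
known exponent of subdiffusive fractional Brownian motion (H = 1/d_w =
0.25) and check increment stationarity, the diagnostic that should be run
before trusting any single-exponent description.
"""
import numpy as np

import recordage as ra

trajs = [ra.simulate_fbm(0.25, 2**14, seed=3, traj_index=i) for i in range(30)]
res = ra.dma_walk_dimension(trajs, ell_list=2 ** np.arange(3, 11), ell_max=1024)
print(f"DMA: 1/d_w = {res.inv_d_w:.4f} +- {res.stderr:.4f}  (d_w = {res.d_w:.2f}; true value 4)")

rep = ra.stationarity_check(trajs[0])
print(f"stationarity: first/last-quarter MSD ratio in [{rep.min_ratio:.2f}, {rep.max_ratio:.2f}]"
      f" -> {'stationary' if rep.stationary else 'aging'}")

aging = ra.simulate_sbm(0.75, 100_000, seed=4)
# sample the aging walk at equally spaced *physical* times
phys = np.arange(1, int(aging.times[-1]), 50.0)
x = aging.positions[np.searchsorted(aging.times, phys, side="right") - 1]
rep = ra.stationarity_check(x, lags=2 ** np.arange(0, 9))
print(f"scaled Brownian motion (aging): ratio in [{rep.min_ratio:.2f}, {rep.max_ratio:.2f}]"
      " -- last-quarter increments are smaller, as expected for a slowing-down process")
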