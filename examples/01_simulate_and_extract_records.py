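"""Simulate walks with memory and read off their record structure.

Generates a handful of true self-avoiding walks, extracts record times and
record ages from each, and prints the mean record count, which grows as
t^(1/d_w) with d_w = 3/2 for this model.
"""
import numpy as np

import recordage as ra

ens = ra.collect_records(ra.iter_trajectories("tsaw", n_steps=20_000, n_traj=500, seed=1, beta=1.0))

first = ens[0]
print("first trajectory:")
print(f"  records broken : {first.n_records}")
print(f"  record times   : {first.record_times[:8]} ...")
print(f"  record ages    : {first.ages[:8]} ... (last age censored at {first.censored_age:.0f})")

t_grid, mean_n, slope = ra.record_count_curve(ens)
print(f"\nmean record count n(t): slope of log n vs log t over the last decade = {slope:.3f}")
print("expected 1/d_w = 2/3 ~ 0.667 for the true self-avoiding walk")
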