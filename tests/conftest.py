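import numpy as np
import pytest

import recordage as ra


@pytest.fixture(scope="session")
def rw_ensemble():
    """Moderate simple-walk ensemble shared by several statistical tests."""
    return ra.collect_records(ra.iter_trajectories("simple_rw", 10_000, 4000, seed=7))


@pytest.fixture(scope="session")
def pareto_series():
    """Record series with i.i.d. Pareto(theta=1/2) ages and a horizon far
    beyond every age, so censoring is irrelevant: S(tau) = tau^(-1/2)."""
    rng = np.random.Generator(np.random.PCG64(1234))
    theta = 0.5
    out = []
    for _ in range(4000):
        ages = (1.0 - rng.random(12)) ** (-1.0 / theta)
        t = np.concatenate([[0.0], np.cumsum(ages)])
        out.append(
            ra.RecordSeries(record_times=t, record_values=np.arange(len(t), dtype=float), horizon=t[-1] + 1e12)
        )
    return out


def enumerate_paths(n_steps):
    """All +/-1 paths of length n_steps as a (2**n, n+1) position array."""
    bits = (np.arange(2**n_steps)[:, None] >> np.arange(n_steps)[None, :]) & 1
    steps = 2 * bits - 1
    return np.concatenate([np.zeros((2**n_steps, 1), dtype=int), np.cumsum(steps, axis=1)], axis=1)


def naive_records(x):
    """Textbook record extraction: position t is a record iff it strictly
    exceeds every previous value; returns record times (index 0 included)."""
    times = [0]
    best = x[0]
    for t in range(1, len(x)):
        if x[t] > best:
            best = x[t]
            times.append(t)
    return times
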