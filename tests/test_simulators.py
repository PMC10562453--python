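import numpy as np
import pytest
from scipy import stats

import recordage as ra
from recordage import _kernels
from recordage.simulators import _rng

from conftest import enumerate_paths, naive_records


ALL_MODELS = [
    ("fbm", {"H": 0.25}),
    ("qfbm", {"L": 64}),
    ("erw", {"beta": 0.25}),
    ("satw", {"beta": 1.0}),
    ("sesrw", {"beta": 1.0, "kappa": 0.5}),
    ("tsaw", {"beta": 1.0}),
    ("sub_all", {"a": 0.25}),
    ("sup_all", {"a": 0.5}),
    ("sbm", {"beta_sbm": 0.75}),
    ("simple_rw", {}),
]


@pytest.mark.parametrize("model,params", ALL_MODELS)
def test_reproducibility(model, params):
    """Identical (model, params, n_steps, seed) gives bit-identical paths;
    a different seed gives a different path."""
    a = ra.simulate(model, n_steps=200, n_traj=1, seed=42, **params)[0]
    b = ra.simulate(model, n_steps=200, n_traj=1, seed=42, **params)[0]
    c = ra.simulate(model, n_steps=200, n_traj=1, seed=43, **params)[0]
    np.testing.assert_array_equal(a.positions, b.positions)
    np.testing.assert_array_equal(a.times, b.times)
    assert not np.array_equal(a.positions, c.positions)


@pytest.mark.parametrize("model,params", ALL_MODELS)
def test_trajectory_shape(model, params):
    t = ra.simulate(model, n_steps=150, n_traj=1, seed=3, **params)[0]
    assert len(t.times) == len(t.positions) == 151
    assert t.positions[0] == 0 and t.times[0] == 0
    assert np.all(np.diff(t.times) > 0)


class TestFbm:
    def test_brownian_limit_iid_increments(self):
        x = ra.simulate_fbm(0.5, 20_000, seed=9).positions
        dx = np.diff(x)
        r1 = np.corrcoef(dx[:-1], dx[1:])[0, 1]
        assert abs(r1) < 0.03
        assert abs(dx.var() - 1.0) < 0.05

    def test_covariance_matches_definition(self):
        """Sample covariance over 10^4 paths matches
        Cov(X_t, X_s) = (t^2H + s^2H - |t-s|^2H)/2 within 4 MC errors."""
        H, n, n_paths = 0.25, 16, 10_000
        xs = np.array([ra.simulate_fbm(H, n, 11, i).positions for i in range(n_paths)])
        t = np.arange(n + 1, dtype=float)
        target = 0.5 * (
            t[:, None] ** (2 * H) + t[None, :] ** (2 * H) - np.abs(t[:, None] - t[None, :]) ** (2 * H)
        )
        emp = (xs.T @ xs) / n_paths  # zero-mean process
        # MC standard error of a Gaussian covariance estimate
        se = np.sqrt((np.diag(target)[:, None] * np.diag(target)[None, :] + target**2) / n_paths)
        err = np.abs(emp - target)[1:, 1:] / se[1:, 1:]
        assert err.max() < 4.0
        assert abs(emp[1, 2] - 0.5 * (1 + 2**0.5 - 1)) < 4 * se[1, 2]

    def test_variance_growth(self):
        H = 0.25
        xs = np.array([ra.simulate_fbm(H, 64, 13, i).positions for i in range(10_000)])
        for t in (4, 16, 64):
            assert abs(xs[:, t].var() / t ** (2 * H) - 1.0) < 0.06

    def test_invalid_hurst(self):
        with pytest.raises(ValueError):
            ra.simulate_fbm(1.2, 100, 0)


class TestQfbm:
    def test_zero_noise_stays_flat(self):
        t = ra.simulate_qfbm(n_steps=50, L=64, seed=1, noise_amp=0.0)
        assert np.all(t.positions == 0.0)

    def test_single_site_is_integrated_noise(self):
        xs = np.array([ra.simulate_qfbm(n_steps=64, L=1, seed=5, traj_index=i).positions for i in range(2000)])
        v = xs[:, -1].var()
        assert abs(v / 64.0 - 1.0) < 0.15  # Var(X_t) = t for pure noise integration

    def test_subdiffusive_tagged_site(self):
        """Edwards-Wilkinson tagged site: Var(X_t) grows ~ t^(1/2)."""
        xs = np.array(
            [ra.simulate_qfbm(n_steps=1024, L=128, seed=6, traj_index=i).positions for i in range(24)]
        )
        ts = np.array([64, 1024])
        v = xs[:, ts].reshape(-1, 2).var(axis=0)
        slope = np.log(v[1] / v[0]) / np.log(ts[1] / ts[0])
        assert abs(slope - 0.5) < 0.12

    def test_bad_lattice_size(self):
        with pytest.raises(ValueError):
            ra.simulate_qfbm(n_steps=10, L=63, seed=0)


class TestElephant:
    def test_half_flip_is_diffusive(self):
        xs = np.array([ra.simulate_erw(0.5, 4000, 17, i).positions[-1] for i in range(3000)])
        assert abs(xs.var() / 4000 - 1.0) < 0.1

    def test_zero_flip_is_superdiffusive(self):
        t_probe = (500, 8000)
        xs = np.array([ra.simulate_erw(0.0, t_probe[1], 19, i).positions for i in range(2000)])
        v = xs[:, list(t_probe)].var(axis=0)
        slope = np.log(v[1] / v[0]) / np.log(t_probe[1] / t_probe[0])
        assert slope > 1.3  # frozen early steps dominate: faster than diffusive


def _forced_walk_prob(kernel, forced, probe, args):
    """Exact threshold check: drive the kernel along ``forced`` (+1 right,
    -1 left), then verify the next-step right-probability equals ``probe``
    by bracketing the decision threshold."""
    u_lo = [0.001 if d > 0 else 0.999 for d in forced]
    below = kernel(np.array(u_lo + [probe - 1e-4]), *args)
    above = kernel(np.array(u_lo + [probe + 1e-4]), *args)
    return below[-1] - below[-2], above[-1] - above[-2]


class TestSelfInteracting:
    def test_satw_virgin_neighbours_are_symmetric(self):
        step_lo, step_hi = _forced_walk_prob(_kernels.satw_positions, [], 0.5, (1.0,))
        assert step_lo == 1 and step_hi == -1  # p(right) = 1/2 exactly

    def test_satw_visited_vs_virgin_probability(self):
        """From site 1 with the origin visited and site 2 virgin,
        p(right) = 1/(1 + e^-beta) ~ 0.7311 at beta = 1."""
        p = 1.0 / (1.0 + np.exp(-1.0))
        step_lo, step_hi = _forced_walk_prob(_kernels.satw_positions, [1], p, (1.0,))
        assert step_lo == 1 and step_hi == -1

    def test_satw_beta_zero_is_simple(self):
        x = ra.simulate_satw(0.0, 5000, 23).positions
        y = ra.simulate_simple_rw(5000, 23).positions
        np.testing.assert_array_equal(x, y)

    def test_sesrw_example_probability(self):
        """Visit counts (4 left, 1 right) with beta=1, kappa=0.5 give
        p(right) = e^-1/(e^-1 + e^-2) ~ 0.7311."""
        # forced path 0->1->2->1->0->1->0->1->0->1 leaves counts c0=4, c2=1, pos=1
        forced = [1, 1, -1, -1, 1, -1, 1, -1, 1]
        p = np.exp(-1.0) / (np.exp(-1.0) + np.exp(-2.0))
        step_lo, step_hi = _forced_walk_prob(_kernels.sesrw_positions, forced, p, (1.0, 0.5))
        assert step_lo == 1 and step_hi == -1

    def test_tsaw_is_kappa_one(self):
        a = ra.simulate_tsaw(1.0, 500, 31).positions
        b = ra.simulate_sesrw(1.0, 1.0, 500, 31).positions
        np.testing.assert_array_equal(a, b)


class TestAllGas:
    def test_a_near_one_sub_is_persistent(self):
        """t(x) -> 1 for a -> 1: the sub walk reverses direction only with
        vanishing probability, so almost every step keeps the direction."""
        x = ra.simulate_all(0.999, "sub", 1000, seed=2).positions
        d = np.diff(x)
        persistence = np.mean(d[1:] == d[:-1])
        assert persistence > 0.98

    def test_msd_exponents(self):
        probes = {"sub": (0.25, 2 / 2.75, 30_000), "super": (0.5, 4 / 3, 30_000)}
        for mode, (a, expo, n) in probes.items():
            xs = np.array([ra.simulate_all(a, mode, n, 37, i).positions for i in range(400)])
            ts = np.array([n // 100, n])
            v = xs[:, ts].var(axis=0)
            slope = np.log(v[1] / v[0]) / np.log(ts[1] / ts[0])
            assert abs(slope - expo) < 0.15, (mode, slope)

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            ra.simulate_all(0.5, "sideways", 100, 0)


class TestSbm:
    def test_identity_time_change(self):
        t = ra.simulate_sbm(1.0, 500, seed=3)
        np.testing.assert_allclose(t.times, np.arange(501))

    def test_msd_exponent(self):
        beta = 0.75
        xs = np.array([ra.simulate_sbm(beta, 20_000, 41, i).positions[-1] for i in range(3000)])
        t_phys = 20_000 ** (1 / beta)
        assert abs(np.log(xs.var()) / np.log(t_phys) - beta) < 0.05

    def test_record_ages_match_time_changed_walk(self):
        """Exact mapping: record ages of the sBm equal the record ages of a
        plain walk pushed through t = u^(1/beta); two-sample KS between
        independently seeded realisations stays below the 1% critical value."""
        beta, n_ops, n_traj, n = 0.75, 2000, 800, 3
        a = []
        for i in range(n_traj):
            rs = ra.extract_records(ra.simulate_sbm(beta, n_ops, 51, i))
            if rs.n_records > n + 1:
                a.append(rs.ages[n])
        b = []
        for i in range(n_traj):
            rs = ra.extract_records(ra.simulate_simple_rw(n_ops, 52, i))
            if rs.n_records > n + 1:
                t = rs.record_times ** (1 / beta)
                b.append(np.diff(t)[n])
        res = stats.ks_2samp(a, b)
        crit = 1.628 * np.sqrt((len(a) + len(b)) / (len(a) * len(b)))  # alpha = 1%
        assert res.statistic < crit

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            ra.simulate_sbm(2.5, 100, 0)


class TestSimpleWalk:
    def test_moments(self):
        xs = np.array([ra.simulate_simple_rw(400, 61, i).positions[-1] for i in range(4000)])
        assert abs(xs.mean()) < 0.7
        assert abs(xs.var() / 400 - 1.0) < 0.1

    def test_record_count_is_one_plus_max_on_all_short_paths(self):
        """Exhaustive check over every +/-1 path of length 10: the number
        of strict records equals 1 + the running maximum."""
        paths = enumerate_paths(10)
        for x in paths:
            rs = ra.extract_records(ra.Trajectory(np.arange(11, dtype=float), x))
            assert rs.n_records == 1 + x.max()
            assert rs.record_times.tolist() == naive_records(x)
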