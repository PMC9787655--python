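"""Movement kernels: initial draw, step means, simulation, exact density."""

import numpy as np
import pytest
from scipy import stats

from scrmove.landscape import build_potential, build_state_space, synthetic_landscape
from scrmove.movement import (
    MovementParams,
    Trajectory,
    path_logdensity,
    sample_initial,
    sample_initials,
    simulate_paths,
    simulate_trajectory,
    step_mean,
    trajectory_logdensity,
)


class TestSampleInitial:
    def test_single_ice_cell_deterministic(self, rng):
        ice = np.zeros((3, 3), dtype=int)
        ice[1, 2] = 1
        ss = build_state_space(ice, 1.0)
        g, s1 = sample_initial(ss, rng)
        assert g == 1 * 3 + 2
        assert ss.cell_index(s1) == g

    def test_two_cell_frequencies_within_binomial_error(self, rng):
        ice = np.zeros((1, 4), dtype=int)
        ice[0, [0, 3]] = 1
        ss = build_state_space(ice, 1.0)
        n = 100_000
        g, _ = sample_initials(n, ss, rng)
        k = (g == 0).sum()
        sd = np.sqrt(n * 0.25)
        assert abs(k - n / 2) < 3 * sd

    def test_locations_fall_inside_drawn_cell(self, rng):
        ss = synthetic_landscape(7, 6, 6, resolution_km=2.0, shore_fraction=0.3)
        g, s1 = sample_initials(500, ss, rng)
        np.testing.assert_array_equal(ss.cell_index(s1), g)


class TestStepMean:
    def test_crw_with_zero_gamma_equals_plain_walk(self, coastal_landscape, rng):
        ss, pot = coastal_landscape
        crw = MovementParams(model="crw", sigma=10.0, gamma=0.0, delta=25.0)
        bvn = MovementParams(model="bvn_rw", sigma=10.0, delta=25.0)
        for _ in range(20):
            s = rng.uniform(5, 95, 2)
            prev = rng.uniform(5, 95, 2)
            np.testing.assert_array_equal(
                step_mean(s, prev, crw, pot), step_mean(s, None, bvn, pot)
            )

    def test_persistence_arithmetic(self, flat_landscape):
        ss, pot = flat_landscape
        p = MovementParams(model="crw", sigma=1.0, gamma=1.0, delta=0.0)
        m = step_mean(np.array([10.0, 10.0]), np.array([8.0, 9.0]), p, pot)
        np.testing.assert_allclose(m, [12.0, 11.0])

    def test_drift_scaling(self, flat_landscape):
        ss, pot = flat_landscape
        # impose a synthetic gradient of (0.02, 0) everywhere
        from scrmove.landscape import PotentialSurface

        grad = np.zeros((ss.nrows, ss.ncols, 2))
        grad[..., 0] = 0.02
        pot2 = PotentialSurface(state_space=ss, c=pot.c, grad=grad)
        p = MovementParams(model="bvn_rw", sigma=1.0, delta=50.0)
        m = step_mean(np.array([30.0, 40.0]), None, p, pot2)
        np.testing.assert_allclose(m, [31.0, 40.0])

    def test_first_crw_step_uses_plain_mean(self, flat_landscape):
        ss, pot = flat_landscape
        p = MovementParams(model="crw", sigma=1.0, gamma=0.9, delta=0.0)
        s = np.array([50.0, 50.0])
        np.testing.assert_array_equal(step_mean(s, None, p, pot), s)


class TestSimulation:
    def test_degenerate_sigma_stays_put(self, flat_landscape, rng):
        ss, pot = flat_landscape
        p = MovementParams(model="crw", sigma=1e-9, gamma=0.0, delta=0.0)
        traj = simulate_trajectory(ss, pot, p, T=20, rng=rng)
        assert np.allclose(traj.s, traj.s[0], atol=1e-6)

    def test_mean_step_length_matches_rayleigh(self, flat_landscape):
        # isotropic Gaussian steps of scale sigma have mean length
        # sigma * sqrt(pi / 2)
        ss, pot = flat_landscape
        rng = np.random.default_rng(6)
        sigma = 2.0
        n = 100_000
        s, _ = simulate_paths(
            ss, pot, np.full(n, sigma), np.zeros(n), 0.0, 2, rng,
            s1=np.tile([50.0, 50.0], (n, 1)),
        )
        lengths = np.linalg.norm(s[:, 1] - s[:, 0], axis=1)
        expect = sigma * np.sqrt(np.pi / 2)
        assert abs(lengths.mean() - expect) < 4 * lengths.std() / np.sqrt(n)

    def test_attraction_reduces_distance_to_ice(self, rng):
        ss = synthetic_landscape(2, 30, 30, resolution_km=2.0, shore_fraction=0.4)
        pot = build_potential(ss)
        # start 20 km inside the no-ice band
        start = np.tile([ss.ncols * 2.0 - 10.0, 30.0], (200, 1))
        start[:, 0] = 55.0  # 19 km from the ice edge at x = 36
        s, _ = simulate_paths(
            ss, pot, np.full(200, 3.0), np.zeros(200), 20.0, 6, rng, s1=start
        )
        row0, col0 = ss.cell_rowcol(s[:, 0])
        rowT, colT = ss.cell_rowcol(s[:, -1])
        assert pot.c[rowT, colT].mean() < pot.c[row0, col0].mean()

    def test_simulated_locations_stay_in_extent(self, flat_landscape, rng):
        ss, pot = flat_landscape
        s, _ = simulate_paths(
            ss, pot, np.full(300, 40.0), np.full(300, 0.9), 0.0, 15, rng
        )
        assert ss.contains(s).all()

    def test_seeded_reproducibility(self, coastal_landscape):
        ss, pot = coastal_landscape
        p = MovementParams(model="crw", sigma=8.0, gamma=0.5, delta=10.0)
        t1 = simulate_trajectory(ss, pot, p, 12, np.random.default_rng(33))
        t2 = simulate_trajectory(ss, pot, p, 12, np.random.default_rng(33))
        np.testing.assert_array_equal(t1.s, t2.s)
        assert t1.g1 == t2.g1


class TestLogDensity:
    def test_single_occasion_on_four_ice_cells(self):
        ice = np.zeros((2, 4), dtype=int)
        ice[0] = 1  # 4 ice cells of 1 km... make exactly 4
        ss = build_state_space(ice, 1.0)
        pot = build_potential(ss)
        p = MovementParams(model="bvn_rw", sigma=1.0)
        traj = Trajectory(g1=1, s=np.array([[1.5, 0.5]]))
        lp = trajectory_logdensity(traj, p, ss, pot)
        assert np.isclose(lp, np.log(0.25))

    def test_matches_independent_bivariate_normal_sum(self, flat_landscape):
        ss, pot = flat_landscape
        p = MovementParams(model="bvn_rw", sigma=3.0)
        s = np.array([[50.0, 50.0], [53.0, 47.5], [49.0, 50.0]])
        traj = Trajectory(g1=int(ss.cell_index(s[0])), s=s)
        lp = trajectory_logdensity(traj, p, ss, pot)
        oracle = np.log(ss.pi[ss.cell_index(s[0])]) - 2 * np.log(10.0)
        for t in range(2):
            oracle += stats.multivariate_normal.logpdf(
                s[t + 1], mean=s[t], cov=9.0 * np.eye(2)
            )
        assert abs(lp - oracle) < 1e-12

    def test_crw_zero_gamma_identical_to_plain_walk(self, coastal_landscape, rng):
        ss, pot = coastal_landscape
        crw = MovementParams(model="crw", sigma=6.0, gamma=0.0, delta=15.0)
        bvn = MovementParams(model="bvn_rw", sigma=6.0, delta=15.0)
        for _ in range(20):
            traj = simulate_trajectory(ss, pot, crw, 8, rng)
            a = trajectory_logdensity(traj, crw, ss, pot)
            b = trajectory_logdensity(traj, bvn, ss, pot)
            assert a == b

    def test_rotation_invariance_without_drift(self, flat_landscape, rng):
        ss, pot = flat_landscape
        p = MovementParams(model="crw", sigma=2.0, gamma=0.6, delta=0.0)
        center = np.array([50.0, 50.0])
        s = center + rng.normal(scale=3.0, size=(6, 2))
        th = 0.77
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        s_rot = (s - s[0]) @ R.T + s[0]
        lp = path_logdensity(s[None], np.array([2.0]), np.array([0.6]), 0.0, ss, pot)
        lp_rot = path_logdensity(
            s_rot[None], np.array([2.0]), np.array([0.6]), 0.0, ss, pot
        )
        # the initial-cell factor is identical on the all-ice grid, and the
        # step factors are isotropic
        assert abs(lp[0] - lp_rot[0]) < 1e-9

    def test_off_support_start_gives_minus_inf(self, coastal_landscape):
        ss, pot = coastal_landscape
        p = MovementParams(model="bvn_rw", sigma=5.0)
        # start in the no-ice shore band (pi = 0 there)
        traj = Trajectory(g1=int(ss.cell_index(np.array([97.0, 50.0]))),
                          s=np.array([[97.0, 50.0], [90.0, 50.0]]))
        assert trajectory_logdensity(traj, p, ss, pot) == -np.inf

    def test_out_of_extent_point_gives_minus_inf(self, flat_landscape):
        ss, pot = flat_landscape
        lp = path_logdensity(
            np.array([[[50.0, 50.0], [120.0, 50.0]]]),
            np.array([5.0]),
            np.array([0.0]),
            0.0,
            ss,
            pot,
        )
        assert lp[0] == -np.inf


class TestMovementParams:
    @pytest.mark.parametrize("bad", [{"sigma": 0.0}, {"gamma": 1.2}, {"model": "levy"}])
    def test_invalid_parameters_rejected(self, bad):
        kw = {"model": "crw", "sigma": 5.0, "gamma": 0.5}
        kw.update(bad)
        with pytest.raises(ValueError):
            MovementParams(**kw)

    def test_class_keyed_lookup(self):
        p = MovementParams(
            model="crw", sigma={"male": 15.0, "female": 11.0},
            gamma={"male": 0.47, "female": 0.51},
        )
        assert p.sigma_for("female") == 11.0
        assert p.gamma_for("male") == 0.47
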