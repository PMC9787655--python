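"""Search-encounter detection and telemetry observation models."""

import numpy as np
import pytest
from scipy.special import softmax
from scipy.stats import multivariate_normal

from scrmove.observation import (
    ARGOS_AXIS_SCALE,
    DetectionParams,
    EncounterData,
    TelemetryData,
    argos_covariance,
    detection_probs,
    encounter_loglik,
    simulate_encounter,
    simulate_encounter_histories,
    telemetry_loglik,
)

CENTROIDS = np.array([[10.0, 10.0], [30.0, 10.0], [10.0, 30.0], [30.0, 30.0]])


def random_state(rng):
    s = rng.uniform(0, 40, 2)
    effort = np.where(rng.random(4) < 0.3, 0.0, rng.uniform(1, 40, 4))
    B = int(rng.random() < 0.2)
    params = DetectionParams(
        alpha0=rng.normal(-4, 2),
        alpha1=rng.uniform(0.5, 3),
        alpha2=rng.normal(0, 1),
        sigma_det=rng.uniform(2, 10),
    )
    return s, effort, B, params


def softmax_oracle(s, effort, B, params, centroids):
    """Brute-force reference: explicit softmax over J traps + baseline 0."""
    d2 = ((s - centroids) ** 2).sum(axis=1)
    with np.errstate(divide="ignore"):
        eta = (
            params.alpha0
            + params.alpha1 * np.log(effort)
            + params.alpha2 * B
            - d2 / (2 * params.sigma_det**2)
        )
    return softmax(np.append(eta, 0.0))


class TestDetectionProbs:
    def test_matches_softmax_oracle_on_random_states(self, rng):
        for _ in range(1000):
            s, effort, B, params = random_state(rng)
            xi = detection_probs(s, effort, B, params, CENTROIDS)
            assert np.isclose(xi.sum(), 1.0, atol=1e-12)
            assert (xi >= 0).all() and (xi <= 1).all()
            np.testing.assert_allclose(
                xi, softmax_oracle(s, effort, B, params, CENTROIDS), atol=1e-12
            )

    def test_zero_effort_means_no_detection(self):
        params = DetectionParams(alpha0=0.0, alpha1=1.0, sigma_det=5.0)
        xi = detection_probs(
            np.array([10.0, 10.0]), np.zeros(4), 0, params, CENTROIDS
        )
        np.testing.assert_array_equal(xi, [0, 0, 0, 0, 1])

    def test_single_cell_hand_arithmetic(self):
        # one trap at distance 0, effort 24.5 km, alpha0 = -8, alpha1 = 2.5
        params = DetectionParams(alpha0=-8.0, alpha1=2.5, sigma_det=5.0)
        eta = -8.0 + 2.5 * np.log(24.5)
        xi = detection_probs(
            np.array([10.0, 10.0]),
            np.array([24.5]),
            0,
            params,
            np.array([[10.0, 10.0]]),
        )
        np.testing.assert_allclose(xi[0], np.exp(eta) / (1 + np.exp(eta)), atol=1e-14)
        assert np.isclose(xi.sum(), 1.0)

    def test_monotone_decreasing_in_distance(self):
        params = DetectionParams(alpha0=-2.0, alpha1=1.0, sigma_det=5.0)
        effort = np.array([20.0])
        cent = np.array([[0.0, 0.0]])
        p0 = detection_probs(np.array([0.0, 0.0]), effort, 0, params, cent)[0]
        p1 = detection_probs(np.array([5.0, 0.0]), effort, 0, params, cent)[0]
        assert p1 < p0

    def test_monotone_increasing_in_effort(self):
        params = DetectionParams(alpha0=-2.0, alpha1=1.0, sigma_det=5.0)
        cent = np.array([[0.0, 0.0]])
        s = np.array([2.0, 0.0])
        p_small = detection_probs(s, np.array([5.0]), 0, params, cent)[0]
        p_big = detection_probs(s, np.array([25.0]), 0, params, cent)[0]
        assert p_big > p_small

    def test_behavioural_response_shifts_logit_only_when_flagged(self):
        params = DetectionParams(alpha0=-2.0, alpha1=1.0, alpha2=1.3, sigma_det=5.0)
        s = np.array([12.0, 9.0])
        eff = np.array([10.0, 0.0, 3.0, 8.0])
        xi0 = detection_probs(s, eff, 0, params, CENTROIDS)
        xi1 = detection_probs(s, eff, 1, params, CENTROIDS)
        # with B = 1 every surveyed-cell logit shifts by alpha2
        odds0 = xi0[:4] / xi0[4]
        odds1 = xi1[:4] / xi1[4]
        pos = eff > 0
        np.testing.assert_allclose(
            odds1[pos] / odds0[pos], np.exp(1.3), atol=1e-10
        )

    def test_negative_effort_rejected(self):
        params = DetectionParams(alpha0=0.0, alpha1=1.0)
        with pytest.raises(ValueError, match="non-negative"):
            detection_probs(np.zeros(2), np.array([-1.0, 2, 2, 2]), 0, params, CENTROIDS)


class TestSimulateEncounter:
    def test_certain_nondetection(self, rng):
        xi = np.array([0.0, 0.0, 1.0])
        assert all(simulate_encounter(xi, rng) == 2 for _ in range(20))

    def test_degenerate_mass_on_one_trap(self, rng):
        xi = np.zeros(9)
        xi[6] = 1.0
        assert simulate_encounter(xi, rng) == 6

    def test_frequencies_match_probabilities(self, rng):
        xi = np.array([0.2, 0.5, 0.3])
        n = 100_000
        draws = np.array([simulate_encounter(xi, rng) for _ in range(n)])
        for k, p in enumerate(xi):
            sd = np.sqrt(n * p * (1 - p))
            assert abs((draws == k).sum() - n * p) < 3 * sd


class TestEncounterLoglik:
    def test_nondetection_probability(self):
        xi = np.array([0.05, 0.05, 0.9])
        assert np.isclose(encounter_loglik(2, xi), np.log(0.9))

    def test_zero_probability_cell_is_minus_inf(self):
        xi = np.array([0.0, 0.1, 0.9])
        assert encounter_loglik(0, xi) == -np.inf

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match="out of range"):
            encounter_loglik(5, np.array([0.5, 0.5]))

    def test_summed_loglik_matches_categorical_pmf(self, rng):
        total = 0.0
        oracle = 0.0
        for _ in range(200):
            s, effort, B, params = random_state(rng)
            xi = detection_probs(s, effort, B, params, CENTROIDS)
            y = simulate_encounter(xi, rng)
            total += encounter_loglik(y, xi)
            oracle += np.log(softmax_oracle(s, effort, B, params, CENTROIDS)[y])
        assert abs(total - oracle) < 1e-9


class TestArgosCovariance:
    def test_circular_ellipse_with_unit_scale(self):
        np.testing.assert_allclose(
            argos_covariance(2.0, 2.0, 1.234, axis_scale=1.0), 4.0 * np.eye(2),
            atol=1e-12,
        )

    def test_rotation_by_half_pi_swaps_diagonal(self):
        c0 = argos_covariance(6.0, 2.0, 0.0)
        c90 = argos_covariance(6.0, 2.0, np.pi / 2)
        np.testing.assert_allclose(c0[0, 0], c90[1, 1], atol=1e-12)
        np.testing.assert_allclose(c0[1, 1], c90[0, 0], atol=1e-12)

    def test_eigenvalues_are_scaled_squared_axes(self, rng):
        for _ in range(50):
            b, a = np.sort(rng.uniform(0.5, 12.0, 2))
            th = rng.uniform(0, np.pi)
            cov = argos_covariance(a, b, th, axis_scale=1.0)
            ev = np.sort(np.linalg.eigvalsh(cov))
            np.testing.assert_allclose(ev, [b**2, a**2], atol=1e-10)
            assert np.allclose(cov, cov.T)

    def test_default_scale_is_half_normal_convention(self):
        cov = argos_covariance(3.0, 3.0, 0.0)
        np.testing.assert_allclose(cov, 9.0 / 2.0 * np.eye(2), atol=1e-12)

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            argos_covariance(1.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            argos_covariance(2.0, 0.0, 0.0)


class TestTelemetryLoglik:
    def test_gps_density_at_mean(self):
        lp = telemetry_loglik(np.array([5.0, 5.0]), np.array([5.0, 5.0]), 3.0)
        assert np.isclose(lp, np.log(1.0 / (2 * np.pi * 9.0)))

    def test_argos_matches_monte_carlo_marginalization(self, rng):
        s = np.array([0.0, 0.0])
        sigma_det = 4.0
        cov_e = argos_covariance(6.0, 3.0, 0.7, axis_scale=1.0)
        u = np.array([3.0, -2.0])
        lp = telemetry_loglik(u, s, sigma_det, cov_e)
        # oracle: integrate the latent true fix location out by simulation
        n = 400_000
        mu = rng.multivariate_normal(s, sigma_det**2 * np.eye(2), size=n)
        vals = multivariate_normal(mean=[0.0, 0.0], cov=cov_e).pdf(u - mu)
        mc = np.log(vals.mean())
        assert abs(lp - mc) < 0.02

    def test_argos_near_zero_ellipse_converges_to_gps(self):
        u = np.array([1.0, 2.0])
        s = np.array([0.0, 0.0])
        tiny = argos_covariance(1e-6, 1e-6, 0.3, axis_scale=1.0)
        assert np.isclose(
            telemetry_loglik(u, s, 5.0, tiny), telemetry_loglik(u, s, 5.0), atol=1e-9
        )

    def test_matches_analytic_bivariate_normal(self, rng):
        for _ in range(20):
            cov_e = argos_covariance(*np.sort(rng.uniform(1, 8, 2))[::-1], rng.uniform(0, np.pi))
            u, s = rng.normal(size=2), rng.normal(size=2)
            sd = rng.uniform(1, 6)
            lp = telemetry_loglik(u, s, sd, cov_e)
            oracle = multivariate_normal(mean=s, cov=sd**2 * np.eye(2) + cov_e).logpdf(u)
            assert abs(lp - oracle) < 1e-10

    def test_singular_covariance_raises(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(np.linalg.LinAlgError):
            telemetry_loglik(np.zeros(2), np.zeros(2), 1e-6, bad)


class TestDataContainers:
    def test_detection_in_zero_effort_cell_rejected(self):
        y = np.array([[0, 2]])
        effort = np.array([[0.0, 5.0], [5.0, 5.0]])
        with pytest.raises(ValueError, match="zero-effort"):
            EncounterData(y=y, effort=effort, B=np.zeros((1, 2), int),
                          state=np.array([1]))

    def test_max_four_fixes_per_individual_day(self):
        with pytest.raises(ValueError, match="at most 4"):
            TelemetryData(
                individual=np.zeros(5, int),
                occasion=np.zeros(5, int),
                u=np.zeros((5, 2)),
            )

    def test_ellipse_axis_order_enforced(self):
        with pytest.raises(ValueError, match="semi_major"):
            TelemetryData(
                individual=np.array([0]),
                occasion=np.array([0]),
                u=np.zeros((1, 2)),
                ellipse=np.array([[1.0, 2.0, 0.0]]),
            )


class TestSimulateEncounterHistories:
    def test_excluded_individuals_never_detected(self, rng):
        s = rng.uniform(0, 40, (30, 5, 2))
        effort = np.full((5, 4), 20.0)
        z = np.zeros(30, dtype=int)
        params = DetectionParams(alpha0=5.0, alpha1=1.0, sigma_det=50.0)
        y, B = simulate_encounter_histories(s, z, params, effort, CENTROIDS, rng)
        assert (y == 4).all()

    def test_behavioural_flag_set_on_next_surveyed_occasion(self, rng):
        s = np.tile(np.array([10.0, 10.0]), (1, 6, 1))
        effort = np.full((6, 4), 25.0)
        effort[2] = 0.0  # occasion 2 not surveyed
        params = DetectionParams(alpha0=8.0, alpha1=1.0, sigma_det=50.0)
        y, B = simulate_encounter_histories(
            s, np.ones(1, int), params, effort, CENTROIDS, rng
        )
        first = int((y[0] < 4).argmax())
        assert first == 0  # detection is near-certain with these logits
        # first survey strictly after capture is occasion 1
        assert B[0, 1] == 1 and B[0].sum() == 1


class TestFixesToOccasions:
    def test_half_open_day_assignment(self):
        from scrmove.observation import fixes_to_occasions

        # tau in (t-1, t] attaches to occasion t (1-based), so 0-based
        # occasion ceil(tau) - 1; tau = 1.0 is still occasion 0
        times = np.array([0.2, 1.0, 1.0001, 2.5, 9.99])
        idx, occ = fixes_to_occasions(times, n_occasions=10, max_per_day=0)
        np.testing.assert_array_equal(idx, np.arange(5))
        np.testing.assert_array_equal(occ, [0, 0, 1, 2, 9])

    def test_out_of_window_fixes_dropped(self):
        from scrmove.observation import fixes_to_occasions

        idx, occ = fixes_to_occasions(np.array([0.5, 12.3]), 10, max_per_day=0)
        np.testing.assert_array_equal(idx, [0])

    def test_thinning_caps_at_four_per_day(self, rng):
        from scrmove.observation import fixes_to_occasions

        times = np.concatenate([np.linspace(0.05, 0.95, 9), [1.5, 1.7]])
        idx, occ = fixes_to_occasions(times, 3, rng=rng)
        assert (occ == 0).sum() == 4
        assert (occ == 1).sum() == 2
        # retained indices are a subset of the originals, in order
        assert np.all(np.diff(idx) > 0)
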