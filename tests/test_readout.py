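"""Decoding and recall statistics against brute-force oracles."""
import numpy as np
import pytest

from swmsim import (
    GroupConfig,
    UndecodableProfileError,
    circular_kurtosis,
    circular_variance,
    compare_conditions,
    decode_population_vector,
    empirical_tc,
    empirical_tc_prime,
    first_zero_crossing,
    generate_synthetic_responses,
    group_efficacy,
    normalized_target_probability,
    recall_angle,
    significance_category,
)
from swmsim.ring import RingGrid, wrap_orientation


def circ_moments_oracle(errors):
    """Scalar-loop trigonometric moments on doubled angles (CircStat)."""
    phi = [2.0 * e for e in errors]
    n = len(phi)
    c1 = sum(np.cos(p) for p in phi) / n
    s1 = sum(np.sin(p) for p in phi) / n
    c2 = sum(np.cos(2 * p) for p in phi) / n
    s2 = sum(np.sin(2 * p) for p in phi) / n
    rbar = np.hypot(c1, s1)
    mu1 = np.arctan2(s1, c1)
    rho2 = np.hypot(c2, s2)
    mu2 = np.arctan2(s2, c2)
    cv = 1.0 - rbar
    ck = (rho2 * np.cos(mu2 - 2 * mu1) - rbar**4) / (1 - rbar) ** 2
    return cv, ck


class TestGroupEfficacy:
    def test_zero_release_probability_gives_zero_efficacy(self, small_grid):
        groups = GroupConfig((0.0, 0.5))
        T, N = 5, small_grid.n
        jux, delta = group_efficacy(np.zeros((T, N)), np.ones((T, N)),
                                    small_grid, groups, j_peak=2.0)
        assert np.all(jux == 0.0)
        assert np.all(delta[(0, 1)] == 0.0)

    def test_uniform_state_gives_equal_groups(self, small_grid):
        groups = GroupConfig((-0.4, 0.3))
        T, N = 3, small_grid.n
        jux, delta = group_efficacy(np.full((T, N), 0.5), np.full((T, N), 0.4),
                                    small_grid, groups, j_peak=2.0)
        assert np.allclose(jux, 2.0 * 0.5 * 0.4)
        assert np.allclose(delta[(0, 1)], 0.0)

    def test_empty_group_rejected(self):
        # on a coarse 8-neuron ring, a centre midway between two grid points
        # has no member within a 10 degree half-width
        grid = RingGrid(8)
        with pytest.raises(ValueError):
            GroupConfig((0.2,), half_width=np.deg2rad(10.0)).masks(grid)


class TestPopulationVector:
    def test_symmetric_bump_decodes_center(self, small_grid):
        for center in (-1.0, 0.0, 0.7):
            d = wrap_orientation(small_grid.thetas - center)
            profile = np.exp(-(d / 0.2) ** 2)
            est = decode_population_vector(profile, small_grid)
            assert abs(wrap_orientation(est - center)) < small_grid.spacing

    def test_uniform_profile_undecodable(self, small_grid):
        with pytest.raises(UndecodableProfileError):
            decode_population_vector(np.ones(small_grid.n), small_grid)
        with pytest.raises(UndecodableProfileError):
            decode_population_vector(np.zeros(small_grid.n), small_grid)

    def test_rms_error_under_amplitude_noise(self, small_grid, rng):
        errs = []
        for _ in range(100):
            center = rng.uniform(-np.pi / 2, np.pi / 2)
            d = wrap_orientation(small_grid.thetas - center)
            profile = np.exp(-(d / 0.2) ** 2)
            profile *= 1.0 + 0.05 * rng.standard_normal(profile.shape)
            est = decode_population_vector(profile, small_grid)
            errs.append(wrap_orientation(est - center))
        assert np.sqrt(np.mean(np.square(errs))) < np.deg2rad(2.0)

    def test_unbiased_over_uniform_centers(self, small_grid):
        errs = []
        for center in np.linspace(-np.pi / 2, np.pi / 2, 73, endpoint=False):
            d = wrap_orientation(small_grid.thetas - center)
            profile = np.exp(-(d / 0.25) ** 2)
            errs.append(wrap_orientation(
                decode_population_vector(profile, small_grid) - center))
        assert abs(np.mean(errs)) < np.deg2rad(0.5)


class TestRecallAngle:
    def test_reduces_to_population_vector(self, small_grid):
        times = np.linspace(0, 1, 101)
        d = wrap_orientation(small_grid.thetas - 0.4)
        prof = np.exp(-(d / 0.2) ** 2)
        trace = np.tile(prof, (101, 1))
        est = recall_angle(trace, times, (0.5, 1.0), small_grid)
        assert abs(wrap_orientation(est - 0.4)) < small_grid.spacing

    def test_zero_length_window_rejected(self, small_grid):
        trace = np.ones((10, small_grid.n))
        with pytest.raises(ValueError, match="window"):
            recall_angle(trace, np.linspace(0, 1, 10), (0.5, 0.5), small_grid)


class TestMixture:
    def test_all_on_target_approaches_one(self, rng):
        err_t = 1e-3 * rng.standard_normal(200)
        err_nt = err_t[:, None] + np.deg2rad(40.0)
        fit = normalized_target_probability(err_t, err_nt)
        assert fit.p_target > 0.99
        assert fit.kappa > 100

    def test_uniform_responses_near_chance(self, rng):
        resp = rng.uniform(-np.pi / 2, np.pi / 2, 10_000)
        target, nontarget = 0.3, -0.5
        fit = normalized_target_probability(
            wrap_orientation(resp - target),
            wrap_orientation(resp - nontarget)[:, None],
        )
        assert fit.p_target < 0.25

    def test_symmetric_split_gives_half(self, rng):
        # responses sit exactly on the two item orientations, half and half
        n = 400
        target, nontarget = 0.2, -0.4
        resp = np.where(np.arange(n) % 2 == 0, target, nontarget)
        resp = resp + 1e-3 * rng.standard_normal(n)
        fit = normalized_target_probability(
            wrap_orientation(resp - target),
            wrap_orientation(resp - nontarget)[:, None],
        )
        assert fit.p_target == pytest.approx(0.5, abs=0.03)

    def test_parameter_recovery(self, rng):
        angles = np.array([0.1, -0.6])
        resp = generate_synthetic_responses(
            angles, kappa=8.0, weights=[0.7, 0.2, 0.1], n_trials=2000, rng=rng)
        fit = normalized_target_probability(
            wrap_orientation(resp - angles[0]),
            wrap_orientation(resp - angles[1])[:, None],
        )
        assert fit.weights[0] == pytest.approx(0.7, abs=0.05)
        assert fit.weights[1] == pytest.approx(0.2, abs=0.05)

    def test_guess_trials_dilute_p(self, rng):
        err_t = 1e-3 * rng.standard_normal(30)
        fit = normalized_target_probability(err_t, None, n_guess_trials=30)
        assert fit.p_target == pytest.approx(0.5, abs=0.05)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="20"):
            normalized_target_probability(np.zeros(5))


class TestCircularStats:
    def test_identical_angles_zero_variance(self):
        assert circular_variance(np.full(10, 0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_angles_full_variance(self, rng):
        errs = rng.uniform(-np.pi / 2, np.pi / 2, 100_000)
        assert circular_variance(errs) == pytest.approx(1.0, abs=0.02)

    def test_three_point_example_matches_oracle(self):
        errs = np.deg2rad([-10.0, 0.0, 10.0])
        cv_o, ck_o = circ_moments_oracle(errs)
        assert circular_variance(errs) == pytest.approx(cv_o, abs=1e-12)
        assert circular_kurtosis(errs) == pytest.approx(ck_o, abs=1e-12)

    def test_agree_with_oracle_on_random_samples(self, rng):
        for _ in range(20):
            errs = rng.uniform(-np.pi / 2, np.pi / 2, rng.integers(3, 40))
            cv_o, ck_o = circ_moments_oracle(errs)
            assert circular_variance(errs) == pytest.approx(cv_o, abs=1e-10)
            assert circular_kurtosis(errs) == pytest.approx(ck_o, abs=1e-10)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            circular_variance([0.1])


class TestComparisons:
    def test_identical_runs_not_significant(self):
        p = np.full(10, 0.6)
        assert compare_conditions(p, p) == ("n.s.", 1.0)

    def test_uniform_shift_over_50_runs_highly_significant(self):
        p1 = np.linspace(0.4, 0.6, 50)
        cat, pval = compare_conditions(p1, p1 + 0.1)
        assert cat == "***" and pval < 1e-3

    def test_category_boundaries(self):
        assert significance_category(0.2) == "n.s."
        assert significance_category(0.03) == "*"
        assert significance_category(0.005) == "**"
        assert significance_category(0.0005) == "***"

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([0.1] * 4, [0.2] * 4)


class TestCrossings:
    def test_midpoint_interpolation(self):
        assert empirical_tc([1.0, 2.0, 3.0], [-0.2, 0.2, 0.4]) == pytest.approx(1.5)

    def test_no_crossing_is_nan(self):
        assert np.isnan(empirical_tc([1.0, 2.0, 3.0], [0.1, 0.2, 0.3]))

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            empirical_tc([1.0, 2.0], [-0.1, 0.1])

    def test_plateau_counts_as_crossing(self):
        # saturated statistics produce a noise-level plateau; the crossing
        # is the first sample at the plateau after the negative branch
        tc = first_zero_crossing([1.0, 2.0, 3.0], [-0.1, 0.001, 0.1],
                                 zero_eps=0.002)
        assert tc == pytest.approx(2.0)

    def test_delta_jux_crossing(self):
        assert empirical_tc_prime([0.2, 0.4], [-1.0, 1.0]) == pytest.approx(0.3)
        assert np.isnan(empirical_tc_prime([0.2, 0.4], [1.0, 2.0]))

    def test_bootstrap_interval_contains_point_estimate(self, rng):
        t = np.array([0.5, 1.0, 2.0, 4.0])
        runs = np.array([[-0.3, -0.1, 0.1, 0.2]] * 12) \
            + 0.02 * rng.standard_normal((12, 4))
        tc, (lo, hi) = empirical_tc(t, runs.mean(axis=0), runs=runs,
                                    n_boot=200, rng=rng)
        assert lo <= tc <= hi


class TestSyntheticResponses:
    def test_degenerate_target_weight(self, rng):
        resp = generate_synthetic_responses(
            [0.3, -0.5], kappa=500.0, weights=[1.0, 0.0, 0.0],
            n_trials=100, rng=rng)
        assert np.all(np.abs(wrap_orientation(resp - 0.3)) < np.deg2rad(5))

    def test_pure_uniform_component(self, rng):
        from scipy import stats

        resp = generate_synthetic_responses(
            [0.3, -0.5], kappa=8.0, weights=[0.0, 0.0, 1.0],
            n_trials=5000, rng=rng)
        u = (resp + np.pi / 2) / np.pi
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_invalid_weights_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_synthetic_responses([0.1, 0.2], 8.0, [0.5, 0.2],
                                         10, rng)
        with pytest.raises(ValueError):
            generate_synthetic_responses([0.1, 0.2], 8.0, [0.5, 0.2, 0.2],
                                         10, rng)
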