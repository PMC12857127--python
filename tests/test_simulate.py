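"""The synthetic-data generator: truth curves, noise, event times,
censoring, and reproducibility."""

import numpy as np
import pytest
from scipy import stats

from dtmarkov import SimulationConfig, generate_dataset, truth_probs
from dtmarkov.simulate import (
    apply_proportional_noise,
    censor,
    default_g12,
    default_g13,
    sample_transition_time,
)


class TestTruthFunctions:
    def test_hand_evaluated_points(self):
        l12, _, _ = truth_probs([0.3, 0.0])
        assert l12 == pytest.approx(0.075, abs=1e-12)
        _, l13, _ = truth_probs([0.0, 0.0])
        assert l13 == pytest.approx((2 / 3) * (np.exp(-4) + 0.15), rel=1e-12)
        assert l13 == pytest.approx(0.11221, abs=5e-6)

    def test_complement_identity_on_a_grid(self):
        for x1 in np.linspace(0, 1, 7):
            for x2 in np.linspace(0, 1, 7):
                l12, l13, l11 = truth_probs([x1, x2])
                assert l11 + l12 + l13 == pytest.approx(1.0, abs=1e-15)
                assert l12 >= 0 and l13 >= 0 and l11 >= 0

    def test_out_of_range_covariates_rejected(self):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            truth_probs([1.2, 0.0])

    def test_second_covariate_effect_is_non_monotone(self):
        vals = [default_g12(0.5, x2) for x2 in np.linspace(0, 1, 21)]
        diffs = np.diff(vals)
        assert np.any(diffs > 0) and np.any(diffs < 0)


class TestProportionalNoise:
    def test_zero_noise_is_identity(self):
        l12, l13, l11 = apply_proportional_noise(0.1, 0.2, np.zeros(2))
        assert (l12, l13, l11) == (0.1, 0.2, 0.7)

    def test_scaling_per_transition(self):
        l12, l13, _ = apply_proportional_noise(0.1, 0.2, np.array([0.1, -0.1]))
        assert l12 == pytest.approx(0.11)
        assert l13 == pytest.approx(0.18)

    def test_simplex_restored_after_pathological_draw(self):
        l12, l13, l11 = apply_proportional_noise(0.5, 0.5, np.array([0.5, 0.5]))
        assert l12 + l13 <= 1.0 and l11 >= 0.0

    def test_noise_scale_matches_configured_sd(self):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(10_000):
            eps = rng.normal(0, 0.05, size=2)
            l12, _, _ = apply_proportional_noise(0.1, 0.2, eps)
            ratios.append(l12 / 0.1 - 1.0)
        assert np.std(ratios) == pytest.approx(0.05, rel=0.05)


class TestTransitionTimes:
    def test_certain_transition_is_immediate(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            dest, k, truncated = sample_transition_time(1.0 - 1e-12, 0.0, rng)
            assert (dest, k, truncated) == (2, 1, False)

    def test_marginals_match_geometric_closed_forms(self):
        rng = np.random.default_rng(1)
        n = 40_000
        draws = [sample_transition_time(0.25, 0.25, rng) for _ in range(n)]
        dests = np.array([d[0] for d in draws])
        times = np.array([d[1] for d in draws])
        # P(dest 2) = 0.5; mean time = 1/0.5 = 2 (geometric)
        p_se = np.sqrt(0.25 / n)
        assert abs(np.mean(dests == 2) - 0.5) < 3 * p_se
        t_se = np.sqrt((1 - 0.5) / 0.5**2 / n)
        assert abs(times.mean() - 2.0) < 3 * t_se

    def test_degenerate_rates_hit_the_time_cap(self):
        rng = np.random.default_rng(2)
        dest, k, truncated = sample_transition_time(0.0, 0.0, rng, max_time=50)
        assert truncated and k == 50 and dest is None

    def test_fixed_seed_reproduces_paths(self):
        a = [sample_transition_time(0.2, 0.1, np.random.default_rng(9)) for _ in range(5)]
        b = [sample_transition_time(0.2, 0.1, np.random.default_rng(9)) for _ in range(5)]
        assert a == b


class TestCensoring:
    def test_degenerate_interval_widened(self):
        config = SimulationConfig(poisson_rate=0.0, right_censor_prob=0.0)
        obs = censor(4, 2, np.random.default_rng(0), config)
        assert obs.time_kind == "interval"
        assert (obs.k1, obs.k2) == (3, 4)

    def test_right_censored_at_event_time_when_draw_is_zero(self):
        config = SimulationConfig(right_censor_prob=1.0,
                                  right_censor_poisson_rate=0.0)
        obs = censor(4, 2, np.random.default_rng(0), config)
        assert obs.event == 0 and obs.time_kind == "exact" and obs.k_star == 4

    def test_censor_time_clipped_at_zero(self):
        config = SimulationConfig(right_censor_prob=1.0,
                                  right_censor_poisson_rate=50.0)
        obs = censor(1, 2, np.random.default_rng(0), config)
        assert obs.k_star == 0

    def test_right_censoring_fraction(self):
        config = SimulationConfig(right_censor_prob=0.5)
        rng = np.random.default_rng(3)
        n = 4000
        censored = sum(censor(3, 2, rng, config).event == 0 for _ in range(n))
        assert abs(censored / n - 0.5) < 3 * np.sqrt(0.25 / n)


class TestGenerateDataset:
    def test_cardinality_and_truth_simplex(self):
        ds = generate_dataset(SimulationConfig(n_individuals=10, seed=1))
        assert len(ds.observations) == 10
        assert ds.truth.shape[0] == 10
        lam = ds.truth_lambdas
        np.testing.assert_allclose(lam.sum(axis=1), 1.0, atol=1e-15)
        assert np.all(lam >= 0)

    def test_seed_reproducibility(self):
        a = generate_dataset(SimulationConfig(n_individuals=100, seed=7))
        b = generate_dataset(SimulationConfig(n_individuals=100, seed=7))
        c = generate_dataset(SimulationConfig(n_individuals=100, seed=8))
        assert a.truth.equals(b.truth)
        assert [(o.event, o.k_star, o.k1, o.k2) for o in a.observations] == \
               [(o.event, o.k_star, o.k1, o.k2) for o in b.observations]
        assert not a.truth.equals(c.truth)

    def test_destination_split_matches_rates(self):
        """Flat rates, no noise or censoring: the destination frequencies
        follow the lambda12:lambda13 odds."""
        config = SimulationConfig(
            n_individuals=20_000, seed=13, noise_sd=0.0, right_censor_prob=0.0,
            truth_functions=(lambda x1, x2: np.full_like(np.asarray(x1, float), 0.1),
                             lambda x1, x2: np.full_like(np.asarray(x1, float), 0.3)))
        ds = generate_dataset(config)
        dests = np.array([o.destination_state for o in ds.observations])
        frac2 = np.mean(dests == 1)
        assert abs(frac2 - 0.25) < 3 * np.sqrt(0.25 * 0.75 / len(dests))

    def test_event_times_are_geometric(self):
        """With width-one intervals the upper bound is the event time; a
        chi-square test compares it with the geometric pmf."""
        total = 0.4
        config = SimulationConfig(
            n_individuals=20_000, seed=17, noise_sd=0.0, right_censor_prob=0.0,
            poisson_rate=0.0,
            truth_functions=(lambda x1, x2: np.full_like(np.asarray(x1, float), total / 2),
                             lambda x1, x2: np.full_like(np.asarray(x1, float), total / 2)))
        ds = generate_dataset(config)
        times = np.array([o.k2 for o in ds.observations])
        kmax = 12
        observed = np.array([(times == k).sum() for k in range(1, kmax)] +
                            [(times >= kmax).sum()])
        pmf = np.array([total * (1 - total) ** (k - 1) for k in range(1, kmax)])
        expected = np.append(pmf, 1 - pmf.sum()) * len(times)
        _, p = stats.chisquare(observed, expected)
        assert p > 1e-3

    def test_right_censoring_rate_and_observation_validity(self):
        ds = generate_dataset(SimulationConfig(n_individuals=5000, seed=19))
        events = np.array([o.event for o in ds.observations])
        assert abs(events.mean() - 0.5) < 3 * np.sqrt(0.25 / len(events))
        for o in ds.observations:
            if o.event:
                assert o.time_kind == "interval" and 0 <= o.k1 < o.k2
            else:
                assert o.time_kind == "exact" and o.k_star >= 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_individuals=0)
        with pytest.raises(ValueError):
            SimulationConfig(covariate_low=0.5, covariate_high=0.4)
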