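"""Likelihood contributions under exact, right-censored, and interval
observation, checked against closed forms and enumeration oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from dtmarkov import (
    ConstantPredictor,
    LikelihoodContext,
    Observation,
    ObservationSet,
    ProbabilityRow,
    TransitionStructure,
    dataset_negloglik,
    loglik_exact,
    loglik_interval,
    survival,
)

TWO_RISK = ProbabilityRow(np.array([0.1, 0.2]))


def interval_obs(dest, k1, k2):
    return Observation("i", 0, 1, dest, "interval", None, k1, k2)


def exact_obs(event, dest, k):
    return Observation("i", 0, event, dest, "exact", k)


class TestSurvival:
    def test_competing_risk_power(self):
        assert survival(TWO_RISK, 3) == pytest.approx(0.7**3, rel=1e-14)

    def test_zero_steps_is_one(self):
        assert survival(TWO_RISK, 0) == 1.0

    def test_single_risk(self):
        assert survival(ProbabilityRow(np.array([0.5])), 2) == 0.25

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            survival(TWO_RISK, -1)


class TestExact:
    def test_event_with_survival(self):
        ll = loglik_exact(TWO_RISK, exact_obs(1, 0, 2))
        assert ll == pytest.approx(np.log(0.1) + 2 * np.log(0.7), rel=1e-12)

    def test_censored_at_zero_carries_no_information(self):
        assert loglik_exact(TWO_RISK, exact_obs(0, None, 0)) == 0.0

    def test_single_risk_event(self):
        row = ProbabilityRow(np.array([0.5]))
        assert loglik_exact(row, exact_obs(1, 0, 1)) == pytest.approx(np.log(0.25))

    def test_zero_probability_destination_is_minus_inf(self):
        row = ProbabilityRow(np.array([0.0, 0.2]))
        assert loglik_exact(row, exact_obs(1, 0, 1)) == -np.inf


class TestInterval:
    def test_single_risk_closed_form(self):
        row = ProbabilityRow(np.array([0.5]))
        ll = loglik_interval(row, interval_obs(0, 1, 2))
        assert ll == pytest.approx(np.log(0.5 - 0.25), rel=1e-12)

    def test_term_by_term_sum(self):
        ll = loglik_interval(TWO_RISK, interval_obs(0, 0, 2))
        assert ll == pytest.approx(np.log(0.1 * 1 + 0.1 * 0.7), rel=1e-12)

    def test_wide_interval_approaches_subdistribution_mass(self):
        # total mass ever reaching destination 0 is lam0 / (1 - q)
        ll = loglik_interval(TWO_RISK, interval_obs(0, 0, 500))
        assert ll == pytest.approx(np.log(0.1 / 0.3), rel=1e-10)

    def test_equals_logsumexp_of_per_time_terms(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            lam = rng.dirichlet(np.ones(3))[:2] * 0.9
            row = ProbabilityRow(lam)
            k1 = int(rng.integers(0, 5))
            k2 = k1 + int(rng.integers(1, 6))
            d = int(rng.integers(0, 2))
            per_time = [np.log(lam[d]) + (k - 1) * np.log(row.stay)
                        for k in range(k1 + 1, k2 + 1)]
            assert loglik_interval(row, interval_obs(d, k1, k2)) == pytest.approx(
                logsumexp(per_time), rel=1e-10)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_obs(0, 2, 2)

    def test_zero_mass_interval_is_minus_inf(self):
        row = ProbabilityRow(np.array([0.0, 0.3]))
        assert loglik_interval(row, interval_obs(0, 0, 2)) == -np.inf


class TestSingleRiskReduction:
    """With one destination the competing-risk forms reduce to the
    single-risk closed forms on a grid of rates and times."""

    grid = [0.05, 0.2, 0.5, 0.8, 0.95]

    @pytest.mark.parametrize("lam", grid)
    def test_exact_reduction(self, lam):
        row = ProbabilityRow(np.array([lam]))
        for k in range(6):
            expected = np.log(lam) + k * np.log(1 - lam)
            assert loglik_exact(row, exact_obs(1, 0, k)) == pytest.approx(
                expected, rel=1e-12)
            assert loglik_exact(row, exact_obs(0, None, k)) == pytest.approx(
                k * np.log(1 - lam), rel=1e-12)

    @pytest.mark.parametrize("lam", grid)
    def test_interval_reduction_to_survival_difference(self, lam):
        row = ProbabilityRow(np.array([lam]))
        for k1 in range(4):
            for k2 in range(k1 + 1, k1 + 5):
                expected = np.log((1 - lam) ** k1 - (1 - lam) ** k2)
                assert loglik_interval(row, interval_obs(0, k1, k2)) == pytest.approx(
                    expected, rel=1e-12)


class TestConservationAndEntropy:
    def test_outcome_probabilities_sum_to_one(self):
        """All first-transition outcomes up to a horizon, plus survival
        past it, exhaust the probability space."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            lam = rng.uniform(0.01, 0.45, size=2)
            row = ProbabilityRow(lam)
            T = 40
            mass = sum(lam[n] * survival(row, k - 1)
                       for k in range(1, T + 1) for n in range(2))
            assert mass + survival(row, T) == pytest.approx(1.0, abs=1e-10)

    def test_negloglik_of_enumerated_outcomes_is_entropy(self):
        """Width-one intervals carry the exact outcome probability, so the
        probability-weighted NLL equals the outcome entropy."""
        structure = TransitionStructure.star((1, 2, 3))
        lam = np.array([0.15, 0.3])
        row = ProbabilityRow(lam)
        T = 30
        outcomes, probs = [], []
        for k in range(1, T + 1):
            for n, state in enumerate((1, 2)):
                outcomes.append(interval_obs(state, k - 1, k))
                probs.append(lam[n] * survival(row, k - 1))
        outcomes.append(exact_obs(0, None, T))
        probs.append(survival(row, T))
        probs = np.array(probs)
        nll_terms = np.array([
            -(loglik_interval(row, o, structure) if o.time_kind == "interval"
              else loglik_exact(row, o, structure))
            for o in outcomes])
        entropy = -np.sum(probs * np.log(probs))
        assert np.sum(probs * nll_terms) == pytest.approx(entropy, rel=1e-10)


class TestDatasetNegloglik:
    def test_single_term(self, star3):
        pred = ConstantPredictor(2)
        # scores chosen so the link returns (0.1, 0.2)
        pred.params[0][:] = np.log(np.array([0.1, 0.2]) / 0.7)
        data = ObservationSet([exact_obs(1, 1, 2)], star3)
        expected = -(np.log(0.1) + 2 * np.log(0.7))
        assert dataset_negloglik(pred, data) == pytest.approx(expected, rel=1e-10)

    def test_additivity(self, star3):
        pred = ConstantPredictor(2)
        pred.params[0][:] = [-1.0, -0.5]
        one = ObservationSet([interval_obs(1, 1, 3)], star3)
        two = ObservationSet([interval_obs(1, 1, 3)] * 2, star3)
        assert dataset_negloglik(pred, two) == pytest.approx(
            2 * dataset_negloglik(pred, one), rel=1e-12)

    def test_empty_dataset_rejected(self, star3):
        with pytest.raises(ValueError, match="empty"):
            ObservationSet([], star3)

    def test_covariate_dimension_mismatch(self, star3):
        a = Observation("a", 0, 0, None, "exact", 1, covariates=[0.1])
        b = Observation("b", 0, 0, None, "exact", 1, covariates=[0.1, 0.2])
        with pytest.raises(ValueError, match="mismatch"):
            ObservationSet([a, b], star3)


class TestClosedFormMLE:
    def test_constant_single_risk_optimum(self, star3):
        """Two exact events at times 1 and 3: the likelihood maximizer is
        D / (D + sum k*) = 1/3."""
        structure = TransitionStructure.star((1, 2))
        data = ObservationSet(
            [exact_obs(1, 1, 1), exact_obs(1, 1, 3)], structure)

        def nll(theta):
            pred = ConstantPredictor(1)
            pred.params[0][:] = theta
            return dataset_negloglik(pred, data)

        res = minimize_scalar(nll, bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-10})
        lam_hat = 1 / (1 + np.exp(-res.x))
        assert lam_hat == pytest.approx(1 / 3, abs=1e-6)

    def test_context_horizon_validation(self, star3):
        with pytest.raises(ValueError):
            LikelihoodContext(star3, horizon=0)
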