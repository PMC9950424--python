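import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from adprog.observation import (
    CensorSpec,
    Item,
    ItemBank,
    LinkParams,
    NoiseParams,
    censored_gaussian_loglik,
    gaussian_loglik,
    inverse_sigmoid_link,
    irt_category_probs,
    score_traits,
    sigmoid_link,
)


class TestSigmoidLink:
    link = LinkParams(lower=0.0, upper=100.0, slope=1.0, midpoint=0.0)

    def test_midpoint_maps_to_centre(self):
        assert sigmoid_link(0.0, self.link) == pytest.approx(50.0)

    def test_plateau_at_upper_asymptote(self):
        assert sigmoid_link(50.0, self.link) == pytest.approx(100.0)
        assert sigmoid_link(-50.0, self.link) == pytest.approx(0.0)

    def test_logistic_evaluation(self):
        # logistic(ln 3) = 3/4
        assert sigmoid_link(np.log(3.0), self.link) == pytest.approx(75.0, abs=1e-12)

    @pytest.mark.parametrize("x", np.linspace(-4, 4, 9))
    def test_inverse_recovers_latent(self, x):
        link = LinkParams(lower=200.0, upper=2400.0, slope=0.8, midpoint=0.3)
        assert inverse_sigmoid_link(sigmoid_link(x, link), link) == pytest.approx(x, abs=1e-9)

    def test_monotone(self):
        xs = np.linspace(-6, 6, 100)
        assert np.all(np.diff(sigmoid_link(xs, self.link)) > 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LinkParams(lower=1.0, upper=0.0, slope=1.0, midpoint=0.0)
        with pytest.raises(ValueError):
            LinkParams(lower=0.0, upper=1.0, slope=-1.0, midpoint=0.0)


class TestGaussianLoglik:
    def test_mode_of_standard_normal(self):
        assert gaussian_loglik(0.0, 0.0, NoiseParams(1.0)) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_one_sigma_away(self):
        sigma = 2.5
        expected = -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5
        assert gaussian_loglik(1.0 + sigma, 1.0, NoiseParams(sigma)) == pytest.approx(expected)

    def test_symmetry(self):
        n = NoiseParams(0.7)
        assert gaussian_loglik(3.0 + 0.4, 3.0, n) == pytest.approx(gaussian_loglik(3.0 - 0.4, 3.0, n))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseParams(0.0)


class TestCensoredGaussian:
    censor = CensorSpec(upper_limit=1700.0)

    def test_mean_at_limit_gives_half_mass(self):
        ll = censored_gaussian_loglik(1700.0, NoiseParams(100.0), self.censor)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_three_sigma_above_limit(self):
        ll = censored_gaussian_loglik(1700.0 + 300.0, NoiseParams(100.0), self.censor)
        assert ll == pytest.approx(np.log(norm.cdf(3.0)), abs=1e-10)

    def test_total_mass_integrates_to_one(self):
        mean, sigma = 1650.0, 120.0
        noise = NoiseParams(sigma)
        below, _ = quad(lambda v: np.exp(gaussian_loglik(v, mean, noise)), -np.inf, 1700.0)
        tail = np.exp(censored_gaussian_loglik(mean, noise, self.censor))
        assert below + tail == pytest.approx(1.0, abs=1e-6)

    def test_missing_limit_is_a_data_error(self):
        with pytest.raises(ValueError, match="without"):
            censored_gaussian_loglik(10.0, NoiseParams(1.0), CensorSpec(), side="upper")


class TestGradedResponse:
    def test_flat_item_degenerates(self):
        item = Item(discrimination=0.0, thresholds=(0.0, 1.0, 2.0), domain="mem")
        probs = irt_category_probs(0.0, item)
        np.testing.assert_allclose(probs, [0.5, 0.0, 0.0, 0.5], atol=1e-12)

    def test_binary_item_reduces_to_2pl(self):
        item = Item(discrimination=1.3, thresholds=(0.4,), domain="lang")
        probs = irt_category_probs(1.0, item)
        p_correct = 1.0 / (1.0 + np.exp(-1.3 * (1.0 - 0.4)))
        np.testing.assert_allclose(probs, [1.0 - p_correct, p_correct], atol=1e-12)

    def test_worked_two_threshold_example(self):
        item = Item(discrimination=1.0, thresholds=(0.0, 1.0), domain="praxis")
        probs = irt_category_probs(0.0, item)
        logistic = lambda z: 1.0 / (1.0 + np.exp(-z))
        np.testing.assert_allclose(probs, [0.5, 0.5 - logistic(-1.0), logistic(-1.0)], atol=1e-5)

    @pytest.mark.parametrize("trait", [-2.0, -0.3, 0.0, 1.7])
    def test_probabilities_sum_to_one(self, trait):
        item = Item(discrimination=1.8, thresholds=(-1.0, 0.0, 0.8, 2.0), domain="mem")
        assert irt_category_probs(trait, item).sum() == pytest.approx(1.0, abs=1e-12)

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            Item(discrimination=1.0, thresholds=(1.0, 0.0), domain="mem")


def _grid_map(responses):
    """Brute-force posterior mode on a fine grid (independent oracle)."""
    grid = np.linspace(-6, 6, 4001)
    logpost = -0.5 * grid**2
    for item, cat in responses:
        logpost = logpost + np.log([max(irt_category_probs(t, item)[cat], 1e-300) for t in grid])
    return grid[np.argmax(logpost)]


class TestScoreTraits:
    bank = ItemBank([
        Item(discrimination=1.5, thresholds=(-1.0, 0.0, 1.0), domain="mem"),
        Item(discrimination=1.0, thresholds=(-0.5, 0.5), domain="mem"),
        Item(discrimination=1.2, thresholds=(0.0,), domain="lang"),
    ])

    def test_prior_consistent_responses_score_near_zero(self):
        # symmetric binary items answered so the likelihood peaks at trait 0
        lo = Item(discrimination=1.5, thresholds=(-0.5,), domain="mem")
        hi = Item(discrimination=1.5, thresholds=(0.5,), domain="mem")
        scores = score_traits([(lo, 1), (hi, 0)], ItemBank([lo, hi]))
        assert abs(scores["mem"][0]) < 0.05
        assert scores["praxis"] is None  # no praxis items -> missing

    def test_single_binary_item_matches_grid_search(self):
        item = self.bank.items[2]
        for cat in (0, 1):
            est, se = score_traits([(item, cat)], self.bank)["lang"]
            assert est == pytest.approx(_grid_map([(item, cat)]), abs=0.01)
            assert se > 0

    def test_worse_responses_do_not_decrease_trait(self):
        """Higher categories mean worse cognition, hence a larger trait."""
        items = [it for it in self.bank.items if it.domain == "mem"]
        prev = -np.inf
        for shift in range(4):
            responses = [(it, min(shift, it.n_categories - 1)) for it in items]
            est = score_traits(responses, self.bank)["mem"][0]
            oracle = _grid_map(responses)
            assert est == pytest.approx(oracle, abs=0.02)
            assert est >= prev - 1e-9
            prev = est

    def test_empty_responses_all_missing(self):
        scores = score_traits([], self.bank)
        assert all(v is None for v in scores.values())
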