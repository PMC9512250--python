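"""Unit and property tests for the 1D impact-prediction pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ndtr

from ppspace import (
    POSITION_CLAMP_CM,
    FutureBelief1D,
    ModelParams,
    Percept1D,
    WorldState1D,
    expected_loss,
    future_belief,
    hit_probability,
    loss,
    optimal_prediction_closed_form,
    optimal_prediction_grid,
    predict_impact,
    prediction_grid,
    sample_percept,
)

probabilities = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def _tail_mass_oracle(mu, sigma, n=200_001):
    """Trapezoid integration of the Gaussian density over (-inf, 0].

    Independent of the closed-form CDF used in production.
    """
    lo = min(mu - 12 * sigma, -12 * sigma)
    xs = np.linspace(lo, 0.0, n)
    density = np.exp(-0.5 * ((xs - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    return np.trapezoid(density, xs)


class TestTypes:
    def test_defaults_are_baseline(self):
        params = ModelParams()
        assert (params.sigma_x, params.sigma_v) == (2.5, 20.0)
        assert (params.fn, params.fp, params.r) == (5.0, 1.0, 2.0)
        assert (params.delta_t, params.grid_step) == (0.5, 0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma_x": -1.0},
            {"sigma_v": -0.1},
            {"fn": -1.0},
            {"fn": 0.0, "fp": 0.0},
            {"delta_t": 0.0},
            {"r": 0.0},
            {"grid_step": 0.0},
            {"grid_step": 0.3},  # does not divide 1
            {"grid_step": 1.5},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_world_state_behind_body_rejected(self):
        with pytest.raises(ValueError):
            WorldState1D(x=-1.0, v=0.0)

    def test_grid_endpoints(self):
        grid = prediction_grid(0.05)
        assert grid[0] == 0.0 and grid[-1] == 1.0 and grid.size == 21


class TestSamplePercept:
    def test_zero_noise_returns_truth(self, rng):
        params = ModelParams(sigma_x=0.0, sigma_v=0.0)
        percept = sample_percept(WorldState1D(30.0, -50.0), params, rng)
        assert percept.x_hat == 30.0 and percept.v_hat == -50.0

    def test_sampling_distribution_mean(self):
        rng = np.random.default_rng(7)
        params = ModelParams(sigma_x=4.0)
        n = 100_000
        draws = np.array(
            [sample_percept(WorldState1D(30.0, -25.0), params, rng).x_hat for _ in range(n)]
        )
        assert abs(draws.mean() - 30.0) < 3 * 4.0 / np.sqrt(n)

    def test_negative_position_draws_clamped(self):
        rng = np.random.default_rng(3)
        params = ModelParams(sigma_x=5.0)
        draws = np.array(
            [sample_percept(WorldState1D(0.0, 0.0), params, rng).x_hat for _ in range(4000)]
        )
        assert draws.min() >= 0.0
        clamped = np.mean(draws == POSITION_CLAMP_CM)
        assert 0.45 < clamped < 0.55  # half the raw draws fall inside the body

    def test_percept_carries_uncertainties(self, rng, baseline_params):
        percept = sample_percept(WorldState1D(30.0, -25.0), baseline_params, rng)
        assert percept.sigma_x == baseline_params.sigma_x
        assert percept.sigma_v == baseline_params.sigma_v


class TestFutureBelief:
    def test_fig_style_arithmetic(self):
        params = ModelParams(sigma_x=4.0, sigma_v=5.0, delta_t=0.5)
        belief = future_belief(Percept1D(32.0, -48.0, 4.0, 5.0), params)
        assert belief.mu == pytest.approx(8.0)
        assert belief.sigma == pytest.approx(np.sqrt(16.0 + 6.25))

    def test_static_object(self):
        params = ModelParams(sigma_x=3.0, sigma_v=0.0)
        belief = future_belief(Percept1D(12.0, 0.0, 3.0, 0.0), params)
        assert belief.mu == 12.0 and belief.sigma == 3.0

    def test_noiseless_limit(self):
        params = ModelParams(sigma_x=0.0, sigma_v=0.0)
        belief = future_belief(Percept1D(12.0, -4.0, 0.0, 0.0), params)
        assert belief.sigma == 0.0


class TestHitProbability:
    def test_symmetric_belief(self):
        assert hit_probability(FutureBelief1D(0.0, 4.717)) == pytest.approx(0.5)

    def test_matches_numeric_integration_oracle(self):
        for mu, sigma in [(8.0, 4.717), (-3.0, 2.0), (1.0, 10.0)]:
            expected = _tail_mass_oracle(mu, sigma)
            assert hit_probability(FutureBelief1D(mu, sigma)) == pytest.approx(
                expected, abs=1e-6
            )

    def test_far_away_limit(self):
        assert hit_probability(FutureBelief1D(1000.0, 4.717)) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_sigma_is_step_function(self):
        assert hit_probability(FutureBelief1D(-0.5, 0.0)) == 1.0
        assert hit_probability(FutureBelief1D(0.0, 0.0)) == 1.0
        assert hit_probability(FutureBelief1D(0.5, 0.0)) == 0.0

    def test_strictly_decreasing_in_position(self, baseline_params):
        sigma = baseline_params.future_sigma
        probs = [hit_probability(FutureBelief1D(mu, sigma)) for mu in (-5.0, 0.0, 5.0, 20.0)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_uncertainty_interchangeability(self):
        # hit probability depends on sigma_x, sigma_v only through
        # sigma_x**2 + (delta_t*sigma_v)**2
        pa = ModelParams(sigma_x=2.5, sigma_v=20.0)
        total = pa.future_sigma**2
        sigma_x_alt = np.sqrt(total - (0.5 * 10.0) ** 2)
        pb = ModelParams(sigma_x=sigma_x_alt, sigma_v=10.0)
        percept_a = Percept1D(30.0, -25.0, pa.sigma_x, pa.sigma_v)
        percept_b = Percept1D(30.0, -25.0, pb.sigma_x, pb.sigma_v)
        assert hit_probability(future_belief(percept_a, pa)) == pytest.approx(
            hit_probability(future_belief(percept_b, pb)), rel=1e-12
        )

    def test_sigma_widening_moves_tail_mass_toward_half(self):
        # mu > 0: more diffuse belief puts more mass behind the body;
        # mu < 0: more diffuse belief leaks mass back in front.
        for mu, increasing in [(5.0, True), (-5.0, False)]:
            probs = [hit_probability(FutureBelief1D(mu, s)) for s in (1.0, 3.0, 9.0)]
            deltas = np.diff(probs)
            assert np.all(deltas > 0) if increasing else np.all(deltas < 0)


class TestLossAndExpectedLoss:
    def test_perfect_predictions_cost_nothing(self, baseline_params):
        assert loss(1, 1.0, baseline_params) == 0.0
        assert loss(0, 0.0, baseline_params) == 0.0

    def test_maximal_errors_cost_the_factors(self, baseline_params):
        assert loss(0, 1.0, baseline_params) == baseline_params.fp
        assert loss(1, 0.0, baseline_params) == baseline_params.fn

    def test_quadratic_miss(self):
        assert loss(1, 0.5, ModelParams()) == pytest.approx(5 * 0.25)

    def test_rejects_out_of_range(self, baseline_params):
        with pytest.raises(ValueError):
            loss(1, 1.5, baseline_params)
        with pytest.raises(ValueError):
            loss(2, 0.5, baseline_params)
        with pytest.raises(ValueError):
            expected_loss(1.2, 0.5, baseline_params)

    @pytest.mark.parametrize(
        "p_hit, y_pred, expected",
        [(0.0, 0.0, 0.0), (1.0, 0.0, 5.0), (0.5, 0.5, 0.75)],
    )
    def test_expected_loss_values(self, p_hit, y_pred, expected, baseline_params):
        assert expected_loss(p_hit, y_pred, baseline_params) == pytest.approx(expected)

    @given(p=probabilities, y=probabilities)
    def test_expected_loss_mixes_the_two_outcomes(self, p, y):
        params = ModelParams()
        combined = p * loss(1, y, params) + (1 - p) * loss(0, y, params)
        assert expected_loss(p, y, params) == pytest.approx(combined)


class TestOptimalPrediction:
    def test_boundary_certainty(self, baseline_params):
        assert optimal_prediction_grid(0.0, baseline_params) == 0.0
        assert optimal_prediction_grid(1.0, baseline_params) == 1.0

    def test_symmetric_loss_matches_probability_on_grid(self):
        params = ModelParams(fn=1.0, fp=1.0)
        for p in np.linspace(0.0, 1.0, 21):
            assert optimal_prediction_grid(p, params) == pytest.approx(p)

    def test_fine_grid_matches_asymmetric_optimum(self, baseline_params):
        # closed form p*fn / (p*fn + (1-p)*fp) at p = 0.0449
        got = optimal_prediction_grid(0.0449, baseline_params, grid_step=1e-4)
        closed = 0.0449 * 5 / (0.0449 * 5 + (1 - 0.0449) * 1)  # = 0.19033...
        assert got == pytest.approx(closed, abs=1e-4)
        assert got == pytest.approx(0.190, abs=5e-4)

    def test_closed_form_examples(self):
        assert optimal_prediction_closed_form(0.5, ModelParams(fn=1, fp=1)) == 0.5
        assert optimal_prediction_closed_form(0.5, ModelParams()) == pytest.approx(2.5 / 3.0)
        assert optimal_prediction_closed_form(0.0, ModelParams()) == 0.0

    def test_closed_form_rejects_other_exponents(self):
        with pytest.raises(ValueError):
            optimal_prediction_closed_form(0.5, ModelParams(r=1.0))

    def test_grid_agrees_with_closed_form_everywhere(self, baseline_params):
        # fine grid must track the analytic argmin to within one grid step
        p = np.arange(0.0, 1.0001, 0.001)
        grid_opt = optimal_prediction_grid(p, baseline_params, grid_step=1e-4)
        closed = optimal_prediction_closed_form(p, baseline_params)
        assert np.max(np.abs(grid_opt - closed)) <= 1e-4 + 1e-12

    @given(p=probabilities, fn=st.floats(0.1, 100), fp=st.floats(0.1, 100))
    def test_closed_form_minimises_expected_loss(self, p, fn, fp):
        params = ModelParams(fn=fn, fp=fp)
        y_star = optimal_prediction_closed_form(p, params)
        base = expected_loss(p, y_star, params)
        for eps in (-1e-3, 1e-3):
            y = min(1.0, max(0.0, y_star + eps))
            assert expected_loss(p, y, params) >= base - 1e-12

    @given(p=probabilities)
    def test_symmetric_loss_is_probability_matching(self, p):
        assert optimal_prediction_closed_form(p, ModelParams(fn=2.0, fp=2.0)) == pytest.approx(p)


class TestPredictImpact:
    def test_noiseless_receding_object_scores_zero(self, rng):
        params = ModelParams(sigma_x=0.0, sigma_v=0.0)
        assert predict_impact(WorldState1D(100.0, 25.0), params, rng) == 0.0

    def test_noiseless_certain_hit(self, rng):
        params = ModelParams(sigma_x=0.0, sigma_v=0.0)
        # mu = 5 - 12.5 <= 0: contact is certain within the horizon
        assert predict_impact(WorldState1D(5.0, -25.0), params, rng) == 1.0

    def test_noisy_draws_vary(self, baseline_params):
        rng = np.random.default_rng(11)
        draws = {predict_impact(WorldState1D(30.0, -25.0), baseline_params, rng) for _ in range(50)}
        assert len(draws) > 1

    def test_predictions_stay_in_unit_interval(self, baseline_params):
        rng = np.random.default_rng(12)
        draws = [predict_impact(WorldState1D(x, -25.0), baseline_params, rng) for x in range(0, 100, 10)]
        assert all(0.0 <= d <= 1.0 for d in draws)

    def test_optimal_predictions_nonincreasing_in_position(self, baseline_params):
        # deterministic percepts: feed the decision stage directly
        sigma = baseline_params.future_sigma
        p_hits = [
            hit_probability(FutureBelief1D(x - 12.5, sigma)) for x in (0.0, 10.0, 30.0, 60.0)
        ]
        preds = [optimal_prediction_grid(p, baseline_params) for p in p_hits]
        assert all(a >= b for a, b in zip(preds, preds[1:]))
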