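import itertools

import numpy as np
import pytest

from moals._nn import numerical_gradient
from moals.downstream_tasks import (SurvivalLabel, TaskHeadSpec, TimeGrid,
                                    classification_loss, encode_survival_label,
                                    make_time_grid, mtlr_log_probability,
                                    predict_survival_curve, regression_loss,
                                    risk_score, survival_loss)
from moals.synthetic_data import ConfigError


def enumerate_monotone_probabilities(scores):
    """Brute-force MTLR: probability of every monotone 0/1 configuration,
    computed by direct summation (independent of the suffix-sum path)."""
    m = len(scores)
    configs = []
    for switch in range(1, m + 2):
        y = [1 if i >= switch else 0 for i in range(1, m + 1)]
        configs.append(y)
    numerators = [np.exp(sum(y_i * s_i for y_i, s_i in zip(y, scores)))
                  for y in configs]
    denom = sum(np.exp(sum(scores[i] for i in range(j, m)))
                for j in range(m + 1))
    return np.array(numerators) / denom, configs


class TestClassificationLoss:
    def test_confident_correct_prediction_is_near_zero(self):
        loss = classification_loss(np.array([0]), np.array([[30.0, 0.0]]))
        assert loss < 1e-10

    def test_uniform_logits_give_entropy(self):
        loss = classification_loss(np.array([1]), np.array([[0.0, 0.0]]))
        assert loss == pytest.approx(np.log(2))

    def test_hand_softmax(self):
        loss = classification_loss(np.array([0]), np.array([[1.0, 0.0]]))
        assert loss == pytest.approx(0.313262, abs=1e-6)

    def test_label_outside_set_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(np.array([2]), np.array([[0.0, 0.0]]))

    def test_gradient_matches_finite_differences(self, rng):
        y = np.array([0, 1, 1])
        logits = rng.normal(size=(3, 2))
        _, grad = classification_loss(y, logits, return_grad=True)
        num = numerical_gradient(lambda: classification_loss(y, logits), logits)
        np.testing.assert_allclose(grad, num, atol=1e-7)

    def test_class_weights_reweight_minority(self):
        y = np.array([0, 0, 0, 1])
        logits = np.zeros((4, 2))
        unweighted = classification_loss(y, logits)
        weighted = classification_loss(y, logits, class_weights=np.array([1.0, 3.0]))
        assert unweighted == pytest.approx(np.log(2))
        assert weighted == pytest.approx(np.log(2))  # symmetric logits


class TestRegressionLoss:
    def test_exact_prediction_zero(self):
        assert regression_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_hand_value(self):
        assert regression_loss(np.zeros(2), np.array([1.0, 3.0])) == pytest.approx(5.0)

    def test_quadratic_homogeneity(self, rng):
        y = rng.normal(size=6)
        p = rng.normal(size=6)
        base = regression_loss(y, p)
        assert regression_loss(y, y + 2 * (p - y)) == pytest.approx(4 * base)


class TestTimeGrid:
    def test_uniform_boundaries(self):
        grid = make_time_grid(np.arange(1.0, 101.0), 4, strategy="uniform")
        np.testing.assert_allclose(grid.boundaries[:4], [0, 25, 50, 75], rtol=1e-6)
        assert grid.boundaries[4] >= 100.0

    def test_single_interval(self):
        grid = make_time_grid(np.array([3.0, 7.0]), 1)
        assert grid.m == 1 and grid.boundaries[1] > 7.0

    def test_ties_collapse_with_warning(self):
        times = np.array([5.0] * 50 + [10.0])
        with pytest.warns(UserWarning, match="reduced"):
            grid = make_time_grid(times, 8, strategy="quantile")
        assert grid.m <= 8
        assert np.all(np.diff(grid.boundaries) > 0)

    def test_invalid_m_rejected(self):
        with pytest.raises(ConfigError):
            make_time_grid(np.array([1.0]), 0)

    def test_interval_lookup(self):
        grid = TimeGrid(np.array([0.0, 10.0, 20.0]))
        assert grid.interval_of(0.0) == 1
        assert grid.interval_of(10.0) == 2
        with pytest.warns(UserWarning, match="beyond"):
            assert grid.interval_of(25.0) == 2


class TestSurvivalLabels:
    grid = TimeGrid(np.array([0.0, 10.0, 20.0, 30.0]))

    def test_event_in_middle_interval(self):
        lab = encode_survival_label(15.0, 1, self.grid)
        np.testing.assert_array_equal(lab.y, [0, 1, 1])

    def test_event_in_first_interval(self):
        lab = encode_survival_label(5.0, 1, self.grid)
        np.testing.assert_array_equal(lab.y, [1, 1, 1])

    def test_censored_compatible_configurations(self):
        lab = encode_survival_label(15.0, 0, self.grid)
        np.testing.assert_array_equal(lab.compatible_switches(), [2, 3, 4])

    def test_uncensored_single_configuration(self):
        lab = encode_survival_label(15.0, 1, self.grid)
        np.testing.assert_array_equal(lab.compatible_switches(), [2])


class TestMTLR:
    def test_uniform_scores_give_uniform_configurations(self):
        # m=2, zero scores: three equally likely configurations
        for y in ([0, 0], [0, 1], [1, 1]):
            assert np.exp(mtlr_log_probability(np.array(y), np.zeros(2))) == \
                pytest.approx(1.0 / 3.0)

    def test_hand_evaluated_example(self):
        p = np.exp(mtlr_log_probability(np.array([1, 1]),
                                        np.array([np.log(2.0), 0.0])))
        assert p == pytest.approx(0.5)  # denominator 2 + 1 + 1

    def test_nonmonotone_label_rejected(self):
        with pytest.raises(ValueError):
            mtlr_log_probability(np.array([1, 0]), np.zeros(2))

    @pytest.mark.parametrize("m", range(1, 7))
    def test_probabilities_sum_to_one(self, m, rng):
        for _ in range(20):
            scores = rng.normal(scale=3.0, size=m)
            probs, configs = enumerate_monotone_probabilities(scores)
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)
            ours = [np.exp(mtlr_log_probability(np.array(y), scores))
                    for y in configs]
            np.testing.assert_allclose(ours, probs, atol=1e-9)

    def test_large_scores_do_not_overflow(self):
        val = mtlr_log_probability(np.array([0, 1]), np.array([800.0, -800.0]))
        assert np.isfinite(val)


class TestSurvivalLoss:
    grid = TimeGrid(np.array([0.0, 1.0, 2.0]))

    def test_uncensored_equals_negative_log_probability(self, rng):
        scores = rng.normal(size=(1, 2))
        lab = SurvivalLabel(event=1, interval=2, m=2)
        loss = survival_loss([lab], scores)
        assert loss == pytest.approx(-mtlr_log_probability(lab.y, scores[0]))

    def test_uniform_scores_uncensored(self):
        lab = SurvivalLabel(event=1, interval=1, m=2)
        assert survival_loss([lab], np.zeros((1, 2))) == pytest.approx(np.log(3))

    def test_censored_marginalizes_compatible_configurations(self):
        # censored in the last interval, uniform scores: 2 of 3 configurations
        lab = SurvivalLabel(event=0, interval=2, m=2)
        assert survival_loss([lab], np.zeros((1, 2))) == \
            pytest.approx(-np.log(2.0 / 3.0))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            survival_loss([], np.zeros((0, 2)))

    def test_gradient_matches_finite_differences(self, rng):
        labels = [SurvivalLabel(event=1, interval=2, m=3),
                  SurvivalLabel(event=0, interval=1, m=3),
                  SurvivalLabel(event=1, interval=3, m=3)]
        scores = rng.normal(size=(3, 3))
        _, grad = survival_loss(labels, scores, return_grad=True)
        num = numerical_gradient(lambda: survival_loss(labels, scores), scores)
        np.testing.assert_allclose(grad, num, atol=1e-7)


class TestSurvivalCurveAndRisk:
    grid2 = TimeGrid(np.array([0.0, 1.0, 2.0]))

    def test_uniform_scores_curve(self):
        S = predict_survival_curve(np.zeros(2), self.grid2)
        np.testing.assert_allclose(S, [2.0 / 3.0, 1.0 / 3.0])

    def test_certain_early_event(self):
        S = predict_survival_curve(np.array([50.0, 0.0]), self.grid2)
        assert S[0] == pytest.approx(0.0, abs=1e-10)

    def test_monotone_and_bounded_for_random_scores(self, rng):
        grid = TimeGrid(np.concatenate([[0.0], np.arange(1.0, 6.0)]))
        for _ in range(1000):
            S = predict_survival_curve(rng.normal(scale=5, size=5), grid)
            assert np.all(S >= -1e-12) and np.all(S <= 1 + 1e-12)
            assert np.all(np.diff(S) <= 1e-12)

    def test_no_event_mass_gives_zero_risk(self):
        r = risk_score(np.array([-60.0, -60.0]), self.grid2)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_uniform_scores_risk(self):
        # S = (2/3, 1/3) -> h = (1/3, 1/2) -> r = 5/6
        assert risk_score(np.zeros(2), self.grid2) == pytest.approx(5.0 / 6.0)

    def test_configuration_logit_shift_invariance(self, rng):
        """Probabilities are a softmax over the configuration log-scores
        A_s, so shifting every A_s by a constant changes nothing. (A
        constant shift of the raw interval scores y' is NOT such a shift:
        it adds (m+1-s)c to configuration s and moves mass toward earlier
        events.)"""
        from moals.downstream_tasks import (_suffix_logits,
                                            mtlr_configuration_probabilities)
        from scipy.special import softmax
        scores = rng.normal(size=4)
        A = _suffix_logits(scores)
        np.testing.assert_allclose(mtlr_configuration_probabilities(scores),
                                   softmax(A + 11.7), atol=1e-12)

    def test_raising_all_scores_increases_risk(self, rng):
        grid = TimeGrid(np.concatenate([[0.0], np.arange(1.0, 5.0)]))
        scores = rng.normal(size=4)
        assert risk_score(scores + 2.0, grid) > risk_score(scores, grid)


class TestTaskHeadSpec:
    def test_regression_head_single_output(self):
        with pytest.raises(ValueError):
            TaskHeadSpec(kind="regression", output_width=3)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            TaskHeadSpec(kind="ranking", output_width=1)
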