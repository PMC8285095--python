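import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igt_pvl import (
    ModelSpec,
    PVLParams,
    choice_probabilities,
    log_likelihood,
    sensitivity,
    simulate_subject,
    traditional_scores,
    update_expectancies,
    utility,
)
from igt_pvl.pvl import cohort_arrays, log_likelihood_cohort

from _oracles import pvl_loglik_loop


class TestUtility:
    def test_zero(self):
        for alpha in (0.0, 0.5, 1.0):
            assert utility(0.0, alpha, 3.0) == 0.0

    def test_hand_values(self):
        assert utility(1.0, 0.5, 2.0) == pytest.approx(1.0)
        assert utility(-1.0, 0.5, 2.0) == pytest.approx(-2.0)
        assert utility(0.25, 0.5, 1.0) == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0.01, 5, allow_nan=False), st.floats(0, 1))
    def test_symmetry_at_lambda_one(self, x, alpha):
        assert utility(-x, alpha, 1.0) == pytest.approx(-utility(x, alpha, 1.0))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.floats(-5, 5, allow_nan=False),
        st.floats(-5, 5, allow_nan=False),
        st.floats(0.05, 1),
        st.floats(0, 5),
    )
    def test_monotone_in_outcome(self, x1, x2, alpha, lam):
        lo, hi = sorted([x1, x2])
        assert utility(lo, alpha, lam) <= utility(hi, alpha, lam) + 1e-12

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(-5, -0.01), st.floats(0.05, 1), st.floats(0, 4.9))
    def test_more_loss_attention_hurts_losses(self, x, alpha, lam):
        assert utility(x, alpha, lam + 0.1) <= utility(x, alpha, lam)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            utility(float("nan"), 0.5, 1.0)


class TestUpdateExpectancies:
    def test_delta_extremes(self):
        E = np.array([0.5, -0.2, 0.1, 0.0])
        np.testing.assert_array_equal(update_expectancies(E, 1, 2.0, 0.0, "delta"), E)
        assert update_expectancies(E, 1, 2.0, 1.0, "delta")[1] == 2.0

    def test_delta_recursion(self):
        E = np.zeros(4)
        E = update_expectancies(E, 0, 1.0, 0.3, "delta")
        assert E[0] == pytest.approx(0.3)
        E = update_expectancies(E, 0, 1.0, 0.3, "delta")
        assert E[0] == pytest.approx(0.51)

    def test_decay_orientation(self):
        # carry-over is (1 - A): larger retention = faster forgetting
        E = np.array([1.0, 1.0, 1.0, 1.0])
        out = update_expectancies(E, 2, 0.5, 0.2, "decay")
        np.testing.assert_allclose(out, [0.8, 0.8, 1.3, 0.8])

    def test_unchosen_unchanged_delta(self):
        E = np.array([0.5, -0.2, 0.1, 0.0])
        out = update_expectancies(E, 2, 1.0, 0.4, "delta")
        np.testing.assert_array_equal(out[[0, 1, 3]], E[[0, 1, 3]])

    def test_unknown_deck(self):
        with pytest.raises(ValueError):
            update_expectancies(np.zeros(4), "E", 1.0, 0.5, "delta")


class TestSensitivity:
    def test_trial_dependent(self):
        assert sensitivity(5, 0.0, "trial_dependent") == 1.0
        assert sensitivity(10, 3.7, "trial_dependent") == 1.0
        assert sensitivity(100, 1.0, "trial_dependent") == pytest.approx(10.0)

    def test_trial_independent(self):
        assert sensitivity(1, 0.0, "trial_independent") == 0.0
        assert sensitivity(50, 1.0, "trial_independent") == pytest.approx(2.0)
        # constant in t
        assert sensitivity(1, 2.0, "trial_independent") == sensitivity(99, 2.0, "trial_independent")

    def test_range_enforced(self):
        with pytest.raises(ValueError):
            sensitivity(1, -0.5, "trial_independent")
        with pytest.raises(ValueError):
            sensitivity(1, 6.0, "trial_dependent")


class TestChoiceProbabilities:
    def test_uniform_cases(self):
        np.testing.assert_allclose(choice_probabilities(np.ones(4), 2.0), 0.25)
        np.testing.assert_allclose(choice_probabilities(np.array([5.0, -3, 2, 0]), 0.0), 0.25)

    def test_hand_softmax(self):
        p = choice_probabilities(np.array([1.0, 0, 0, 0]), 1.0)
        assert p[0] == pytest.approx(math.e / (math.e + 3), rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=4),
        st.floats(0, 10),
        st.floats(-20, 20),
    )
    def test_sum_and_shift_invariance(self, E, theta, shift):
        E = np.array(E)
        p = choice_probabilities(E, theta)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(p, choice_probabilities(E + shift, theta), atol=1e-12)

    def test_overflow_safe(self):
        p = choice_probabilities(np.array([1e4, 0, 0, 0]), 10.0)
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)


class TestLogLikelihood:
    def test_uniform_when_theta_zero(self, schedule):
        spec = ModelSpec("delta", "trial_independent")
        params = PVLParams(0.3, 0.0, 1.0, 0.5)
        seq = simulate_subject(params, spec, schedule, 100, seed=4)
        assert log_likelihood(params, seq, spec) == pytest.approx(100 * math.log(0.25))

    def test_first_trial_uniform(self, schedule, delta_td):
        params = PVLParams(0.5, 2.0, 1.0, 0.5)
        seq = simulate_subject(params, delta_td, schedule, 1, seed=0)
        assert log_likelihood(params, seq, delta_td) == pytest.approx(math.log(0.25))

    @pytest.mark.parametrize("lr", ["delta", "decay"])
    @pytest.mark.parametrize("cr", ["trial_dependent", "trial_independent"])
    def test_matches_loop_oracle(self, schedule, lr, cr):
        from conftest import random_params, random_sequence_arrays
        from igt_pvl.pvl import OUTCOME_SCALE

        spec = ModelSpec(lr, cr)
        rng = np.random.default_rng(123)
        for _ in range(10):
            p = random_params(rng, spec)
            decks, gains, losses = random_sequence_arrays(rng, schedule, 80)
            net = (gains - losses) * OUTCOME_SCALE
            fast = log_likelihood_cohort(p[None, :], decks[None, :], net[None, :], spec)[0]
            slow = pvl_loglik_loop(p, decks, net, lr, cr)
            assert fast == pytest.approx(slow, abs=1e-10)


class TestSimulateSubject:
    def test_seed_reproducibility(self, schedule, delta_td):
        p = PVLParams(0.4, 1.0, 1.5, 0.6)
        a = simulate_subject(p, delta_td, schedule, 100, seed=9)
        b = simulate_subject(p, delta_td, schedule, 100, seed=9)
        assert list(a.decks) == list(b.decks)
        np.testing.assert_array_equal(a.gains, b.gains)
        assert np.isfinite(log_likelihood(p, a, delta_td))

    def test_uniform_choice_frequencies(self, schedule):
        spec = ModelSpec("delta", "trial_independent")
        seq = simulate_subject(PVLParams(0.3, 0.0, 1.0, 0.5), spec, schedule, 10_000, seed=2)
        props = np.array([(seq.decks == d).mean() for d in "ABCD"])
        assert np.abs(props - 0.25).max() < 0.02  # ~4 binomial SEs

    def test_loss_attention_promotes_advantageous_choice(self, schedule, delta_td):
        def mean_adv(lam, seed0):
            vals = []
            for i in range(30):
                p = PVLParams(0.2, 1.0, lam, 0.5)
                seq = simulate_subject(p, delta_td, schedule, 100, seed=seed0 + i)
                vals.append(traditional_scores(seq).prop_advantageous_total)
            return np.mean(vals)

        assert mean_adv(3.0, 1000) > mean_adv(0.0, 2000)

    def test_gain_chasing_when_losses_ignored(self, schedule, delta_td):
        # lam ~ 0 with decisive choice: A+B (large constant gains) dominate
        props = []
        for i in range(30):
            p = PVLParams(0.2, 2.0, 0.0, 0.5)
            seq = simulate_subject(p, delta_td, schedule, 100, seed=3000 + i)
            props.append(1.0 - traditional_scores(seq).prop_advantageous_total)
        assert np.mean(props) > 0.5
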