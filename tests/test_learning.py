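"""Surprise-controlled forgetting: the alpha logistic and Dirichlet decay."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coeruleus.learning import (
    AlphaParams,
    alpha_from_sape,
    calibrate_m,
    decay_update,
    end_of_trial_learning,
    m_from_sapes,
)
from coeruleus.mdp import DirichletParams
from coeruleus.tasks import build_gonogo


class TestAlphaFromSape:
    def test_fixed_mode_ignores_the_error(self):
        params = AlphaParams(mode="fixed", fixed_value=16.0)
        assert alpha_from_sape([5.0], params) == 16.0

    def test_extreme_surprise_reaches_the_fast_forgetting_asymptote(self):
        params = AlphaParams(m=0.5)
        assert alpha_from_sape([1e3], params) == pytest.approx(2.0, abs=1e-10)

    def test_midpoint_gives_alpha_18(self):
        params = AlphaParams(m=0.5)
        assert alpha_from_sape([0.5], params) == pytest.approx(18.0, abs=1e-12)

    def test_zero_error_matches_direct_logistic_evaluation(self):
        params = AlphaParams(m=0.5, k=8.0)
        expect = 2.0 + 32.0 / (1.0 + np.exp(-4.0))
        assert alpha_from_sape([0.0], params) == pytest.approx(expect, abs=1e-12)

    def test_maximum_of_trial_errors_is_used(self):
        params = AlphaParams(m=0.5)
        assert alpha_from_sape([0.1, 2.0], params) == alpha_from_sape([2.0], params)

    def test_empty_trial_rejected(self):
        with pytest.raises(ValueError):
            alpha_from_sape([], AlphaParams())

    @given(st.lists(st.floats(min_value=0, max_value=10), min_size=1, max_size=5))
    def test_bounded_and_monotone(self, values):
        params = AlphaParams(m=1.0)
        alpha = alpha_from_sape(values, params)
        # open interval algebraically; saturates to alpha_min at float precision
        assert 2.0 <= alpha < 34.0
        assert alpha_from_sape([max(values) + 0.5], params) <= alpha


class TestCalibration:
    def test_constant_stream_returns_the_constant(self):
        assert m_from_sapes([0.4, 0.4, 0.4]) == pytest.approx(0.4, abs=1e-12)

    def test_two_level_stream_is_mean_plus_sd(self):
        assert m_from_sapes([0.1, 0.3, 0.1, 0.3]) == pytest.approx(0.3, abs=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            m_from_sapes([0.4])

    def test_calibration_is_seed_deterministic(self):
        def factory(seed):
            return lambda: build_gonogo(rng=np.random.default_rng(seed))

        m1 = calibrate_m(factory(3), n_trials=20, rng=np.random.default_rng(4))
        m2 = calibrate_m(factory(3), n_trials=20, rng=np.random.default_rng(4))
        assert m1 == m2

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            calibrate_m(lambda: build_gonogo(), n_trials=1, rng=np.random.default_rng(0))


class TestDecayUpdate:
    def test_baseline_counts_are_a_fixed_point(self):
        out = decay_update(np.ones(3), np.array([0.5, 0.0, 0.2]), alpha=7.0)
        assert np.allclose(out, [1.5, 1.0, 1.2], atol=1e-12)

    def test_pure_decay_arithmetic(self):
        assert decay_update(np.array([33.0]), np.array([0.0]), 32.0)[0] == pytest.approx(
            32.0, abs=1e-12
        )

    def test_increment_balances_decay_at_the_equilibrium(self):
        assert decay_update(np.array([3.0]), np.array([1.0]), 2.0)[0] == pytest.approx(
            3.0, abs=1e-12
        )

    def test_alpha_below_one_rejected(self):
        with pytest.raises(ValueError):
            decay_update(np.ones(2), np.zeros(2), 0.5)

    def test_mask_freezes_unlearnable_entries(self):
        out = decay_update(
            np.array([5.0, 5.0]), np.ones(2), 2.0, mask=np.array([True, False])
        )
        assert out[0] == pytest.approx(4.0)
        assert out[1] == 5.0

    @given(
        st.floats(min_value=1.0, max_value=40.0),
        st.lists(st.floats(min_value=0, max_value=2), min_size=5, max_size=25),
    )
    def test_counts_never_fall_below_baseline(self, alpha, increments):
        counts = np.array([1.0, 4.0, 12.0])
        base = np.array([0.25, 1.0, 1.0])
        counts = np.maximum(counts, base)
        for inc in increments:
            counts = decay_update(
                counts, np.full(3, inc), alpha, baseline=base
            )
            assert np.all(counts >= base - 1e-9)

    def test_convergence_to_closed_form_fixed_point(self):
        # under constant increments counts approach base + alpha*inc
        # geometrically with rate (1 - 1/alpha)
        alpha, inc = 8.0, 0.4
        c = np.array([1.0])
        target = 1.0 + alpha * inc
        errors = []
        for _ in range(200):
            c = decay_update(c, np.array([inc]), alpha)
            errors.append(abs(c[0] - target))
        assert errors[-1] < 1e-8
        ratios = [errors[i + 1] / errors[i] for i in range(3, 10)]
        assert np.allclose(ratios, 1 - 1 / alpha, atol=1e-6)


class TestEndOfTrialLearning:
    def _counts(self, **kw):
        return DirichletParams(
            a=np.ones((2, 2)), b=np.ones((2, 2, 1)), d=np.ones(2), **kw
        )

    def test_no_learnable_arrays_means_no_change(self):
        counts = self._counts()
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        new = end_of_trial_learning(counts, S, [0, 1], [0], alpha=16.0)
        assert np.array_equal(new.a, counts.a)
        assert np.array_equal(new.b, counts.b)
        assert np.array_equal(new.d, counts.d)

    def test_certain_posterior_accretes_one_count(self):
        counts = self._counts(learn_d=True)
        S = np.array([[0.0 + 1e-12, 1.0], [1.0, 0.0]])
        new = end_of_trial_learning(counts, S, [0, 1], [0], alpha=1e9)
        assert new.d[1] == pytest.approx(2.0, abs=1e-6)
        assert new.d[0] == pytest.approx(1.0, abs=1e-6)

    def test_likelihood_counts_accrue_outcome_state_coincidences(self):
        counts = self._counts(learn_a=True)
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        new = end_of_trial_learning(counts, S, [0, 1], [0], alpha=1e9)
        assert new.a[0, 0] == pytest.approx(2.0, abs=1e-6)
        assert new.a[1, 1] == pytest.approx(2.0, abs=1e-6)

    def test_transition_counts_accrue_action_conditioned_coincidences(self):
        counts = self._counts(learn_b=True)
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        new = end_of_trial_learning(counts, S, [0, 1], [0], alpha=1e9)
        assert new.b[1, 0, 0] == pytest.approx(2.0, abs=1e-6)

    def test_repeated_trials_converge_to_the_decay_fixed_point(self):
        counts = self._counts(learn_d=True)
        S = np.array([[0.3, 0.7], [0.0, 1.0]])
        alpha = 8.0
        for _ in range(300):
            counts = end_of_trial_learning(counts, S, [0, 1], [0], alpha)
        assert np.allclose(counts.d, 1.0 + alpha * S[0], atol=1e-8)
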