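"""Dynamics of the seven choice models: prediction and state updates."""

import numpy as np
import pytest

from inequitylearn.models import MODELS, get_model
from inequitylearn.models.learners import SimilarityRL

TOL = 1e-10


class TestRegistry:
    def test_parameter_counts(self):
        assert [MODELS[i].k for i in range(1, 8)] == [5, 3, 2, 6, 7, 4, 5]

    def test_lookup_by_id_name_instance(self):
        m = get_model(6)
        assert get_model("preference_inference") is m
        assert get_model(m) is m

    def test_unknown_keys(self):
        with pytest.raises(KeyError):
            get_model(8)
        with pytest.raises(KeyError):
            get_model("bayesian_tom")

    def test_bounds_exported(self):
        b = get_model(6).bounds
        assert b.shape == (4, 2)
        assert b[0].tolist() == [0.0, 5.0]  # learning rate
        assert b[2].tolist() == [0.0, 10.0]  # initial envy

    def test_param_shape_validation(self):
        with pytest.raises(ValueError, match="expects 4 parameters"):
            get_model(6).check_params(np.zeros(3))
        with pytest.raises(ValueError, match="outside bounds"):
            get_model(3).check_params(np.array([1.5, 1.0]))


class TestPredictions:
    def test_random_choice_lookup(self):
        m = get_model(1)
        theta = np.array([0.7, 0.2, 0.1, 0.3, 0.9])
        assert m.predict_reject(theta, m.init_state(theta), 0, 12.0) == pytest.approx(0.7)

    def test_fresh_rl_is_indifferent(self):
        m = get_model(3)
        theta = np.array([0.3, 5.0])
        state = m.init_state(theta)
        for k in range(5):
            assert m.predict_reject(theta, state, k, 30.0) == pytest.approx(0.5, abs=TOL)

    def test_selfless_inference_accepts_positive_offers(self):
        # with zero envy/guilt, accepting any positive offer dominates
        m = get_model(6)
        theta = np.array([1.0, 0.5, 0.0, 0.0])
        state = m.init_state(theta)
        for share in (10.0, 50.0, 90.0):
            assert m.predict_reject(theta, state, 0, share) < 0.5

    @pytest.mark.parametrize("mid", range(1, 8))
    def test_probabilities_interior(self, mid):
        from inequitylearn.fit import random_starts

        m = get_model(mid)
        rng = np.random.default_rng(mid)
        for theta in random_starts(m, 5, rng):
            state = m.init_state(theta)
            for k, s in [(0, 12.0), (2, 55.0), (4, 83.0)]:
                p = m.predict_reject(theta, state, k, s)
                assert 0.0 < p < 1.0


class TestRLUpdate:
    def test_delta_step(self):
        m = get_model(3)
        theta = np.array([0.2, 1.0])
        state = m.init_state(theta)
        m.update(theta, state, 1, 30.0, action=1, teacher_action=1)  # match -> R=1
        assert state["q"][1, 1] == pytest.approx(0.6, abs=TOL)
        assert state["q"][0, 1] == 0.5  # untaken action untouched
        assert np.all(state["q"][:, [0, 2, 3, 4]] == 0.5)  # other types untouched

    def test_mismatch_gives_zero_reward(self):
        m = get_model(3)
        theta = np.array([0.2, 1.0])
        state = m.init_state(theta)
        m.update(theta, state, 0, 12.0, action=1, teacher_action=0)
        assert state["q"][1, 0] == pytest.approx(0.4, abs=TOL)

    def test_per_type_learning_rates(self):
        m = get_model(4)
        theta = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 1.0])
        state = m.init_state(theta)
        m.update(theta, state, 3, 72.0, action=0, teacher_action=0)
        assert state["q"][0, 3] == pytest.approx(0.5 + 0.4 * 0.5, abs=TOL)

    def test_free_initial_values(self):
        m = get_model(5)
        q0 = [0.9, 0.7, 0.1, 0.6, 0.8]
        theta = np.array([0.3, 1.0] + q0)
        state = m.init_state(theta)
        assert state["q"][1].tolist() == q0
        assert np.all(state["q"][0] == 0.5)

    def test_constant_reward_closed_form(self):
        m = get_model(3)
        eta = 0.2
        theta = np.array([eta, 1.0])
        state = m.init_state(theta)
        for t in range(1, 25):
            m.update(theta, state, 2, 50.0, action=1, teacher_action=1)
            expected = 1.0 - (1.0 - eta) ** t * 0.5
            assert state["q"][1, 2] == pytest.approx(expected, abs=1e-14)


class TestPreferenceInference:
    def make(self, eta=0.5, tau=1.0, alpha0=1.0, beta0=1.0):
        m = get_model(6)
        theta = np.array([eta, tau, alpha0, beta0])
        return m, theta, m.init_state(theta)

    def test_reject_moves_envy_toward_lower_bound(self):
        m, theta, state = self.make(eta=0.5, alpha0=1.0)
        m.update(theta, state, 1, 30.0, action=0, teacher_action=1)  # bound 1.5
        assert state["alpha"] == pytest.approx(1.25, abs=TOL)

    def test_satisfied_bound_leaves_envy_unchanged(self):
        m, theta, state = self.make(alpha0=2.0)
        m.update(theta, state, 1, 30.0, action=0, teacher_action=1)
        assert state["alpha"] == 2.0

    def test_overshoot_with_large_learning_rate(self):
        m, theta, state = self.make(eta=5.0, alpha0=1.0)
        m.update(theta, state, 1, 30.0, action=0, teacher_action=1)
        assert state["alpha"] == pytest.approx(1.0 + 5.0 * 0.5, abs=TOL)  # 3.5

    def test_update_clipped_to_box(self):
        m, theta, state = self.make(eta=5.0, alpha0=8.0)
        # reject at share 45: bound 9; 8 + 5*(9-8) = 13 -> clipped to 10
        m.update(theta, state, 2, 45.0, action=0, teacher_action=1)
        assert state["alpha"] == 10.0

    def test_accept_moves_guilt_down_toward_upper_bound(self):
        m, theta, state = self.make(eta=0.5, beta0=8.0)
        # teacher accepts share 70: guilt upper bound 3.5; 8 -> 8+0.5*(3.5-8)
        m.update(theta, state, 3, 70.0, action=1, teacher_action=0)
        assert state["beta"] == pytest.approx(8.0 + 0.5 * (3.5 - 8.0), abs=TOL)

    def test_fair_offer_is_noop(self):
        m, theta, state = self.make()
        m.update(theta, state, 2, 50.0, action=1, teacher_action=1)
        assert state == {"alpha": 1.0, "beta": 1.0}

    def test_envy_and_guilt_updated_on_disjoint_offers(self):
        m, theta, state = self.make(eta=1.0, alpha0=0.0, beta0=0.0)
        m.update(theta, state, 0, 10.0, action=0, teacher_action=1)
        assert state["beta"] == 0.0  # disadvantageous offer never touches guilt
        m.update(theta, state, 4, 90.0, action=0, teacher_action=1)
        assert state["alpha"] == pytest.approx(0.25)  # unchanged by the second update

    def test_consistent_rejection_makes_envy_monotone_nondecreasing(self):
        m, theta, state = self.make(eta=0.8, alpha0=0.0)
        rng = np.random.default_rng(3)
        prev = state["alpha"]
        for _ in range(50):
            share = float(rng.choice([10, 30]) + rng.integers(-9, 10))
            m.update(theta, state, 0, share, action=0, teacher_action=1)
            assert state["alpha"] >= prev - TOL
            prev = state["alpha"]

    def test_consistent_acceptance_makes_envy_monotone_nonincreasing(self):
        m, theta, state = self.make(eta=0.8, alpha0=9.0)
        rng = np.random.default_rng(4)
        prev = state["alpha"]
        for _ in range(50):
            share = float(rng.choice([10, 30]) + rng.integers(-9, 10))
            m.update(theta, state, 0, share, action=0, teacher_action=0)
            assert state["alpha"] <= prev + TOL
            prev = state["alpha"]

    def test_state_stays_in_box_under_arbitrary_feedback(self):
        m, theta, state = self.make(eta=5.0, alpha0=5.0, beta0=5.0)
        rng = np.random.default_rng(5)
        for _ in range(500):
            share = float(rng.integers(1, 100))
            m.update(theta, state, 0, share, action=int(rng.integers(2)),
                     teacher_action=int(rng.integers(2)))
            assert 0.0 <= state["alpha"] <= 10.0
            assert 0.0 <= state["beta"] <= 10.0


class TestSimilarityRL:
    def test_vshape_initialization(self):
        m = get_model(7)
        theta = np.array([0.3, 1.0, 50.0, 2.0, 1.0])
        state = m.init_state(theta)
        assert state["q"][1, 50] == 0.0
        assert state["q"][1, 10] == pytest.approx(1.6)
        assert state["q"][1, 90] == pytest.approx(0.8)
        assert np.all(state["q"][0] == SimilarityRL.Q0_ACCEPT)

    def test_narrow_kernel_reduces_to_local_update(self):
        # with sigma -> 0 the update touches only the experienced offer,
        # matching the per-type delta rule step
        m = get_model(7)
        eta = 0.4
        theta = np.array([eta, 1.0, 1e-2, 0.0, 0.0])
        state = m.init_state(theta)
        before = state["q"].copy()
        m.update(theta, state, 1, 30.0, action=1, teacher_action=1)
        local = before[1, 30] + eta * (1.0 - before[1, 30])
        assert state["q"][1, 30] == pytest.approx(local, abs=1e-9)
        others = np.delete(np.arange(1, 101), 29)
        assert np.allclose(state["q"][1, others], before[1, others], atol=1e-9)

    def test_wide_kernel_updates_everything(self):
        m = get_model(7)
        theta = np.array([1.0, 1.0, 200.0, 0.0, 0.0])
        state = m.init_state(theta)
        before = state["q"][1].copy()
        m.update(theta, state, 1, 30.0, action=1, teacher_action=1)
        # worst case is the farthest offer (distance 70): exp(-70^2/80000)
        applied = (state["q"][1, 1:] - before[1:]) / (1.0 - before[1:])
        assert np.all(applied >= np.exp(-(70.0**2) / 80000.0) - 1e-12)
        assert np.all(applied >= 0.94)

    def test_single_update_monotone_in_similarity(self):
        m = get_model(7)
        theta = np.array([0.5, 1.0, 30.0, 0.0, 0.0])
        state = m.init_state(theta)
        m.update(theta, state, 1, 40.0, action=1, teacher_action=1)
        q = state["q"][1]
        dists = np.abs(np.arange(1, 101) - 40)
        order = np.argsort(dists, kind="stable")
        vals = q[1:][order]
        assert np.all(np.diff(vals) <= TOL)  # closer offers moved at least as much
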