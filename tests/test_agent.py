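"""Belief recursion primitives and the generative loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardsort.agent import (
    AgentParams,
    ImpossibleObservationError,
    action_probabilities,
    activation_update,
    likelihood_from_match,
    matching_signal,
    observation_likelihood,
    posterior_update,
    predictive_update,
    run_agent,
    sample_action,
    stability_matrix,
)
from cardsort.task import Card, TaskConfig, card_for_feature

TOL = 1e-12


class TestObservationLikelihood:
    @pytest.mark.parametrize(
        "match, feedback, expected",
        [
            ((1, 0, 0), 1, (1.0, 0.0, 0.0)),
            ((1, 0, 0), 0, (0.0, 0.5, 0.5)),
            ((1, 1, 0), 1, (0.5, 0.5, 0.0)),
            ((0, 1, 1), 0, (1.0, 0.0, 0.0)),
        ],
    )
    def test_hand_cases(self, match, feedback, expected):
        got = likelihood_from_match(np.array(match), feedback)
        assert np.allclose(got, expected, atol=TOL)

    def test_wraps_match_vector(self):
        # blue star x3 vs card 2 (green star x2), positive feedback
        got = observation_likelihood(Card(3, 2, 3), 2, 1)
        assert np.allclose(got, (0, 1, 0), atol=TOL)

    def test_positive_feedback_without_match_is_impossible(self):
        with pytest.raises(ImpossibleObservationError):
            likelihood_from_match(np.array([0, 0, 0]), 1)


class TestPosteriorUpdate:
    def test_unambiguous_confirmation(self):
        post, marginal = posterior_update(np.full(3, 1 / 3), np.array([1.0, 0, 0]))
        assert np.allclose(post, (1, 0, 0), atol=TOL)
        assert abs(marginal - 1 / 3) < TOL

    def test_disconfirmation_spreads_over_survivors(self):
        post, marginal = posterior_update(
            np.full(3, 1 / 3), np.array([0, 0.5, 0.5])
        )
        assert np.allclose(post, (0, 0.5, 0.5), atol=TOL)
        assert abs(marginal - 1 / 3) < TOL

    def test_uniform_likelihood_preserves_prior(self):
        prior = np.array([0.2, 0.5, 0.3])
        post, _ = posterior_update(prior, np.full(3, 1 / 3))
        assert np.allclose(post, prior, atol=TOL)

    def test_zero_mass_observation_raises(self):
        with pytest.raises(ImpossibleObservationError):
            posterior_update(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))


class TestMatchingSignal:
    def test_positive_feedback_passes_match(self):
        assert tuple(matching_signal(np.array([1, 0, 0]), 1)) == (1, 0, 0)
        assert tuple(matching_signal(np.array([1, 1, 0]), 1)) == (1, 1, 0)

    def test_negative_feedback_gates_to_zero_by_default(self):
        assert tuple(matching_signal(np.array([1, 0, 0]), 0)) == (0, 0, 0)

    def test_ungated_variant_passes_match_regardless(self):
        got = matching_signal(np.array([1, 0, 0]), 0, gate_on_feedback=False)
        assert tuple(got) == (1, 0, 0)


class TestActivationUpdate:
    @pytest.mark.parametrize(
        "f, lam, delta, m, expected",
        [
            (1, 0.5, 0.0, (1, 0, 0), (1.0, 1e-6, 1e-6)),
            (1, 0.5, 1.0, (1, 0, 0), (0.5, 1e-6, 1e-6)),
            (0, 0.5, 0.0, (0, 0, 0), (0.25, 0.25, 0.25)),
        ],
    )
    def test_hand_cases(self, f, lam, delta, m, expected):
        params = AgentParams(lam=lam, delta=delta)
        omega = activation_update(
            np.full(3, 0.5), np.array(m, dtype=float), f, params
        )
        assert np.allclose(omega, expected, atol=TOL)

    @given(
        lam=st.floats(0, 1),
        delta=st.floats(0, 1),
        f=st.integers(0, 1),
        omega=st.lists(st.floats(1e-6, 1.0), min_size=3, max_size=3),
        m_idx=st.integers(0, 2),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_stays_in_unit_interval_above_floor(self, lam, delta, f, omega, m_idx):
        m = np.zeros(3)
        if f:
            m[m_idx] = 1.0
        out = activation_update(
            np.array(omega), m, f, AgentParams(lam=lam, delta=delta)
        )
        assert np.all(out >= 1e-6) and np.all(out <= 1.0 + 1e-12)


class TestStabilityMatrix:
    def test_symmetric_example(self):
        gamma = stability_matrix(np.full(3, 0.5))
        expected = np.array(
            [[0.5, 0.25, 0.25], [0.25, 0.5, 0.25], [0.25, 0.25, 0.5]]
        )
        assert np.allclose(gamma, expected, atol=TOL)

    def test_boundary_example(self):
        gamma = stability_matrix(np.array([1.0, 0.0, 0.0]))
        expected = np.array([[1, 0, 0], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        assert np.allclose(gamma, expected, atol=TOL)

    @given(st.lists(st.floats(0, 1), min_size=3, max_size=3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rows_sum_to_one_and_diag_is_omega(self, omega):
        gamma = stability_matrix(np.array(omega))
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=TOL)
        assert np.allclose(np.diag(gamma), omega, atol=TOL)


class TestPredictiveUpdate:
    def test_hand_case(self):
        pred = predictive_update(
            np.array([0, 0.5, 0.5]), stability_matrix(np.full(3, 0.5))
        )
        assert np.allclose(pred, (0.25, 0.375, 0.375), atol=TOL)

    def test_identity_transition_preserves_posterior(self):
        post = np.array([0.1, 0.6, 0.3])
        pred = predictive_update(post, stability_matrix(np.ones(3)))
        assert np.allclose(pred, post, atol=TOL)

    def test_uniform_fixed_point(self):
        pred = predictive_update(np.full(3, 1 / 3), stability_matrix(np.full(3, 0.7)))
        assert np.allclose(pred, 1 / 3, atol=TOL)


class TestActionSampling:
    def test_degenerate_predictive_always_matches_feature(self, rng):
        target = Card(3, 2, 3)
        for _ in range(20):
            feat, action = sample_action(np.array([1.0, 0, 0]), target, rng)
            assert feat == 1 and action == card_for_feature(target, 1)

    def test_zero_lapse_excludes_nonmatching_cards(self):
        target = Card(3, 2, 1)  # matches cards 4 (color), 2 (shape), 1 (number)
        q = action_probabilities(np.full(3, 1 / 3), target)
        assert q[2] == 0.0  # card 3 matches on no feature
        assert abs(q.sum() - 1.0) < TOL

    def test_lapse_mixes_uniform_mass(self):
        target = Card(3, 2, 1)
        q = action_probabilities(np.full(3, 1 / 3), target, lapse=0.01)
        assert abs(q[2] - 0.0025) < TOL

    def test_empirical_frequencies_match_closed_form(self):
        target = Card(3, 2, 1)  # three distinct matching cards
        pred = np.full(3, 1 / 3)
        rng = np.random.default_rng(11)
        n = 100_000
        counts = np.zeros(4)
        for _ in range(n):
            _, a = sample_action(pred, target, rng)
            counts[a - 1] += 1
        q = action_probabilities(pred, target)
        band = 3 * np.sqrt(q * (1 - q) / n)
        assert np.all(np.abs(counts / n - q) <= band + 1e-12)


class TestRunAgent:
    def test_identical_seed_identical_session(self):
        p = AgentParams(0.7, 0.5)
        a = run_agent(p, seed=123)
        b = run_agent(p, seed=123)
        assert a.to_frame(beliefs=True).equals(b.to_frame(beliefs=True))

    @pytest.mark.parametrize("lam,delta,seed", [(0.1, 0.9, 0), (0.9, 0.1, 1),
                                                (0.5, 0.5, 2), (1.0, 0.0, 3),
                                                (0.0, 1.0, 4)])
    def test_belief_simplex_invariants(self, lam, delta, seed):
        session = run_agent(AgentParams(lam, delta), seed=seed)
        for rec in session:
            b = rec.belief
            assert abs(b.prior.sum() - 1.0) < TOL
            assert abs(b.posterior.sum() - 1.0) < TOL
            assert np.all(b.prior >= 0) and np.all(b.posterior >= 0)
            assert np.all(b.omega >= 1e-6) and np.all(b.omega <= 1.0 + TOL)
            assert 0.0 < b.marginal <= 1.0 + TOL

    def test_flexible_agents_complete_more_categories(self):
        """Cohort-level sanity: perfect flexibility with minimal information
        loss completes more categories than rigid agents."""
        from cardsort.experiments import simulate_cohort
        from cardsort.scoring import categories_completed

        fast = np.mean(
            [categories_completed(s) for s in simulate_cohort(1.0, 0.01, 30, seed=8)]
        )
        slow = np.mean(
            [categories_completed(s) for s in simulate_cohort(0.3, 0.01, 30, seed=8)]
        )
        assert fast > slow

    def test_max_categories_protocol_terminates_early(self):
        cfg = TaskConfig(max_trials=128, max_categories=1)
        session = run_agent(AgentParams(1.0, 0.0), cfg, seed=0)
        assert len(session) < 128
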