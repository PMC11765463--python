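"""Expected free energy, policy posteriors and action selection."""

import numpy as np
import pytest
from scipy.stats import chisquare

from conftest import random_model
from actinf.model import DirichletCounts, construct_policies
from actinf.planning import (
    PlanningSettings,
    action_distribution,
    expected_free_energy,
    expected_observations,
    expected_states,
    marginal_action_probabilities,
    param_info_gain,
    policy_posterior,
    pragmatic_value,
    sample_action,
    state_info_gain,
)


class TestExpectedStates:
    def test_identity_B_keeps_beliefs(self):
        B = [np.eye(3)[:, :, None]]
        q = [np.array([0.2, 0.3, 0.5])]
        roll = expected_states(B, q, np.array([[1], [1]]))
        for step in roll:
            assert np.allclose(step[0], q[0])

    def test_deterministic_rollout(self):
        B = [np.zeros((4, 4, 4))]
        for u in range(4):
            B[0][u, :, u] = 1.0
        roll = expected_states(B, [np.array([1.0, 0, 0, 0])], np.array([[4], [3]]))
        assert roll[0][0].tolist() == [0, 0, 0, 1]
        assert roll[1][0].tolist() == [0, 0, 1, 0]

    def test_matches_repeated_matrix_product(self):
        M = np.array([[0.7, 0.3], [0.3, 0.7]])
        B = [M[:, :, None]]
        q0 = np.array([1.0, 0.0])
        roll = expected_states(B, [q0], np.array([[1], [1]]))
        assert np.allclose(roll[0][0], M @ q0)
        assert np.allclose(roll[1][0], M @ M @ q0)


class TestExpectedObservations:
    def test_identity_delta(self):
        A = [np.eye(3)]
        qo = expected_observations(A, [np.array([0, 1.0, 0])])
        assert np.allclose(qo[0], [0, 1, 0])

    def test_uniform(self):
        A = [np.full((4, 3), 0.25)]
        qo = expected_observations(A, [np.array([0.5, 0.2, 0.3])])
        assert np.allclose(qo[0], 0.25)

    def test_symmetric_mixture(self):
        A = [np.array([[0.9, 0.1], [0.1, 0.9]])]
        qo = expected_observations(A, [np.array([0.5, 0.5])])
        assert np.allclose(qo[0], [0.5, 0.5])


class TestStateInfoGain:
    def test_uniform_A_zero(self):
        A = [np.full((3, 4), 1 / 3)]
        assert state_info_gain(A, [np.full(4, 0.25)]) == pytest.approx(0.0, abs=1e-12)

    def test_delta_belief_zero(self):
        A = [np.array([[0.9, 0.1], [0.1, 0.9]])]
        assert state_info_gain(A, [np.array([1.0, 0.0])]) == pytest.approx(0.0, abs=1e-9)

    def test_identity_A_ln2(self):
        A = [np.eye(2)]
        assert state_info_gain(A, [np.array([0.5, 0.5])]) == pytest.approx(np.log(2), abs=1e-6)

    def test_non_negative_random(self, rng):
        for _ in range(50):
            A, _, _, D, _, _ = random_model(rng, [3, 2], [3, 2])
            assert state_info_gain(A, D) >= -1e-12


class TestPragmaticValue:
    def test_neutral_preferences(self):
        C = [np.zeros(4)]
        qo = [np.array([0.7, 0.1, 0.1, 0.1])]
        assert pragmatic_value(qo, C) == pytest.approx(-np.log(4), abs=1e-12)

    def test_onehot_on_preferred(self):
        C = [np.array([0.0, 3.0, -3.0])]
        qo = [np.array([0.0, 1.0, 0.0])]
        expected = 3 - np.log(np.exp(0) + np.exp(3) + np.exp(-3))
        assert pragmatic_value(qo, C) == pytest.approx(expected, abs=1e-12)

    def test_additive_over_modalities(self):
        C = [np.zeros(3), np.zeros(5)]
        qo = [np.full(3, 1 / 3), np.full(5, 0.2)]
        single = pragmatic_value([qo[0]], [C[0]]) + pragmatic_value([qo[1]], [C[1]])
        assert pragmatic_value(qo, C) == pytest.approx(single, abs=1e-12)


class TestParamInfoGain:
    def _counts(self):
        A = np.zeros((3, 4, 2))
        A[0, 0, :] = A[0, 3, :] = 1.0
        A[1, 1:3, :] = A[2, 1:3, :] = 0.5
        return [None, 2.0 * A, None], A

    def test_vanishes_with_large_counts(self):
        counts, A = self._counts()
        big = [None, 1e6 * counts[1], None]
        q = [np.full(4, 0.25), np.full(2, 0.5)]
        qo = [None, np.full(3, 1 / 3), None]
        assert param_info_gain(big, q, qo, (2,)) < 1e-5

    def test_unlearned_modality_contributes_zero(self):
        counts, _ = self._counts()
        q = [np.full(4, 0.25), np.full(2, 0.5)]
        qo = [None, np.full(3, 1 / 3), None]
        assert param_info_gain(counts, q, qo, ()) == 0.0

    def test_matches_direct_summation(self):
        counts, _ = self._counts()
        theta = counts[1]
        q = [np.full(4, 0.25), np.full(2, 0.5)]
        qo = [None, np.array([0.2, 0.5, 0.3]), None]
        # brute-force the expectation of w(o, s) over q(o) * q(s1) * q(s2)
        expected = 0.0
        col = theta.sum(axis=0)
        for o in range(3):
            for s1 in range(4):
                for s2 in range(2):
                    if theta[o, s1, s2] <= 0:
                        continue
                    w = 0.5 * (1 / theta[o, s1, s2] - 1 / col[s1, s2])
                    expected += qo[1][o] * q[0][s1] * q[1][s2] * w
        got = param_info_gain(counts, q, qo, (2,))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got >= 0


class TestExpectedFreeEnergy:
    def test_pure_ambiguity_closed_form(self):
        # uniform A, neutral C: G = T * sum_m ln(m_outcomes)
        A = [np.full((3, 2), 1 / 3), np.full((4, 2), 0.25)]
        B = [np.eye(2)[:, :, None]]
        C = [np.zeros(3), np.zeros(4)]
        q = [np.array([0.5, 0.5])]
        res = expected_free_energy(
            A, B, C, q, np.array([[1], [1]]), PlanningSettings(policy_length=2)
        )
        assert res.G == pytest.approx(2 * (np.log(3) + np.log(4)), abs=1e-10)
        assert res.risk == pytest.approx(0.0, abs=1e-10)
        assert res.info_gain == pytest.approx(0.0, abs=1e-10)

    def test_no_uncertainty_no_cost(self):
        A = [np.eye(2)]
        B = [np.eye(2)[:, :, None]]
        C = [np.zeros(2)]
        res = expected_free_energy(
            A, B, C, [np.array([1.0, 0.0])], np.array([[1]]), PlanningSettings()
        )
        # delta beliefs, identity likelihood: ambiguity 0; neutral C over 2
        # outcomes and a delta prediction: risk = ln 2 = info gain cancels in G
        assert res.ambiguity == pytest.approx(0.0, abs=1e-9)
        assert res.G == pytest.approx(res.risk + res.ambiguity, abs=1e-10)

    def test_epistemic_pragmatic_equals_risk_ambiguity(self, rng):
        # the two standard decompositions agree on random models
        for _ in range(200):
            A, B, C, D, _, shape = random_model(rng, [3, 2], [3, 2], [2, 1], 2)
            pol = construct_policies(shape.num_controls, 2)[int(rng.integers(0, 4))]
            res = expected_free_energy(A, B, C, D, pol, PlanningSettings(policy_length=2))
            assert res.G == pytest.approx(res.risk + res.ambiguity, abs=1e-10)


class TestPolicyPosterior:
    def test_gamma_zero_recovers_habit(self):
        E = np.array([0.1, 0.2, 0.3, 0.4])
        q = policy_posterior(np.array([5.0, 1.0, 0.0, 2.0]), E, 0.0)
        assert np.allclose(q, E, atol=1e-12)

    def test_equal_G_uniform(self):
        q = policy_posterior(np.full(8, 3.3), np.full(8, 1 / 8), 16.0)
        assert np.allclose(q, 1 / 8, atol=1e-12)

    def test_softmax_example(self):
        q = policy_posterior(np.array([1.0, 2.0]), np.array([0.5, 0.5]), 1.0)
        assert np.allclose(q, [0.73105857863, 0.26894142137], atol=1e-9)

    def test_sharper_preferences_favour_preferred_policies(self, rng):
        # adding log-preference toward an outcome never lowers the posterior
        # probability of the policy predicting that outcome
        for _ in range(20):
            A, B, C, D, E, shape = random_model(rng, [3], [3], [3], 1)
            pols = construct_policies(shape.num_controls, 1)
            settings = PlanningSettings(policy_length=1)

            def qpi(C_):
                G = [expected_free_energy(A, B, C_, D, p, settings).G for p in pols]
                return policy_posterior(np.array(G), E, 16.0)

            target_obs = 1
            best = np.argmax(
                [
                    expected_free_energy(A, B, C, D, p, settings).predicted_obs[0][0][0]
                    for p in pols
                ]
            )
            C_stronger = [C[0].copy()]
            C_stronger[0][target_obs - 1] += 1.0
            assert qpi(C_stronger)[best] >= qpi(C)[best] - 1e-12


class TestActionSelection:
    def test_single_policy_marginal(self):
        pols = construct_policies([3], 1)
        q_pi = np.zeros(3)
        q_pi[1] = 1.0
        marg = marginal_action_probabilities(q_pi, pols, [3])
        assert marg[0].tolist() == [0, 1, 0]

    def test_uniform_over_tmaze_policies(self):
        pols = construct_policies([4, 1], 2)
        marg = marginal_action_probabilities(np.full(16, 1 / 16), pols, [4, 1])
        assert np.allclose(marg[0], 0.25)
        assert np.allclose(marg[1], 1.0)

    def test_two_policies_sharing_first_action(self):
        pols = construct_policies([2], 2)  # (1,1),(1,2),(2,1),(2,2)
        q_pi = np.array([0.5, 0.5, 0.0, 0.0])
        marg = marginal_action_probabilities(q_pi, pols, [2])
        assert np.allclose(marg[0], [1.0, 0.0])

    def test_marginals_sum_to_one_random(self, rng):
        pols = construct_policies([3, 2], 2)
        q_pi = rng.dirichlet(np.ones(len(pols)))
        for p in marginal_action_probabilities(q_pi, pols, [3, 2]):
            assert p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_probs_any_alpha(self):
        d = action_distribution([np.array([0.5, 0.5])], alpha=7.3)[0]
        assert np.allclose(d, 0.5)

    def test_large_alpha_argmax(self, rng):
        draws = [
            sample_action([np.array([0.6, 0.4])], 1e6, rng)[0] for _ in range(10_000)
        ]
        assert all(a == 1 for a in draws)

    def test_alpha_one_identity_distribution(self, rng):
        p = np.array([0.2, 0.5, 0.3])
        draws = np.array([sample_action([p], 1.0, rng)[0] for _ in range(10_000)])
        counts = np.bincount(draws, minlength=4)[1:]
        assert chisquare(counts, 10_000 * p).pvalue > 0.01
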