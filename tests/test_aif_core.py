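import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nested_aif.aif_core import (
    AgentState,
    GenerativeModel,
    ImpossibleObservationError,
    action_distribution,
    action_marginal,
    action_probabilities,
    agent_step,
    default_mab_model,
    enumerate_policies,
    evaluate_policies,
    expected_free_energy,
    free_energy,
    infer_states,
    policy_posterior,
    predict_under_policy,
)
from .conftest import random_model

simplex = (
    st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6)
    .map(lambda xs: np.array(xs) / np.sum(xs))
)


# ---------------------------------------------------------------------------
# enumerate_policies
# ---------------------------------------------------------------------------

def test_enumerate_policies_3x2():
    policies = enumerate_policies(3, 2)
    assert len(policies) == 9
    assert policies[0] == (0, 0)  # first action of each arm, 0-based
    assert policies[-1] == (2, 2)
    assert policies == sorted(policies)  # lexicographic


def test_enumerate_policies_2x1():
    assert enumerate_policies(2, 1) == [(0,), (1,)]


def test_enumerate_policies_single_action():
    assert enumerate_policies(1, 3) == [(0, 0, 0)]


# ---------------------------------------------------------------------------
# infer_states
# ---------------------------------------------------------------------------

def test_infer_uninformative_likelihood_keeps_prior_uniform():
    A = np.array([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]])
    B = np.zeros((3, 3, 1))
    B[0, :, 0] = 1.0
    m = GenerativeModel(
        A=A, B=B, C=np.array([0.5, 0.5]), D=np.full(3, 1 / 3),
        E=np.array([1.0]), policy_len=1,
    )
    res = infer_states(m, 0, np.full(3, 1 / 3))
    np.testing.assert_allclose(res.posterior, np.full(3, 1 / 3), atol=1e-12)


def test_infer_hand_bayes_oracle(model):
    # normalize (0.8, 0.2, 0.2) / 3 by hand
    res = infer_states(model, 0, np.full(3, 1 / 3))
    np.testing.assert_allclose(res.posterior, [2 / 3, 1 / 6, 1 / 6], atol=1e-12)
    assert res.surprise == pytest.approx(-np.log(0.4), abs=1e-12)
    assert res.free_energy == pytest.approx(res.surprise, abs=1e-10)


def test_infer_delta_prior_preserved(model):
    res = infer_states(model, 0, np.array([0.0, 1.0, 0.0]))
    np.testing.assert_allclose(res.posterior, [0, 1, 0], atol=1e-12)


def test_infer_impossible_observation_raises():
    A = np.array([[1.0, 0.0], [0.0, 1.0]])
    B = np.zeros((2, 2, 1))
    B[0, :, 0] = 1.0
    m = GenerativeModel(
        A=A, B=B, C=np.array([0.5, 0.5]), D=np.array([0.5, 0.5]),
        E=np.array([1.0]), policy_len=1,
    )
    with pytest.raises(ImpossibleObservationError, match="observation 1"):
        infer_states(m, 1, np.array([1.0, 0.0]))


def test_exact_bayes_oracle_200_random_models():
    rng = np.random.default_rng(7)
    for _ in range(200):
        m = random_model(rng)
        prior = rng.dirichlet(np.ones(m.n_states))
        o = int(rng.integers(m.n_observations))
        joint = m.A[o] * prior
        if joint.sum() <= 0:
            continue
        expected = joint / joint.sum()  # brute-force joint normalization
        res = infer_states(m, o, prior)
        np.testing.assert_allclose(res.posterior, expected, atol=1e-10)
        assert res.free_energy == pytest.approx(res.surprise, abs=1e-10)


def test_free_energy_minimised_at_posterior(model, rng):
    prior = np.full(3, 1 / 3)
    res = infer_states(model, 0, prior)
    f_star = free_energy(res.posterior, model, 0, prior)
    for _ in range(100):
        q = rng.dirichlet(np.ones(3))
        if np.allclose(q, res.posterior, atol=1e-8):
            continue
        assert free_energy(q, model, 0, prior) > f_star


# ---------------------------------------------------------------------------
# predict_under_policy
# ---------------------------------------------------------------------------

def test_predict_deterministic_b_delta_belief(model):
    states, obs = predict_under_policy(model, np.array([1.0, 0, 0]), (1, 2))
    np.testing.assert_allclose(states[0], [0, 1, 0], atol=1e-12)
    np.testing.assert_allclose(states[1], [0, 0, 1], atol=1e-12)
    np.testing.assert_allclose(obs.sum(axis=1), 1.0, atol=1e-12)


def test_predict_identity_b_keeps_belief():
    A = np.array([[0.7, 0.3], [0.3, 0.7]])
    B = np.dstack([np.eye(2), np.eye(2)])
    m = GenerativeModel(
        A=A, B=B, C=np.array([0.5, 0.5]), D=np.array([0.5, 0.5]),
        E=np.full(4, 0.25), policy_len=2,
    )
    belief = np.array([0.4, 0.6])
    states, _ = predict_under_policy(m, belief, (0, 1))
    for row in states:
        np.testing.assert_allclose(row, belief, atol=1e-12)


def test_predict_mapping_state(model):
    states, _ = predict_under_policy(model, np.array([1.0, 0, 0]), (1,))
    np.testing.assert_allclose(states[0], [0, 1, 0], atol=1e-12)


# ---------------------------------------------------------------------------
# expected_free_energy
# ---------------------------------------------------------------------------

def test_zero_info_gain_with_deterministic_b(model):
    for pi in model.policies:
        ev = expected_free_energy(model, model.D, pi)
        assert ev.info_gain == pytest.approx(0.0, abs=1e-12)
        assert ev.G == pytest.approx(-(ev.info_gain + ev.pragmatic_value), abs=1e-10)


def test_uniform_c_makes_policies_equivalent():
    m = default_mab_model(preference=0.5)
    G = evaluate_policies(m, m.D)
    np.testing.assert_allclose(G, G[0], atol=1e-12)
    post = policy_posterior(G, m.gamma, m.E)
    np.testing.assert_allclose(post, m.E, atol=1e-12)


def test_pragmatic_value_direct_sum():
    # single-step policy, predicted o = (0.8, 0.2) under C = (0.8, 0.2)
    m = default_mab_model(preference=0.8, policy_len=1)
    ev = expected_free_energy(m, np.array([1.0, 0, 0]), (0,))
    expected = 0.8 * np.log(0.8) + 0.2 * np.log(0.2)  # independent evaluation
    assert ev.pragmatic_value == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(-0.5004, abs=5e-5)


def test_vectorised_policy_evaluation_matches_scalar():
    rng = np.random.default_rng(3)
    for _ in range(25):
        m = random_model(rng)
        belief = rng.dirichlet(np.ones(m.n_states))
        fused = evaluate_policies(m, belief)
        per_policy = np.array(
            [expected_free_energy(m, belief, pi).G for pi in m.policies]
        )
        np.testing.assert_allclose(fused, per_policy, atol=1e-10)


def test_info_gain_nonnegative_random_models():
    rng = np.random.default_rng(11)
    for _ in range(50):
        m = random_model(rng)
        belief = rng.dirichlet(np.ones(m.n_states))
        for pi in m.policies:
            assert expected_free_energy(m, belief, pi).info_gain >= 0.0


# ---------------------------------------------------------------------------
# policy_posterior / action_marginal
# ---------------------------------------------------------------------------

def test_policy_posterior_gamma_zero_returns_prior():
    E = np.array([0.6, 0.3, 0.1])
    post = policy_posterior(np.array([5.0, -2.0, 0.4]), 0.0, E)
    np.testing.assert_allclose(post, E, atol=1e-12)


def test_policy_posterior_equal_G_returns_prior():
    E = np.array([0.2, 0.5, 0.3])
    post = policy_posterior(np.array([1.0, 1.0, 1.0]), 16.0, E)
    np.testing.assert_allclose(post, E, atol=1e-12)


def test_policy_posterior_softmax_arithmetic():
    gamma = 3.7
    G = np.array([0.0, np.log(2) / gamma])
    post = policy_posterior(G, gamma, np.array([0.5, 0.5]))
    np.testing.assert_allclose(post, [2 / 3, 1 / 3], atol=1e-12)


def test_action_marginal_symmetry():
    policies = enumerate_policies(3, 2)
    q = action_marginal(np.full(9, 1 / 9), policies, 3)
    np.testing.assert_allclose(q, np.full(3, 1 / 3), atol=1e-12)


def test_action_marginal_delta():
    policies = enumerate_policies(3, 2)
    post = np.zeros(9)
    post[policies.index((1, 0))] = 1.0
    np.testing.assert_allclose(action_marginal(post, policies, 3), [0, 1, 0])


def test_action_marginal_direct_sum():
    policies = [(0, 0), (0, 1), (1, 0)]
    q = action_marginal(np.array([0.5, 0.3, 0.2]), policies, 2)
    np.testing.assert_allclose(q, [0.8, 0.2], atol=1e-12)


# ---------------------------------------------------------------------------
# action_probabilities
# ---------------------------------------------------------------------------

def test_probability_matching_at_alpha_one():
    q = np.array([0.5, 0.25, 0.25])
    np.testing.assert_allclose(action_probabilities(q, 1.0), q, atol=1e-15)


def test_alpha_zero_uniform():
    q = np.array([0.7, 0.2, 0.1])
    np.testing.assert_allclose(action_probabilities(q, 0.0), np.full(3, 1 / 3))


def test_alpha_two_power_law():
    p = action_probabilities(np.array([0.5, 0.25, 0.25]), 2.0)
    np.testing.assert_allclose(p, [2 / 3, 1 / 6, 1 / 6], atol=1e-12)


def test_negative_alpha_raises():
    with pytest.raises(ValueError, match="alpha"):
        action_probabilities(np.array([0.5, 0.5]), -0.1)


def test_zero_probability_actions_stay_zero():
    p = action_probabilities(np.array([0.0, 0.4, 0.6]), 0.7)
    assert p[0] == 0.0
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


@given(q=simplex, alphas=st.tuples(st.floats(0, 50), st.floats(0, 50)))
@settings(max_examples=100, deadline=None)
def test_modal_probability_monotone_in_alpha(q, alphas):
    lo, hi = sorted(alphas)
    modal = int(np.argmax(q))
    p_lo = action_probabilities(q, lo)
    p_hi = action_probabilities(q, hi)
    assert p_hi[modal] >= p_lo[modal] - 1e-12
    assert p_lo.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.all(p_lo >= 0)


def test_alpha_limits():
    q = np.array([0.5, 0.3, 0.2])
    np.testing.assert_allclose(action_probabilities(q, 0.0), np.full(3, 1 / 3))
    p_inf = action_probabilities(q, 1e6)
    assert p_inf[0] > 0.999999


# ---------------------------------------------------------------------------
# agent_step
# ---------------------------------------------------------------------------

def test_agent_step_uniform_c_and_e_gives_uniform_actions(rng):
    m = default_mab_model(preference=0.5, alpha=1.0)
    state = AgentState(belief=m.D)
    _, p, _ = agent_step(m, state, None, rng)
    np.testing.assert_allclose(p, np.full(3, 1 / 3), atol=1e-12)
    # regardless of history
    _, p2, _ = agent_step(m, AgentState(belief=m.D, last_action=2), 1, rng)
    np.testing.assert_allclose(p2, np.full(3, 1 / 3), atol=1e-12)


def test_agent_step_large_alpha_matches_argmax_oracle(rng):
    m = default_mab_model(alpha=1e6)
    argmax = int(np.argmax(action_distribution(m.with_alpha(1.0), m.D)))
    state = AgentState(belief=m.D)
    draws = [agent_step(m, state, None, rng)[0] for _ in range(10_000)]
    assert np.mean(np.asarray(draws) == argmax) >= 0.999


def test_agent_step_deterministic_given_seed(model):
    out = []
    for _ in range(2):
        rng = np.random.default_rng(99)
        state = AgentState(belief=model.D)
        actions = []
        obs = None
        for _t in range(10):
            a, _, state = agent_step(model, state, obs, rng)
            actions.append(a)
            obs = int(rng.integers(2))
        out.append(actions)
    assert out[0] == out[1]


def test_model_validation_rejects_bad_matrices():
    bad_A = np.array([[0.9, 0.2, 0.2], [0.2, 0.8, 0.8]])  # col 0 sums to 1.1
    B = np.zeros((3, 3, 3))
    for u in range(3):
        B[u, :, u] = 1.0
    with pytest.raises(ValueError, match="A"):
        GenerativeModel(
            A=bad_A, B=B, C=np.array([0.6, 0.4]), D=np.full(3, 1 / 3),
            E=np.full(9, 1 / 9), policy_len=2,
        )
    with pytest.raises(ValueError, match="alpha"):
        default_mab_model(alpha=-0.5)
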