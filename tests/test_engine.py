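"""Unit and property tests for the active inference engine.

The central check is agreement between the engine's tensor-contraction
state inference and an independent brute-force Bayes oracle that loops
over every joint state sequence in pure Python.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moodsim import build_agent_model
from moodsim.engine import (
    AgentModel,
    expected_free_energy,
    infer_policies,
    infer_states,
    select_action,
    softmax,
    update_dirichlet,
)
from moodsim.environment import SocialEnvironment, generate_outcome
from moodsim.errors import (
    BeliefNormalizationError,
    InvalidObservationError,
    InvalidPolicyError,
    NumericalError,
)
from moodsim.task import (
    CONTEXT_GO,
    LOC_CAROLINE,
    LOC_HOME,
    LOC_MEDIA,
    OUT_CUE_GO,
    OUT_HIGH,
    OUT_START,
)


def enumeration_oracle(model, observations, policy):
    """Exact posterior by explicit summation over all state sequences."""
    n_ctx, n_loc = model.n_states
    states = [(c, l) for c in range(n_ctx) for l in range(n_loc)]
    A, Bc, Bl = model.A, model.B_context, model.B_location
    D = {s: model.D_context[s[0]] * model.D_location[s[1]] for s in states}
    obs = list(observations)

    def lik(t, s):
        if t < len(obs):
            return A[obs[t], s[0], s[1]]
        return 1.0

    evidence = 0.0
    marg = [dict.fromkeys(states, 0.0) for _ in range(model.T)]
    for s1 in states:
        for s2 in states:
            p12 = (Bc[s2[0], s1[0]] * Bl[s2[1], s1[1], policy[0]])
            for s3 in states:
                p23 = (Bc[s3[0], s2[0]] * Bl[s3[1], s2[1], policy[1]])
                w = D[s1] * lik(0, s1) * p12 * lik(1, s2) * p23 * lik(2, s3)
                evidence += w
                marg[0][s1] += w
                marg[1][s2] += w
                marg[2][s3] += w
    posts = np.zeros((model.T, n_ctx, n_loc))
    for t in range(model.T):
        for (c, l), w in marg[t].items():
            posts[t, c, l] = w / evidence
    return posts, -math.log(evidence)


def _observed_prefixes(model, policy, seed):
    """Simulate the true environment under a policy to get feasible outcomes."""
    env = SocialEnvironment(rng_seed=seed)
    env.begin_trial(1)
    outcomes = [generate_outcome(env)]
    for action in policy:
        env.step(action)
        outcomes.append(generate_outcome(env))
    return [outcomes[:k] for k in (1, 2, 3)]


def test_infer_states_matches_enumeration_oracle_on_full_task():
    """Tensor inference equals the pure-Python Bayes oracle on the 8-state
    task model for every policy and every observation prefix."""
    model = build_agent_model()
    for p, policy in enumerate(model.policies):
        for prefix in _observed_prefixes(model, policy, seed=p):
            posts, F = infer_states(model, prefix, policy)
            oposts, oF = enumeration_oracle(model, prefix, policy)
            np.testing.assert_allclose(posts, oposts, atol=1e-6)
            assert abs(F - oF) < 1e-6


def _toy_model(rng):
    """Random 2-outcome, (1 context x 2 location) model with 2 actions."""
    a = rng.uniform(0.2, 3.0, size=(2, 1, 2))
    b = rng.uniform(0.2, 3.0, size=(2, 2, 2))
    return AgentModel(
        a=a, b=b, B_context=np.eye(1), C=rng.normal(size=2),
        D_context=np.array([1.0]), D_location=np.array([0.3, 0.7]),
        policies=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
        gamma=4.0, eta=1.0,
    )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_infer_states_matches_bayes_on_random_toy(seed):
    rng = np.random.default_rng(seed)
    model = _toy_model(rng)
    for policy in model.policies:
        for obs in ([0], [0, 1], [1, 0, 1]):
            posts, F = infer_states(model, obs, policy)
            oposts, oF = enumeration_oracle(model, obs, policy)
            np.testing.assert_allclose(posts, oposts, atol=1e-8)
            assert abs(F - oF) < 1e-8


def test_uniform_likelihood_posterior_is_propagated_prior():
    """With an uninformative likelihood the posterior is the prior pushed
    through the transition model."""
    model = build_agent_model()
    model.a = np.ones_like(model.a)
    policy = model.policies[8]  # media then Caroline
    posts, _ = infer_states(model, [OUT_START], policy)
    prior = np.einsum("c,l->cl", model.D_context, model.D_location)
    np.testing.assert_allclose(posts[0], prior, atol=1e-10)
    step1 = np.einsum("lm,cm->cl", model.B_location[:, :, policy[0]], prior)
    np.testing.assert_allclose(posts[1], step1, atol=1e-10)


def test_deterministic_cue_identifies_context():
    """Observing the go-cue on social media makes the context posterior a
    delta on the go context."""
    model = build_agent_model()
    policy = model.policies[8]
    posts, _ = infer_states(model, [OUT_START, OUT_CUE_GO], policy)
    context_marginal = posts[1].sum(axis=1)
    assert context_marginal[CONTEXT_GO] > 1 - 1e-6


def test_infer_states_error_contracts(model):
    with pytest.raises(InvalidObservationError):
        infer_states(model, [99], model.policies[0])
    with pytest.raises(InvalidObservationError):
        infer_states(model, [], model.policies[0])
    with pytest.raises(InvalidPolicyError):
        infer_states(model, [OUT_START], [2, 0])  # not in the policy table


# -- expected free energy --------------------------------------------------

def efe_oracle(model, policy, beliefs, timestep=1):
    """Direct summation over all outcome/state combinations."""
    A = model.A
    pC = softmax(model.C)
    q = np.array(beliefs, dtype=float)
    risk = amb = nov = 0.0
    n_ctx, n_loc = model.n_states
    col_sums = model.a.sum(axis=0)
    for tau in range(timestep + 1, model.T + 1):
        u = policy[tau - 2]
        q_next = np.zeros_like(q)
        for c2 in range(n_ctx):
            for l2 in range(n_loc):
                for c in range(n_ctx):
                    for l in range(n_loc):
                        q_next[c2, l2] += (model.B_context[c2, c]
                                           * model.B_location[l2, l, u]
                                           * q[c, l])
        q = q_next
        qo = np.array([sum(A[o, c, l] * q[c, l]
                           for c in range(n_ctx) for l in range(n_loc))
                       for o in range(model.n_outcomes)])
        for o in range(model.n_outcomes):
            if qo[o] > 0:
                risk += qo[o] * (math.log(qo[o]) - math.log(pC[o]))
        for c in range(n_ctx):
            for l in range(n_loc):
                for o in range(model.n_outcomes):
                    if A[o, c, l] > 0:
                        amb -= q[c, l] * A[o, c, l] * math.log(A[o, c, l])
                    if model.a[o, c, l] > 1e-3:
                        w = 0.5 * (1 / model.a[o, c, l] - 1 / col_sums[c, l])
                        nov += q[c, l] * A[o, c, l] * w
    return risk, amb, nov


@pytest.mark.parametrize("seed", [3, 4])
def test_efe_components_match_direct_summation(seed):
    rng = np.random.default_rng(seed)
    model = _toy_model(rng)
    beliefs = np.array([[0.4, 0.6]])
    for policy in model.policies:
        efe = expected_free_energy(model, policy, beliefs)
        risk, amb, nov = efe_oracle(model, policy, beliefs)
        assert abs(efe.risk - risk) < 1e-8
        assert abs(efe.ambiguity - amb) < 1e-8
        assert abs(efe.novelty - nov) < 1e-8
        assert abs(efe.G - (risk + amb - nov)) < 1e-12


def test_efe_full_task_components_match_direct_summation(model):
    beliefs = np.einsum("c,l->cl", model.D_context, model.D_location)
    for policy in model.policies[[0, 5, 8]]:
        efe = expected_free_energy(model, policy, beliefs)
        risk, amb, nov = efe_oracle(model, policy, beliefs)
        assert abs(efe.G - (risk + amb - nov)) < 1e-8


def test_perfect_knowledge_preference_matched_limit():
    """Deterministic likelihood with huge counts and predictions equal to
    the preference distribution gives G ~ 0."""
    big = 1e8
    a = np.full((2, 1, 2), 1e-12)
    a[0, 0, 0] = big
    a[1, 0, 1] = big
    model = AgentModel(
        a=a, b=np.full((2, 2, 2), 1.0), B_context=np.eye(1),
        C=np.zeros(2), D_context=np.array([1.0]),
        D_location=np.array([0.5, 0.5]),
        policies=np.array([[0, 0], [1, 1]]),
    )
    # staying action keeps the 50/50 location mix; q(o) = (.5,.5) = softmax(C)
    model.b[:, :, 0] = np.eye(2) * 1.0 + 1e-12
    beliefs = np.array([[0.5, 0.5]])
    efe = expected_free_energy(model, [0, 0], beliefs)
    assert abs(efe.risk) < 1e-6
    assert abs(efe.ambiguity) < 1e-6
    assert 0 <= efe.novelty < 1e-6
    assert abs(efe.G) < 1e-5


def test_novelty_decreases_under_count_inflation(model):
    """Doubling all concentration counts strictly decreases the novelty
    component (the information that remains to be gained shrinks)."""
    beliefs = np.einsum("c,l->cl", model.D_context, model.D_location)
    for policy in model.policies[[2, 5, 8]]:
        base = expected_free_energy(model, policy, beliefs).novelty
        doubled = build_agent_model()
        doubled.a = model.a * 2
        inflated = expected_free_energy(doubled, policy, beliefs).novelty
        assert base > 0
        assert inflated < base


def test_efe_rejects_unnormalized_beliefs(model):
    with pytest.raises(BeliefNormalizationError):
        expected_free_energy(model, model.policies[0], np.full((2, 4), 0.2))


# -- policy posterior and action selection ---------------------------------

def test_policy_posterior_symmetry_and_zero_precision(model):
    n = len(model.policies)
    uniform = infer_policies(model, np.zeros(n), np.ones(n))
    np.testing.assert_allclose(uniform, np.full(n, 1 / n), atol=1e-12)
    model.gamma = 0.0
    posterior = infer_policies(model, np.zeros(n), np.arange(n, dtype=float))
    np.testing.assert_allclose(posterior, np.full(n, 1 / n), atol=1e-12)


def test_policy_posterior_matches_hand_computed_softmax(model):
    model.gamma = 1.0
    G = np.array([1.0, 2.0, 3.0])
    F = np.zeros(3)
    posterior = infer_policies(model, F, G)
    expected = np.array([math.exp(-g) for g in G])
    expected /= expected.sum()
    np.testing.assert_allclose(posterior, expected, atol=1e-12)


def test_policy_posterior_rejects_non_finite(model):
    F = np.zeros(10)
    G = np.zeros(10)
    G[7] = np.nan
    with pytest.raises(NumericalError, match="7"):
        infer_policies(model, F, G)


def test_select_action_marginalizes_and_breaks_ties(model):
    policies = model.policies
    delta = np.zeros(10)
    delta[8] = 1.0  # policy 9: media then Caroline
    assert select_action(delta, policies, 1) == LOC_MEDIA
    assert select_action(delta, policies, 2) == LOC_CAROLINE

    split = np.zeros(10)
    split[7], split[8] = 0.4, 0.35  # policies 8 and 9 both start at media
    split[5] = 0.25
    assert select_action(split, policies, 1) == LOC_MEDIA

    uniform = np.full(10, 0.1)
    # home-first and media-first families tie at 0.4; lowest action wins
    assert select_action(uniform, policies, 1) == LOC_HOME


# -- Dirichlet learning ----------------------------------------------------

def test_update_dirichlet_zero_learning_rate(model):
    model.eta = 0.0
    before = model.a.copy()
    posts = np.tile(np.einsum("c,l->cl", model.D_context, model.D_location),
                    (3, 1, 1))
    update_dirichlet(model, [OUT_START, OUT_CUE_GO, OUT_HIGH], posts,
                     actions=[3, 2])
    np.testing.assert_array_equal(model.a, before)


def test_update_dirichlet_delta_posterior_increments_one_cell(model):
    model.eta = 1.0
    delta = np.zeros((3, 2, 4))
    delta[:, CONTEXT_GO, LOC_CAROLINE] = 1.0
    before = model.a.copy()
    update_dirichlet(model, [OUT_HIGH, OUT_HIGH, OUT_HIGH], delta)
    diff = model.a - before
    assert diff[OUT_HIGH, CONTEXT_GO, LOC_CAROLINE] == pytest.approx(3.0)
    diff[OUT_HIGH, CONTEXT_GO, LOC_CAROLINE] = 0.0
    assert np.all(diff == 0)


def test_dirichlet_mean_converges_to_observed_frequency(model):
    """After 20 high-reward observations at (go, Caroline) the normalized
    likelihood approaches the closed form (a0 + n) / (sum(a0) + n)."""
    model.eta = 1.0
    delta = np.zeros((3, 2, 4))
    delta[2, CONTEXT_GO, LOC_CAROLINE] = 1.0  # only the final timestep there
    a0 = model.a[:, CONTEXT_GO, LOC_CAROLINE].copy()
    for _ in range(20):
        update_dirichlet(model, [OUT_START, OUT_START, OUT_HIGH], delta)
    got = model.A[OUT_HIGH, CONTEXT_GO, LOC_CAROLINE]
    want = (a0[OUT_HIGH] + 20) / (a0.sum() + 20)
    assert got == pytest.approx(want, abs=1e-10)
    assert got > 0.9  # approaches certainty, well above the flat initial 1/3


def test_update_dirichlet_learns_transitions_when_enabled(model):
    posts = np.zeros((3, 2, 4))
    posts[0, :, LOC_HOME] = 0.5
    posts[1, :, LOC_MEDIA] = 0.5
    posts[2, :, LOC_CAROLINE] = 0.5
    before_b = model.b.copy()
    update_dirichlet(model, [OUT_START, OUT_CUE_GO, OUT_HIGH], posts,
                     actions=[LOC_MEDIA, LOC_CAROLINE])
    assert (model.b[LOC_MEDIA, LOC_HOME, LOC_MEDIA]
            == pytest.approx(before_b[LOC_MEDIA, LOC_HOME, LOC_MEDIA]
                             + model.eta))
    model2 = build_agent_model()
    model2.learn_b = False
    b_before = model2.b.copy()
    update_dirichlet(model2, [OUT_START, OUT_CUE_GO, OUT_HIGH], posts,
                     actions=[LOC_MEDIA, LOC_CAROLINE])
    np.testing.assert_array_equal(model2.b, b_before)


# -- normalization properties ----------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_all_distributions_normalize(seed):
    """Every distribution any engine operation produces sums to one."""
    rng = np.random.default_rng(seed)
    model = _toy_model(rng)
    obs = [int(rng.integers(2)) for _ in range(int(rng.integers(1, 4)))]
    F, G = [], []
    for policy in model.policies:
        posts, f = infer_states(model, obs, policy)
        assert np.allclose(posts.sum(axis=(1, 2)), 1.0, atol=1e-10)
        F.append(f)
        G.append(expected_free_energy(model, policy, posts[0]).G)
    posterior = infer_policies(model, np.array(F), np.array(G))
    assert posterior.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.allclose(model.A.sum(axis=0), 1.0, atol=1e-10)
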