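"""Generic discrete-state active inference for factorized hidden states.

The agent entertains a generative model with two hidden-state factors
(context x location), a categorical outcome modality, and a finite set of
policies (fixed action sequences) over a short horizon ``T``.  Because the
joint state space is tiny (8 states, T = 3), state inference is *exact*:
posteriors are obtained by enumerating the joint distribution over complete
state sequences under each policy, i.e. an ideal Bayesian observer.  An
iterative variational scheme is unnecessary at this scale and would only
approximate what enumeration computes exactly.

Planning uses the expected free energy G of each policy, decomposed into

* **risk** -- KL divergence of the predicted outcome distribution from the
  preference distribution ``softmax(C)``;
* **ambiguity** -- expected conditional entropy of the outcome likelihood;
* **novelty** -- expected information gain about the Dirichlet concentration
  counts ``a`` of the likelihood, using the standard approximation
  ``W = (1/a - 1/colsum(a)) / 2`` and ``novelty = E_q(s) E_A(o|s)[W(o, s)]``.

Policies are scored by ``softmax(-gamma * G - F)`` where F is the variational
free energy (here: exact negative log evidence) of the observed prefix.
Learning accumulates Dirichlet counts from co-occurrences of observed
outcomes and smoothed state posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BeliefNormalizationError,
    InvalidObservationError,
    InvalidPolicyError,
    NumericalError,
)

__all__ = [
    "AgentModel",
    "BeliefState",
    "EFEComponents",
    "infer_states",
    "expected_free_energy",
    "infer_policies",
    "select_action",
    "update_dirichlet",
]

#: Concentration counts at or below this value are treated as structural
#: zeros: they keep ``a > 0`` strictly true but are excluded from the
#: parameter-novelty term (observing a structurally impossible outcome is
#: not a learning opportunity the agent anticipates).
STRUCTURAL_ZERO = 1e-3

_NORM_TOL = 1e-6


def _normalize_columns(x: np.ndarray) -> np.ndarray:
    """Normalize over the leading (outcome / next-state) axis."""
    return x / x.sum(axis=0, keepdims=True)


def softmax(x: np.ndarray) -> np.ndarray:
    z = np.asarray(x, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass
class AgentModel:
    """The agent's generative model of the social task.

    Shapes (with 6 outcomes, 2 contexts, 4 locations, 4 location actions):

    a : (6, 2, 4)   Dirichlet counts over the outcome likelihood
    b : (4, 4, 4)   Dirichlet counts over location transitions, per action
    B_context : (2, 2)  fixed context transition (identity within a trial)
    C : (6,)        log-preference per outcome (unitless utility)
    D_context, D_location : priors over initial states per factor
    policies : (n_policies, T - 1) integer action sequences
    """

    a: np.ndarray
    b: np.ndarray
    B_context: np.ndarray
    C: np.ndarray
    D_context: np.ndarray
    D_location: np.ndarray
    policies: np.ndarray
    gamma: float = 16.0
    eta: float = 1.0
    T: int = 3
    learn_b: bool = True
    a0: np.ndarray = field(default=None, repr=False)
    b0: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.policies = np.asarray(self.policies, dtype=int)
        if self.a0 is None:
            self.a0 = self.a.copy()
        if self.b0 is None:
            self.b0 = self.b.copy()
        self.validate()

    # -- normalized beliefs ------------------------------------------------
    @property
    def A(self) -> np.ndarray:
        """Normalized likelihood P(outcome | context, location)."""
        return _normalize_columns(self.a)

    @property
    def B_location(self) -> np.ndarray:
        """Normalized location transitions P(l' | l, action)."""
        return _normalize_columns(self.b)

    @property
    def n_outcomes(self) -> int:
        return self.a.shape[0]

    @property
    def n_states(self) -> tuple[int, int]:
        return self.a.shape[1], self.a.shape[2]

    def validate(self) -> None:
        if not (self.a > 0).all():
            raise ValueError("all entries of a must be strictly positive")
        if not (self.b > 0).all():
            raise ValueError("all entries of b must be strictly positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.policies.shape[1] != self.T - 1:
            raise ValueError("policies must have length T - 1")
        for name, arr in [("A", self.A), ("B_context", self.B_context),
                          ("B_location", self.B_location)]:
            if not np.allclose(arr.sum(axis=0), 1.0, atol=1e-10):
                raise ValueError(f"columns of {name} must sum to 1")
        for name, arr in [("D_context", self.D_context),
                          ("D_location", self.D_location)]:
            if not np.isclose(np.sum(arr), 1.0, atol=1e-10):
                raise ValueError(f"{name} must sum to 1")

    def policy_index(self, policy) -> int:
        policy = np.asarray(policy, dtype=int)
        matches = np.flatnonzero((self.policies == policy).all(axis=1))
        if matches.size == 0:
            raise InvalidPolicyError(f"policy {policy.tolist()} is not in the policy set")
        return int(matches[0])


@dataclass
class EFEComponents:
    """Expected free energy of one policy, with its three components.

    ``G = risk + ambiguity - novelty`` (all in nats, summed over the
    remaining future timesteps of the trial).
    """

    risk: float
    ambiguity: float
    novelty: float

    @property
    def G(self) -> float:
        return self.risk + self.ambiguity - self.novelty


@dataclass
class BeliefState:
    """Per-trial beliefs: state posteriors, F, G and the policy posterior."""

    state_posterior: np.ndarray  # (n_policies, T, n_ctx, n_loc)
    F: np.ndarray                # (n_policies,)
    G: np.ndarray                # (n_policies,)
    policy_posterior: np.ndarray  # (n_policies,)


def _joint_transition(model: AgentModel, action: int) -> np.ndarray:
    """P(c', l' | c, l, action) as a (2, 4, 2, 4) tensor."""
    return np.einsum("ca,lm->clam", model.B_context, model.B_location[:, :, action])


def infer_states(model: AgentModel, observations, policy):
    """Exact state inference under one policy given an observation prefix.

    Parameters
    ----------
    observations : sequence of outcome indices observed so far (length 1..T).
    policy : action sequence of length T - 1; must be in ``model.policies``.

    Returns
    -------
    posteriors : (T, n_ctx, n_loc) array; observed timesteps are smoothed on
        the data, future timesteps are predictions through B under the policy.
    F : float, the negative log evidence of the observed prefix (nats).
    """
    model.policy_index(policy)  # membership check
    policy = np.asarray(policy, dtype=int)
    obs = list(observations)
    if not 1 <= len(obs) <= model.T:
        raise InvalidObservationError(
            f"need 1..{model.T} observations, got {len(obs)}")
    for o in obs:
        if not 0 <= int(o) < model.n_outcomes:
            raise InvalidObservationError(f"unknown outcome index {o}")

    A = model.A
    n_ctx, n_loc = model.n_states
    likelihoods = []
    for t in range(model.T):
        if t < len(obs):
            likelihoods.append(A[int(obs[t])])
        else:
            likelihoods.append(np.ones((n_ctx, n_loc)))

    D = np.einsum("c,l->cl", model.D_context, model.D_location)
    B1 = _joint_transition(model, policy[0])
    B2 = _joint_transition(model, policy[1])

    # Joint weight over complete state sequences (s1, s2, s3); exact since
    # the state space is 8 and T = 3.
    w = np.einsum(
        "cl,cl,dmcl,dm,endm,en->cldmen",
        D, likelihoods[0], B1, likelihoods[1], B2, likelihoods[2],
    )
    evidence = w.sum()
    if evidence <= 0:
        raise NumericalError("observation prefix has zero probability under policy")
    posteriors = np.stack([
        w.sum(axis=(2, 3, 4, 5)),
        w.sum(axis=(0, 1, 4, 5)),
        w.sum(axis=(0, 1, 2, 3)),
    ]) / evidence
    return posteriors, -float(np.log(evidence))


def expected_free_energy(model: AgentModel, policy, current_beliefs,
                         timestep: int = 1) -> EFEComponents:
    """Expected free energy of ``policy`` from ``timestep`` to the horizon.

    ``current_beliefs`` is the joint state posterior at ``timestep``
    (1-based).  Risk, ambiguity and novelty are accumulated over the
    remaining future timesteps and returned separately for testability.
    """
    policy = np.asarray(policy, dtype=int)
    q = np.asarray(current_beliefs, dtype=float)
    if not np.isclose(q.sum(), 1.0, atol=_NORM_TOL):
        raise BeliefNormalizationError(
            f"current beliefs sum to {q.sum():.6g}, expected 1")

    A = model.A
    ln_pC = model.C - np.log(np.sum(np.exp(model.C)))  # log softmax(C)
    with np.errstate(divide="ignore", invalid="ignore"):
        lnA = np.where(A > 0, np.log(np.maximum(A, 1e-300)), 0.0)
    H_cols = -(A * lnA).sum(axis=0)  # (n_ctx, n_loc) conditional entropies

    learnable = model.a > STRUCTURAL_ZERO
    col_sums = model.a.sum(axis=0, keepdims=True)
    W = np.where(learnable, 0.5 * (1.0 / model.a - 1.0 / col_sums), 0.0)
    novelty_cols = (A * W).sum(axis=0)  # expected info gain per state

    risk = ambiguity = novelty = 0.0
    for tau in range(timestep + 1, model.T + 1):
        action = policy[tau - 2]
        q = np.einsum("clam,am->cl", _joint_transition(model, action), q)
        qo = np.einsum("ocl,cl->o", A, q)
        nz = qo > 1e-300
        risk += float(np.sum(qo[nz] * (np.log(qo[nz]) - ln_pC[nz])))
        ambiguity += float(np.sum(q * H_cols))
        novelty += float(np.sum(q * novelty_cols))
    return EFEComponents(risk=risk, ambiguity=ambiguity, novelty=novelty)


def infer_policies(model: AgentModel, F: np.ndarray, G: np.ndarray,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Posterior over policies: ``softmax(-gamma * G - F)``.

    ``mask`` restricts the support to policies consistent with actions
    already taken (within-trial pruning); masked-out entries get zero mass.
    """
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if mask is None:
        mask = np.ones(F.shape, dtype=bool)
    active = np.flatnonzero(mask)
    for name, arr in (("F", F), ("G", G)):
        bad = np.flatnonzero(~np.isfinite(arr[mask]))
        if bad.size:
            raise NumericalError(
                f"non-finite {name} for policy index {int(active[bad[0]])}")
    logits = -model.gamma * G[mask] - F[mask]
    posterior = np.zeros_like(F)
    posterior[mask] = softmax(logits)
    return posterior


def select_action(policy_posterior: np.ndarray, policies: np.ndarray,
                  timestep: int) -> int:
    """Most likely action at ``timestep`` (1-based) under the policy posterior.

    The posterior mass of policies prescribing each action is summed and the
    argmax returned; exact ties break toward the lowest action index.
    """
    if timestep not in (1, 2):
        raise ValueError("timestep must be 1 or 2")
    prescribed = np.asarray(policies, dtype=int)[:, timestep - 1]
    n_actions = int(prescribed.max()) + 1
    mass = np.zeros(n_actions)
    np.add.at(mass, prescribed, np.asarray(policy_posterior, dtype=float))
    # np.argmax already returns the first (lowest-index) maximum
    return int(np.argmax(mass))


def update_dirichlet(model: AgentModel, outcomes, state_posteriors,
                     actions=None) -> AgentModel:
    """Accumulate Dirichlet counts from one completed trial.

    ``a[o_t] += eta * q(s_t)`` for each observed outcome, and -- when
    transition learning is enabled and the executed ``actions`` are given --
    ``b[:, :, u_t] += eta * outer(q_loc(s_{t+1}), q_loc(s_t))``.  The
    normalized likelihood ``A`` is a property of ``a`` and therefore stays
    the column normalization of the updated counts.
    """
    posts = np.asarray(state_posteriors, dtype=float)
    for t, o in enumerate(outcomes):
        model.a[int(o)] += model.eta * posts[t]
    if actions is not None and model.learn_b:
        loc = posts.sum(axis=1)  # location-factor marginals, (T, n_loc)
        for t, u in enumerate(actions):
            model.b[:, :, int(u)] += model.eta * np.outer(loc[t + 1], loc[t])
    return model
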