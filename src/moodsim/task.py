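"""Generative model of the social decision-making task.

A 64-day, two-arm social bandit with an epistemic cue.  Hidden states
factorize into a *context* (whether Caroline, the risky but rewarding
partner, is available -- "go" -- or busy -- "no-go") and a *location*
(home, Rudolph, Caroline, social media).  The context is outside the
agent's control and alternates across days; locations change under four
actions (one per destination).  Rudolph and Caroline are absorbing: once
the agent reaches a partner, the encounter lasts the rest of the day.

Six outcomes: the neutral "start" observation at home, three levels of
social reward (a low / negative outcome from a failed encounter, the
moderate reward of safe Rudolph, the high reward of a successful visit
to Caroline), and the context cue ("go" / "no-go") observed on social
media.  A trial has T = 3 timesteps, hence two moves, and exactly ten
distinguishable two-move policies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import AgentModel
from .errors import ConfigError

# -- state, outcome and action codes --------------------------------------
CONTEXT_GO, CONTEXT_NOGO = 0, 1
N_CONTEXTS = 2
CONTEXT_NAMES = ("go", "no-go")

LOC_HOME, LOC_RUDOLPH, LOC_CAROLINE, LOC_MEDIA = 0, 1, 2, 3
N_LOCATIONS = 4
LOCATION_NAMES = ("home", "Rudolph", "Caroline", "social-media")

OUT_START, OUT_LOW, OUT_MODERATE, OUT_HIGH, OUT_CUE_GO, OUT_CUE_NOGO = range(6)
N_OUTCOMES = 6
OUTCOME_NAMES = ("start", "low-reward", "moderate-reward", "high-reward",
                 "cue-go", "cue-no-go")

#: Actions target a destination; moving "home" from home (or staying on
#: social media via the media action) is the wait/stay move.
ACTION_NAMES = ("go-home", "go-Rudolph", "go-Caroline", "go-media")

#: 1-based indices of policies that never reach a social partner.
WITHDRAWAL_POLICIES = (1, 4, 7, 10)

T_TRIAL = 3

#: Floor keeping Dirichlet counts strictly positive in structurally
#: impossible cells without affecting inference.
COUNT_FLOOR = 1e-6


def enumerate_policies() -> np.ndarray:
    """The ordered ten-policy table as (10, 2) action indices.

    1  stay home, stay home            6  go to Caroline (absorbing)
    2  stay home, go to Rudolph        7  go to social media, go home
    3  stay home, go to Caroline       8  go to social media, go to Rudolph
    4  stay home, go to social media   9  go to social media, go to Caroline
    5  go to Rudolph (absorbing)       10 go to social media, stay on media

    The second moves of 5 and 6 are irrelevant (the partner states are
    absorbing) and are encoded as repeating the destination, i.e. "stay".
    """
    return np.array([
        [LOC_HOME, LOC_HOME],
        [LOC_HOME, LOC_RUDOLPH],
        [LOC_HOME, LOC_CAROLINE],
        [LOC_HOME, LOC_MEDIA],
        [LOC_RUDOLPH, LOC_RUDOLPH],
        [LOC_CAROLINE, LOC_CAROLINE],
        [LOC_MEDIA, LOC_HOME],
        [LOC_MEDIA, LOC_RUDOLPH],
        [LOC_MEDIA, LOC_CAROLINE],
        [LOC_MEDIA, LOC_MEDIA],
    ], dtype=int)


def location_transitions() -> np.ndarray:
    """True location dynamics P(l' | l, action) as a (4, 4, 4) array.

    Each action moves the agent to its destination from home or social
    media; Rudolph and Caroline map every action to themselves.
    """
    B = np.zeros((N_LOCATIONS, N_LOCATIONS, N_LOCATIONS))
    for action in range(N_LOCATIONS):
        for loc in range(N_LOCATIONS):
            if loc in (LOC_RUDOLPH, LOC_CAROLINE):
                B[loc, loc, action] = 1.0
            else:
                B[action, loc, action] = 1.0
    return B


def actions_to_policy(first: int, second: int) -> int:
    """Map two executed actions back to the 1-based policy table index."""
    if first == LOC_RUDOLPH:
        return 5
    if first == LOC_CAROLINE:
        return 6
    table = enumerate_policies()
    match = (table[:, 0] == first) & (table[:, 1] == second)
    return int(np.flatnonzero(match)[0]) + 1


@dataclass
class TaskSpec:
    """Task construction parameters.

    ``preference_values`` are the C entries in outcome order (start, low,
    moderate, high, cue-go, cue-no-go).  ``known_count`` initializes the
    likelihood cells the agent already trusts (home -> start and the
    context cues); ``arm_count`` initializes the learnable reward cells at
    Rudolph and Caroline (flat over low/moderate/high).  The defaults are
    calibrated so that the healthy agent reproduces the epistemic-first
    baseline signature (see docs/methods.md).
    """

    horizon_days: int = 64
    preference_values: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -1.9, 0.35, 2.0, 0.0, 0.0]))
    known_count: float = 128.0
    arm_count: float = 0.4
    transition_count_scale: float = 1.0
    gamma: float = 16.0
    eta: float = 0.28
    learn_b: bool = True

    context_levels: int = N_CONTEXTS
    location_levels: int = N_LOCATIONS
    outcome_levels: int = N_OUTCOMES

    def validate(self) -> None:
        if self.horizon_days < 1:
            raise ConfigError("horizon_days must be positive")
        if len(np.atleast_1d(self.preference_values)) != N_OUTCOMES:
            raise ConfigError("preference_values must have one entry per outcome")
        if self.known_count <= 0 or self.arm_count <= 0:
            raise ConfigError("likelihood count scales must be positive")
        if self.transition_count_scale <= 0:
            raise ConfigError("transition_count_scale must be positive")
        if (self.context_levels, self.location_levels, self.outcome_levels) != (
                N_CONTEXTS, N_LOCATIONS, N_OUTCOMES):
            raise ConfigError("the task builder is specialized to 2 contexts, "
                              "4 locations and 6 outcomes")


def initial_likelihood_counts(spec: TaskSpec) -> np.ndarray:
    """Initial Dirichlet counts ``a`` over P(outcome | context, location).

    Home and cue mappings are effectively known (large counts); the reward
    mappings at both social partners are flat and learnable within about a
    week of visits.
    """
    a = np.full((N_OUTCOMES, N_CONTEXTS, N_LOCATIONS), COUNT_FLOOR)
    a[OUT_START, :, LOC_HOME] = spec.known_count
    a[OUT_CUE_GO, CONTEXT_GO, LOC_MEDIA] = spec.known_count
    a[OUT_CUE_NOGO, CONTEXT_NOGO, LOC_MEDIA] = spec.known_count
    for loc in (LOC_RUDOLPH, LOC_CAROLINE):
        a[[OUT_LOW, OUT_MODERATE, OUT_HIGH], :, loc] = spec.arm_count
    return a


def build_agent_model(spec: TaskSpec | None = None) -> AgentModel:
    """Construct the agent's generative model for the social task."""
    spec = spec or TaskSpec()
    spec.validate()
    b = spec.transition_count_scale * location_transitions() + COUNT_FLOOR
    D_location = np.zeros(N_LOCATIONS)
    D_location[LOC_HOME] = 1.0
    return AgentModel(
        a=initial_likelihood_counts(spec),
        b=b,
        B_context=np.eye(N_CONTEXTS),
        C=np.asarray(spec.preference_values, dtype=float),
        D_context=np.array([0.5, 0.5]),
        D_location=D_location,
        policies=enumerate_policies(),
        gamma=spec.gamma,
        eta=spec.eta,
        T=T_TRIAL,
        learn_b=spec.learn_b,
    )
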