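"""The generative process: a synthetic social world.

The environment is the counterpart of the agent's generative model.  It
holds the *true* context (alternating deterministically every day), the
agent's true location within a trial, and Dirichlet concentration counts
over the outcome-generating likelihood.  When social support is active the
environment is *responsive*: every day the agent signals on social media,
counts are added that make the social partners more reliable.  This module
is also the synthetic-data generator of the study -- every observation the
agent ever receives is drawn here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .task import (
    CONTEXT_GO,
    CONTEXT_NOGO,
    LOC_CAROLINE,
    LOC_HOME,
    LOC_MEDIA,
    LOC_RUDOLPH,
    N_CONTEXTS,
    N_LOCATIONS,
    N_OUTCOMES,
    OUT_CUE_GO,
    OUT_CUE_NOGO,
    OUT_HIGH,
    OUT_LOW,
    OUT_MODERATE,
    OUT_START,
    location_transitions,
)

__all__ = [
    "SocialEnvironment",
    "pre_adversity_probs",
    "post_adversity_probs",
    "generate_outcome",
    "apply_social_support",
]


def pre_adversity_probs() -> np.ndarray:
    """Outcome probabilities P(o | context, location) before the adverse event.

    Home always yields the start observation and social media the cue that
    matches the true context.  Rudolph reliably yields a moderate reward;
    Caroline yields a high reward with probability 0.75 on a good ("go")
    day and 0.25 on a busy day, and a low (negative) outcome otherwise.
    """
    p = np.zeros((N_OUTCOMES, N_CONTEXTS, N_LOCATIONS))
    p[OUT_START, :, LOC_HOME] = 1.0
    p[OUT_CUE_GO, CONTEXT_GO, LOC_MEDIA] = 1.0
    p[OUT_CUE_NOGO, CONTEXT_NOGO, LOC_MEDIA] = 1.0
    p[OUT_MODERATE, :, LOC_RUDOLPH] = 1.0
    p[OUT_HIGH, CONTEXT_GO, LOC_CAROLINE] = 0.75
    p[OUT_LOW, CONTEXT_GO, LOC_CAROLINE] = 0.25
    p[OUT_HIGH, CONTEXT_NOGO, LOC_CAROLINE] = 0.25
    p[OUT_LOW, CONTEXT_NOGO, LOC_CAROLINE] = 0.75
    return p


def post_adversity_probs() -> np.ndarray:
    """Outcome probabilities after the adverse life event.

    The contingencies flip: Rudolph now rejects the agent with certainty
    (low outcome in both contexts), Caroline always rejects on a busy day,
    and even on a good day her odds invert to a 25% chance of a high
    reward.  Home and cue cells are unchanged.
    """
    p = pre_adversity_probs()
    p[:, :, LOC_RUDOLPH] = 0.0
    p[OUT_LOW, :, LOC_RUDOLPH] = 1.0
    p[:, :, LOC_CAROLINE] = 0.0
    p[OUT_HIGH, CONTEXT_GO, LOC_CAROLINE] = 0.25
    p[OUT_LOW, CONTEXT_GO, LOC_CAROLINE] = 0.75
    p[OUT_LOW, CONTEXT_NOGO, LOC_CAROLINE] = 1.0
    return p


@dataclass
class SocialEnvironment:
    """State of the synthetic social world.

    ``counts`` are Dirichlet concentration counts over the outcome
    likelihood (same shape as the agent's ``a``); outcomes are sampled from
    their column normalization.  ``count_scale`` converts probability
    tables into counts, so that the fixed +10 support increments move
    probabilities appreciably within a few social signals.
    """

    rng_seed: int | np.random.SeedSequence = 0
    responsive: bool = False
    count_scale: float = 10.0
    start_context: int = CONTEXT_GO
    support_increment: float = 10.0
    support_rudolph_outcome: int = OUT_HIGH

    counts: np.ndarray = None
    day: int = 1
    true_location: int = LOC_HOME
    adversity_applied: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = self.count_scale * pre_adversity_probs()
        self.rng = np.random.default_rng(self.rng_seed)
        self._B_true = location_transitions()

    # -- context and movement ---------------------------------------------
    def context_on(self, day: int) -> int:
        """True context on a 1-based day; alternates every other day."""
        offset = (day - 1) % 2
        return self.start_context ^ offset

    @property
    def true_context(self) -> int:
        return self.context_on(self.day)

    @property
    def likelihood(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def begin_trial(self, day: int) -> None:
        self.day = day
        self.true_location = LOC_HOME

    def step(self, action: int) -> int:
        """Move the agent; partner locations are absorbing."""
        probs = self._B_true[:, self.true_location, action]
        self.true_location = int(np.argmax(probs))
        return self.true_location


def generate_outcome(env: SocialEnvironment, location: int | None = None,
                     context: int | None = None) -> int:
    """Sample an outcome index for (context, location) from the environment.

    Exactly one uniform variate is consumed per call regardless of whether
    the cell is deterministic, so random streams stay aligned across
    conditions that share a seed.
    """
    location = env.true_location if location is None else int(location)
    context = env.true_context if context is None else int(context)
    if not 0 <= location < N_LOCATIONS or not 0 <= context < N_CONTEXTS:
        raise ConfigError("invalid location or context index")
    p = env.counts[:, context, location]
    cdf = np.cumsum(p / p.sum())
    u = env.rng.random()
    return int(np.searchsorted(cdf, u, side="right"))


def support_cells(env: SocialEnvironment) -> list[tuple[int, int, int]]:
    """The (outcome, context, location) cells reinforced by social support.

    Three logical mappings: Rudolph -> reward (context-independent, so both
    context columns are touched), Caroline on a good day -> high reward,
    Caroline on a busy day -> low reward.  The last makes Caroline's
    *unavailability* reliable too -- support reduces uncertainty, it does
    not make every day a good one.
    """
    return [
        (env.support_rudolph_outcome, CONTEXT_GO, LOC_RUDOLPH),
        (env.support_rudolph_outcome, CONTEXT_NOGO, LOC_RUDOLPH),
        (OUT_HIGH, CONTEXT_GO, LOC_CAROLINE),
        (OUT_LOW, CONTEXT_NOGO, LOC_CAROLINE),
    ]


def apply_social_support(env: SocialEnvironment,
                         agent_visited_media: bool) -> np.ndarray:
    """Adapt the environment to the agent's social signalling.

    If the agent solicited the epistemic cue (visited social media) during
    the trial, add ``support_increment`` counts to each designated support
    cell.  Called once per trial while support is active.
    """
    if not env.responsive:
        raise ConfigError("social support applied to a non-responsive environment")
    if agent_visited_media:
        for o, c, l in support_cells(env):
            env.counts[o, c, l] += env.support_increment
    return env.counts
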