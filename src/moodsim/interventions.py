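"""Condition-defining manipulations: adversity, support, pharmacotherapy.

The study crosses three factors after a shared 28-day run-in: social
adversity (a flip of the environment's social contingencies plus a reset
of the agent's likelihood counts), social support (the environment becomes
responsive to social signalling), and two simulated antidepressants --
serotonin biases the prior over the initial context toward "go", while
noradrenaline dilutes the precision of the transition counts day by day.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .engine import AgentModel
from .environment import SocialEnvironment, post_adversity_probs
from .errors import ConfigError, StateError
from .task import N_LOCATIONS

__all__ = [
    "ConditionConfig",
    "condition",
    "CONDITION_NAMES",
    "apply_adversity",
    "apply_serotonin",
    "apply_noradrenaline_daily",
]

CONDITION_NAMES = {
    0: "baseline",
    1: "severe depression",
    2: "social support",
    3: "serotonin",
    4: "noradrenaline",
    5: "serotonin + noradrenaline",
    6: "social support + serotonin",
    7: "social support + noradrenaline",
    8: "social support + serotonin + noradrenaline",
}

# (support, serotonin, noradrenaline) flags per condition; all conditions
# except the baseline include the adverse event on day 28.
_FACTORIAL = {
    0: (False, False, False),
    1: (False, False, False),
    2: (True, False, False),
    3: (False, True, False),
    4: (False, False, True),
    5: (False, True, True),
    6: (True, True, False),
    7: (True, False, True),
    8: (True, True, True),
}


@dataclass(frozen=True)
class ConditionConfig:
    """Which interventions are active and on which day each begins."""

    condition_id: int
    adversity_day: int | None = 28
    support_day: int | None = 30
    pharma_day: int | None = 35
    support: bool = False
    serotonin: bool = False
    noradrenaline: bool = False

    def __post_init__(self) -> None:
        if self.condition_id not in CONDITION_NAMES:
            raise ConfigError(f"unknown condition id {self.condition_id}")

    @property
    def name(self) -> str:
        return CONDITION_NAMES[self.condition_id]


def condition(condition_id: int, **overrides) -> ConditionConfig:
    """Preset for one of the nine study conditions (0 = healthy baseline)."""
    if condition_id not in _FACTORIAL:
        raise ConfigError(f"unknown condition id {condition_id}")
    support, serotonin, noradrenaline = _FACTORIAL[condition_id]
    cfg = ConditionConfig(
        condition_id=condition_id,
        adversity_day=None if condition_id == 0 else 28,
        support_day=30 if support else None,
        pharma_day=35 if (serotonin or noradrenaline) else None,
        support=support,
        serotonin=serotonin,
        noradrenaline=noradrenaline,
    )
    return replace(cfg, **overrides) if overrides else cfg


def apply_adversity(env: SocialEnvironment, model: AgentModel) -> None:
    """The adverse life event: flip social contingencies, reset sensitivity.

    The environment's likelihood is set to the post-adversity tables
    (Rudolph always rejects; Caroline's good-day odds invert to 25% and her
    busy days always fail); cue and home cells are untouched.  The agent's
    likelihood counts ``a`` revert to their day-1 initialization, restoring
    the sensitivity to new contingencies that weeks of count accumulation
    had dulled.  Called once, at the end of the adversity day's trial, so
    the flipped world is what the agent wakes up to the next day.
    """
    if env.adversity_applied:
        raise StateError("adversity has already been applied")
    env.counts = env.count_scale * post_adversity_probs()
    env.adversity_applied = True
    model.a = model.a0.copy()


def apply_serotonin(model: AgentModel,
                    bias: tuple[float, float] = (0.99, 0.01)) -> None:
    """Serotonergic optimism: prior over the initial context becomes ``bias``.

    The default shifts D(context) from (.5, .5) to (.99, .01) in favour of
    the "go" context, for every subsequent trial.
    """
    bias = np.asarray(bias, dtype=float)
    if bias.shape != (2,) or not np.isclose(bias.sum(), 1.0):
        raise ConfigError("serotonin bias must be a 2-vector summing to 1")
    model.D_context = bias.copy()


def apply_noradrenaline_daily(model: AgentModel, omega: float = 0.9) -> None:
    """One day of noradrenergic dilution of transition precision.

    Each column of the transition counts ``b`` is mixed toward uniform
    counts of equal total mass: ``b <- omega * b + (1 - omega) * uniform``.
    Column totals are preserved, so uncertainty about *unvisited*
    transitions accumulates gradually while Dirichlet learning (which
    continues under treatment) re-sharpens the transitions the agent
    actually experiences.
    """
    if not 0.0 < omega <= 1.0:
        raise ConfigError(f"omega must lie in (0, 1], got {omega}")
    uniform = np.broadcast_to(model.b.sum(axis=0, keepdims=True) / N_LOCATIONS,
                              model.b.shape)
    model.b = omega * model.b + (1.0 - omega) * uniform
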