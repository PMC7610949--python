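"""Synthetic diagnostic criteria and condition summaries.

Two synthetic symptoms are scored per day:

* **anhedonia (intensity)** -- the day's mood proxy falls below a threshold
  derived from the healthy baseline: the one-sided 5th percentile
  (nearest-rank rule) of the pooled baseline distribution, so a healthy
  agent falls below it roughly one day in twenty.  The mood proxy is by
  default the *expected utility* of the day's enacted engagement evaluated
  under the beliefs the agent ends the day with (``expected_post``); the
  planning-time expectation (``expected``) and the realized pragmatic
  value of observed outcomes (``realized``) are available as alternative
  metrics.
* **anhedonia (duration)** -- a day inside a maximal block of two or more
  consecutive intensity days.
* **social withdrawal** -- the enacted policy never reaches a social
  partner (policies 1, 4, 7, 10).

Condition summaries report each criterion as a percentage of the 36
post-adversity days (days 29-64), averaged across seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import WITHDRAWAL_POLICIES

__all__ = [
    "TrialRecord",
    "ConditionSummary",
    "baseline_threshold",
    "flag_symptoms",
    "duration_days",
    "summarize_condition",
    "records_to_frame",
]

POST_ADVERSITY_START = 29
POST_ADVERSITY_DAYS = 36


@dataclass
class TrialRecord:
    """Per-day log of one trial."""

    day: int
    true_context: str
    policy_posterior: np.ndarray
    selected_policy: int           # 1-based index into the policy table
    actions: tuple[int, int]
    outcomes: tuple[int, int, int]
    daily_utility: float           # realized sum of C over observed outcomes
    expected_utility: float        # anticipated utility of the enacted policy
    expected_utility_post: float = 0.0  # same, under end-of-day beliefs
    anhedonia_flag: bool = False
    withdrawal_flag: bool = field(default=None)

    def __post_init__(self) -> None:
        if self.withdrawal_flag is None:
            self.withdrawal_flag = self.selected_policy in WITHDRAWAL_POLICIES


@dataclass
class ConditionSummary:
    """Post-adversity symptom percentages for one condition (a Table row)."""

    condition_id: int
    pct_intensity: float
    pct_duration: float
    pct_withdrawal: float
    n_seeds: int = 1
    sd_intensity: float = 0.0
    sd_duration: float = 0.0
    sd_withdrawal: float = 0.0

    def rounded(self) -> dict[str, int]:
        """Integer percentages for report display (half-up rounding)."""
        return {
            "intensity": round_half_up(self.pct_intensity),
            "duration": round_half_up(self.pct_duration),
            "withdrawal": round_half_up(self.pct_withdrawal),
        }


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _utilities(run: list[TrialRecord], metric: str) -> np.ndarray:
    if metric == "expected":
        return np.array([r.expected_utility for r in run])
    if metric == "expected_post":
        return np.array([r.expected_utility_post for r in run])
    if metric == "realized":
        return np.array([r.daily_utility for r in run])
    raise ValueError(f"unknown mood metric {metric!r}")


def baseline_threshold(baseline_runs: list[list[TrialRecord]],
                       metric: str = "expected_post",
                       percentile: float = 5.0) -> float:
    """One-sided lower threshold from pooled healthy-baseline days.

    Nearest-rank percentile: with n pooled values sorted ascending, the
    threshold is the value at rank ``ceil(n * percentile / 100)``.  Days
    *strictly below* the threshold then occur on at most ~5% of healthy
    days ("about once every 20 days").
    """
    if not baseline_runs:
        raise ValueError("need at least one baseline run")
    pooled = np.sort(np.concatenate([_utilities(r, metric) for r in baseline_runs]))
    if pooled.size == 0:
        raise ValueError("baseline runs contain no days")
    rank = max(1, math.ceil(pooled.size * percentile / 100.0))
    return float(pooled[rank - 1])


def flag_symptoms(run: list[TrialRecord], threshold: float,
                  metric: str = "expected_post") -> list[TrialRecord]:
    """Fill the per-day anhedonia and withdrawal flags of a completed run."""
    utilities = _utilities(run, metric)
    for record, u in zip(run, utilities):
        record.anhedonia_flag = bool(u < threshold)
        record.withdrawal_flag = record.selected_policy in WITHDRAWAL_POLICIES
    return run


def duration_days(flags) -> np.ndarray:
    """Days belonging to maximal blocks of >= 2 consecutive flagged days."""
    flags = np.asarray(flags, dtype=bool)
    out = np.zeros_like(flags)
    i = 0
    while i < flags.size:
        if flags[i]:
            j = i
            while j < flags.size and flags[j]:
                j += 1
            if j - i >= 2:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def summarize_condition(flagged_runs: list[list[TrialRecord]],
                        condition_id: int,
                        post_start: int = POST_ADVERSITY_START) -> ConditionSummary:
    """Average post-adversity symptom percentages across seeds.

    Percentages are computed over days ``post_start``..horizon (36 days by
    default) within each seed, then averaged; the raw means are retained
    and ``ConditionSummary.rounded()`` gives the display form.  Duration
    blocks are identified on the full run, so a post-adversity day extends
    a block that began before the window.
    """
    if not flagged_runs:
        raise ValueError("no runs to summarize")
    per_seed = []
    for run in flagged_runs:
        anhedonia = np.array([r.anhedonia_flag for r in run])
        withdrawal = np.array([r.withdrawal_flag for r in run])
        days = np.array([r.day for r in run])
        window = days >= post_start
        dur = duration_days(anhedonia)
        per_seed.append((100.0 * anhedonia[window].mean(),
                         100.0 * dur[window].mean(),
                         100.0 * withdrawal[window].mean()))
    per_seed = np.array(per_seed)
    mean = per_seed.mean(axis=0)
    sd = per_seed.std(axis=0, ddof=1) if len(per_seed) > 1 else np.zeros(3)
    return ConditionSummary(
        condition_id=condition_id,
        pct_intensity=float(mean[0]), pct_duration=float(mean[1]),
        pct_withdrawal=float(mean[2]), n_seeds=len(per_seed),
        sd_intensity=float(sd[0]), sd_duration=float(sd[1]),
        sd_withdrawal=float(sd[2]),
    )


def records_to_frame(runs: list[list[TrialRecord]]) -> pd.DataFrame:
    """Flatten per-seed runs into a tidy per-day table (schema v1)."""
    rows = []
    for seed_idx, run in enumerate(runs):
        for r in run:
            rows.append({
                "seed": seed_idx,
                "day": r.day,
                "context": r.true_context,
                "policy": r.selected_policy,
                "action1": r.actions[0],
                "action2": r.actions[1],
                "outcome1": r.outcomes[0],
                "outcome2": r.outcomes[1],
                "outcome3": r.outcomes[2],
                "utility": r.daily_utility,
                "expected_utility": r.expected_utility,
                "expected_utility_post": r.expected_utility_post,
                "anhedonia": r.anhedonia_flag,
                "withdrawal": r.withdrawal_flag,
            })
    return pd.DataFrame(rows)
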