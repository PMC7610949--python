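"""Qualitative figures: policy-posterior heatmaps and daily mood bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .diagnostics import TrialRecord
from .interventions import ConditionConfig

__all__ = ["plot_condition"]


def plot_condition(run: list[TrialRecord], cond: ConditionConfig,
                   threshold: float):
    """Two-panel figure for one run: policy posteriors per day (heatmap)
    and the daily mood proxy against the healthy-baseline threshold, with
    intervention day-lines."""
    days = [r.day for r in run]
    posteriors = np.array([r.policy_posterior for r in run]).T  # (10, days)
    utilities = [r.expected_utility_post for r in run]

    fig, (ax_pol, ax_mood) = plt.subplots(
        2, 1, figsize=(10, 6), sharex=True,
        gridspec_kw={"height_ratios": [2, 1]})
    ax_pol.imshow(1.0 - posteriors, aspect="auto", cmap="gray",
                  extent=[days[0] - 0.5, days[-1] + 0.5, 10.5, 0.5])
    ax_pol.set_yticks(range(1, 11))
    ax_pol.set_ylabel("policy")
    ax_pol.set_title(f"condition {cond.condition_id}: {cond.name}")

    colors = ["tab:red" if r.anhedonia_flag else "black" for r in run]
    ax_mood.bar(days, utilities, color=colors, width=0.8)
    ax_mood.axhline(threshold, color="hotpink", lw=2,
                    label="healthy 5th-percentile threshold")
    for day, color, name in [(cond.adversity_day, "red", "adversity"),
                             (cond.support_day, "blue", "support"),
                             (cond.pharma_day, "orange", "pharma")]:
        if day is not None:
            for ax in (ax_pol, ax_mood):
                ax.axvline(day + 0.5, color=color, lw=1.5, alpha=0.8)
            ax_mood.text(day + 0.7, ax_mood.get_ylim()[1] * 0.9, name,
                         color=color, fontsize=8)
    ax_mood.set_xlabel("day")
    ax_mood.set_ylabel("expected utility")
    ax_mood.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    return fig
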