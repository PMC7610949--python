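"""Orchestration of trials, conditions and the full nine-condition study.

A trial is one day: three timesteps, two moves.  The perception-action
loop is: observe the start outcome, infer states and policies, act;
observe, re-infer (pruning policies inconsistent with the executed move),
act again; observe the final outcome and learn.  Interventions fire on
their scheduled days, and a responsive environment accumulates support
counts on every day the agent signals on social media.

Seeding: one master seed spawns an independent stream per (condition,
seed) pair via ``numpy``'s SeedSequence; the stream depends only on the
seed index, not the condition, so conditions sharing a seed see identical
outcome randomness and behave identically until interventions diverge.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _code_version
from .config import SimulationConfig
from .diagnostics import (
    ConditionSummary,
    TrialRecord,
    baseline_threshold,
    flag_symptoms,
    records_to_frame,
    summarize_condition,
)
from .engine import (
    AgentModel,
    expected_free_energy,
    infer_policies,
    infer_states,
    select_action,
    update_dirichlet,
)
from .environment import (
    SocialEnvironment,
    apply_social_support,
    generate_outcome,
)
from .errors import StateError
from .interventions import (
    ConditionConfig,
    apply_adversity,
    apply_noradrenaline_daily,
    apply_serotonin,
    condition,
)
from .task import (
    CONTEXT_NAMES,
    LOC_MEDIA,
    WITHDRAWAL_POLICIES,
    actions_to_policy,
    build_agent_model,
)

__all__ = [
    "run_trial",
    "run_condition",
    "run_study",
    "StudyResult",
    "support_delay_sweep",
    "epistemic_onset",
    "first_sustained_withdrawal",
    "make_report",
]

log = logging.getLogger(__name__)


def _env_for(cfg: SimulationConfig, master_seed: int, seed_index: int,
             responsive: bool) -> SocialEnvironment:
    from .task import CONTEXT_GO, CONTEXT_NOGO, OUT_HIGH, OUT_MODERATE

    return SocialEnvironment(
        rng_seed=np.random.SeedSequence((int(master_seed), int(seed_index))),
        responsive=responsive,
        count_scale=cfg.env_count_scale,
        start_context=CONTEXT_GO if cfg.start_context == "go" else CONTEXT_NOGO,
        support_increment=cfg.support_increment,
        support_rudolph_outcome=(OUT_HIGH if cfg.support_rudolph_outcome == "high"
                                 else OUT_MODERATE),
    )


def run_trial(model: AgentModel, env: SocialEnvironment, day: int,
              support_active: bool = False,
              preferences: np.ndarray | None = None) -> TrialRecord:
    """One day of the perception-action-learning cycle.

    Returns the completed :class:`TrialRecord`; mutates ``model`` (Dirichlet
    learning) and ``env`` (location, and support counts when the agent
    signalled on social media while support is active).
    """
    if env.day != day and not (env.day == day - 1 or day == 1):
        raise StateError(f"environment at day {env.day}, trial wants day {day}")
    env.begin_trial(day)
    C = model.C if preferences is None else preferences
    policies = model.policies
    n_pol = len(policies)

    outcomes = [generate_outcome(env)]
    actions: list[int] = []

    posterior = np.full(n_pol, 1.0 / n_pol)
    mask = np.ones(n_pol, dtype=bool)
    posts_by_policy = [None] * n_pol
    for t in (1, 2):
        F = np.full(n_pol, np.inf)
        G = np.zeros(n_pol)
        for p in np.flatnonzero(mask):
            posts, F_p = infer_states(model, outcomes, policies[p])
            posts_by_policy[p] = posts
            F[p] = F_p
            G[p] = expected_free_energy(model, policies[p], posts[t - 1],
                                        timestep=t).G
        posterior = infer_policies(model, F, G, mask=mask)
        action = select_action(posterior, policies, timestep=t)
        actions.append(action)
        mask &= policies[:, t - 1] == action
        # Social signalling is registered the moment the agent solicits the
        # cue: a responsive environment adds its support counts before any
        # later outcome of the same day is drawn.
        if env.step(action) == LOC_MEDIA and support_active and env.responsive:
            apply_social_support(env, True)
        outcomes.append(generate_outcome(env))

    selected_policy = actions_to_policy(actions[0], actions[1])
    enacted = selected_policy - 1

    # Mood proxy: expected utility of the enacted policy at the final
    # planning step -- what the agent anticipates from the remaining
    # engagement of the day (the last move's predicted outcome).
    pred = np.einsum(
        "clam,am->cl",
        np.einsum("ca,lm->clam", model.B_context,
                  model.B_location[:, :, actions[1]]),
        posts_by_policy[enacted][1],
    )
    q_outcome = np.einsum("ocl,cl->o", model.A, pred)
    expected_utility = float(q_outcome @ C)
    daily_utility = float(sum(C[o] for o in outcomes))

    # Smoothed posteriors under the enacted policy, for learning.
    posts, _ = infer_states(model, outcomes, policies[enacted])
    update_dirichlet(model, outcomes, posts, actions=actions)

    # End-of-day variant of the mood proxy: the same anticipated engagement
    # utility re-evaluated under the beliefs the agent goes to sleep with.
    q_outcome_post = np.einsum("ocl,cl->o", model.A, posts[2])
    expected_utility_post = float(q_outcome_post @ C)

    return TrialRecord(
        day=day,
        true_context=CONTEXT_NAMES[env.true_context],
        policy_posterior=posterior,
        selected_policy=selected_policy,
        actions=(actions[0], actions[1]),
        outcomes=tuple(outcomes),
        daily_utility=daily_utility,
        expected_utility=expected_utility,
        expected_utility_post=expected_utility_post,
    )


def run_condition(cond: ConditionConfig | int,
                  cfg: SimulationConfig | None = None,
                  n_seeds: int = 20,
                  master_seed: int = 0,
                  seeds: list[int] | None = None) -> list[list[TrialRecord]]:
    """Run one condition over seeds; returns per-seed 64-day runs.

    Interventions follow the condition schedule: the adverse event flips
    the world at the end of ``adversity_day`` (so days 1..28 are identical
    across conditions sharing a seed), support counts flow from
    ``support_day`` onward, serotonin acts from ``pharma_day`` and
    noradrenaline is applied daily from ``pharma_day``.
    """
    if isinstance(cond, int):
        cond = condition(cond)
    cfg = cfg or SimulationConfig()
    seed_indices = list(seeds) if seeds is not None else list(range(n_seeds))
    spec = cfg.task_spec()
    serotonin_bias = (cfg.serotonin_bias_go, 1.0 - cfg.serotonin_bias_go)

    runs = []
    for seed_index in seed_indices:
        model = build_agent_model(spec)
        env = _env_for(cfg, master_seed, seed_index, responsive=cond.support)
        run: list[TrialRecord] = []
        for day in range(1, cfg.horizon_days + 1):
            if cond.noradrenaline and cond.pharma_day and day >= cond.pharma_day:
                apply_noradrenaline_daily(model, omega=cfg.omega)
            if cond.serotonin and cond.pharma_day and day == cond.pharma_day:
                apply_serotonin(model, bias=serotonin_bias)
            support_active = (cond.support and cond.support_day is not None
                              and day >= cond.support_day)
            run.append(run_trial(model, env, day, support_active=support_active))
            if (cond.adversity_day is not None and day == cond.adversity_day
                    and not env.adversity_applied):
                apply_adversity(env, model)
        runs.append(run)
    return runs


@dataclass
class StudyResult:
    """Runs, summaries and provenance for a set of conditions."""

    runs: dict[int, list[list[TrialRecord]]]
    threshold: float
    summaries: dict[int, ConditionSummary]
    provenance: dict = field(default_factory=dict)


def run_study(cfg: SimulationConfig | None = None,
              condition_ids: list[int] | None = None,
              n_seeds: int = 20,
              master_seed: int = 0) -> StudyResult:
    """Baseline plus the requested conditions, flagged and summarized.

    The baseline (condition 0) is always run: it defines the anhedonia
    threshold.  Every condition uses the same horizon and seed list.
    """
    cfg = cfg or SimulationConfig()
    if n_seeds < 1:
        raise ValueError("need at least one seed")
    condition_ids = sorted(set(condition_ids or range(9)) | {0})

    runs: dict[int, list[list[TrialRecord]]] = {}
    for cid in condition_ids:
        log.info("running condition %d over %d seeds", cid, n_seeds)
        runs[cid] = run_condition(condition(cid), cfg, n_seeds=n_seeds,
                                  master_seed=master_seed)
    threshold = baseline_threshold(runs[0], metric=cfg.mood_metric,
                                   percentile=cfg.threshold_percentile)
    summaries = {}
    for cid, cond_runs in runs.items():
        for run in cond_runs:
            flag_symptoms(run, threshold, metric=cfg.mood_metric)
        summaries[cid] = summarize_condition(cond_runs, cid)

    cfg_hash = hashlib.sha256(
        json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    provenance = {
        "config_hash": cfg_hash,
        "master_seed": master_seed,
        "n_seeds": n_seeds,
        "condition_ids": condition_ids,
        "code_version": _code_version,
        "threshold": threshold,
    }
    return StudyResult(runs=runs, threshold=threshold, summaries=summaries,
                       provenance=provenance)


# -- derived behavioural signatures ---------------------------------------

def epistemic_onset(run: list[TrialRecord]) -> int:
    """Last day whose trial does *not* begin with the social-media action.

    After this day every remaining trial opens by consulting the cue
    (epistemic-first behaviour); 0 if the whole run is epistemic-first.
    """
    last = 0
    for r in run:
        if r.actions[0] != LOC_MEDIA:
            last = r.day
    return last


def first_sustained_withdrawal(run: list[TrialRecord],
                               start_day: int = 29,
                               min_run: int = 2) -> int | None:
    """First day from ``start_day`` opening >= ``min_run`` consecutive
    withdrawal days; None if withdrawal never sets in."""
    flags = {r.day: r.withdrawal_flag if r.withdrawal_flag is not None
             else r.selected_policy in WITHDRAWAL_POLICIES for r in run}
    days = sorted(d for d in flags if d >= start_day)
    for d in days:
        if all(flags.get(d + k, False) for k in range(min_run)):
            return d
    return None


def support_delay_sweep(cfg: SimulationConfig | None = None,
                        offsets=range(1, 7),
                        n_seeds: int = 20,
                        master_seed: int = 0,
                        recovered_withdrawal_pct: float = 25.0) -> dict:
    """Delay social support by 1..6 days after adversity; find the critical
    window for mood recovery.

    For each offset, condition-2 runs are classified as *recovered* when
    their post-adversity withdrawal percentage stays below
    ``recovered_withdrawal_pct`` (near zero, against a severe-depression
    signature of ~60%).  Returns per-offset recovery fractions and the
    largest offset at which the majority of runs recover.
    """
    cfg = cfg or SimulationConfig()
    baseline_runs = run_condition(condition(0), cfg, n_seeds=n_seeds,
                                  master_seed=master_seed)
    threshold = baseline_threshold(baseline_runs, metric=cfg.mood_metric,
                                   percentile=cfg.threshold_percentile)
    results = {}
    for offset in offsets:
        cond = condition(2, support_day=cfg.adversity_day + int(offset))
        runs = run_condition(cond, cfg, n_seeds=n_seeds, master_seed=master_seed)
        recovered = []
        for run in runs:
            flag_symptoms(run, threshold, metric=cfg.mood_metric)
            summary = summarize_condition([run], 2)
            recovered.append(summary.pct_withdrawal < recovered_withdrawal_pct)
        results[int(offset)] = float(np.mean(recovered))
    max_offset = 0
    for offset in sorted(results):
        if results[offset] > 0.5:
            max_offset = offset
    return {"recovery_fraction": results, "max_recovering_delay": max_offset}


def make_report(study: StudyResult, outdir: str | Path,
                plots: bool = True) -> Path:
    """Write per-day CSVs, the summary table (CSV + JSON) and figures."""
    if not study.runs or not any(study.runs.values()):
        raise ValueError("study contains no runs")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary_rows = []
    for cid in sorted(study.summaries):
        s = study.summaries[cid]
        rounded = s.rounded()
        summary_rows.append({
            "condition": cid,
            "intensity_pct": rounded["intensity"],
            "duration_pct": rounded["duration"],
            "withdrawal_pct": rounded["withdrawal"],
            "intensity_raw": s.pct_intensity,
            "duration_raw": s.pct_duration,
            "withdrawal_raw": s.pct_withdrawal,
            "n_seeds": s.n_seeds,
        })
        records_to_frame(study.runs[cid]).to_csv(
            outdir / f"condition_{cid}_days.csv", index=False)

    import pandas as pd
    pd.DataFrame(summary_rows).to_csv(outdir / "summary.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps({
        "threshold": study.threshold,
        "provenance": study.provenance,
        "conditions": summary_rows,
    }, indent=2))

    if plots:
        from .plots import plot_condition
        for cid, cond_runs in study.runs.items():
            fig = plot_condition(cond_runs[0], condition(cid), study.threshold)
            fig.savefig(outdir / f"condition_{cid}.png", dpi=120)
            import matplotlib.pyplot as plt
            plt.close(fig)
    return outdir
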