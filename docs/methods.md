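# Methods

## The simulation in one paragraph

A synthetic agent plays a 64-day social decision task.  Hidden states
factorize into a binary *context* -- whether Caroline, the risky social
partner, is available ("go") or busy ("no-go") -- and a four-level
*location* (home, Rudolph, Caroline, social media).  The context is
outside the agent's control and alternates deterministically every day,
starting on a "go" day.  Each day is one trial of T = 3 timesteps: the
agent wakes at home (observing the neutral "start" outcome), makes two
moves, and observes an outcome after each.  Rudolph and Caroline are
absorbing -- an encounter, once begun, lasts the rest of the day.  With
four destination actions and the absorbing structure there are exactly
ten distinguishable two-move policies; policies 1, 4, 7 and 10 never
reach a social partner and define *social withdrawal*.  Social media
emits a cue that reveals the day's context, making policies 8 and 9
(forage first, then choose an arm) the epistemic backbone of healthy
behaviour.

## Generative process (the environment)

Outcome probabilities P(o | context, location) are held as Dirichlet
concentration counts (counts = 10 x the probability tables, so the fixed
support increments below move probabilities appreciably within a few
signals):

| location | go day | no-go day |
|---|---|---|
| home | start 1.0 | start 1.0 |
| Rudolph | moderate 1.0 | moderate 1.0 |
| Caroline | high .75 / low .25 | high .25 / low .75 |
| social media | go-cue 1.0 | no-go-cue 1.0 |

One uniform variate is consumed per outcome draw even in deterministic
cells, so conditions sharing a seed see identical randomness until their
interventions diverge.

**Adversity** (end of day 28, so days 29-64 form the 36-day scoring
window): Rudolph -> low with certainty in both contexts; Caroline's
no-go days -> low with certainty; her go-day odds invert to high .25 /
low .75.  The agent's likelihood counts are simultaneously reset to
their day-1 values, restoring the sensitivity to new contingencies that
four weeks of count accumulation had dulled.

**Social support** (responsive environment, from day 30 in the standard
schedule): every time the agent arrives at social media, +10 counts are
added to three logical cells -- Rudolph -> high reward (both context
columns of the tensor, since Rudolph's mapping is context-independent),
Caroline on go days -> high, Caroline on no-go days -> low.  The third
cell means support makes Caroline's *unavailability* reliable too:
support reduces uncertainty rather than making every day a good one.
Increments fire at the moment of solicitation, so an arm visited later
the same day already faces the partly repaired contingencies, and a
media-media day signals twice.  Support counts accumulate without bound.

## Generative model (the agent)

* **a** (likelihood counts): home->start and the two cue cells start at
  128 (effectively known -- the agent already trusts the cue); the nine
  reward cells at the two partners start flat at 0.4 per outcome,
  learnable within roughly a week of visits.  Structurally impossible
  cells hold a 1e-6 floor so all counts stay strictly positive without
  affecting inference; cells at or below 1e-3 are treated as structural
  zeros by the novelty term.
* **b** (transition counts): the true location dynamics at scale 1 plus
  the same floor -- "blank slate" in the sense of being weakly held, so
  transition learning and the noradrenaline manipulation both have
  something to act on.  Transition learning is on by default
  (`learn_b`), which makes "the agent continues to learn transitions
  under treatment" literally true; switching it off changes the graded
  results by under 2 percentage points in the untreated conditions
  because the visited transitions are deterministic anyway.
* **C** (log-preferences, unitless): start 0, low -1.9, moderate +0.35,
  high +2.0, cues 0.  See *Calibration*.
* **D**: location is a delta on home; context is (.5, .5) each morning --
  the agent does not track the alternation and relies on the cue.
* **gamma** = 16 (policy precision; high enough that action selection is
  near-deterministic), **eta** = 0.28 (learning rate on count
  increments).

## Inference, planning, learning

With 8 joint states and T = 3, state posteriors and the policy evidence
F = -log P(o_prefix | policy) are computed *exactly* by enumerating
complete state sequences (tensor contraction; a pure-Python loop oracle
in the test suite checks every policy and prefix to 1e-6).  Expected
free energy accumulates per future timestep: risk = KL from the
predicted outcome distribution to softmax(C); ambiguity = expected
conditional outcome entropy; novelty = expected information gain over
the likelihood counts, W = (1/a - 1/colsum(a))/2 -- the standard
Dirichlet approximation, restricted to learnable cells (a structural
zero would otherwise contribute a spurious constant 0.5/colsum through
the eps * 1/eps limit).  Novelty is computed for **a** only.

The policy posterior is softmax(-gamma G - F) over the policies
consistent with actions already executed; the action with the greatest
summed posterior mass is executed, ties breaking to the lowest action
index.  After the third outcome, counts accumulate: a[o_t] += eta *
q(s_t) using the smoothed posteriors under the enacted policy, and
b[:, :, u_t] += eta * outer(q_loc(t+1), q_loc(t)).

## Interventions

* **Serotonin** (day 35): D(context) becomes (.99, .01) -- an optimism
  bias about Caroline's availability.  Nothing else changes.
* **Noradrenaline** (daily from day 35): b <- omega b + (1 - omega)
  uniform counts of equal column mass, omega = 0.9 per day.  Column
  totals are preserved, so uncertainty accumulates on unvisited
  transitions while experienced ones re-sharpen through learning.  The
  0.9 rate makes exploratory diffusion over the policy space visible
  within about five treated days.
* **Conditions**: 0 baseline (no adversity); 1 adversity alone; 2
  +support; 3 +serotonin; 4 +noradrenaline; 5 +both drugs; 6
  +support+serotonin; 7 +support+noradrenaline; 8 all three.
  Schedules (28 / 30 / 35) are config-exposed.

## Mood and diagnostics

The mood proxy for a day is the expected utility of the day's final
engagement -- Sum_o q(o) C(o) for the enacted policy's last move --
evaluated under the beliefs the agent ends the day with
(`mood_metric: expected_post`).  A supported good encounter therefore
lifts mood the same day, and a freshly-reset agent's flat beliefs give
the mildly positive mood of ignorant optimism.  Two alternative readings
are config switches: the planning-time expectation (`expected`) and the
realized preference sum of observed outcomes (`realized`).  The realized
reading cannot reproduce the reference summary profile: healthy realized
utilities take three spiky values whose lower tail is the failure
outcome itself, so no percentile threshold can separate withdrawal days
(utility 0) from healthy days.

*Anhedonia intensity*: mood strictly below the one-sided 5th percentile
(nearest-rank) of the pooled healthy-baseline days -- a level the
healthy agent visits about once every 20 days, essentially during its
first learning week.  *Duration*: days inside maximal blocks of >= 2
consecutive intensity days.  *Withdrawal*: enacted policy in {1, 4, 7,
10}.  Summaries average the three percentages over days 29-64 (exactly
36 days) per seed, then across seeds; display values round half-up.

## Calibration

The preference values, learning rate, count scales and omega have no
externally fixed values; they were calibrated, as a package design step, so
that the healthy baseline reproduces the task's qualitative signature
and the condition table its quantitative one, then frozen.  The
constraints that pin them:

* *Epistemic-first behaviour*: the cue route beats committing directly
  to Caroline when (C_high + C_low)/2 < ln 2 - (residual novelty +
  context-outcome information at the arm), and beats double-dipping safe
  Rudolph when 2 C_mod < -ln(1/2) + (C_high + C_low)/2 + ln 2.  These
  cap C_mod and force C_low close to -C_high.
* *Exploration week*: novelty of a flat arm column (1/(3 arm_count))
  plus flat-belief utility must exceed ln 2 for the agent to explore the
  arms directly at first, and must decay below it within about a week;
  arm_count 0.4 and eta 0.28 put the modal last non-epistemic trial at
  ~5 and make the reward mappings learnable in ~7 trials.
* *Withdrawal onset*: after the adversity reset, engagement persists
  while expected arm utility plus novelty stays positive; C_low -1.9
  with eta 0.28 burns that budget in ~6 go-day visits, producing the
  ~two-week onset of sustained withdrawal and a ~60-70% withdrawal rate.
* *Mood scale separation*: C sums to ~0.45 over the three rewards so the
  flat-belief mood (~0.15) sits above withdrawal mood (exactly 0), and
  the healthy threshold (~0.19) lands between the early-learning ramp
  and the healthy bands.

## What the generator does and does not emulate

Every observation is drawn from the tabulated environment, so the
simulations inherit its idealizations: a strictly alternating context, a
perfectly reliable cue, two partners, stationary contingencies between
interventions, and support that never decays or saturates.  Passing
tests therefore demonstrate the internal consistency of the
model-environment loop at these study conditions, not properties of
clinical data; none of the diagnostic percentages should be read as
empirical prevalence estimates.

## Problem sizes and determinism

The reported studies use 20 seeds per condition and a 64-day horizon
(the full nine-condition study runs in well under a minute on one CPU).
One master seed spawns a per-seed stream shared across conditions;
agent-side computation is deterministic (argmax actions, lowest-index
ties), so runs are bit-reproducible per seed.

## Known limitations

Three summary quantities are reproduced only approximately, for reasons
that appear structural under this package's exact-inference reading:

* *Support-condition intensity* (reference value ~6%) lands at ~20%: the
  reset agent re-explores both arms after adversity, and its mood dips
  below threshold for the handful of days the repaired contingencies
  take to relearn.  Pessimism depth and relearning speed share the one
  learning rate, so shrinking this number destroys the two-week
  withdrawal onset elsewhere.
* *Serotonin-alone withdrawal* (reference value 81%) lands at ~71%: once the
  cue has been read, the near-deterministic cue likelihood overrides the
  serotonergic context prior, so the post-cue engagement decision is the
  same as in the untreated condition and serotonin acts only through its
  (small) planning-time optimism.  That large a gap seems to require
  the treated agent to stop consulting the cue altogether, which exact
  inference with a deterministic cue never favours.
* *Critical support delay* (reference value 2 days): recovery here degrades
  smoothly with delay rather than cliff-like -- support repairs the
  environment on every social-media visit and even a withdrawn agent
  keeps signalling -- so the sweep reports the largest tested delay
  rather than 2.  A 2-day cliff would require belief lock-in within ~3
  days of adversity, which contradicts the two-week withdrawal onset in
  the untreated condition.

Hierarchical (deep) generative models, dopamine/precision dynamics,
stochastic action sampling, and fitting to empirical data are out of
scope.
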