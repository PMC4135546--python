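# Methods

## Task model

The simulator reproduces the discrete-trial lever-press avoidance paradigm
at a resolution of one timestep ≈ 10 s.  A standard trial is 54 timesteps:
a 6-step warning period (tone *W* on), a 30-step shock period (*W* and
shock *U* on), and an 18-step inter-trial interval (safety light *S* on).
A lever press during the warning period is scored as an avoidance, turns
*W* off, and jumps the trial directly to the ITI (no shock-period timesteps
occur at all); a press during the shock period is an escape and likewise
truncates to the ITI.  Truncation conserves the ITI: every trial ends with
exactly `iti_len` ITI steps.  Sessions begin with a 6-step stimulus-free
pre-period in the chamber (presses there are logged as anticipatory and
cost `r_press`), followed by 20 trials.  Twelve acquisition sessions are
followed by twelve extinction sessions in which *U* never appears: *W*
stays on for `warning_len + shock_len` steps unless terminated by a press,
and only presses within the warning window count as avoidances.

Between every pair of consecutive sessions (including the
acquisition→extinction boundary) an 18,000-step "overnight" period models
alternate-day training: the home-cage context is the only active input, and
the lever press is removed from the softmax's allowed set (configurable via
`lever_available_between`), so reinforcement is identically zero while
learning and trace turnover continue.  Under round-the-clock housing the
chamber context instead stays on throughout.  Latency is counted in
timesteps from warning onset to the first press and defaults to the full
configured trial length (54) when no press occurs; a first press during the
ITI leaves the outcome `none` but records that press time.

### Input encoding

Five binary units in fixed order: *W*, *S*, *U*, chamber context, home
context.  The two context units are one-hot, so moving the animal between
home cage and chamber changes the active pattern — required for the
context-shift (housing) manipulation.  Phase patterns: pre (0,0,0,1,0),
warning (1,0,0,1,0), shock (1,0,1,1,0), ITI (0,1,0,1,0), overnight
(0,0,0,0,1), or (0,0,0,1,0) under round-the-clock housing.

## Agent

A linear actor-critic with softmax action selection over *A* = 100
candidate actions, one designated as the lever press; the rest stand in for
the animal's other behaviors (grooming, rearing, ...).

Action values are `M_a = Σ_i m[a][i]·I_i + P·c[a][i]`.  Two deliberate
choices here:

- **The perseveration term is not gated by the current inputs.**  The trace
  sum `Σ_i c[a][i]` contributes regardless of which inputs are active, so
  traces of behaviors executed in the home cage continue to bias selection
  after the context switches to the chamber.  This carry-over is the
  warm-up mechanism: at the first trial of a session, the lever press —
  disabled during the overnight period — is the one behavior with no fresh
  trace, so it is transiently out-competed until it is re-executed and
  traces from home-cage behaviors decay (0.95 per step, ~0.28 per trial).
  Gating by the current inputs would erase the influence at the context
  boundary and abolish warm-up after a home-cage interval.
- **The executed action's full trace row is refreshed to 1** (`c[r][i] = 1`
  for every input *i*), making the trace effectively per-action with
  selection weight `P × 5`.  The alternative — refreshing only currently
  active inputs, with the executed action's inactive entries decaying like
  all others — is available as `ModelParams.trace_active_only` and is
  exercised by the test suite, but it weakens cross-context carry-over and
  is not the default.

The critic is linear, `V = Σ_i v[i]·I_i`, trained by the TD(0) error
`PE = R + γ·V(t+1) − V′` with γ = 0.9 fixed.  One learning step per
timestep: observe `I(t)`, select and execute an action, let the environment
produce `I(t+1)` (an avoidance/escape press removes the shock from `t+1`),
assign `R` (= `r_shock` if shock is present at `t+1`, else `r_press` for a
press, else 0; the two costs never sum), then update the **pre-transition**
state: `Δv[i] = α·PE·I_i(t)` and, for the executed action only,
`Δm[r][i] = ε·(PE − m[r][i])·I_i(t)`.  Critic weights are clipped at
±|r_shock|; actor weights are floored at 0; `V′` then advances to
`V(I(t+1))`.  The paradox of avoidance — pressing is reinforced although it
only ever costs — resolves through the critic: once the warning state
predicts punishment (`v[W]` negative), a press that jumps to the safe ITI
state yields `PE ≈ −0.2 + γ·V(ITI) − V(W) > 0`.

## Parameters

| parameter | meaning | default (SD) | WKY |
|---|---|---|---|
| α | critic learning rate | 0.05 | 0.005 |
| ε | actor learning rate | 0.005 | 0.005 |
| T | softmax temperature (explore/exploit) | 1.0 | 0.25 |
| P | perseveration weight | 0.25 | 0 |
| γ | TD discount per 10-s step | 0.9 (fixed) | — |
| R_shock | shock reinforcement | −4 (−8 = doubled amplitude) | — |
| R_press | lever-press cost | −0.2 | — |
| A | candidate actions | 100 | — |
| m_init | initial actor weight | 0.01 | — |
| trace decay | per-step trace multiplier | 0.95 (fixed) | — |

WKY inherits every SD value not listed.  The three WKY changes map onto
dissociable behavioral effects: low *T* (behavioral inhibition → strong
exploitation) accelerates acquisition, low α slows the critic's
re-learning that the warning state is safe and hence slows extinction, and
*P* = 0 removes warm-up.

Schedule defaults (10-s steps): warning 6, shock 30, ITI 18, pre 6,
20 trials/session, 12 + 12 sessions, overnight 18,000 steps.  The named
inter-session grid maps labels to steps at 10 s each (30 m = 180, 1 h =
360, 6 h = 2,160, 24 h = 8,640, 30 d = 259,200), except that the standard
"48 h" condition uses the canonical 18,000-step overnight rather than the
literal conversion.  The continuous-session condition (interval 0) also
drops the pre-period, since only discrete sessions begin with the 1-min
stimulus-free interval.

## Numerical and implementation choices

- Softmax computed with shift-by-maximum; selection walks the cumulative
  unnormalized mass against a single uniform variate.  No tie-breaking is
  needed (selection is sampling).
- Each run uses an independent `numpy` Generator seeded `base_seed + k`;
  compared conditions share seeds (paired design, overridable).  Every
  constant-input stretch of the task draws its uniforms as a block, so the
  stream position does not depend on behavior within the stretch.
- Constant-input stretches are executed by a numba-compiled kernel; a pure
  Python path built from the documented update operations runs scripted
  (stub-policy) simulations, and the test suite holds the two paths to
  identical behavioral records and 1e−9-level weight agreement on shared
  uniform streams.
- At the final timestep of an experiment there is no successor segment; the
  transition target is taken to be the current inputs.  This affects one
  terminal update and no reported measure.
- Degenerate configurations are defined: zero-length ITI/pre/overnight
  segments are no-ops; `trials_per_session = 0` yields an empty session;
  SEM over a single run is reported as 0 with a warning.

## What the simulations do and do not show

The generator's defaults are the study conditions themselves (10 replicate
runs per condition, full 24-session experiments with 18,000-step
overnights), so simulated cohorts are the object of study, not a proxy for
empirical data.  The model deliberately omits processes known to matter in
real rats: freezing and other species-specific defense responses, arousal
or stress carry-over between sessions, satiety/fatigue, and any
neurobiological realization (dopaminergic prediction-error signaling is
motivation for the WKY α reduction, not a mechanism in the code).
Reproducing strain differences here shows that linear TD learning plus
perseveration suffices for these phenomena, not that rats implement them
this way.

Known limitations found while validating against the published phenomena:

- With one-hot contexts and input-gated updates, the overnight period
  touches only home-context weights and traces.  For a P = 0 agent
  (WKY) traces never reach action selection, so overnight length cannot
  influence chamber behavior at all; the WKY preset consequently sits at
  ceiling (≈100% avoidance) through most of extinction at R_shock = −4,
  and inter-session-interval effects on WKY asymptote do not emerge.
  Contrasts that need WKY headroom (shock-intensity effects on late
  extinction, ISI effects on WKY session-12 performance) are therefore
  compressed relative to the patterns reported for rats.
- The warm-up difference score (trial 2 − trial 1 avoidance indicator,
  averaged over a 3-session window) is coarse: with 10 runs its SEM is
  ~0.1, so real but modest effects (e.g. at the 30-min interval,
  mean ≈ +0.16) are not reliably more than 2 SEM from zero.  The
  `block_edges` scoring mode (last two trials of the preceding session vs
  first two of the current, positive = warm-up) is provided for the
  empirical analysis convention.
- Sub-timestep shock timing (0.5-s shocks every 3 s) is not modeled; shock
  is simply present at every shock-period timestep.
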