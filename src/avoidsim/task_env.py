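"""Signaled lever-press avoidance task: trials, sessions, overnight periods.

The task timeline mirrors the canonical rat paradigm at a 10-s timestep
resolution.  Each trial is warning (W, 6 steps) -> shock (W+U, 30 steps) ->
ITI (safety signal S, 18 steps), 54 steps in all.  A press during the
warning period is an avoidance (cancels the shock period entirely); a press
during the shock period is an escape; either jumps the trial straight to the
ITI.  Sessions open with a short stimulus-free pre-period and hold 20
trials; between sessions an 18,000-step "overnight" period runs in the home
cage context with the lever unavailable.  Extinction sessions are identical
to acquisition except that the shock never occurs.

All stretches of constant input are executed by the compiled kernel in
:mod:`avoidsim._kernels`; a pure-Python path (used when a scripted policy is
injected, and by the equivalence tests) reproduces the same semantics from
the :mod:`avoidsim.rl_core` operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels
from .rl_core import (
    LEVER_PRESS,
    AgentState,
    InputVector,
    ModelParams,
    action_values,
    learning_step,
    select_action,
)

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "SessionRecord",
    "RunResult",
    "encode_inputs",
    "run_trial",
    "run_session",
    "run_intersession",
    "run_experiment",
    "ACQUISITION",
    "EXTINCTION",
]

logger = logging.getLogger("avoidsim")

ACQUISITION = "acquisition"
EXTINCTION = "extinction"

#: A policy stub maps (phase_tag, within-trial or within-segment timestep)
#: to an action index, overriding softmax selection.  Used for scripted tests.
Policy = Callable[[str, int], int]


@dataclass(frozen=True)
class TaskConfig:
    """Schedule parameters of the avoidance task, in 10-s timesteps.

    Defaults reproduce the standard paradigm: 54-step trials
    (6 warning + 30 shock + 18 ITI), 20 trials per session, a 6-step
    pre-period, 12 acquisition + 12 extinction sessions, and an
    18,000-step inter-session (overnight) period, corresponding to
    alternate-day training.
    """

    warning_len: int = 6
    shock_len: int = 30
    iti_len: int = 18
    pre_len: int = 6
    trials_per_session: int = 20
    n_acq_sessions: int = 12
    n_ext_sessions: int = 12
    intersession_len: int = 18000
    round_the_clock: bool = False
    lever_available_between: bool = False
    timestep_seconds: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "shock_len",
            "iti_len",
            "pre_len",
            "trials_per_session",
            "n_acq_sessions",
            "n_ext_sessions",
            "intersession_len",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.warning_len < 1:
            raise ValueError("warning_len must be >= 1")

    @property
    def trial_len(self) -> int:
        """Full (untruncated) trial length; 54 under the defaults."""
        return self.warning_len + self.shock_len + self.iti_len

    def replace(self, **changes) -> "TaskConfig":
        return replace(self, **changes)


@dataclass
class TrialRecord:
    """Outcome of one trial.

    ``latency`` counts timesteps from warning onset to the first press
    (0-based), defaulting to the configured full trial length when no press
    occurs anywhere in the trial.  ``outcome`` reflects the first press
    only: ``avoid`` if it fell in the warning period, ``escape`` if in the
    shock period, ``none`` otherwise (ITI press or no press).
    """

    session: int
    trial: int
    outcome: str
    latency: int
    press_times: list[int]
    trial_length: int


@dataclass
class SessionRecord:
    session: int
    phase: str
    trials: list[TrialRecord]
    anticipatory_presses: int


@dataclass
class RunResult:
    run: int
    seed: int
    sessions: list[SessionRecord]
    final_state: Optional[AgentState] = None


_PHASE_TABLE = {
    "pre": (0, 0, 0, 1, 0),
    "warning": (1, 0, 0, 1, 0),
    "shock": (1, 0, 1, 1, 0),
    "iti": (0, 1, 0, 1, 0),
}


def encode_inputs(phase_tag: str, config: TaskConfig) -> InputVector:
    """Binary input pattern (W, S, U, ctx_chamber, ctx_home) for a task phase.

    The inter-session period presents the home-cage context alone, unless
    ``round_the_clock`` housing keeps the animal in the chamber context.
    """
    if phase_tag == "intersession":
        if config.round_the_clock:
            return InputVector(0, 0, 0, 1, 0)
        return InputVector(0, 0, 0, 0, 1)
    try:
        return InputVector(*_PHASE_TABLE[phase_tag])
    except KeyError:
        raise ValueError(f"unknown phase tag {phase_tag!r}") from None


def _run_segment(
    agent: AgentState,
    params: ModelParams,
    *,
    inputs: np.ndarray,
    inputs_end: np.ndarray,
    inputs_press: np.ndarray,
    shock_within: bool,
    shock_at_end: bool,
    press_allowed: bool,
    stop_on_press: bool,
    n_steps: int,
    rng: np.random.Generator,
    policy: Optional[Policy] = None,
    tag: str = "",
    t_offset: int = 0,
) -> tuple[int, int, list[int]]:
    """Advance the agent through one constant-input stretch.

    Draws exactly ``n_steps`` uniforms from ``rng`` regardless of truncation
    so that the stream position is independent of behavior within the
    segment.  Returns (steps executed, first press step or -1, press steps).
    """
    if n_steps == 0:
        return 0, -1, []
    uniforms = rng.random(n_steps)
    if policy is None:
        press_flags = np.zeros(n_steps, dtype=np.uint8)
        steps, first, _n, v_prev = _kernels.run_segment(
            agent.m,
            agent.c,
            agent.v,
            agent.v_prev,
            inputs,
            inputs_end,
            inputs_press,
            shock_within,
            shock_at_end,
            press_allowed,
            stop_on_press,
            LEVER_PRESS,
            params.alpha,
            params.epsilon,
            params.temperature,
            params.persev,
            params.gamma,
            params.r_shock,
            params.r_press,
            params.trace_decay,
            params.trace_active_only,
            uniforms,
            press_flags,
            n_steps,
        )
        agent.v_prev = v_prev
        press_steps = np.flatnonzero(press_flags[:steps]).tolist()
        return steps, first, press_steps

    # Reference path built from the rl_core operations (scripted policies,
    # kernel-equivalence tests).
    allowed = [a for a in range(params.n_actions) if press_allowed or a != LEVER_PRESS]
    press_steps: list[int] = []
    first = -1
    steps = 0
    for t in range(n_steps):
        M = action_values(agent, inputs, params)
        if policy is _SOFTMAX:
            r = select_action(M, params, allowed, u=float(uniforms[t]))
        else:
            r = int(policy(tag, t_offset + t))
        press = press_allowed and r == LEVER_PRESS
        if press and stop_on_press:
            nxt, shock_next = inputs_press, False
        elif t == n_steps - 1:
            nxt, shock_next = inputs_end, shock_at_end
        else:
            nxt, shock_next = inputs, shock_within
        learning_step(agent, inputs, nxt, r, press, shock_next, params)
        steps += 1
        if press:
            press_steps.append(t)
            if first < 0:
                first = t
            if stop_on_press:
                break
    return steps, first, press_steps


def _softmax_sentinel(tag: str, t: int) -> int:  # pragma: no cover
    raise RuntimeError("sentinel policy; never called")


#: Sentinel selecting the ordinary softmax policy but forcing the
#: pure-Python execution path (for kernel-equivalence testing).
_SOFTMAX: Policy = _softmax_sentinel


def run_trial(
    agent: AgentState,
    params: ModelParams,
    config: TaskConfig,
    phase: str,
    rng: np.random.Generator,
    *,
    next_inputs: Optional[np.ndarray] = None,
    policy: Optional[Policy] = None,
    session: int = 1,
    trial: int = 1,
) -> tuple[AgentState, TrialRecord]:
    """Run one trial, mutating the agent in place.

    A press during the warning period scores an avoidance and jumps directly
    to the ITI (no shock-period timesteps occur at all); a press during the
    shock period scores an escape and likewise truncates to the ITI.  In
    extinction the timeline is identical but the shock input never appears:
    W stays on for warning_len + shock_len steps unless terminated by a
    press, and only presses within the warning period count as avoidance.

    ``next_inputs`` is the input pattern of the timestep that follows the
    trial's final ITI step (the next trial's warning signal, or the
    overnight period after the session's last trial).
    """
    acq = phase == ACQUISITION
    w_arr = encode_inputs("warning", config).as_array()
    iti_arr = encode_inputs("iti", config).as_array()
    shock_arr = encode_inputs("shock", config).as_array() if acq else w_arr
    end_arr = iti_arr if next_inputs is None else next_inputs

    press_times: list[int] = []
    outcome = "none"
    latency: Optional[int] = None

    steps, first, _ = _run_segment(
        agent,
        params,
        inputs=w_arr,
        inputs_end=shock_arr,
        inputs_press=iti_arr,
        shock_within=False,
        shock_at_end=acq,
        press_allowed=True,
        stop_on_press=True,
        n_steps=config.warning_len,
        rng=rng,
        policy=policy,
        tag="warning",
        t_offset=0,
    )
    elapsed = steps
    if first >= 0:
        outcome = "avoid"
        latency = first
        press_times.append(first)
    else:
        steps2, first2, _ = _run_segment(
            agent,
            params,
            inputs=shock_arr,
            inputs_end=iti_arr,
            inputs_press=iti_arr,
            shock_within=acq,
            shock_at_end=False,
            press_allowed=True,
            stop_on_press=True,
            n_steps=config.shock_len,
            rng=rng,
            policy=policy,
            tag="shock",
            t_offset=config.warning_len,
        )
        elapsed += steps2
        if first2 >= 0:
            outcome = "escape"
            latency = config.warning_len + first2
            press_times.append(latency)

    steps3, _first3, iti_presses = _run_segment(
        agent,
        params,
        inputs=iti_arr,
        inputs_end=end_arr,
        inputs_press=iti_arr,
        shock_within=False,
        shock_at_end=False,
        press_allowed=True,
        stop_on_press=False,
        n_steps=config.iti_len,
        rng=rng,
        policy=policy,
        tag="iti",
        t_offset=elapsed,
    )
    iti_press_times = [elapsed + k for k in iti_presses]
    press_times.extend(iti_press_times)
    elapsed += steps3

    if latency is None:
        latency = iti_press_times[0] if iti_press_times else config.trial_len

    record = TrialRecord(
        session=session,
        trial=trial,
        outcome=outcome,
        latency=latency,
        press_times=press_times,
        trial_length=elapsed,
    )
    return agent, record


def run_session(
    agent: AgentState,
    params: ModelParams,
    config: TaskConfig,
    phase: str,
    rng: np.random.Generator,
    *,
    session: int = 1,
    after_inputs: Optional[np.ndarray] = None,
    policy: Optional[Policy] = None,
) -> tuple[AgentState, SessionRecord]:
    """Run one session: pre-period (anticipatory presses counted) then trials.

    ``after_inputs`` is the input pattern following the session's last
    timestep (normally the overnight period).
    """
    pre_arr = encode_inputs("pre", config).as_array()
    w_arr = encode_inputs("warning", config).as_array()
    if config.trials_per_session > 0:
        pre_end = w_arr
    elif after_inputs is not None:
        pre_end = after_inputs
    else:
        pre_end = pre_arr

    _steps, _first, pre_presses = _run_segment(
        agent,
        params,
        inputs=pre_arr,
        inputs_end=pre_end,
        inputs_press=pre_arr,
        shock_within=False,
        shock_at_end=False,
        press_allowed=True,
        stop_on_press=False,
        n_steps=config.pre_len,
        rng=rng,
        policy=policy,
        tag="pre",
        t_offset=0,
    )

    trials: list[TrialRecord] = []
    for k in range(1, config.trials_per_session + 1):
        nxt = w_arr if k < config.trials_per_session else after_inputs
        agent, rec = run_trial(
            agent,
            params,
            config,
            phase,
            rng,
            next_inputs=nxt,
            policy=policy,
            session=session,
            trial=k,
        )
        trials.append(rec)

    record = SessionRecord(
        session=session,
        phase=phase,
        trials=trials,
        anticipatory_presses=len(pre_presses),
    )
    return agent, record


def run_intersession(
    agent: AgentState,
    params: ModelParams,
    config: TaskConfig,
    rng: np.random.Generator,
    *,
    after_inputs: Optional[np.ndarray] = None,
    policy: Optional[Policy] = None,
) -> tuple[AgentState, int]:
    """Run the overnight period; returns the agent and the press count.

    The home-cage context is the sole input (chamber context instead under
    round-the-clock housing) and the lever press is removed from the allowed
    action set unless ``lever_available_between`` is set, so reinforcement
    is 0 throughout; learning still runs (value decay toward the unsignaled
    context, trace turnover from home-cage behaviors).
    """
    inter_arr = encode_inputs("intersession", config).as_array()
    end_arr = inter_arr if after_inputs is None else after_inputs
    _steps, _first, presses = _run_segment(
        agent,
        params,
        inputs=inter_arr,
        inputs_end=end_arr,
        inputs_press=inter_arr,
        shock_within=False,
        shock_at_end=False,
        press_allowed=config.lever_available_between,
        stop_on_press=False,
        n_steps=config.intersession_len,
        rng=rng,
        policy=policy,
        tag="intersession",
        t_offset=0,
    )
    return agent, len(presses)


def run_experiment(
    params: ModelParams,
    config: TaskConfig,
    seed: int,
    *,
    run: int = 0,
    keep_state: bool = False,
    policy: Optional[Policy] = None,
) -> RunResult:
    """Run a full acquisition + extinction experiment for one agent.

    A fresh agent (m at m_init, v and c at 0) runs ``n_acq_sessions``
    acquisition sessions followed by ``n_ext_sessions`` extinction sessions,
    with an overnight period between every pair of consecutive sessions
    (including the acquisition-to-extinction boundary).  Fully deterministic
    given (params, config, seed).
    """
    rng = np.random.default_rng(seed)
    agent = AgentState.fresh(params)

    phases = [ACQUISITION] * config.n_acq_sessions + [EXTINCTION] * config.n_ext_sessions
    n_sessions = len(phases)

    inter_arr = encode_inputs("intersession", config).as_array()
    pre_arr = encode_inputs("pre", config).as_array()
    w_arr = encode_inputs("warning", config).as_array()
    session_start = pre_arr if config.pre_len > 0 else w_arr

    sessions: list[SessionRecord] = []
    for s_idx, phase in enumerate(phases):
        last = s_idx == n_sessions - 1
        if last:
            after = None
        elif config.intersession_len > 0:
            after = inter_arr
        else:
            after = session_start
        agent, rec = run_session(
            agent,
            params,
            config,
            phase,
            rng,
            session=s_idx + 1,
            after_inputs=after,
            policy=policy,
        )
        sessions.append(rec)
        n_avoid = sum(1 for t in rec.trials if t.outcome == "avoid")
        logger.info(
            "run %d session %d (%s): %d/%d avoidance",
            run,
            s_idx + 1,
            phase,
            n_avoid,
            len(rec.trials),
        )
        if not last:
            agent, _ = run_intersession(
                agent, params, config, rng, after_inputs=session_start, policy=policy
            )

    return RunResult(
        run=run,
        seed=seed,
        sessions=sessions,
        final_state=agent if keep_state else None,
    )
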