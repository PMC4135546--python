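"""Actor-critic core: action values, softmax selection, reinforcement, TD learning.

The agent is a linear actor-critic. At every 10-s timestep the actor picks one
of ``n_actions`` candidate behaviors (one arbitrarily designated as the lever
press) by a softmax over action values

    M_a = sum_i m[a][i] * I_i  +  P * c[a][i]

where ``I`` is the binary stimulus/context input vector, ``m`` the actor
weights, ``c`` a decaying perseveration trace of recently executed actions,
and ``P`` a perseveration factor.  Note that the trace term is *not* gated by
the current inputs: traces laid down in one context keep biasing selection
after a context switch, which is what lets perseveration carry over from the
home cage into the conditioning chamber (the warm-up mechanism).

The critic learns a linear value function V = sum_i v[i] * I_i trained by the
temporal-difference error

    PE = R + gamma * V(t+1) - V(t)

which also trains the actor weights of the executed action.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "N_INPUTS",
    "IDX_W",
    "IDX_S",
    "IDX_U",
    "IDX_CTX_CHAMBER",
    "IDX_CTX_HOME",
    "LEVER_PRESS",
    "ModelParams",
    "InputVector",
    "AgentState",
    "action_values",
    "select_action",
    "reinforcement_signal",
    "state_value",
    "prediction_error",
    "update_critic",
    "update_actor",
    "update_trace",
    "learning_step",
]

#: Input layout: warning signal W, safety/ITI signal S, shock U, and a one-hot
#: context pair (conditioning chamber vs home cage).
N_INPUTS = 5
IDX_W, IDX_S, IDX_U, IDX_CTX_CHAMBER, IDX_CTX_HOME = range(N_INPUTS)

#: Action index arbitrarily designated as the lever press.
LEVER_PRESS = 0


@dataclass(frozen=True)
class ModelParams:
    """Free and fixed parameters of the actor-critic agent.

    Defaults are the Sprague-Dawley (SD) preset.  The Wistar Kyoto (WKY)
    preset differs in ``alpha`` (0.005), ``temperature`` (0.25) and
    ``persev`` (0).

    Parameters
    ----------
    alpha
        Critic learning rate (dimensionless, in (0, 1)).
    epsilon
        Actor learning rate (dimensionless, in (0, 1)).
    temperature
        Explore/exploit parameter T of the softmax; lower values make
        selection more exploitative.
    persev
        Perseveration factor P weighting the action trace; negative values
        would produce spontaneous alternation.
    gamma
        Temporal-discount factor of the TD error (fixed at 0.9).
    r_shock
        Reinforcement delivered when shock is present at the next timestep
        (large negative; -8 models a doubled shock amplitude).
    r_press
        Cost of executing a lever press (small negative).
    n_actions
        Number of candidate actions A available to the actor.
    m_init
        Initial value of every actor weight.
    trace_decay
        Per-timestep multiplier applied to traces of non-executed actions.
    trace_active_only
        If True, an executed action's trace is set to 1 only for inputs
        active at execution time (its other entries decay); the default
        refreshes the full row.
    """

    alpha: float = 0.05
    epsilon: float = 0.005
    temperature: float = 1.0
    persev: float = 0.25
    gamma: float = 0.9
    r_shock: float = -4.0
    r_press: float = -0.2
    n_actions: int = 100
    m_init: float = 0.01
    trace_decay: float = 0.95
    trace_active_only: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError(f"epsilon must be in (0, 1), got {self.epsilon}")
        if not self.temperature > 0.0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if not (0.0 < self.trace_decay < 1.0):
            raise ValueError(f"trace_decay must be in (0, 1), got {self.trace_decay}")
        if not (self.r_shock < self.r_press < 0.0):
            raise ValueError(
                f"need r_shock < r_press < 0, got r_shock={self.r_shock}, "
                f"r_press={self.r_press}"
            )
        if self.n_actions < 2:
            raise ValueError(f"n_actions must be >= 2, got {self.n_actions}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields changed (validated)."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class InputVector:
    """Binary stimulus/context pattern presented to actor and critic.

    Exactly one of the two context units is on; shock (``u``) only ever
    occurs while the warning signal (``w``) is on.
    """

    w: int
    s: int
    u: int
    ctx_chamber: int
    ctx_home: int

    def __post_init__(self) -> None:
        for name in ("w", "s", "u", "ctx_chamber", "ctx_home"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"input component {name!r} must be 0 or 1")
        if self.ctx_chamber + self.ctx_home != 1:
            raise ValueError("exactly one context unit must be active")
        if self.u == 1 and self.w != 1:
            raise ValueError("shock input requires the warning signal to be on")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.w, self.s, self.u, self.ctx_chamber, self.ctx_home],
            dtype=np.float64,
        )


def _as_input_array(inputs) -> np.ndarray:
    if isinstance(inputs, InputVector):
        return inputs.as_array()
    arr = np.asarray(inputs, dtype=np.float64)
    if arr.shape != (N_INPUTS,):
        raise ValueError(f"input vector must have shape ({N_INPUTS},), got {arr.shape}")
    return arr


@dataclass
class AgentState:
    """Mutable learning state: actor weights, traces, critic weights.

    ``v_prev`` holds V', the value prediction computed at the previous
    timestep, so that the TD error can bridge the state transition.
    """

    m: np.ndarray
    c: np.ndarray
    v: np.ndarray
    v_prev: float = 0.0

    @classmethod
    def fresh(cls, params: ModelParams) -> "AgentState":
        """A naive agent: m at ``m_init`` everywhere, traces and critic at 0."""
        return cls(
            m=np.full((params.n_actions, N_INPUTS), params.m_init, dtype=np.float64),
            c=np.zeros((params.n_actions, N_INPUTS), dtype=np.float64),
            v=np.zeros(N_INPUTS, dtype=np.float64),
            v_prev=0.0,
        )

    def copy(self) -> "AgentState":
        return AgentState(self.m.copy(), self.c.copy(), self.v.copy(), self.v_prev)

    def check_dims(self, params: ModelParams) -> None:
        if self.m.shape != (params.n_actions, N_INPUTS):
            raise ValueError(
                f"actor weight matrix has shape {self.m.shape}, expected "
                f"({params.n_actions}, {N_INPUTS})"
            )
        if self.c.shape != self.m.shape:
            raise ValueError("trace matrix shape differs from actor weight matrix")
        if self.v.shape != (N_INPUTS,):
            raise ValueError(f"critic weight vector has shape {self.v.shape}")


def action_values(state: AgentState, inputs, params: ModelParams) -> np.ndarray:
    """Compute M_a = sum_i m[a][i]*I_i + P*c[a][i] for every action.

    The perseveration term sums the trace over *all* inputs regardless of
    which are currently active, so recently executed actions stay favored
    across a context change.
    """
    state.check_dims(params)
    arr = _as_input_array(inputs)
    return state.m @ arr + params.persev * state.c.sum(axis=1)


def select_action(
    M: np.ndarray,
    params: ModelParams,
    allowed: Iterable[int],
    rng: Optional[np.random.Generator] = None,
    *,
    u: Optional[float] = None,
) -> int:
    """Sample an action from the softmax Pr(r) = exp(M_r/T) / sum_a exp(M_a/T).

    Normalization runs over ``allowed`` only.  Computed with a
    shift-by-maximum so arbitrarily large |M|/T stays finite.  ``u`` may
    supply the uniform variate directly (used to share a pre-drawn stream
    with the compiled simulation kernel); otherwise it is drawn from ``rng``.
    """
    idx = np.asarray(sorted(set(int(a) for a in allowed)), dtype=np.intp)
    if idx.size == 0:
        raise ValueError("allowed action set is empty: misconfigured environment")
    if idx.min() < 0 or idx.max() >= len(M):
        raise ValueError("allowed action index out of range")
    if u is None:
        if rng is None:
            raise ValueError("either rng or u must be provided")
        u = float(rng.random())
    scores = np.asarray(M, dtype=np.float64)[idx] / params.temperature
    z = np.exp(scores - scores.max())
    total = z.sum()
    # Walk the cumulative mass exactly as the compiled kernel does.
    threshold = u * total
    acc = 0.0
    for pos, weight in enumerate(z):
        acc += weight
        if acc > threshold:
            return int(idx[pos])
    return int(idx[-1])


def selection_probabilities(
    M: np.ndarray, params: ModelParams, allowed: Iterable[int]
) -> np.ndarray:
    """Softmax probabilities over the full action vector (zero if disallowed)."""
    idx = np.asarray(sorted(set(int(a) for a in allowed)), dtype=np.intp)
    if idx.size == 0:
        raise ValueError("allowed action set is empty: misconfigured environment")
    scores = np.asarray(M, dtype=np.float64)[idx] / params.temperature
    z = np.exp(scores - scores.max())
    out = np.zeros(len(M), dtype=np.float64)
    out[idx] = z / z.sum()
    return out


def reinforcement_signal(
    action_was_press: bool, shock_present_next: bool, params: ModelParams
) -> float:
    """Reinforcement R for the transition just taken.

    Shock presence is evaluated *after* the environment applied the action's
    consequences, so an avoidance or escape press never collects the shock
    cost: R = r_shock if shock is present at t+1, else r_press if the action
    was a lever press, else 0.  The two costs never sum.
    """
    if shock_present_next:
        return float(params.r_shock)
    if action_was_press:
        return float(params.r_press)
    return 0.0


def state_value(state: AgentState, inputs) -> float:
    """Critic prediction V = sum_i v[i] * I_i."""
    return float(state.v @ _as_input_array(inputs))


def prediction_error(R: float, V_new: float, V_prev: float, params: ModelParams) -> float:
    """TD error PE = R + gamma * V_new - V_prev."""
    return float(R + params.gamma * V_new - V_prev)


def update_critic(
    state: AgentState, PE: float, inputs_prev, params: ModelParams
) -> AgentState:
    """Apply dv[i] = alpha * PE * I_i to the pre-transition inputs, clipped.

    Critic weights are clipped at +/-|r_shock| to keep value predictions
    bounded by the largest reinforcement magnitude.  Mutates in place and
    returns the state.
    """
    arr = _as_input_array(inputs_prev)
    bound = abs(params.r_shock)
    active = arr != 0.0
    state.v[active] = np.clip(
        state.v[active] + params.alpha * PE * arr[active], -bound, bound
    )
    return state


def update_actor(
    state: AgentState, action: int, PE: float, inputs_prev, params: ModelParams
) -> AgentState:
    """Apply dm[r][i] = epsilon * (PE - m[r][i]) * I_i to the executed action.

    Actor weights are floored at 0.  Only the executed action's row changes.
    Mutates in place and returns the state.
    """
    arr = _as_input_array(inputs_prev)
    row = state.m[action]
    active = arr != 0.0
    row[active] = np.maximum(
        0.0, row[active] + params.epsilon * (PE - row[active]) * arr[active]
    )
    return state


def update_trace(
    state: AgentState, action: int, params: ModelParams, inputs=None
) -> AgentState:
    """Refresh the executed action's trace to 1; decay all other rows by 0.95.

    With ``trace_active_only`` set, only the executed action's currently
    active input entries are refreshed (the rest of its row decays), which
    requires ``inputs``.  Mutates in place and returns the state.
    """
    decay_mask = np.ones(len(state.c), dtype=bool)
    decay_mask[action] = False
    state.c[decay_mask] *= params.trace_decay
    if params.trace_active_only:
        if inputs is None:
            raise ValueError("trace_active_only requires the current inputs")
        arr = _as_input_array(inputs)
        row = state.c[action]
        row[arr != 0.0] = 1.0
        row[arr == 0.0] *= params.trace_decay
    else:
        state.c[action] = 1.0
    return state


def learning_step(
    state: AgentState,
    inputs_t,
    inputs_next,
    action: int,
    action_was_press: bool,
    shock_present_next: bool,
    params: ModelParams,
) -> tuple[AgentState, float, float]:
    """One full TD(0) learning step after the action has been executed.

    Bookkeeping: R is assigned from the post-transition shock state; the TD
    error PE = R + gamma*V(I(t+1)) - V' corrects the value of the
    pre-transition inputs I(t), so critic and actor updates both use I(t);
    the trace is then refreshed for the executed action and V' advances.

    Returns ``(state, PE, R)``; the state is mutated in place.
    """
    R = reinforcement_signal(action_was_press, shock_present_next, params)
    V_new = state_value(state, inputs_next)
    PE = prediction_error(R, V_new, state.v_prev, params)
    update_critic(state, PE, inputs_t, params)
    update_actor(state, action, PE, inputs_t, params)
    update_trace(state, action, params, inputs=inputs_t)
    state.v_prev = V_new
    return state, PE, R
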