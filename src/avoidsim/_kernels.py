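"""Compiled inner loop for constant-input simulation segments.

Every stretch of the task (pre-period, warning, shock, ITI, overnight) is a
run of timesteps with a fixed input pattern and a fixed allowed-action set;
``run_segment`` advances the agent through one such stretch.  The Python
layer in :mod:`avoidsim.task_env` handles the transitions between segments.

Semantics are defined by :mod:`avoidsim.rl_core`; the test suite pins this
kernel to the pure-Python operations on identical uniform streams.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_segment(
    m,  # (A, n_in) actor weights, mutated
    c,  # (A, n_in) perseveration traces, mutated
    v,  # (n_in,) critic weights, mutated
    v_prev,  # float: V' carried in from the previous timestep
    inputs,  # (n_in,) inputs active throughout the segment
    inputs_end,  # (n_in,) inputs of the step after the segment's last step
    inputs_press,  # (n_in,) inputs following a truncating press (ITI)
    shock_within,  # bool: shock present at t+1 for a mid-segment non-press
    shock_at_end,  # bool: shock present at t+1 after the segment's last step
    press_allowed,  # bool: lever press in the allowed action set
    stop_on_press,  # bool: a press ends the segment (warning/shock periods)
    lever,  # int: lever-press action index
    alpha,
    epsilon,
    temperature,
    persev,
    gamma,
    r_shock,
    r_press,
    trace_decay,
    trace_active_only,
    uniforms,  # (n_steps,) pre-drawn uniforms, one per potential step
    press_flags,  # (n_steps,) uint8 out-buffer, 1 where a press occurred
    n_steps,
):
    """Advance up to ``n_steps`` timesteps; returns
    ``(steps_done, first_press_step, n_presses, v_prev)``.
    """
    n_actions, n_inputs = m.shape
    bound = abs(r_shock)
    z = np.empty(n_actions, dtype=np.float64)
    csum = np.empty(n_actions, dtype=np.float64)
    for a in range(n_actions):
        s = 0.0
        for i in range(n_inputs):
            s += c[a, i]
        csum[a] = s

    steps = 0
    first_press = -1
    n_presses = 0
    for t in range(n_steps):
        # Action values and softmax over the allowed set (max-shifted).
        mmax = -np.inf
        for a in range(n_actions):
            if a == lever and not press_allowed:
                continue
            acc = persev * csum[a]
            for i in range(n_inputs):
                acc += m[a, i] * inputs[i]
            score = acc / temperature
            z[a] = score
            if score > mmax:
                mmax = score
        total = 0.0
        for a in range(n_actions):
            if a == lever and not press_allowed:
                z[a] = 0.0
            else:
                z[a] = np.exp(z[a] - mmax)
                total += z[a]

        # Sample by walking the cumulative mass.
        threshold = uniforms[t] * total
        acc = 0.0
        r = -1
        for a in range(n_actions):
            if a == lever and not press_allowed:
                continue
            acc += z[a]
            r = a
            if acc > threshold:
                break

        press = press_allowed and (r == lever)

        # Environment consequence: what inputs (and shock) follow this step.
        if press and stop_on_press:
            nxt = inputs_press
            shock_next = False
        elif t == n_steps - 1:
            nxt = inputs_end
            shock_next = shock_at_end
        else:
            nxt = inputs
            shock_next = shock_within

        if shock_next:
            R = r_shock
        elif press:
            R = r_press
        else:
            R = 0.0

        V_new = 0.0
        for i in range(n_inputs):
            V_new += v[i] * nxt[i]
        pe = R + gamma * V_new - v_prev

        # Critic update on the pre-transition inputs, clipped at +/-|r_shock|.
        for i in range(n_inputs):
            if inputs[i] != 0.0:
                nv = v[i] + alpha * pe * inputs[i]
                if nv > bound:
                    nv = bound
                elif nv < -bound:
                    nv = -bound
                v[i] = nv

        # Actor update for the executed action only, floored at 0.
        for i in range(n_inputs):
            if inputs[i] != 0.0:
                nm = m[r, i] + epsilon * (pe - m[r, i]) * inputs[i]
                m[r, i] = nm if nm > 0.0 else 0.0

        # Trace turnover: decay every non-executed row, refresh the executed one.
        for a in range(n_actions):
            if a != r:
                for i in range(n_inputs):
                    c[a, i] *= trace_decay
                csum[a] *= trace_decay
        if trace_active_only:
            srow = 0.0
            for i in range(n_inputs):
                if inputs[i] != 0.0:
                    c[r, i] = 1.0
                else:
                    c[r, i] *= trace_decay
                srow += c[r, i]
            csum[r] = srow
        else:
            for i in range(n_inputs):
                c[r, i] = 1.0
            csum[r] = float(n_inputs)

        v_prev = V_new
        steps += 1
        if press:
            press_flags[t] = 1
            n_presses += 1
            if first_press < 0:
                first_press = t
            if stop_on_press:
                break

    return steps, first_press, n_presses, v_prev
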