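"""Unit and property tests for the actor-critic mathematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avoidsim.rl_core import (
    LEVER_PRESS,
    N_INPUTS,
    AgentState,
    InputVector,
    ModelParams,
    action_values,
    learning_step,
    prediction_error,
    reinforcement_signal,
    select_action,
    selection_probabilities,
    state_value,
    update_actor,
    update_critic,
    update_trace,
)

SD = ModelParams()
WARNING = InputVector(1, 0, 0, 1, 0)
SHOCK = InputVector(1, 0, 1, 1, 0)
ITI = InputVector(0, 1, 0, 1, 0)


def small_state(params, m=None, c=None, v=None):
    state = AgentState.fresh(params)
    if m is not None:
        state.m[:] = m
    if c is not None:
        state.c[:] = c
    if v is not None:
        state.v[:] = v
    return state


class TestParamsAndInputs:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(alpha=0.0),
            dict(alpha=1.5),
            dict(epsilon=0.0),
            dict(temperature=0.0),
            dict(trace_decay=1.0),
            dict(r_shock=-0.1),  # violates r_shock < r_press
            dict(r_press=0.1),
            dict(n_actions=1),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    @pytest.mark.parametrize(
        "bad",
        [
            (2, 0, 0, 1, 0),  # non-binary
            (1, 0, 0, 1, 1),  # two contexts
            (1, 0, 0, 0, 0),  # no context
            (0, 0, 1, 1, 0),  # shock without warning
        ],
    )
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            InputVector(*bad)


class TestActionValues:
    def test_symmetric_initialization(self):
        state = AgentState.fresh(SD)
        M = action_values(state, InputVector(0, 0, 0, 1, 0), SD)
        assert np.allclose(M, 0.01)

    def test_persev_zero_ignores_trace(self):
        params = SD.replace(persev=0.0)
        rng = np.random.default_rng(3)
        state = small_state(params, c=rng.random((params.n_actions, N_INPUTS)))
        with_c = action_values(state, WARNING, params)
        state.c[:] = 0.0
        without_c = action_values(state, WARNING, params)
        assert np.array_equal(with_c, without_c)

    def test_trace_term_ungated_by_inputs(self):
        # trace on a single action over all 5 inputs contributes P * 5
        state = small_state(SD, m=0.0)
        state.c[7, :] = 1.0
        M = action_values(state, WARNING, SD)
        assert M[7] == pytest.approx(1.25, abs=1e-15)
        mask = np.ones(SD.n_actions, bool)
        mask[7] = False
        assert np.all(M[mask] == 0.0)


class TestSelectAction:
    def test_uniform_at_equal_values(self):
        M = np.zeros(100)
        p = selection_probabilities(M, SD, range(100))
        assert np.allclose(p, 0.01)

    @pytest.mark.parametrize(
        "temperature,expected",
        [(1.0, np.e / (np.e + 1.0)), (0.25, np.exp(4) / (np.exp(4) + 1.0))],
    )
    def test_two_action_closed_form(self, temperature, expected):
        params = SD.replace(temperature=temperature)
        M = np.array([1.0, 0.0])
        p = selection_probabilities(M, params.replace(n_actions=2), [0, 1])
        assert p[0] == pytest.approx(expected, rel=1e-12)

    def test_normalization_restricted_to_allowed(self):
        M = np.array([100.0, 1.0, 0.0])
        p = selection_probabilities(M, SD.replace(n_actions=3), [1, 2])
        assert p[0] == 0.0
        assert p[1] + p[2] == pytest.approx(1.0, abs=1e-12)

    def test_numerically_stable_for_huge_values(self):
        M = np.array([5000.0, 4990.0])
        p = selection_probabilities(M, SD.replace(n_actions=2), [0, 1])
        assert np.all(np.isfinite(p))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_allowed_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_action(np.zeros(3), SD, [], np.random.default_rng(0))

    def test_sampling_matches_probabilities(self):
        rng = np.random.default_rng(11)
        params = SD.replace(n_actions=3)
        M = np.array([1.0, 0.5, -0.3])
        draws = np.array(
            [select_action(M, params, [0, 1, 2], rng) for _ in range(4000)]
        )
        freq = np.bincount(draws, minlength=3) / 4000
        p = selection_probabilities(M, params, [0, 1, 2])
        assert np.allclose(freq, p, atol=0.03)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 5.0))
    def test_probabilities_sum_to_one(self, seed, temperature):
        rng = np.random.default_rng(seed)
        M = rng.normal(0, 10, size=50)
        params = ModelParams(temperature=temperature, n_actions=50)
        allowed = rng.choice(50, size=rng.integers(1, 51), replace=False)
        p = selection_probabilities(M, params, allowed)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_lower_temperature_sharpens_argmax(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.normal(0, 1, size=20)
        M[rng.integers(20)] += 0.5  # ensure non-constant
        params_hi = ModelParams(n_actions=20, temperature=1.0)
        params_lo = ModelParams(n_actions=20, temperature=0.25)
        best = int(np.argmax(M))
        p_hi = selection_probabilities(M, params_hi, range(20))[best]
        p_lo = selection_probabilities(M, params_lo, range(20))[best]
        assert p_lo > p_hi


class TestReinforcement:
    def test_press_without_shock_costs_press(self):
        assert reinforcement_signal(True, False, SD) == -0.2

    def test_shock_dominates_and_costs_never_sum(self):
        assert reinforcement_signal(False, True, SD) == -4.0
        assert reinforcement_signal(True, True, SD) == -4.0

    def test_idle_step_is_free(self):
        assert reinforcement_signal(False, False, SD) == 0.0


class TestCritic:
    def test_state_value_inner_product(self):
        state = small_state(SD, v=np.array([-2.0, 0, 0, 0.5, 0]))
        assert state_value(state, WARNING) == pytest.approx(-1.5)
        state.v[:] = 0
        assert state_value(state, SHOCK) == 0.0

    def test_prediction_error_formula(self):
        assert prediction_error(0, 0, 0, SD) == 0.0
        assert prediction_error(-4, 0, -1, SD) == pytest.approx(-3.0)
        assert prediction_error(0, -2, 0, SD) == pytest.approx(-1.8)

    def test_update_applies_alpha_pe_on_active_inputs(self):
        state = small_state(SD)
        update_critic(state, -3.0, WARNING, SD)
        assert state.v[0] == pytest.approx(-0.15)
        assert state.v[3] == pytest.approx(-0.15)
        assert np.all(state.v[[1, 2, 4]] == 0.0)

    def test_clipping_at_shock_magnitude(self):
        state = small_state(SD, v=np.array([-3.9, 0, 0, 0, 0]))
        # PE chosen so the raw update (-0.2) would overshoot the bound
        update_critic(state, -4.0, InputVector(1, 0, 0, 1, 0), SD)
        assert state.v[0] == -4.0

    def test_zero_pe_is_identity(self):
        state = small_state(SD, v=np.array([0.3, -1, 0, 0.2, 0]))
        before = state.v.copy()
        update_critic(state, 0.0, WARNING, SD)
        assert np.array_equal(state.v, before)


class TestActor:
    def test_update_moves_toward_pe(self):
        state = small_state(SD)
        update_actor(state, 5, 2.0, InputVector(1, 0, 0, 1, 0), SD)
        assert state.m[5, 0] == pytest.approx(0.01 + 0.005 * 1.99)
        assert state.m[5, 1] == 0.01  # inactive input untouched
        assert np.all(state.m[4] == 0.01)  # other rows untouched

    def test_floor_at_zero(self):
        state = small_state(SD, m=0.001)
        update_actor(state, 0, -4.0, WARNING, SD)
        assert state.m[0, 0] == 0.0

    def test_trace_decay_and_refresh(self):
        state = small_state(SD)
        state.c[3, :] = 1.0
        update_trace(state, 5, SD)
        assert np.allclose(state.c[3], 0.95)
        assert np.all(state.c[5] == 1.0)
        for _ in range(13):
            update_trace(state, 5, SD)
        assert state.c[3, 0] == pytest.approx(0.95**14, rel=1e-12)

    def test_trace_active_only_variant(self):
        params = SD.replace(trace_active_only=True)
        state = small_state(params)
        update_trace(state, 2, params, inputs=WARNING)
        assert state.c[2, 0] == 1.0 and state.c[2, 3] == 1.0
        assert state.c[2, 1] == 0.0


def manual_episode():
    """Hand-transcribed scalar arithmetic for a scripted 5-step episode.

    Mimics a short trial: two warning steps (the second transitions into the
    shock period), an escape press, an ITI press, and an idle ITI step.
    Kept free of numpy and of the package's own operations.
    """
    A, N = 3, 5
    alpha, eps, gamma, decay = 0.05, 0.005, 0.9, 0.95
    r_shock, r_press = -4.0, -0.2
    W, SH, IT = (1, 0, 0, 1, 0), (1, 0, 1, 1, 0), (0, 1, 0, 1, 0)
    # (inputs, next inputs, action, was press, shock at t+1)
    script = [
        (W, W, 1, False, False),
        (W, SH, 2, False, True),
        (SH, IT, 0, True, False),
        (IT, IT, 0, True, False),
        (IT, W, 1, False, False),
    ]
    m = [[0.01] * N for _ in range(A)]
    c = [[0.0] * N for _ in range(A)]
    v = [0.0] * N
    v_prev = 0.0
    pes = []
    for inputs, nxt, a, press, shock in script:
        R = r_shock if shock else (r_press if press else 0.0)
        V_new = sum(v[i] * nxt[i] for i in range(N))
        pe = R + gamma * V_new - v_prev
        for i in range(N):
            if inputs[i]:
                x = v[i] + alpha * pe
                v[i] = max(-abs(r_shock), min(abs(r_shock), x))
        for i in range(N):
            if inputs[i]:
                m[a][i] = max(0.0, m[a][i] + eps * (pe - m[a][i]))
        for b in range(A):
            if b != a:
                for i in range(N):
                    c[b][i] *= decay
        for i in range(N):
            c[a][i] = 1.0
        v_prev = V_new
        pes.append(pe)
    return m, c, v, v_prev, pes


class TestCompositionOracle:
    def test_five_step_episode_matches_hand_computation(self):
        params = ModelParams(n_actions=3)
        state = AgentState.fresh(params)
        script = [
            (WARNING, WARNING, 1, False, False),
            (WARNING, SHOCK, 2, False, True),
            (SHOCK, ITI, 0, True, False),
            (ITI, ITI, 0, True, False),
            (ITI, WARNING, 1, False, False),
        ]
        pes = []
        for inputs, nxt, action, press, shock in script:
            _, pe, _ = learning_step(state, inputs, nxt, action, press, shock, params)
            pes.append(pe)
        m_exp, c_exp, v_exp, v_prev_exp, pes_exp = manual_episode()
        assert np.allclose(state.m, m_exp, atol=1e-12, rtol=0)
        assert np.allclose(state.c, c_exp, atol=1e-12, rtol=0)
        assert np.allclose(state.v, v_exp, atol=1e-12, rtol=0)
        assert state.v_prev == pytest.approx(v_prev_exp, abs=1e-12)
        assert np.allclose(pes, pes_exp, atol=1e-12, rtol=0)
        # spot values computable in one's head
        assert pes[0] == 0.0
        assert pes[1] == -4.0
        assert pes[2] == pytest.approx(-0.38, abs=1e-12)


class TestStateInvariants:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_hold_after_random_update_sequences(self, seed):
        rng = np.random.default_rng(seed)
        params = ModelParams(n_actions=8)
        state = AgentState.fresh(params)
        patterns = [WARNING, SHOCK, ITI, InputVector(0, 0, 0, 0, 1)]
        for _ in range(200):
            inputs = patterns[rng.integers(len(patterns))]
            nxt = patterns[rng.integers(len(patterns))]
            action = int(rng.integers(params.n_actions))
            press = bool(rng.integers(2))
            shock = bool(rng.integers(2))
            learning_step(state, inputs, nxt, action, press, shock, params)
            assert np.all(state.m >= 0.0)
            assert np.all(np.abs(state.v) <= abs(params.r_shock))
            assert np.all((state.c >= 0.0) & (state.c <= 1.0))

    def test_zero_critic_zero_reinforcement_is_fixed_point(self):
        params = ModelParams(n_actions=4)
        state = small_state(params, m=0.0)
        for t in range(50):
            _, pe, _ = learning_step(state, WARNING, WARNING, t % 4, False, False, params)
            assert pe == 0.0
        assert np.all(state.v == 0.0)
        assert np.all(state.m == 0.0)
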