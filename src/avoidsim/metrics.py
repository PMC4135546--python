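"""Behavioral dependent measures computed from raw run records.

All functions here are pure: they consume :class:`~avoidsim.task_env.RunResult`
objects and return numbers, never touching an RNG or the agent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .task_env import RunResult

__all__ = [
    "SessionBlockCurve",
    "percent_avoidance_by_session",
    "latency_by_session",
    "block_trial_curve",
    "warmup_score",
    "sem",
]


def sem(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Standard error of the mean (sample SD, n-1 denominator, over runs).

    A single run has no spread estimate; the SEM is reported as 0 with a
    warning.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.shape[axis]
    if n < 2:
        warnings.warn("SEM undefined for a single run; reporting 0", stacklevel=2)
        return np.zeros_like(values.mean(axis=axis))
    return values.std(axis=axis, ddof=1) / np.sqrt(n)


@dataclass(frozen=True)
class SessionBlockCurve:
    """Trial-by-trial avoidance proportions averaged over a 3-session block."""

    block: int
    sessions: tuple[int, ...]
    proportions: np.ndarray  # length trials_per_session, values in [0, 1]


def _avoid_matrix(run: RunResult) -> np.ndarray:
    """(n_sessions, trials_per_session) 0/1 avoidance indicators."""
    return np.array(
        [[1.0 if t.outcome == "avoid" else 0.0 for t in s.trials] for s in run.sessions]
    )


def percent_avoidance_by_session(run: RunResult) -> np.ndarray:
    """Per-session percentage of trials with an avoidance response."""
    if not run.sessions:
        raise ValueError("run contains no sessions")
    return np.array(
        [
            100.0 * sum(1 for t in s.trials if t.outcome == "avoid") / len(s.trials)
            for s in run.sessions
        ]
    )


def latency_by_session(run: RunResult) -> np.ndarray:
    """Per-session mean first-press latency in timesteps.

    Trials without any press contribute the configured full trial length
    (54 under the defaults).
    """
    return np.array([np.mean([t.latency for t in s.trials]) for s in run.sessions])


def block_trial_curve(
    runs: Sequence[RunResult], block_size: int = 3
) -> list[SessionBlockCurve]:
    """Within-session avoidance curves averaged over blocks of sessions.

    For each block of ``block_size`` consecutive sessions and each trial
    position, the proportion of (run x session) observations with an
    avoidance response.  A trailing partial block is dropped with a warning.
    """
    if not runs:
        raise ValueError("no runs provided")
    mats = np.stack([_avoid_matrix(r) for r in runs])  # (runs, sessions, trials)
    n_sessions = mats.shape[1]
    n_blocks, rem = divmod(n_sessions, block_size)
    if rem:
        warnings.warn(
            f"{rem} trailing session(s) do not fill a block of {block_size}; dropped",
            stacklevel=2,
        )
    curves = []
    for b in range(n_blocks):
        lo, hi = b * block_size, (b + 1) * block_size
        curves.append(
            SessionBlockCurve(
                block=b + 1,
                sessions=tuple(range(lo + 1, hi + 1)),
                proportions=mats[:, lo:hi, :].mean(axis=(0, 1)),
            )
        )
    return curves


def warmup_score(
    runs: Sequence[RunResult],
    sessions: Iterable[int] = (10, 11, 12),
    mode: str = "trial2_vs_trial1",
) -> tuple[float, float]:
    """Warm-up difference score: responding on trial 2 minus trial 1.

    Per run, the score is the mean over the requested sessions (1-based
    indices) of [avoid indicator at trial 2] - [avoid indicator at trial 1];
    a positive score means avoidance is transiently depressed at session
    start, i.e. warm-up is present.  The default window is the last
    acquisition block (sessions 10-12); pass an extinction window to score
    warm-up there instead.

    ``mode="block_edges"`` instead contrasts the last two trials of the
    preceding session against the first two trials of each requested session
    (mirroring the empirical analysis convention), signed so that positive
    still means warm-up.

    Returns the across-run mean and SEM.
    """
    sessions = sorted(int(s) for s in sessions)
    if not sessions:
        raise ValueError("empty session window")
    scores = []
    for run in runs:
        n = len(run.sessions)
        for s in sessions:
            if not 1 <= s <= n:
                raise ValueError(f"session {s} out of range (run has {n})")
            if mode == "block_edges" and s < 2:
                raise ValueError("block_edges mode needs a preceding session")
        mat = _avoid_matrix(run)
        if mode == "trial2_vs_trial1":
            per_session = [mat[s - 1, 1] - mat[s - 1, 0] for s in sessions]
        elif mode == "block_edges":
            per_session = [
                mat[s - 2, -2:].mean() - mat[s - 1, :2].mean() for s in sessions
            ]
        else:
            raise ValueError(f"unknown warm-up mode {mode!r}")
        scores.append(float(np.mean(per_session)))
    scores = np.asarray(scores)
    return float(scores.mean()), float(sem(scores))
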