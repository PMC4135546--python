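"""Strain presets, cohort execution, and experimental manipulations.

The two presets reproduce the published parameterizations: Sprague-Dawley
(SD, the outbred control) with alpha=0.05, epsilon=0.005, T=1.0, P=0.25, and
Wistar Kyoto (WKY, the behaviorally inhibited strain) differing only in
alpha=0.005, T=0.25, P=0.  Cohorts average a condition over independent
replicate runs (10 by default) seeded base_seed .. base_seed+n_runs-1, so
conditions compared at the same base seed form a paired design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .metrics import (
    SessionBlockCurve,
    block_trial_curve,
    latency_by_session,
    percent_avoidance_by_session,
    sem,
    warmup_score,
)
from .rl_core import ModelParams
from .task_env import RunResult, TaskConfig, run_experiment

__all__ = [
    "StrainPreset",
    "CohortSummary",
    "strain_preset",
    "run_cohort",
    "make_condition",
    "parameter_sweep",
    "INTERSESSION_GRID",
    "DEFAULT_N_RUNS",
]

#: Replicates per condition; all reported results average this many runs.
DEFAULT_N_RUNS = 10

#: Named inter-session intervals (timesteps at 10 s each).  The "standard"
#: 48-h alternate-day interval uses the canonical 18,000-step value.
INTERSESSION_GRID: dict[str, int] = {
    "contin": 0,
    "2m": 12,
    "10m": 60,
    "30m": 180,
    "1h": 360,
    "6h": 2160,
    "24h": 8640,
    "48h": 18000,
    "30d": 259200,
}

_WKY_CHANGES = {"alpha": 0.005, "temperature": 0.25, "persev": 0.0}


@dataclass(frozen=True)
class StrainPreset:
    name: str
    params: ModelParams


def strain_preset(name: str) -> StrainPreset:
    """Published parameter preset for a rat strain ('SD' or 'WKY').

    WKY inherits every SD value not listed as altered (epsilon, gamma,
    reinforcement magnitudes, action count, initial weights, trace decay).
    """
    if name == "SD":
        return StrainPreset("SD", ModelParams())
    if name == "WKY":
        return StrainPreset("WKY", ModelParams(**_WKY_CHANGES))
    raise ValueError(f"unknown strain {name!r}; expected 'SD' or 'WKY'")


@dataclass
class CohortSummary:
    """Across-run aggregates for one experimental condition."""

    label: str
    n_runs: int
    base_seed: int
    pct_avoid_mean: np.ndarray  # per session
    pct_avoid_sem: np.ndarray
    latency_mean: np.ndarray  # per session, timesteps
    latency_sem: np.ndarray
    block_curves: list[SessionBlockCurve]
    warmup_mean: float
    warmup_sem: float
    warmup_sessions: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_runs": self.n_runs,
            "base_seed": self.base_seed,
            "pct_avoid_mean": self.pct_avoid_mean.tolist(),
            "pct_avoid_sem": self.pct_avoid_sem.tolist(),
            "latency_mean": self.latency_mean.tolist(),
            "latency_sem": self.latency_sem.tolist(),
            "block_curves": [
                {
                    "block": c.block,
                    "sessions": list(c.sessions),
                    "proportions": c.proportions.tolist(),
                }
                for c in self.block_curves
            ],
            "warmup_mean": self.warmup_mean,
            "warmup_sem": self.warmup_sem,
            "warmup_sessions": list(self.warmup_sessions),
        }


def _default_warmup_window(config: TaskConfig) -> tuple[int, ...]:
    """Last 3 acquisition sessions (sessions 10-12 under the defaults)."""
    hi = config.n_acq_sessions
    lo = max(1, hi - 2)
    return tuple(range(lo, hi + 1))


def run_cohort(
    preset: StrainPreset | ModelParams,
    config: TaskConfig,
    n_runs: int = DEFAULT_N_RUNS,
    base_seed: int = 0,
    *,
    label: Optional[str] = None,
    warmup_sessions: Optional[Sequence[int]] = None,
) -> tuple[CohortSummary, list[RunResult]]:
    """Run ``n_runs`` independent replicates and aggregate the metrics.

    Run k uses seed ``base_seed + k``; the summary and the raw runs are both
    returned.  Deterministic given (preset, config, n_runs, base_seed).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if isinstance(preset, StrainPreset):
        params, name = preset.params, preset.name
    else:
        params, name = preset, "custom"
    runs = [
        run_experiment(params, config, base_seed + k, run=k) for k in range(n_runs)
    ]
    if warmup_sessions is None:
        warmup_sessions = _default_warmup_window(config)
    summary = summarize_runs(
        runs,
        label=label or name,
        base_seed=base_seed,
        warmup_sessions=tuple(warmup_sessions),
    )
    return summary, runs


def summarize_runs(
    runs: Sequence[RunResult],
    *,
    label: str,
    base_seed: int = 0,
    warmup_sessions: Sequence[int] = (10, 11, 12),
) -> CohortSummary:
    """Aggregate metrics across an existing list of runs."""
    pct = np.stack([percent_avoidance_by_session(r) for r in runs])
    lat = np.stack([latency_by_session(r) for r in runs])
    w_mean, w_sem = warmup_score(runs, sessions=warmup_sessions)
    return CohortSummary(
        label=label,
        n_runs=len(runs),
        base_seed=base_seed,
        pct_avoid_mean=pct.mean(axis=0),
        pct_avoid_sem=sem(pct),
        latency_mean=lat.mean(axis=0),
        latency_sem=sem(lat),
        block_curves=block_trial_curve(runs),
        warmup_mean=w_mean,
        warmup_sem=w_sem,
        warmup_sessions=tuple(int(s) for s in warmup_sessions),
    )


def make_condition(
    params: ModelParams,
    config: TaskConfig,
    manipulation: str,
    value,
) -> tuple[ModelParams, TaskConfig]:
    """Derive an experimental condition from a base parameterization.

    Supported manipulations:

    - ``shock_intensity``: sets ``r_shock`` (doubled amplitude = -8).
    - ``isi``: sets ``warning_len`` in timesteps (10-s ISI = 1).
    - ``intersession``: sets ``intersession_len`` in timesteps; the
      continuous condition (0) also drops the pre-period, since only
      discrete sessions begin with the 1-min stimulus-free interval.
    - ``housing``: toggles ``round_the_clock``.
    """
    if manipulation == "shock_intensity":
        return params.replace(r_shock=float(value)), config
    if manipulation == "isi":
        if int(value) < 1:
            raise ValueError("warning_len must be >= 1")
        return params, config.replace(warning_len=int(value))
    if manipulation == "intersession":
        if int(value) < 0:
            raise ValueError("intersession_len must be >= 0")
        new = config.replace(intersession_len=int(value))
        if int(value) == 0:
            new = new.replace(pre_len=0)
        return params, new
    if manipulation == "housing":
        return params, config.replace(round_the_clock=bool(value))
    raise ValueError(f"unknown manipulation {manipulation!r}")


def parameter_sweep(
    preset: StrainPreset,
    axis: str,
    values: Sequence[float],
    config: TaskConfig,
    n_runs: int = DEFAULT_N_RUNS,
    base_seed: int = 0,
) -> list[CohortSummary]:
    """Sweep one free parameter, holding everything else at the preset.

    ``axis`` is one of alpha, epsilon, temperature, persev.  All cohorts
    share the same seeds (paired design), enabling the dissociation
    analyses: T moves acquisition rate, alpha moves extinction rate, and P
    moves warm-up, each with little effect on the others.
    """
    if axis not in ("alpha", "epsilon", "temperature", "persev"):
        raise ValueError(f"sweep axis must be a free parameter, got {axis!r}")
    if len(values) == 0:
        raise ValueError("empty sweep value list")
    out = []
    for val in values:
        params = preset.params.replace(**{axis: float(val)})
        summary, _ = run_cohort(
            StrainPreset(preset.name, params),
            config,
            n_runs,
            base_seed,
            label=f"{preset.name}:{axis}={val}",
        )
        out.append(summary)
    return out
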