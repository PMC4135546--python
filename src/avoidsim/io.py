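"""Configuration loading and result serialization (CSV + JSON)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .experiments import CohortSummary
from .rl_core import ModelParams
from .task_env import RunResult, SessionRecord, TaskConfig, TrialRecord

__all__ = [
    "runs_to_frame",
    "frame_to_runs",
    "write_trials_csv",
    "read_trials_csv",
    "write_summary_json",
    "load_config",
]

TRIAL_COLUMNS = [
    "run",
    "phase",
    "session",
    "trial",
    "outcome",
    "latency",
    "n_presses",
    "anticipatory_presses_session",
]


def runs_to_frame(runs: Sequence[RunResult]) -> pd.DataFrame:
    """Flatten runs into a long/tidy trial table (one row per trial)."""
    rows = []
    for r in runs:
        for s in r.sessions:
            for t in s.trials:
                rows.append(
                    (
                        r.run,
                        s.phase,
                        s.session,
                        t.trial,
                        t.outcome,
                        t.latency,
                        len(t.press_times),
                        s.anticipatory_presses,
                    )
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_runs(df: pd.DataFrame) -> list[RunResult]:
    """Rebuild run records from a trial table (scored fields only).

    Press-time lists are not stored in the CSV; reconstructed trials carry
    an empty list and the untruncated trial length, which is sufficient for
    every metric in :mod:`avoidsim.metrics`.
    """
    runs = []
    for run_id, run_df in df.groupby("run", sort=True):
        sessions = []
        for (sess_id, phase), s_df in run_df.groupby(["session", "phase"], sort=False):
            s_df = s_df.sort_values("trial")
            trials = [
                TrialRecord(
                    session=int(sess_id),
                    trial=int(row.trial),
                    outcome=str(row.outcome),
                    latency=int(row.latency),
                    press_times=[],
                    trial_length=int(row.latency),
                )
                for row in s_df.itertuples()
            ]
            sessions.append(
                SessionRecord(
                    session=int(sess_id),
                    phase=str(phase),
                    trials=trials,
                    anticipatory_presses=int(s_df["anticipatory_presses_session"].iloc[0]),
                )
            )
        sessions.sort(key=lambda s: s.session)
        runs.append(RunResult(run=int(run_id), seed=-1, sessions=sessions))
    return runs


def write_trials_csv(runs: Sequence[RunResult], path) -> None:
    runs_to_frame(runs).to_csv(path, index=False, lineterminator="\n")


def read_trials_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _config_echo(
    params: ModelParams, config: TaskConfig, n_runs: int, base_seed: int
) -> dict:
    return {
        "model": dataclasses.asdict(params),
        "task": dataclasses.asdict(config),
        "cohort": {"n_runs": n_runs, "base_seed": base_seed},
    }


def write_summary_json(
    path,
    summary: CohortSummary,
    params: ModelParams,
    config: TaskConfig,
    n_runs: int,
    base_seed: int,
) -> None:
    """Summary JSON: cohort metrics plus a complete configuration echo.

    The echo holds every resolved parameter and the seed list, so the file
    alone suffices to re-launch the identical experiment.
    """
    payload = {
        "version": __version__,
        "config": _config_echo(params, config, n_runs, base_seed),
        "seeds": list(range(base_seed, base_seed + n_runs)),
        "summary": summary.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


_SECTIONS = {"model": ModelParams, "task": TaskConfig}
_COHORT_KEYS = {"n_runs": int, "base_seed": int}


def load_config(
    path=None, *, text: Optional[str] = None
) -> tuple[ModelParams, TaskConfig, dict]:
    """Load a YAML config with sections ``model``, ``task``, ``cohort``.

    Every key is optional and merged over the standard-condition defaults
    (SD preset, 54-step trials, 18,000-step overnight).  Unknown sections
    or keys, type mismatches, and out-of-range values are rejected with the
    offending key named.
    """
    if text is None:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping of sections")
    unknown = set(raw) - {"model", "task", "cohort"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")

    resolved = {}
    for section, cls in _SECTIONS.items():
        entries = raw.get(section) or {}
        if not isinstance(entries, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(entries) - valid
        if bad:
            raise ValueError(f"unknown key(s) in {section!r}: {sorted(bad)}")
        coerced = {}
        for key, val in entries.items():
            if isinstance(val, str) or val is None:
                raise ValueError(f"malformed value for {section}.{key}: {val!r}")
            coerced[key] = val
        try:
            resolved[section] = cls(**coerced)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid {section} configuration: {exc}") from exc

    cohort_raw = raw.get("cohort") or {}
    bad = set(cohort_raw) - set(_COHORT_KEYS)
    if bad:
        raise ValueError(f"unknown key(s) in 'cohort': {sorted(bad)}")
    cohort = {"n_runs": 10, "base_seed": 0}
    for key, val in cohort_raw.items():
        if not isinstance(val, int) or isinstance(val, bool):
            raise ValueError(f"malformed value for cohort.{key}: {val!r}")
        cohort[key] = val

    return resolved["model"], resolved["task"], cohort
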