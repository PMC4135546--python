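"""Shared fixtures: cached cohorts under the standard study conditions.

Every cohort uses 10 replicate runs and base seed 0 (run k is seeded
``0 + k``), matching the convention that all reported results average 10
simulation runs with seeds shared across compared conditions.
"""

from __future__ import annotations

import pytest

from avoidsim import TaskConfig, make_condition, run_cohort, strain_preset
from avoidsim.experiments import INTERSESSION_GRID, StrainPreset

N_RUNS = 10
BASE_SEED = 0


def _build(strain: str, manip=None, value=None, override=None):
    preset = strain_preset(strain)
    params, config = preset.params, TaskConfig()
    label = strain
    if manip is not None:
        params, config = make_condition(params, config, manip, value)
        label = f"{strain}:{manip}={value}"
    if override:
        params = params.replace(**override)
        label = f"{strain}:{override}"
    return run_cohort(
        StrainPreset(strain, params), config, N_RUNS, BASE_SEED, label=label
    )


@pytest.fixture(scope="session")
def cohorts():
    """Memoized cohort factory: cohorts(strain, manip=, value=, override=)."""
    cache: dict = {}

    def get(strain: str, manip=None, value=None, override: dict | None = None):
        key = (
            strain,
            manip,
            value,
            tuple(sorted(override.items())) if override else None,
        )
        if key not in cache:
            cache[key] = _build(strain, manip, value, override)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def sd_cohort(cohorts):
    return cohorts("SD")


@pytest.fixture(scope="session")
def wky_cohort(cohorts):
    return cohorts("WKY")


@pytest.fixture(scope="session")
def intersession_steps():
    return dict(INTERSESSION_GRID)
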