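"""Shared fixtures: small synthetic sessions built once per test run."""

from __future__ import annotations

import numpy as np
import pytest

from odorseq.simulate import (
    BehaviorProfile,
    PopulationTemplate,
    make_task_schedule,
    simulate_behavior,
    simulate_group,
)
from odorseq.task import SessionRecord, TaskConfig, UnitSpikeTrain


@pytest.fixture(scope="session")
def task() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def small_task() -> TaskConfig:
    """Complete but short task: 5 repeats per sequence -> 40 trials."""
    return TaskConfig(n_repeats_per_sequence=5)


@pytest.fixture(scope="session")
def perfect_behavior() -> BehaviorProfile:
    return BehaviorProfile(accuracy_by_type={tt: 1.0 for tt in range(1, 9)})


@pytest.fixture(scope="session")
def small_session(small_task, perfect_behavior) -> SessionRecord:
    """A 40-trial, 12-unit compressed-template session (all trials correct)."""
    template = PopulationTemplate.compressed(n_units=12)
    schedule = make_task_schedule(small_task, seed=0)
    trials = simulate_behavior(schedule, perfect_behavior, small_task, seed=1)
    from odorseq.simulate import _SessionDesign, simulate_unit

    design = _SessionDesign.build(trials, template.global_components)
    rng = np.random.default_rng(2)
    units = []
    for i in range(template.n_units):
        profile, _ = template.sample_unit(rng)
        units.append(
            simulate_unit(profile, trials, rng, unit_id=f"u{i:03d}", design=design)
        )
    session = SessionRecord(
        session_id="fixture0", task=small_task, trials=trials, units=units
    )
    session.validate()
    return session


@pytest.fixture(scope="session")
def compressed_sessions(small_task):
    """Two small compressed sessions with ground truth (30 units each)."""
    template = PopulationTemplate.compressed(n_units=30)
    return simulate_group(template, 2, seed=42, task=small_task)


@pytest.fixture(scope="session")
def differentiated_sessions(small_task):
    template = PopulationTemplate.differentiated(n_units=30)
    return simulate_group(template, 2, seed=43, task=small_task)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
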