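import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from cerebroflux import (
    AnimalRecord,
    CohortTable,
    Group,
    HemodynamicSample,
    PhaseSchedule,
    SimulationConfig,
)


@pytest.fixture(scope="session")
def schedule() -> PhaseSchedule:
    return PhaseSchedule()


def make_record(
    pmap,
    icp,
    times=None,
    animal_id="pig01",
    group=Group.NICPG,
    weight=47.5,
    step=5.0,
    start=0.0,
):
    """Build a record from parallel channel sequences (None = missing)."""
    if times is None:
        times = [start + step * i for i in range(len(pmap))]
    samples = [HemodynamicSample(t, p, i) for t, p, i in zip(times, pmap, icp)]
    return AnimalRecord(animal_id, group, weight, samples)


@pytest.fixture(scope="session")
def gridded_record(schedule) -> AnimalRecord:
    """A clean full-grid record with smooth, non-constant channels."""
    times = schedule.grid()
    pmap = 90 + 10 * np.sin(times / 17.0)
    icp = 17 + 2 * np.cos(times / 23.0)
    return make_record(pmap.tolist(), icp.tolist(), times=times.tolist())


@pytest.fixture(scope="session")
def small_cohort() -> CohortTable:
    """A fast 3+3-animal simulated cohort with default physiology."""
    from cerebroflux import simulate_cohort

    return simulate_cohort(SimulationConfig(n_per_group=3, seed=42))
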