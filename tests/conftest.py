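import numpy as np
import pytest

from seromarkov import (
    IncidenceSchedule,
    KineticsModel,
    default_partition,
    sinusoidal_scenario,
)


@pytest.fixture(scope="session")
def kin() -> KineticsModel:
    """Overlapping-kinetics gamma model on 21-day steps."""
    return KineticsModel.from_preset("sars2")


@pytest.fixture(scope="session")
def sched() -> IncidenceSchedule:
    """Single-wave infection + constant vaccination scenario, 10 steps."""
    return sinusoidal_scenario(10)


@pytest.fixture(scope="session")
def part(kin, sched):
    """Crossing-point partition for the preset kinetics."""
    return default_partition(kin, sched)


def random_schedule(rng: np.random.Generator, t_max: int | None = None) -> IncidenceSchedule:
    """A valid random incidence schedule (nonnegative, total mass <= 1)."""
    if t_max is None:
        t_max = int(rng.integers(2, 12))
    f_i = rng.uniform(0.0, 1.0, t_max + 1)
    f_v = rng.uniform(0.0, 1.0, t_max + 1)
    scale = rng.uniform(0.1, 0.95) / (f_i.sum() + f_v.sum())
    return IncidenceSchedule(f_i * scale, f_v * scale, dt_days=21)
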