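"""Incidence schedules and deterministic prevalence bookkeeping.

Time is discrete: step ``t`` covers ``dt_days`` calendar days, with step 0
the emergence of the disease.  The *incidence* ``f_J(t)`` is the fraction of
the whole population newly entering class ``J`` on step ``t``; the
*prevalence* ``q_J(t)`` is its running sum.  Because re-events are excluded,
``q_I`` and ``q_V`` are nondecreasing, ``q_N = 1 - q_I - q_V`` is
nonincreasing, and everyone is naive the step before emergence
(``q_N(-1) = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Q_NAIVE_BEFORE_EMERGENCE",
    "IncidenceSchedule",
    "PrevalenceSeries",
    "sinusoidal_scenario",
    "prevalence",
    "read_schedule_csv",
    "write_schedule_csv",
]

#: Convention: the whole population is naive on the step before emergence.
Q_NAIVE_BEFORE_EMERGENCE = 1.0

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class IncidenceSchedule:
    """Per-step infection and vaccination incidence fractions.

    Arrays are dense, indexed by absolute time step ``0..t_max``.
    """

    f_infected: np.ndarray
    f_vaccinated: np.ndarray
    dt_days: int = 21

    def __post_init__(self) -> None:
        fi = np.asarray(self.f_infected, dtype=float)
        fv = np.asarray(self.f_vaccinated, dtype=float)
        object.__setattr__(self, "f_infected", fi)
        object.__setattr__(self, "f_vaccinated", fv)
        if fi.ndim != 1 or fv.ndim != 1 or fi.shape != fv.shape:
            raise ValueError("f_infected and f_vaccinated must be 1-D, same length")
        if fi.size == 0:
            raise ValueError("schedule must cover at least step 0")
        if np.any(fi < 0) or np.any(fv < 0):
            raise ValueError("incidences must be nonnegative")
        if fi.sum() + fv.sum() > 1.0 + _SUM_TOL:
            raise ValueError("total incidence exceeds 1")
        if int(self.dt_days) != self.dt_days or self.dt_days < 1:
            raise ValueError("dt_days must be an integer >= 1")

    @property
    def t_max(self) -> int:
        return self.f_infected.size - 1

    def __eq__(self, other) -> bool:
        if not isinstance(other, IncidenceSchedule):
            return NotImplemented
        return (
            self.dt_days == other.dt_days
            and np.array_equal(self.f_infected, other.f_infected)
            and np.array_equal(self.f_vaccinated, other.f_vaccinated)
        )

    __hash__ = None


@dataclass(frozen=True)
class PrevalenceSeries:
    """Class prevalences over steps ``0..t_max`` (fractions of the population)."""

    q_naive: np.ndarray
    q_infected: np.ndarray
    q_vaccinated: np.ndarray

    def q_naive_at(self, t: int) -> float:
        """``q_N(t)``, honoring the ``q_N(-1) = 1`` emergence convention."""
        if t < -1:
            raise ValueError("time step must be >= -1")
        if t == -1:
            return Q_NAIVE_BEFORE_EMERGENCE
        return float(self.q_naive[t])

    @property
    def t_max(self) -> int:
        return self.q_naive.size - 1


def sinusoidal_scenario(t_max: int = 10, dt_days: int = 21) -> IncidenceSchedule:
    """Single-wave epidemic with constant-rate vaccination.

    Infection incidence follows half a sine wave,
    ``f_I(0) = 0.01`` and ``f_I(t) = 0.01 * sin(pi*t/10)`` for ``t >= 1``
    (clipped at zero past the wave, t > 10), with a constant vaccination
    incidence ``f_V(t) = 0.01``.  This mimics a wave of infections during
    the emergence of a disease while vaccines roll out linearly.
    """
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    t = np.arange(t_max + 1)
    f_i = 0.01 * np.maximum(np.sin(np.pi * t / 10.0), 0.0)
    f_i[0] = 0.01
    f_v = np.full(t_max + 1, 0.01)
    return IncidenceSchedule(f_i, f_v, dt_days=dt_days)


def prevalence(schedule: IncidenceSchedule) -> PrevalenceSeries:
    """Cumulate incidences into prevalences; ``q_N = 1 - q_I - q_V``."""
    q_i = np.cumsum(schedule.f_infected)
    q_v = np.cumsum(schedule.f_vaccinated)
    q_n = 1.0 - q_i - q_v
    if np.any(q_n < -_SUM_TOL):
        raise ValueError("cumulative incidence exceeds 1")
    return PrevalenceSeries(q_naive=q_n, q_infected=q_i, q_vaccinated=q_v)


def write_schedule_csv(schedule: IncidenceSchedule, path) -> None:
    """Write a schedule as CSV with columns ``time_step,f_I,f_V``."""
    frame = pd.DataFrame(
        {
            "time_step": np.arange(schedule.t_max + 1),
            "f_I": schedule.f_infected,
            "f_V": schedule.f_vaccinated,
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_schedule_csv(path, dt_days: int = 21) -> IncidenceSchedule:
    """Read a ``time_step,f_I,f_V`` CSV and validate the schedule invariants."""
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"time_step", "f_I", "f_V"}
    if not required.issubset(frame.columns):
        raise ValueError(f"schedule CSV must have columns {sorted(required)}")
    frame = frame.sort_values("time_step")
    steps = frame["time_step"].to_numpy()
    if not np.array_equal(steps, np.arange(len(steps))):
        raise ValueError("time_step column must be contiguous from 0")
    return IncidenceSchedule(
        frame["f_I"].to_numpy(float), frame["f_V"].to_numpy(float), dt_days=dt_days
    )
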