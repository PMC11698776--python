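"""Seeded synthetic-population generator.

Samples are drawn from the exact generative model behind the measurement
density: a categorical label over {naive} u {infected at step t} u
{vaccinated at step t} with probabilities {q_N(T), f_I(t), f_V(t)}, followed
by a gamma draw from the matching kinetic density at lag ``(T - t) * dt``
days.  Labels (class and event step) are carried as optional ground truth;
estimation never reads them.

Reproducibility: one master seed; the stream for dataset ``d`` at time step
``T`` is derived by a counter-based spawn key ``(d, T)`` so datasets and
steps are independently reproducible (and generable in parallel or out of
order).  ``N_s`` counts samples *per time step*: the estimators need a
cross-sectional sample at every step.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .epidemiology import IncidenceSchedule, prevalence
from .kinetics import INFECTED, VACCINATED, KineticsModel

__all__ = [
    "log2_transform",
    "substream",
    "sample_measurements",
    "sample_population",
    "sample_experiment",
]

_CSV_COLUMNS = ["sample_id", "time_step", "measurement", "true_class", "event_step"]
_CLASS_CODES = {0: "N", 1: "I", 2: "V"}


def log2_transform(r_tilde):
    """Base-2 log of a raw arbitrary-unit antibody level (must be > 0)."""
    r_tilde = np.asarray(r_tilde, dtype=float)
    if np.any(r_tilde <= 0):
        raise ValueError("raw measurements must be positive for log2 transform")
    out = np.log2(r_tilde)
    return out if out.ndim else float(out)


def substream(
    seed: int, dataset: int = 0, time_step: int = 0, sweep: int = 0
) -> np.random.Generator:
    """Independent generator for one (sweep, dataset, time step) cell.

    ``sweep`` distinguishes repetitions sharing a master seed (e.g. the
    sample sizes of an experiment grid).
    """
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(sweep, dataset, time_step))
    )


def _event_categories(schedule: IncidenceSchedule, T: int):
    """Category table at step T: (class_code, event_step, probability).

    class codes: 0 naive, 1 infected, 2 vaccinated; naive has event_step -1.
    """
    prev = prevalence(schedule)
    codes = [0] + [1] * (T + 1) + [2] * (T + 1)
    events = [-1] + list(range(T + 1)) * 2
    probs = np.concatenate(
        [[prev.q_naive[T]], schedule.f_infected[: T + 1], schedule.f_vaccinated[: T + 1]]
    )
    total = probs.sum()
    if abs(total - 1.0) > 1e-12:
        raise RuntimeError(f"category weights sum to {total}, expected 1")
    return np.array(codes), np.array(events), probs


def sample_measurements(
    kinetics: KineticsModel,
    schedule: IncidenceSchedule,
    T: int,
    n: int,
    rng: np.random.Generator,
):
    """Fast array-level draw of ``n`` measurements at absolute step ``T``.

    Returns ``(measurements, class_codes, event_steps)`` in random order;
    class codes are 0 (naive), 1 (infected), 2 (vaccinated), event step is
    -1 for naive.  Measurements are clipped to ``[0, r_max]`` (the clipped
    tail carries mass ~1e-12 by model construction).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    codes, events, probs = _event_categories(schedule, T)
    counts = rng.multinomial(n, probs)
    r = np.empty(n)
    out_codes = np.repeat(codes, counts)
    out_events = np.repeat(events, counts)
    pos = 0
    for code, t_event, c in zip(codes, events, counts):
        if c == 0:
            continue
        if code == 0:
            shape = kinetics.alpha_n
        else:
            klass = INFECTED if code == 1 else VACCINATED
            shape = kinetics.shape_at((T - t_event) * kinetics.dt_days, klass)
        r[pos : pos + c] = rng.gamma(shape, scale=kinetics.beta_n, size=c)
        pos += c
    np.clip(r, 0.0, kinetics.r_max, out=r)
    perm = rng.permutation(n)
    return r[perm], out_codes[perm], out_events[perm]


def sample_population(
    kinetics: KineticsModel,
    schedule: IncidenceSchedule,
    T: int,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    labeled: bool = True,
) -> pd.DataFrame:
    """Cross-sectional sample set at step ``T`` as a tidy DataFrame.

    Columns: ``sample_id, time_step, measurement`` and, when ``labeled``,
    the ground-truth ``true_class`` ("N"/"I"/"V") and ``event_step`` (-1 for
    naive).
    """
    if rng is None:
        rng = substream(0 if seed is None else seed, 0, T)
    r, codes, events = sample_measurements(kinetics, schedule, T, n, rng)
    frame = pd.DataFrame(
        {
            "sample_id": np.arange(n),
            "time_step": np.full(n, T),
            "measurement": r,
        }
    )
    if labeled:
        frame["true_class"] = pd.Categorical(
            [_CLASS_CODES[c] for c in codes], categories=["N", "I", "V"]
        )
        frame["event_step"] = events
    return frame


def sample_experiment(
    kinetics: KineticsModel,
    schedule: IncidenceSchedule,
    n_per_step: int,
    n_datasets: int,
    seed: int,
    steps: Sequence[int] | None = None,
    labeled: bool = True,
) -> Iterator[pd.DataFrame]:
    """Yield ``n_datasets`` independent replicate sample sets.

    Each replicate is one DataFrame stacking a cross-section of
    ``n_per_step`` samples at every requested step (default: all steps of
    the schedule), with a ``dataset`` column.  Replicate ``k`` is
    reproducible on its own thanks to the counter-based substreams.
    """
    if steps is None:
        steps = range(schedule.t_max + 1)
    steps = list(steps)
    for d in range(n_datasets):
        parts = []
        for T in steps:
            frame = sample_population(
                kinetics,
                schedule,
                T,
                n_per_step,
                rng=substream(seed, d, T),
                labeled=labeled,
            )
            parts.append(frame)
        out = pd.concat(parts, ignore_index=True)
        out.insert(0, "dataset", d)
        yield out
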