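"""Population-level measurement densities in two equivalent frameworks.

The measurement density ``Q(r, T)`` of an antibody level ``r`` sampled from
the population at absolute step ``T`` is a mixture of the naive density and
per-event-step kinetic densities.  Two bookkeeping routes exist:

* ``convolution`` — mixture weights are the incidences directly:
  ``Q(r,T) = N(r) + sum_t [R(r,T-t) - N(r)] f_I(t)
           + sum_t [W(r,T-t) - N(r)] f_V(t)`` over ``t = 0..T-1``.
* ``markov`` — weights are read off the cumulative transition matrices
  ``H_t``: the newly-infected entry ``H_{t,(3,1)}`` replaces ``f_I(t)`` and
  the naive share comes from ``H_{T-1,(1,1)}``.

Because the chain's state probabilities coincide with the prevalences, the
two routes agree pointwise to rounding; this equivalence is the backbone of
the dual estimation schemes and is enforced by the test battery.
"""

from __future__ import annotations

import numpy as np

from . import markov
from .epidemiology import IncidenceSchedule, prevalence
from .kinetics import INFECTED, NAIVE, VACCINATED, KineticsModel

__all__ = ["MeasurementDensity"]

_FRAMEWORKS = ("convolution", "markov")


def _as_intervals(partition):
    intervals = getattr(partition, "intervals", partition)
    return [tuple(map(float, iv)) for iv in intervals]


class MeasurementDensity:
    """Class-conditional and total measurement densities for one scenario.

    Parameters
    ----------
    kinetics : KineticsModel
    schedule : IncidenceSchedule
    framework : {"convolution", "markov"}
        Which bookkeeping route supplies the mixture weights.
    """

    def __init__(
        self,
        kinetics: KineticsModel,
        schedule: IncidenceSchedule,
        framework: str = "convolution",
    ):
        if framework not in _FRAMEWORKS:
            raise ValueError(f"framework must be one of {_FRAMEWORKS}")
        self.kinetics = kinetics
        self.schedule = schedule
        self.framework = framework
        self._prev = prevalence(schedule)
        self._h_cache: dict[int, np.ndarray] = {}

    # ------------------------------------------------------------------ #
    # mixture weights
    # ------------------------------------------------------------------ #
    def _h_entry(self, t: int, row: int) -> float:
        """Entry ``H_{t,(row+1,1)}`` of the cumulative transition matrix."""
        if t not in self._h_cache:
            self._h_cache[t] = markov.multi_step(self.schedule, t)[:, 0]
        return float(self._h_cache[t][row])

    def _event_weights(self, T: int, klass: str) -> np.ndarray:
        """Weights of the per-event-step components for steps ``t = 0..T``."""
        row = 2 if klass == INFECTED else 4
        if self.framework == "markov":
            return np.array([self._h_entry(t, row) for t in range(T + 1)])
        f = self.schedule.f_infected if klass == INFECTED else self.schedule.f_vaccinated
        return f[: T + 1].copy()

    def _naive_weight(self, T: int) -> float:
        if self.framework == "markov":
            # q_N(T-1) = H_{T-1,(1,1)}, with the emergence convention at T=0
            return 1.0 if T == 0 else self._h_entry(T - 1, 0)
        return self._prev.q_naive_at(T - 1)

    # ------------------------------------------------------------------ #
    # densities
    # ------------------------------------------------------------------ #
    def class_conditional(self, r, T: int, klass: str):
        """Density of ``r`` at step ``T`` given the three-class label.

        The infected (vaccinated) class pools every event step ``t <= T``,
        weighting the kinetic density at lag ``T - t`` by the incidence at
        ``t`` relative to the class prevalence.
        """
        if klass not in (INFECTED, VACCINATED):
            raise ValueError("klass must be 'infected' or 'vaccinated'")
        q = (
            self._prev.q_infected if klass == INFECTED else self._prev.q_vaccinated
        )[T]
        if q <= 0:
            raise ZeroDivisionError(
                f"conditional density undefined: q_{klass}({T}) = 0"
            )
        r = np.asarray(r, dtype=float)
        weights = self._event_weights(T, klass)
        out = np.zeros_like(r, dtype=float)
        dt = self.kinetics.dt_days
        for t, w in enumerate(weights):
            if w == 0.0:
                continue
            out += w * np.asarray(self.kinetics.pdf(r, (T - t) * dt, klass))
        out /= q
        return out if out.ndim else float(out)

    def total(self, r, T: int):
        """Total mixture density ``Q(r, T)`` over the whole population."""
        r = np.asarray(r, dtype=float)
        out = self._naive_weight(T) * np.asarray(self.kinetics.pdf(r, klass=NAIVE))
        dt = self.kinetics.dt_days
        for klass in (INFECTED, VACCINATED):
            weights = self._event_weights(T - 1, klass) if T >= 1 else []
            for t, w in enumerate(weights):
                if w == 0.0:
                    continue
                out += w * np.asarray(self.kinetics.pdf(r, (T - t) * dt, klass))
        return out if out.ndim else float(out)

    # ------------------------------------------------------------------ #
    # subdomain masses
    # ------------------------------------------------------------------ #
    def subdomain_masses(self, partition, T: int) -> np.ndarray:
        """Masses ``Q_j(T)`` of ``Q(.,T)`` on a 3-part partition of the domain.

        Uses closed-form gamma CDF differences, not quadrature of the
        mixture.  ``partition`` is three half-open intervals covering
        ``[0, r_max)`` disjointly, or any object with an ``intervals``
        attribute.
        """
        intervals = _as_intervals(partition)
        self._check_partition(intervals)
        kin = self.kinetics
        masses = self._naive_weight(T) * np.array(
            [kin.subdomain_mass(iv, klass=NAIVE) for iv in intervals]
        )
        for klass in (INFECTED, VACCINATED):
            weights = self._event_weights(T - 1, klass) if T >= 1 else []
            for t, w in enumerate(weights):
                if w == 0.0:
                    continue
                masses += w * np.array(
                    [kin.lag_mass(iv, T - t, klass) for iv in intervals]
                )
        return masses

    def _check_partition(self, intervals) -> None:
        if len(intervals) != 3:
            raise ValueError("partition must have exactly 3 intervals")
        ordered = sorted(intervals)
        if ordered[0][0] > 1e-12:
            raise ValueError("partition does not start at 0")
        if abs(ordered[-1][1] - self.kinetics.r_max) > 1e-9:
            raise ValueError("partition does not end at r_max")
        for (a0, b0), (a1, b1) in zip(ordered, ordered[1:]):
            if abs(b0 - a1) > 1e-12:
                raise ValueError("partition intervals overlap or leave gaps")
            if b0 <= a0 or b1 <= a1:
                raise ValueError("partition intervals must be nonempty")

    # ------------------------------------------------------------------ #
    # export
    # ------------------------------------------------------------------ #
    def grid_frame(self, T: int, n_points: int = 512):
        """Dense ``(r, Q(r,T))`` grid as a DataFrame, for plotting/export."""
        import pandas as pd

        r = np.linspace(0.0, self.kinetics.r_max, n_points)
        return pd.DataFrame({"r": r, "density": self.total(r, T)})
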