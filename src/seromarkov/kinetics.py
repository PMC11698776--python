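"""Class-conditional antibody-measurement models.

A single serological measurement is a scalar ``r``, the base-2 logarithm of
an arbitrary-unit immunoglobulin level, restricted to the instrument range
``Omega = [0, r_max]``.  Three population classes carry distinct measurement
densities:

* **naive** — no infection or vaccination history; the density ``N(r)`` is a
  time-constant gamma distribution with shape ``alpha_n`` and scale
  ``beta_n``.
* **infected** / **vaccinated** — the density ``t`` days after the event is
  a gamma distribution with the same scale ``beta_n`` but a time-varying
  shape ``alpha_c(t) = theta1_c * t / (1 + theta2_c * t**2) + alpha_n``.

The shape dynamics satisfy ``alpha_c(0) = alpha_n`` and
``alpha_c(t) -> alpha_n`` as ``t -> inf``: immediately after an event, and a
long time after it, an individual's antibody distribution is
indistinguishable from naive.  The rise-and-decay in between models the
mounting and waning of the IgG response.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "NAIVE",
    "INFECTED",
    "VACCINATED",
    "EVENT_CLASSES",
    "KineticsModel",
    "PRESETS",
]

NAIVE = "naive"
INFECTED = "infected"
VACCINATED = "vaccinated"
EVENT_CLASSES = (INFECTED, VACCINATED)

#: Named parameter presets.  "sars2" carries gamma-kinetics parameters fit to
#: log2-transformed SARS-CoV-2 IgG levels of naive, once-infected and
#: once-vaccinated individuals, on 21-day reporting periods.
PRESETS: Mapping[str, Mapping[str, float]] = {
    "sars2": {
        "alpha_n": 15.1,
        "beta_n": 0.184,
        "theta1_i": 1.56,
        "theta2_i": 5.1e-4,
        "theta1_v": 1.74,
        "theta2_v": 2.8e-4,
        "dt_days": 21,
        "r_max": 30.0,
    }
}


@dataclass(frozen=True)
class KineticsModel:
    """Gamma antibody-kinetics model for the three classes.

    Parameters
    ----------
    alpha_n : float
        Naive gamma shape (unitless), > 0.
    beta_n : float
        Gamma scale shared by all classes (log2 AU), > 0.
    theta1_i, theta2_i : float
        Shape-dynamics parameters for the infected class (per-day and
        per-day**2); ``theta1 >= 0``, ``theta2 > 0``.
    theta1_v, theta2_v : float
        Same for the vaccinated class.
    dt_days : int
        Days per reporting time step (>= 1).  Kinetics at a lag of ``k``
        time steps are evaluated at ``t = k * dt_days`` days.
    r_max : float
        Upper bound of the measurement domain (log2 AU).  Chosen so that the
        gamma tails beyond it carry mass below ~1e-12; densities are *not*
        renormalized after truncation.
    """

    alpha_n: float
    beta_n: float
    theta1_i: float
    theta2_i: float
    theta1_v: float
    theta2_v: float
    dt_days: int = 21
    r_max: float = 30.0

    def __post_init__(self) -> None:
        if not (self.alpha_n > 0 and self.beta_n > 0):
            raise ValueError("alpha_n and beta_n must be positive")
        for name in ("theta1_i", "theta1_v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("theta2_i", "theta2_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if int(self.dt_days) != self.dt_days or self.dt_days < 1:
            raise ValueError("dt_days must be an integer >= 1")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")

    # ------------------------------------------------------------------ #
    # construction helpers
    # ------------------------------------------------------------------ #
    @classmethod
    def from_preset(cls, name: str = "sars2", **overrides: float) -> "KineticsModel":
        """Build a model from a named preset, with optional field overrides."""
        try:
            params = dict(PRESETS[name])
        except KeyError:
            raise KeyError(
                f"unknown preset {name!r}; available: {sorted(PRESETS)}"
            ) from None
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_config(cls, config: Mapping[str, float]) -> "KineticsModel":
        """Build a model from a config mapping (YAML/JSON block).

        A ``preset`` key selects a named preset; remaining keys override
        individual fields.
        """
        config = dict(config)
        preset = config.pop("preset", None)
        if preset is not None:
            return cls.from_preset(preset, **config)
        return cls(**config)

    def to_config(self) -> dict:
        return asdict(self)

    # ------------------------------------------------------------------ #
    # shape dynamics
    # ------------------------------------------------------------------ #
    def shape_at(self, t_days, event_class: str):
        """Gamma shape ``alpha_c(t)`` for an event class, ``t`` days post event.

        Satisfies ``shape_at(0, c) == alpha_n`` and tends to ``alpha_n`` as
        ``t`` grows (rise-and-decay antibody response).
        """
        if event_class == INFECTED:
            th1, th2 = self.theta1_i, self.theta2_i
        elif event_class == VACCINATED:
            th1, th2 = self.theta1_v, self.theta2_v
        else:
            raise ValueError(
                f"event_class must be one of {EVENT_CLASSES}, got {event_class!r}"
            )
        t = np.asarray(t_days, dtype=float)
        if np.any(t < 0):
            raise ValueError("t_days must be nonnegative")
        out = th1 * t / (1.0 + th2 * t * t) + self.alpha_n
        return out if out.ndim else float(out)

    def _shape(self, t_days, klass: str) -> float:
        if klass == NAIVE:
            return self.alpha_n
        if t_days is None:
            raise ValueError(f"t_days is required for class {klass!r}")
        return float(self.shape_at(t_days, klass))

    # ------------------------------------------------------------------ #
    # densities and masses
    # ------------------------------------------------------------------ #
    def pdf(self, r, t_days=None, klass: str = NAIVE):
        """Measurement density at ``r`` for a class, ``t_days`` after the event.

        ``klass='naive'`` ignores ``t_days``.  ``r`` outside ``[0, r_max]``
        raises; the density is the untruncated gamma pdf (tail mass beyond
        ``r_max`` is negligible by construction).
        """
        r = np.asarray(r, dtype=float)
        if np.any((r < 0) | (r > self.r_max)):
            raise ValueError(f"measurement outside domain [0, {self.r_max}]")
        out = _frozen(self, self._shape(t_days, klass)).pdf(r)
        return out if out.ndim else float(out)

    def cdf(self, r, t_days=None, klass: str = NAIVE):
        """Gamma CDF counterpart of :meth:`pdf`."""
        r = np.asarray(r, dtype=float)
        out = _frozen(self, self._shape(t_days, klass)).cdf(r)
        return out if out.ndim else float(out)

    def subdomain_mass(self, interval, t_days=None, klass: str = NAIVE) -> float:
        """Probability mass of a half-open interval ``[a, b)``.

        Computed as a closed-form difference of gamma CDFs (the gamma law is
        atomless, so the half-open convention costs nothing).
        """
        a, b = interval
        if a > b:
            raise ValueError(f"inverted interval [{a}, {b})")
        if not (0 <= a and b <= self.r_max + 1e-12):
            raise ValueError(f"interval [{a}, {b}) outside domain [0, {self.r_max}]")
        dist = _frozen(self, self._shape(t_days, klass))
        return float(dist.cdf(b) - dist.cdf(a))

    def lag_mass(self, interval, lag_steps: int, klass: str = NAIVE) -> float:
        """Subdomain mass at a lag of ``lag_steps`` time steps (= lag*dt days)."""
        if klass == NAIVE:
            return self.subdomain_mass(interval, klass=NAIVE)
        return self.subdomain_mass(interval, lag_steps * self.dt_days, klass)

    def naive_mode(self) -> float:
        """Mode of the naive density, ``(alpha_n - 1) * beta_n`` for alpha_n > 1."""
        return max(self.alpha_n - 1.0, 0.0) * self.beta_n


@lru_cache(maxsize=4096)
def _frozen(model: KineticsModel, shape: float):
    # frozen scipy gamma per (model, shape); the per-lag shapes repeat heavily
    # across density evaluations and estimator design matrices.
    return stats.gamma(a=shape, scale=model.beta_n)
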