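"""Weitzman overlapping coefficient between measurement densities.

The overlapping coefficient OVL of two probability densities is the shared
area under their curves, ``integral of min(P1, P2)``: 1 for identical
densities, 0 for disjoint supports.  It quantifies how separable two
classes are from a single antibody measurement — high overlap between the
infected and vaccinated kinetic densities is what drives prevalence
estimation error up.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .kinetics import INFECTED, NAIVE, VACCINATED, KineticsModel

__all__ = ["ovl", "pair_ovl", "overlap_series", "PAIR_CLASSES"]

#: Pair labels accepted by the series helpers.
PAIR_CLASSES = {
    "NI": (NAIVE, INFECTED),
    "NV": (NAIVE, VACCINATED),
    "IV": (INFECTED, VACCINATED),
}


def _crossings(pdf_a, pdf_b, domain, n_grid: int = 2048) -> list[float]:
    """Interior points where the two densities cross (kinks of the min)."""
    lo, hi = domain
    grid = np.linspace(lo, hi, n_grid)
    diff = np.asarray(pdf_a(grid)) - np.asarray(pdf_b(grid))
    sign = np.sign(diff)
    roots = []
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(
            float(
                optimize.brentq(
                    lambda x: float(pdf_a(x)) - float(pdf_b(x)),
                    grid[i],
                    grid[i + 1],
                    xtol=1e-12,
                )
            )
        )
    return roots


def ovl(pdf_a, pdf_b, domain=(0.0, 30.0), atol: float = 1e-6) -> float:
    """Overlapping coefficient of two normalized densities on ``domain``.

    The integrand ``min(P1, P2)`` has kinks wherever the densities cross,
    which defeats plain adaptive quadrature; crossings are located by root
    finding and passed to the integrator as breakpoints.  Inputs that do not
    integrate to 1 on the domain (within 1e-4) are rejected.
    """
    lo, hi = domain
    for name, pdf in (("first", pdf_a), ("second", pdf_b)):
        total, _ = integrate.quad(lambda x: float(pdf(x)), lo, hi, limit=200)
        if abs(total - 1.0) > 1e-4:
            raise ValueError(
                f"{name} density integrates to {total:.6f} on {domain}, not 1"
            )
    points = _crossings(pdf_a, pdf_b, domain)
    value, _ = integrate.quad(
        lambda x: min(float(pdf_a(x)), float(pdf_b(x))),
        lo,
        hi,
        points=points or None,
        limit=200,
        epsabs=atol,
    )
    return float(min(max(value, 0.0), 1.0))


def _class_pdf(kinetics: KineticsModel, klass: str, t_days: float):
    if klass == NAIVE:
        return lambda r: kinetics.pdf(r, klass=NAIVE)
    return lambda r: kinetics.pdf(r, t_days, klass)


def pair_ovl(kinetics: KineticsModel, pair: str, step: int) -> float:
    """OVL between two class densities at a given time step (lag in steps)."""
    try:
        klass_a, klass_b = PAIR_CLASSES[pair]
    except KeyError:
        raise ValueError(f"pair must be one of {sorted(PAIR_CLASSES)}") from None
    t_days = step * kinetics.dt_days
    return ovl(
        _class_pdf(kinetics, klass_a, t_days),
        _class_pdf(kinetics, klass_b, t_days),
        domain=(0.0, kinetics.r_max),
    )


def overlap_series(
    kinetics: KineticsModel,
    steps: Sequence[int],
    pairs: Sequence[str] = ("IV", "NI", "NV"),
) -> pd.DataFrame:
    """Per-step OVL for each class pair, as a tidy DataFrame."""
    rows = [
        {"time_step": int(step), "pair": pair, "ovl": pair_ovl(kinetics, pair, step)}
        for pair in pairs
        for step in steps
    ]
    return pd.DataFrame(rows)
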