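"""Five-state time-inhomogeneous Markov chain over immune-event classes.

States, in fixed order: naive ``N``, previously infected ``I'``, newly
infected ``I``, previously vaccinated ``V'``, newly vaccinated ``V``.  A
"new" state is the transient one-step state occupied on the event step
itself; one step later the individual moves to the corresponding "previous"
state and stays there (no reinfection, revaccination, or cross events).

Matrices are column-stochastic under the "to row ``i`` from column ``j``"
convention.  The one-step matrix from step ``T-1`` to ``T`` has transition
probabilities out of ``N`` given by the incidences normalized by the naive
share of the population one step earlier:

    s_IN(T) = f_I(T) / q_N(T-1),   s_VN(T) = f_V(T) / q_N(T-1),
    s_N(T)  = 1 - s_IN(T) - s_VN(T),

with the degenerate ``q_N(T-1) = 0`` case defined as a self-loop on ``N``.
The ordered product ``H_tau = S(tau)...S(1)S(0)`` applied to the emergence
state ``e_1`` (everyone naive) yields the state distribution; its first
column equals ``[q_N(tau), q_I(tau-1), f_I(tau), q_V(tau-1), f_V(tau)]``,
tying the chain back to the prevalence bookkeeping.
"""

from __future__ import annotations

import json

import numpy as np

from .epidemiology import IncidenceSchedule, PrevalenceSeries, prevalence

__all__ = [
    "STATE_NAMES",
    "one_step",
    "multi_step",
    "multi_step_closed_form",
    "state_probabilities",
    "state_probabilities_closed_form",
    "matrices_to_json",
]

#: State order used everywhere (index 0..4 maps to the field's 1..5).
STATE_NAMES = ("naive", "prev_infected", "new_infected", "prev_vaccinated", "new_vaccinated")
_N, _IPREV, _INEW, _VPREV, _VNEW = range(5)

_TOL = 1e-12


def _rates(schedule: IncidenceSchedule, prev: PrevalenceSeries, T: int):
    """(s_IN, s_VN, s_N) for the step ``T-1 -> T`` transition."""
    q_n_prev = prev.q_naive_at(T - 1)
    if abs(q_n_prev) <= _TOL:
        return 0.0, 0.0, 1.0
    s_in = schedule.f_infected[T] / q_n_prev
    s_vn = schedule.f_vaccinated[T] / q_n_prev
    if s_in + s_vn > 1.0 + 1e-9:
        raise ValueError(
            f"schedule inconsistent at step {T}: s_IN + s_VN = {s_in + s_vn} > 1"
        )
    return s_in, s_vn, 1.0 - s_in - s_vn


def one_step(
    schedule: IncidenceSchedule, prev: PrevalenceSeries | None, T: int
) -> np.ndarray:
    """One-step transition matrix ``S(T)`` (5x5, column-stochastic)."""
    if prev is None:
        prev = prevalence(schedule)
    if not 0 <= T <= schedule.t_max:
        raise ValueError(f"step {T} outside schedule range 0..{schedule.t_max}")
    s_in, s_vn, s_n = _rates(schedule, prev, T)
    S = np.zeros((5, 5))
    S[_N, _N] = s_n
    S[_INEW, _N] = s_in
    S[_VNEW, _N] = s_vn
    S[_IPREV, _IPREV] = 1.0
    S[_IPREV, _INEW] = 1.0
    S[_VPREV, _VPREV] = 1.0
    S[_VPREV, _VNEW] = 1.0
    return S


def multi_step(schedule: IncidenceSchedule, tau: int) -> np.ndarray:
    """``H_tau = S(tau)...S(1)S(0)`` accumulated by left-multiplication."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    prev = prevalence(schedule)
    H = one_step(schedule, prev, 0)
    for t in range(1, tau + 1):
        H = one_step(schedule, prev, t) @ H
    return H


def multi_step_closed_form(schedule: IncidenceSchedule, tau: int) -> np.ndarray:
    """``H_tau`` from prevalences directly, bypassing the matrix product.

    First column is ``[q_N(tau), q_I(tau-1), f_I(tau), q_V(tau-1), f_V(tau)]``;
    the ``prev -> prev`` and ``new -> prev`` unit entries are unchanged by the
    product.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    prev = prevalence(schedule)
    H = np.zeros((5, 5))
    H[_N, _N] = prev.q_naive[tau]
    H[_IPREV, _N] = prev.q_infected[tau - 1] if tau >= 1 else 0.0
    H[_INEW, _N] = schedule.f_infected[tau]
    H[_VPREV, _N] = prev.q_vaccinated[tau - 1] if tau >= 1 else 0.0
    H[_VNEW, _N] = schedule.f_vaccinated[tau]
    H[_IPREV, _IPREV] = H[_IPREV, _INEW] = 1.0
    H[_VPREV, _VPREV] = H[_VPREV, _VNEW] = 1.0
    return H


def state_probabilities(schedule: IncidenceSchedule, T: int) -> np.ndarray:
    """State distribution ``H_T e_1`` after ``T`` steps from emergence."""
    return multi_step(schedule, T)[:, _N].copy()


def state_probabilities_closed_form(schedule: IncidenceSchedule, T: int) -> np.ndarray:
    """State distribution from products of the scalar transition rates.

    Uses the explicit expansions: the naive probability is the running
    product of the stay-naive rates, a "new" state carries the current event
    rate times that product one step back, and a "previous" state sums event
    rates weighted by the survival products before each event step.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    prev = prevalence(schedule)
    s_in = np.empty(T + 1)
    s_vn = np.empty(T + 1)
    s_n = np.empty(T + 1)
    for t in range(T + 1):
        s_in[t], s_vn[t], s_n[t] = _rates(schedule, prev, t)
    # survive[t] = prod_{tau < t} s_N(tau); survive[0] = 1
    survive = np.concatenate([[1.0], np.cumprod(s_n)])
    out = np.empty(5)
    out[_N] = survive[T + 1]
    out[_IPREV] = float(np.sum(s_in[:T] * survive[:T]))
    out[_INEW] = s_in[T] * survive[T]
    out[_VPREV] = float(np.sum(s_vn[:T] * survive[:T]))
    out[_VNEW] = s_vn[T] * survive[T]
    return out


def matrices_to_json(schedule: IncidenceSchedule, steps=None, indent: int = 2) -> str:
    """Serialize one-step and cumulative matrices with state-name labels."""
    if steps is None:
        steps = range(schedule.t_max + 1)
    prev = prevalence(schedule)
    payload = {
        "states": list(STATE_NAMES),
        "one_step": {str(T): one_step(schedule, prev, T).tolist() for T in steps},
        "cumulative": {str(T): multi_step(schedule, T).tolist() for T in steps},
    }
    return json.dumps(payload, indent=indent)
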