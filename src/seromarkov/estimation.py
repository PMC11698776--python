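"""Prevalence estimation from unlabeled cross-sectional antibody samples.

Both schemes start from the same Monte Carlo primitive: partition the
measurement domain into ``D1 = [0,c1), D2 = [c1,c2), D3 = [c2,r_max]`` and
record, at each time step, the fraction of samples falling in each
subdomain.  Writing the population masses ``Q_j(T)`` as linear combinations
of the known kinetic masses with the unknown incidences as coefficients
turns those fractions into linear systems:

* ``recursive`` — a 2x2 system in ``(f_I(T-1), f_V(T-1))`` built from D1
  and D2, peeling off the already-estimated earlier incidences; prevalences
  are running sums.
* ``transition-matrix`` — a 3x3 system per step in ``(q_N(T-1),
  H_{T-1,(3,1)}, H_{T-1,(5,1)})`` using all three subdomains plus the total-
  probability constraint row ``[1,1,1] -> q_N(T-2)``; the previously-
  infected/vaccinated matrix entries accumulate the newly-infected ones.

The step lag is intrinsic: samples taken at step ``T`` inform the
incidences of step ``T-1``, because an event at ``T`` has not yet moved the
antibody distribution away from naive.  Both schemes are algebraically
equivalent and unbiased; estimates may be negative at small sample sizes
and are returned raw unless ``clip`` is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .kinetics import INFECTED, NAIVE, VACCINATED, KineticsModel

__all__ = [
    "Partition",
    "IllPosedPartitionError",
    "EstimationResult",
    "qhat",
    "estimate_recursive",
    "estimate_transition_matrix",
    "default_partition",
]

_COND_LIMIT = 1e12


class IllPosedPartitionError(np.linalg.LinAlgError):
    """Raised when a partition yields a (near-)singular design matrix."""


@dataclass(frozen=True)
class Partition:
    """Cut points ``c1 < c2`` splitting ``[0, r_max]`` into three subdomains.

    Membership is half-open: a measurement equal to a cut point belongs to
    the interval on its right.
    """

    c1: float
    c2: float
    r_max: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 < self.c1 < self.c2 < self.r_max:
            raise ValueError(
                f"need 0 < c1 < c2 < r_max, got {self.c1}, {self.c2}, {self.r_max}"
            )

    @property
    def intervals(self):
        return ((0.0, self.c1), (self.c1, self.c2), (self.c2, self.r_max))

    def assign(self, r) -> np.ndarray:
        """Subdomain index (0, 1 or 2) of each measurement."""
        return np.digitize(np.asarray(r, dtype=float), [self.c1, self.c2])


def qhat(samples, partition: Partition) -> np.ndarray:
    """Monte Carlo subdomain-mass estimator: per-subdomain sample fractions.

    ``samples`` is an array of measurements or a sample-set DataFrame with a
    ``measurement`` column.  The three fractions sum to 1 exactly.
    """
    if isinstance(samples, pd.DataFrame):
        samples = samples["measurement"].to_numpy()
    r = np.asarray(samples, dtype=float)
    if r.size == 0:
        raise ValueError("empty sample set")
    counts = np.bincount(partition.assign(r), minlength=3)
    return counts / r.size


# ---------------------------------------------------------------------- #
# design masses
# ---------------------------------------------------------------------- #
def _design_masses(kinetics: KineticsModel, partition: Partition, t_max: int):
    """Naive masses N_j and per-lag masses R_j(k), W_j(k), k = 1..t_max."""
    ivs = partition.intervals
    n_mass = np.array([kinetics.subdomain_mass(iv, klass=NAIVE) for iv in ivs])
    r_mass = np.array(
        [[kinetics.lag_mass(iv, k, INFECTED) for iv in ivs] for k in range(t_max + 1)]
    )
    w_mass = np.array(
        [[kinetics.lag_mass(iv, k, VACCINATED) for iv in ivs] for k in range(t_max + 1)]
    )
    return n_mass, r_mass, w_mass


def _check_cond(A: np.ndarray, label: str) -> float:
    cond = float(np.linalg.cond(A))
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise IllPosedPartitionError(
            f"{label} design matrix is ill-posed (condition number {cond:.3g}); "
            "choose cut points that separate the naive, infected and "
            "vaccinated lag-1 masses"
        )
    return cond


def _validate_qhat_series(qhat_by_step) -> np.ndarray:
    q = np.asarray(qhat_by_step, dtype=float)
    if q.ndim != 2 or q.shape[1] != 3 or q.shape[0] < 2:
        raise ValueError(
            "qhat_by_step must have shape (t_max + 1, 3); row T holds the "
            "subdomain fractions observed at step T (row 0 is unused)"
        )
    return q


# ---------------------------------------------------------------------- #
# results container
# ---------------------------------------------------------------------- #
@dataclass
class EstimationResult:
    """Per-step incidence and prevalence estimates from one scheme.

    Arrays are indexed by time step ``0..t_max-1`` (a sample at step ``T``
    informs step ``T-1``; the final schedule step has no estimate).
    ``h_*`` fields expose the estimated cumulative-transition-matrix first
    column: ``h_new_* = f`` and ``h_prev_*`` its one-step-lagged running sum.
    """

    f_infected: np.ndarray
    f_vaccinated: np.ndarray
    q_infected: np.ndarray
    q_vaccinated: np.ndarray
    q_naive: np.ndarray
    condition_number: float
    method: str
    clipped: bool = False

    @property
    def h_new_infected(self) -> np.ndarray:
        return self.f_infected

    @property
    def h_new_vaccinated(self) -> np.ndarray:
        return self.f_vaccinated

    @property
    def h_prev_infected(self) -> np.ndarray:
        return np.concatenate([[0.0], self.q_infected[:-1]])

    @property
    def h_prev_vaccinated(self) -> np.ndarray:
        return np.concatenate([[0.0], self.q_vaccinated[:-1]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_step": np.arange(self.f_infected.size),
                "f_I_hat": self.f_infected,
                "f_V_hat": self.f_vaccinated,
                "q_I_hat": self.q_infected,
                "q_V_hat": self.q_vaccinated,
                "q_N_hat": self.q_naive,
            }
        )


def _finalize(f_i, f_v, cond, method, clip) -> EstimationResult:
    q_i = np.cumsum(f_i)
    q_v = np.cumsum(f_v)
    q_n = 1.0 - q_i - q_v
    if clip:
        q_i = np.clip(q_i, 0.0, None)
        q_v = np.clip(q_v, 0.0, None)
        q_n = np.clip(q_n, 0.0, None)
        total = q_i + q_v + q_n
        q_i, q_v, q_n = q_i / total, q_v / total, q_n / total
    return EstimationResult(
        f_infected=f_i,
        f_vaccinated=f_v,
        q_infected=q_i,
        q_vaccinated=q_v,
        q_naive=q_n,
        condition_number=cond,
        method=method,
        clipped=clip,
    )


# ---------------------------------------------------------------------- #
# scheme 1: recursive 2x2 (subdomains D1, D2 only)
# ---------------------------------------------------------------------- #
def estimate_recursive(
    qhat_by_step,
    kinetics: KineticsModel,
    partition: Partition,
    clip: bool = False,
) -> EstimationResult:
    """Recursive incidence estimation from per-step subdomain fractions.

    ``qhat_by_step`` has shape ``(t_max + 1, 3)``: row ``T`` holds the
    observed subdomain fractions at step ``T`` (row 0 is unused — step-0
    samples are distributed exactly as naive and carry no incidence
    information).  Each step solves

        [M(1) - N*] f(T-1) = qhat(T) - N - sum_{t<=T-2} [M(T-t) - N*] f(t)

    with ``M(k)`` the 2x2 matrix of lag-``k`` infected/vaccinated masses on
    D1, D2 and ``N* = N [1,1]`` the rank-one naive-mass matrix.
    """
    q = _validate_qhat_series(qhat_by_step)
    t_max = q.shape[0] - 1
    n_mass, r_mass, w_mass = _design_masses(kinetics, partition, t_max)
    n2 = n_mass[:2]
    # M(k) columns: infected, vaccinated lag-k masses on rows D1, D2
    M = np.stack([r_mass, w_mass], axis=-1)[:, :2, :]  # (t_max+1, 2, 2)
    n_star = np.outer(n2, [1.0, 1.0])
    A = M[1] - n_star
    cond = _check_cond(A, "recursive (2x2)")
    lu = np.linalg.inv(A)  # 2x2; explicit inverse mirrors the closed form
    f = np.zeros((t_max, 2))
    for T in range(1, t_max + 1):
        rhs = q[T, :2] - n2
        for t in range(T - 1):  # t = 0 .. T-2
            rhs -= (M[T - t] - n_star) @ f[t]
        f[T - 1] = lu @ rhs
    return _finalize(f[:, 0], f[:, 1], cond, "recursive", clip)


# ---------------------------------------------------------------------- #
# scheme 2: per-step 3x3 transition-matrix estimation
# ---------------------------------------------------------------------- #
def estimate_transition_matrix(
    qhat_by_step,
    kinetics: KineticsModel,
    partition: Partition,
    clip: bool = False,
) -> EstimationResult:
    """Transition-probability-matrix estimation from subdomain fractions.

    Solves, for each step ``T = 1..t_max``, the 3x3 system

        [[N_1, R_1(1), W_1(1)],      [q_N(T-1)      ]   [b_1(T)]
         [N_2, R_2(1), W_2(1)],   x  [H_{T-1,(3,1)} ] = [b_2(T)]
         [ 1,    1,      1    ]]     [H_{T-1,(5,1)} ]   [qhat_N(T-2)]

    where ``b_j(T)`` subtracts the already-estimated earlier newly-
    infected/vaccinated contributions from the observed ``qhat_j(T)`` and
    the constraint row states that last step's naive share splits into
    staying naive, new infection, or new vaccination.  ``q_N(-1) = 1``
    seeds the recursion.  The previously-infected/vaccinated entries follow
    by accumulation.
    """
    q = _validate_qhat_series(qhat_by_step)
    t_max = q.shape[0] - 1
    n_mass, r_mass, w_mass = _design_masses(kinetics, partition, t_max)
    A = np.array(
        [
            [n_mass[0], r_mass[1, 0], w_mass[1, 0]],
            [n_mass[1], r_mass[1, 1], w_mass[1, 1]],
            [1.0, 1.0, 1.0],
        ]
    )
    cond = _check_cond(A, "transition-matrix (3x3)")
    lu_piv = np.linalg.inv(A)
    h31 = np.zeros(t_max)  # newly infected entries H_{t,(3,1)}
    h51 = np.zeros(t_max)  # newly vaccinated entries H_{t,(5,1)}
    q_n_hat = np.zeros(t_max)  # q_N(T-1) straight from the solves
    q_n_lag2 = 1.0  # qhat_N(T-2), seeded by q_N(-1) = 1
    for T in range(1, t_max + 1):
        b = np.empty(3)
        b[0] = q[T, 0]
        b[1] = q[T, 1]
        for t in range(T - 1):  # t = 0 .. T-2
            b[0] -= r_mass[T - t, 0] * h31[t] + w_mass[T - t, 0] * h51[t]
            b[1] -= r_mass[T - t, 1] * h31[t] + w_mass[T - t, 1] * h51[t]
        b[2] = q_n_lag2
        sol = lu_piv @ b
        q_n_hat[T - 1], h31[T - 1], h51[T - 1] = sol
        q_n_lag2 = q_n_hat[T - 1]
    result = _finalize(h31, h51, cond, "transition-matrix", clip)
    if not clip:
        # expose the directly-solved naive shares (equal to 1 - q_I - q_V up
        # to rounding, since each solve satisfies the constraint row exactly)
        result.q_naive = q_n_hat
    return result


# ---------------------------------------------------------------------- #
# partition selection
# ---------------------------------------------------------------------- #
def _crossing(fa, fb, lo: float, hi: float, n_grid: int = 256) -> float | None:
    """Leftmost root of fa - fb in (lo, hi), or None if no sign change."""
    grid = np.linspace(lo, hi, n_grid)
    diff = np.array([fa(x) - fb(x) for x in grid])
    sign = np.sign(diff)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    return float(
        optimize.brentq(lambda x: fa(x) - fb(x), grid[i], grid[i + 1], xtol=1e-10)
    )


def default_partition(
    kinetics: KineticsModel, schedule=None
) -> Partition:
    """Cut points separating the naive, lag-1 infected and vaccinated masses.

    ``c1`` is the crossing of the naive density and the lag-1 (one time
    step post infection) density to the right of the naive mode; ``c2`` is
    the crossing of the lag-1 infected and vaccinated densities to the
    right of ``c1``.  If either crossing is absent the cut points fall back
    to equal-mass tertiles of the step-1 population mixture (or of the
    equal-weight three-class mixture when no schedule is given).
    """
    dt = kinetics.dt_days
    r_max = kinetics.r_max

    def n_pdf(x):
        return kinetics.pdf(x, klass=NAIVE)

    def r_pdf(x):
        return kinetics.pdf(x, dt, INFECTED)

    def w_pdf(x):
        return kinetics.pdf(x, dt, VACCINATED)

    c1 = _crossing(n_pdf, r_pdf, kinetics.naive_mode(), r_max)
    c2 = _crossing(r_pdf, w_pdf, c1, r_max) if c1 is not None else None
    if c1 is not None and c2 is not None and c1 < c2:
        return Partition(c1, c2, r_max)

    # fallback: equal-mass tertiles of the step-1 mixture
    if schedule is not None:
        from .density import MeasurementDensity

        dens = MeasurementDensity(kinetics, schedule)

        def mass_below(c):
            return dens.subdomain_masses(
                ((0.0, c), (c, 0.5 * (c + r_max)), (0.5 * (c + r_max), r_max)), 1
            )[0]
    else:

        def mass_below(c):
            iv = (0.0, c)
            return (
                kinetics.subdomain_mass(iv, klass=NAIVE)
                + kinetics.lag_mass(iv, 1, INFECTED)
                + kinetics.lag_mass(iv, 1, VACCINATED)
            ) / 3.0

    c1 = optimize.brentq(lambda c: mass_below(c) - 1.0 / 3.0, 1e-9, r_max - 1e-9)
    c2 = optimize.brentq(lambda c: mass_below(c) - 2.0 / 3.0, c1, r_max - 1e-9)
    return Partition(c1, c2, r_max)
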