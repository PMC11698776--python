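"""Replicated prevalence-estimation experiments and error summaries.

A sweep draws many independent synthetic datasets (a cross-section of
``N_s`` unlabeled samples at every time step), runs both estimation schemes
on each, and summarizes accuracy per class.  The headline error metric is
the *percent relative error of the across-dataset mean estimate*: per time
step ``t``, ``|mean_d qhat(t) - q(t)| / q(t) * 100``, then mean +/- sd over
the estimable steps ``0..t_max-1``.  An absolute-error alternative (in
prevalence units) is emitted alongside, and the cross-method norms of the
differences between the two schemes' means and standard deviations are
recorded as an equivalence diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .density import MeasurementDensity
from .epidemiology import IncidenceSchedule, prevalence, read_schedule_csv, sinusoidal_scenario
from .estimation import (
    EstimationResult,
    Partition,
    default_partition,
    estimate_recursive,
    estimate_transition_matrix,
)
from .kinetics import KineticsModel
from .sampler import sample_measurements, substream

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "run_noiseless",
    "exact_qhat_series",
]

METHODS = ("recursive", "transition-matrix")
_ESTIMATORS = {
    "recursive": estimate_recursive,
    "transition-matrix": estimate_transition_matrix,
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of a replicated estimation sweep."""

    kinetics: KineticsModel
    schedule: IncidenceSchedule
    sample_sizes: tuple[int, ...] = (1000,)
    n_datasets: int = 1000
    seed: int = 0
    partition: Partition | None = None
    clip: bool = False

    def __post_init__(self) -> None:
        if self.n_datasets < 2:
            raise ValueError("n_datasets must be >= 2 (spread is reported)")
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be positive")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ExperimentConfig":
        """Build from a plain config mapping (parsed YAML/JSON).

        Keys: ``kinetics`` (preset name or field mapping), ``schedule``
        (``{"scenario": "sinusoidal", "t_max": 10, "dt_days": 21}`` or
        ``{"csv": path}``), ``sample_sizes``, ``n_datasets``, ``seed``,
        ``partition`` (``[c1, c2]`` or absent for automatic), ``clip``.
        """
        raw = dict(raw)
        kin_cfg = raw.get("kinetics", "sars2")
        if isinstance(kin_cfg, str):
            kinetics = KineticsModel.from_preset(kin_cfg)
        else:
            kinetics = KineticsModel.from_config(kin_cfg)
        sched_cfg = dict(raw.get("schedule", {}))
        if "csv" in sched_cfg:
            schedule = read_schedule_csv(
                sched_cfg["csv"], dt_days=sched_cfg.get("dt_days", kinetics.dt_days)
            )
        else:
            schedule = sinusoidal_scenario(
                t_max=sched_cfg.get("t_max", 10),
                dt_days=sched_cfg.get("dt_days", kinetics.dt_days),
            )
        part_cfg = raw.get("partition")
        partition = (
            Partition(float(part_cfg[0]), float(part_cfg[1]), kinetics.r_max)
            if part_cfg
            else None
        )
        return cls(
            kinetics=kinetics,
            schedule=schedule,
            sample_sizes=tuple(int(n) for n in raw.get("sample_sizes", (1000,))),
            n_datasets=int(raw.get("n_datasets", 1000)),
            seed=int(raw.get("seed", 0)),
            partition=partition,
            clip=bool(raw.get("clip", False)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ExperimentResult:
    """Raw replicate estimates plus per-sample-size summaries."""

    truth_infected: np.ndarray
    truth_vaccinated: np.ndarray
    partition: Partition
    seed: int
    #: sample_size -> method -> class -> (n_datasets, t_max) estimate array
    estimates: dict = field(default_factory=dict)
    #: sample_size -> summary dict (see :func:`summarize_sweep`)
    summaries: dict = field(default_factory=dict)

    def replicates_frame(self) -> pd.DataFrame:
        """Long per-replicate table: one row per (N_s, dataset, method, step)."""
        rows = []
        for ns, per_method in self.estimates.items():
            for method, per_class in per_method.items():
                q_i = per_class["q_infected"]
                q_v = per_class["q_vaccinated"]
                n_datasets, t_max = q_i.shape
                for d in range(n_datasets):
                    for t in range(t_max):
                        rows.append(
                            (ns, d, method, t, q_i[d, t], q_v[d, t],
                             self.truth_infected[t], self.truth_vaccinated[t])
                        )
        return pd.DataFrame(
            rows,
            columns=[
                "sample_size", "dataset", "method", "time_step",
                "q_I_hat", "q_V_hat", "q_I_true", "q_V_true",
            ],
        )

    def summary_json(self, indent: int = 2) -> str:
        payload = {
            "partition": [self.partition.c1, self.partition.c2],
            "seed": self.seed,
            "error_metric": (
                "percent relative error of the across-dataset mean estimate, "
                "mean +/- sd over time steps; absolute alternative in "
                "prevalence units"
            ),
            "sweeps": {str(ns): s for ns, s in self.summaries.items()},
        }
        return json.dumps(payload, indent=indent)


def exact_qhat_series(
    kinetics: KineticsModel, schedule: IncidenceSchedule, partition: Partition
) -> np.ndarray:
    """Noise-free subdomain-fraction series: exact mixture masses per step."""
    dens = MeasurementDensity(kinetics, schedule)
    return np.stack(
        [dens.subdomain_masses(partition, T) for T in range(schedule.t_max + 1)]
    )


def run_noiseless(
    kinetics: KineticsModel,
    schedule: IncidenceSchedule,
    partition: Partition | None = None,
) -> dict[str, EstimationResult]:
    """Run both schemes on exact subdomain masses (identity-recovery mode)."""
    if partition is None:
        partition = default_partition(kinetics, schedule)
    q = exact_qhat_series(kinetics, schedule, partition)
    return {m: _ESTIMATORS[m](q, kinetics, partition) for m in METHODS}


def _replicate_qhat(kinetics, schedule, partition, n, seed, sweep, dataset):
    t_max = schedule.t_max
    rows = np.zeros((t_max + 1, 3))
    for T in range(1, t_max + 1):
        rng = substream(seed, dataset, T, sweep=sweep)
        r, _, _ = sample_measurements(kinetics, schedule, T, n, rng)
        counts = np.bincount(
            np.digitize(r, [partition.c1, partition.c2]), minlength=3
        )
        rows[T] = counts / n
    return rows


def summarize_sweep(per_method: dict, truth_i, truth_v, n_failed: int) -> dict:
    """Accuracy and spread summary for one sample size."""
    out: dict = {"n_failed": n_failed}
    truths = {"infected": truth_i, "vaccinated": truth_v}
    for method, per_class in per_method.items():
        block: dict = {}
        for klass, truth in truths.items():
            est = per_class[f"q_{klass}"]
            mean = np.nanmean(est, axis=0)
            sd = np.nanstd(est, axis=0, ddof=1)
            rel = np.abs(mean - truth) / truth * 100.0
            absd = np.abs(mean - truth)
            # per-replicate alternative: mean over datasets of |error|/truth
            rep_rel = np.nanmean(np.abs(est - truth) / truth * 100.0, axis=0)
            block[klass] = {
                "mean_estimate": mean.tolist(),
                "sd_estimate": sd.tolist(),
                "relative_error_pct": rel.tolist(),
                "mean_relative_error_pct": float(np.mean(rel)),
                "sd_relative_error_pct": float(np.std(rel, ddof=1)),
                "mean_absolute_error": float(np.mean(absd)),
                "sd_absolute_error": float(np.std(absd, ddof=1)),
                "replicate_mean_relative_error_pct": float(np.mean(rep_rel)),
            }
        out[method] = block
    if all(m in per_method for m in METHODS):
        cross = {}
        for klass in truths:
            a = per_method["recursive"][f"q_{klass}"]
            b = per_method["transition-matrix"][f"q_{klass}"]
            cross[klass] = {
                "mean_diff_norm": float(
                    np.linalg.norm(np.nanmean(a, 0) - np.nanmean(b, 0))
                ),
                "sd_diff_norm": float(
                    np.linalg.norm(
                        np.nanstd(a, 0, ddof=1) - np.nanstd(b, 0, ddof=1)
                    )
                ),
            }
        out["cross_method"] = cross
    return out


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full replicated sweep described by ``config``.

    For every sample size and dataset: generate per-step cross-sections,
    reduce them to subdomain fractions, run both estimators, and record the
    per-step prevalence estimates.  A replicate whose estimation fails
    (ill-posed partition) is recorded as NaN and counted, without aborting
    the sweep.
    """
    kinetics, schedule = config.kinetics, config.schedule
    partition = config.partition or default_partition(kinetics, schedule)
    prev = prevalence(schedule)
    t_max = schedule.t_max
    truth_i = prev.q_infected[:t_max]
    truth_v = prev.q_vaccinated[:t_max]
    result = ExperimentResult(
        truth_infected=truth_i,
        truth_vaccinated=truth_v,
        partition=partition,
        seed=config.seed,
    )
    for sweep_idx, ns in enumerate(config.sample_sizes):
        per_method = {
            m: {
                "q_infected": np.full((config.n_datasets, t_max), np.nan),
                "q_vaccinated": np.full((config.n_datasets, t_max), np.nan),
            }
            for m in METHODS
        }
        n_failed = 0
        for d in range(config.n_datasets):
            rows = _replicate_qhat(
                kinetics, schedule, partition, ns, config.seed, sweep_idx, d
            )
            try:
                for m in METHODS:
                    res = _ESTIMATORS[m](rows, kinetics, partition, clip=config.clip)
                    per_method[m]["q_infected"][d] = res.q_infected
                    per_method[m]["q_vaccinated"][d] = res.q_vaccinated
            except np.linalg.LinAlgError:
                n_failed += 1
        result.estimates[ns] = per_method
        result.summaries[ns] = summarize_sweep(per_method, truth_i, truth_v, n_failed)
    return result
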