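# seromarkov

Multiclass, time-dependent seroprevalence estimation from unlabeled
cross-sectional antibody measurements.

## The problem

As a disease emerges and vaccines roll out, a serology survey at calendar
step `T` returns scalar antibody measurements `r = log2(IgG level)` from a
mix of naive (`N`), once-infected (`I`) and once-vaccinated (`V`)
individuals — with no labels.  Antibody responses are time-dependent: `t`
days after an event, the measurement density is modeled as a gamma
distribution with fixed scale `β_n` and time-varying shape

    α_c(t) = θ₁,c·t / (1 + θ₂,c·t²) + α_n,     c ∈ {i, v},

which equals the naive shape `α_n` at `t = 0` and as `t → ∞` (responses
mount, then wane).  The population density at step `T` is therefore a
mixture whose weights are the per-step incidences `f_I(t), f_V(t)`:

    Q(r,T) = N(r) + Σ_{t<T} [R(r,(T−t)·dt) − N(r)]·f_I(t)
                  + Σ_{t<T} [W(r,(T−t)·dt) − N(r)]·f_V(t).

The same bookkeeping is generated by a 5-state time-inhomogeneous Markov
chain over (N, I′, I, V′, V) — previously/newly infected or vaccinated —
whose cumulative transition matrix `H_τ = S(τ)···S(0)` carries the
prevalences in its first column.  The package implements both routes,
verifies their equivalence numerically, and inverts the mixture: given
per-step subdomain counts of the samples, per-step linear systems recover
the incidences `f̂` and prevalences `q̂` (a *recursive* 2×2 scheme and a
*transition-matrix* 3×3 scheme, which agree to ~1e-15 on shared data).
A Weitzman overlap module quantifies how separable the class densities
are, which governs estimation error.

Intended users: biostatisticians and epidemiological modelers working with
serosurveillance data or designing serology studies.  Everything runs on
synthetic data drawn from the model itself; see `docs/methods.md` for
assumptions and what that does and does not demonstrate.

## Worked example

Estimate prevalences from one synthetic survey of 10 000 unlabeled samples
per 21-day step, over 10 steps of a single infection wave
(`f_I(t) = 0.01·sin(πt/10)`, `f_I(0) = 0.01`) with constant vaccination
(`f_V = 0.01`):

```python
import numpy as np
from seromarkov import (KineticsModel, sinusoidal_scenario, default_partition,
                        prevalence, estimate_transition_matrix, qhat)
from seromarkov.sampler import sample_measurements, substream

kin = KineticsModel.from_preset("sars2")     # gamma kinetics, dt = 21 days
sched = sinusoidal_scenario(10)
part = default_partition(kin, sched)         # density-crossing cut points
print(f"partition cuts: c1={part.c1:.3f}, c2={part.c2:.3f}")

rows = np.zeros((11, 3))
for T in range(1, 11):
    r, _, _ = sample_measurements(kin, sched, T, 10_000, substream(0, 0, T))
    rows[T] = qhat(r, part)                  # subdomain fractions at step T
res = estimate_transition_matrix(rows, kin, part)
```

Output (truth vs estimate; samples at step `T` inform step `T−1`, so steps
0–9 are estimable):

```
partition cuts: c1=4.940, c2=8.134
step  q_I_true  q_I_hat   q_V_true  q_V_hat
   0  0.0100     0.0157   0.0100     0.0063
   4  0.0366     0.0283   0.0500     0.0583
   9  0.0731     0.0665   0.1000     0.1036
```

The estimates track the truth but wobble: the infected and vaccinated
densities overlap by ~0.664 one step after the event
(`pair_ovl(kin, "IV", 1)`), so single surveys of this size are noisy, and
errors accumulate over steps.  Averaging over many replicate surveys
(`run_experiment`) shows the estimator is unbiased.  The same operations
are available from the shell:

```sh
seromarkov simulate --n 10000 --seed 0 --out samples.csv
seromarkov estimate samples.csv --method both
seromarkov overlap --pairs IV,NI,NV --steps 1-10
seromarkov experiment --preset-sweep --out results/
```

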