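# cyclefit

Nonlinear-model-based analysis of time-course gene expression profiles:
detection of periodically expressed genes and model-based clustering, built
around a damped-sinusoid-plus-trend model fitted by a non-iterative
two-step linear least-squares scheme.

## Who this is for

Experiments that follow a synchronized biological process — a yeast culture
released from alpha-factor arrest traversing the cell division cycle, for
example — measure every gene's expression at m equally spaced time points.
Two recurring questions are: *which genes actually follow the process*
(rather than fluctuating as noise), and *which genes share the same
dynamics* (co-expression clusters). Generic t-test screens and
distance-based clustering ignore the serial structure of a trajectory;
`cyclefit` answers both questions through an explicit dynamic model.

## The model

Each profile x(t), sampled at t_i = iΔ, i = 1..m, is modelled as

    x(t) = e^{αt} [a·cos(ωt) + b·sin(ωt)] + ct + d + ε(t),   ε ~ N(0, σ²)

- **α** — degradation (α < 0) or growth rate of the oscillation envelope,
- **ω** — angular frequency; amplitude A = √(a² + b²), phase Φ = atan2(a, b),
- **c, d** — linear trend and baseline.

The noise-free trajectory solves the linear ODE
x¨ + A x˙ + B x = Ct + D with α = −A/2, ω = √(4B − A²)/2, c = C/B,
d = D/B − AC/B². This turns the nonlinear fit into two ordinary linear
regressions, with no iteration, no starting values, and no local minima:

1. **Step 1** — estimate x˙ and x¨ by central finite differences and
   regress x¨ on [−x˙, −x, t, 1] to get (A, B, C, D), hence (α, ω, c, d).
   Profiles with 4B̂ − Â² ≤ 0 have no oscillatory solution and are flagged
   *degenerate* (not describable by the model).
2. **Step 2** — regress the de-trended, de-damped signal
   z(t) = e^{−αt}(x − ct − d) on cos(ωt) and sin(ωt) to get (a, b).

**Significance screen.** Against the white-noise null x(t) = d + ε(t), the
statistic F = [(S₀² − S₁²)/5] / [S₁²/(m − 6)] — with S₀² the residual about
the mean and S₁² the residual of the full fit — is referred to F(5, m − 6);
genes with F above the upper-γ critical value are called significant.

**Clustering.** A K-way partition is sought that minimizes the pooled
residual cost Σ_k Σ_{x∈C_k} Σ_i (x(t_i) − model_k(t_i))², by
relocation iteration: pooled per-cluster two-step estimation alternates
with reassignment of every profile to its best-fitting cluster model, from
many random initial partitions. Quality and stability are scored by the
adjusted Rand index (ARI) against ground truth and its average over
restarts (AARI).

## Worked example

```python
import numpy as np
from cyclefit import (ModelParams, Profile, evaluate_model,
                      fit_profile, classify_profiles)

truth = ModelParams(alpha=-0.1, omega=1.0, a=1.0, b=0.5, c=0.05, d=2.0)
profile = Profile("gene_A", evaluate_model(truth, m=100, delta=0.1), delta=0.1)

fit = fit_profile(profile)
print(fit.params)       # ModelParams(alpha=-0.100, omega=1.000, a=1.001, ...)
print(fit.s1_sq)        # 3.51e-05

result = classify_profiles([profile], gamma=0.1)[0]
print(result.f_value, result.threshold, result.significant)
# 1.45e+07  1.91  True
```

All six parameters are recovered to three decimals from a clean 100-point
trajectory, the fit residual is ~10⁻⁵, and the F statistic dwarfs the 90%
critical value of F(5, 94) — the gene is called significant.

The same pipeline from the shell, on a simulated benchmark:

```
$ cyclefit simulate --kind mixed --n-noise 500 --n-signal 500 --out-prefix demo --seed 42
$ cyclefit significance demo.tsv --gamma 0.1 --out demo.sig.tsv
significant     174
noise           826
$ cyclefit evaluate sweep demo.sig.tsv demo.truth.tsv
best_threshold  0.505044
sensitivity     0.6620
specificity     0.6620
```

Of 1000 profiles (half pure noise, half model-generated at the default
noise level σ = 0.5 and 18 time points), 174 clear the γ = 0.1 critical
value; sweeping all thresholds, the best balanced operating point
classifies 66% of each class correctly — short sampling and appreciable
noise make the screen conservative (see `docs/methods.md` for an analysis
of this regime). Clustering works the same way:

```
$ cyclefit simulate --kind clusters --k 3 --size 40 --out-prefix cl --seed 42
$ cyclefit cluster cl.tsv --k 3 --restarts 10 --seed 7 --truth cl.truth.tsv --out-prefix cl.out
best_cost       515.2221704
aari            0.8877
```

`cl.out.labels.tsv` holds the best partition and `cl.out.clusters.tsv` the
per-cluster parameter table (α_k, ω_k, a_k, b_k, c_k, d_k, size).

To analyse a real matrix (tab-separated, header row, gene ids in the first
column; genes with missing values are excluded at load time):

```
$ cyclefit significance expression.tsv --gamma 0.1 --out screen.tsv
$ cyclefit cluster expression.tsv --k 5 --restarts 30 --seed 1 --out-prefix clusters
```

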