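# hmrfmix

Spatial empirical-Bayes inference for voxel-level disease-association
studies: FDR-controlled detection **and** selection-bias-corrected
effect-size estimation under a hidden Markov random field.

## The problem

A structural or functional neuroimaging association study compares two
groups of subjects (e.g. converters vs. non-converters to Alzheimer's
disease) voxel by voxel.  Each voxel *s* yields a standardized mean
difference

    Y_s = (x̄_1s − x̄_2s) / σ̂_s ,

a sample-size-free effect-size statistic (essentially a two-sample
*t*-statistic times *c_n*, where *c_n* = √(n/(n₁n₂))).  Two questions
follow:

1. **Detection** — which voxels are associated with disease, controlling
   the false discovery rate, while exploiting the fact that associated
   voxels cluster spatially?
2. **Estimation** — how large are the effects in the *selected* voxels?
   The naive answer (report Y_s itself) systematically overestimates the
   top-ranked voxels: they were selected partly because random error
   pushed them up (the winner's curse).

## The model

Latent indicators Θ ∈ {0,1}^m (null/nonnull) follow an **Ising model** on
the 3-D voxel lattice with 6-neighbor contiguity,

    Pr(Θ = θ) ∝ exp( γ₁ Σ_{(s,t)∈S₁} θ_s θ_t + γ₂ Σ_s θ_s ),

so γ₁ encodes spatial clustering of disease-associated voxels and γ₂
their prevalence.  Given Θ, the statistics are independent with

    Y_s | Θ_s = 0  ~  N(0, c_n²)            (or c_n·t_{n−2} for small n),
    Y_s | δ_s, Θ_s = 1  ~  N(δ_s, c_n²)     (or noncentral t),
    δ_s ~ g,

where the effect-size distribution *g* is **nonparametric**: a discrete
distribution on B ≈ 200 mass points, estimated by the
smoothing-by-roughening method (early-stopped NPMLE fixed-point
iterations) inside a generalized EM algorithm whose E-step is a Gibbs
sampler of Θ | Y.

From the fitted model the package computes, per voxel:

* **LIS** (local index of significance) = Pr(Θ_s = 0 | all Y); the oracle
  LIS procedure sorts LIS ascending and rejects the largest prefix whose
  running mean stays ≤ α, which controls FDR at α under dependency.  A
  pooled variant combines LIS values from models fitted separately per
  brain subregion (e.g. an AAL-style parcellation).
* **d_s** = E[δ_s | y_s, Θ_s = 1], the posterior-mean effect given
  nonnull (shrinkage toward the fitted g), and
  **δ̂_s = d_s · (1 − LIS_s)**, which additionally discounts by the
  probability the voxel is null.  Together they correct the selection
  bias of the naive estimate.

Covariates (age, sex, intracranial volume, …) are handled by a voxel-wise
general linear model on intensities standardized to unit pooled
within-group variance; the adjusted statistic is the disease coefficient
with scale c_n = √((WᵀW)⁻¹₂₂) and df = n − p − 1.

## Worked example

```python
import numpy as np
from hmrfmix import (SimConfig, simulate_dataset, FitConfig, IsingParams,
                     VoxelLattice, calibrate_gamma2, fit, posterior_summary)

lattice = VoxelLattice.full((15, 15, 15))
gamma2 = calibrate_gamma2(gamma1=0.15, target_prop=0.20, lattice=lattice, seed=0)
print(f"calibrated gamma2 = {gamma2:.3f}")

cfg = SimConfig(n=100, gamma1=0.15, target_prop=0.20)
truth, data, lattice = simulate_dataset(cfg, seed=1, gamma2=gamma2)
print(f"m = {data.m} voxels, {truth.theta.mean():.1%} truly nonnull, c_n = {data.c_n:.3f}")

fit_cfg = FitConfig(fix_gamma=True, gamma_init=IsingParams(0.15, gamma2), max_iter=15)
result = fit(data, lattice, fit_cfg, seed=2)
print(f"fitted g mean = {result.params.g.mean:.3f} (generating mean 0.3)")

summ = posterior_summary(data, lattice, result.params, alpha=0.05, seed=3)
nulls = truth.theta == 0
n_rej = int(summ.rejected.sum())
print(f"rejected {n_rej} voxels at FDR 5%; "
      f"false discovery proportion = {(summ.rejected & nulls).sum() / max(n_rej, 1):.3f}")

top = np.argsort(-data.y)[:100]
print(f"top-100 voxels: naive bias = {(data.y[top] - truth.delta[top]).mean():+.3f}, "
      f"shrinkage bias = {(summ.delta_hat[top] - truth.delta[top]).mean():+.3f}")
```

Output:

```
calibrated gamma2 = -1.539
m = 3375 voxels, 21.4% truly nonnull, c_n = 0.200
fitted g mean = 0.291 (generating mean 0.3)
rejected 64 voxels at FDR 5%; false discovery proportion = 0.078
top-100 voxels: naive bias = +0.341, shrinkage bias = +0.015
```

Reading this: the external field was calibrated so one voxel in five is
associated; on one simulated dataset the fitted nonparametric effect
distribution centers near the generating mean 0.3; the LIS procedure
rejects 64 voxels (a single replicate's false discovery proportion
fluctuates around the nominal 5% — its *average* over replicates is what
the procedure controls); and among the 100 voxels with the largest
observed statistics the naive estimate overshoots the true effect by
+0.34 on average while the shrinkage estimate δ̂ is nearly unbiased.

The same pipeline is scriptable from the shell:

```sh
hmrfmix simulate --n 100 --seed 1 --out-prefix sim
hmrfmix fit --data sim_data.tsv --n1 50 --n2 50 --family t --out params.json
hmrfmix test --data sim_data.tsv --params params.json --n1 50 --n2 50 \
             --alpha 0.05 --out rejections.tsv
hmrfmix estimate --data sim_data.tsv --params params.json --n1 50 --n2 50 \
             --out estimates.tsv
hmrfmix run-sim-study --n 50 --n-reps 20 --out-prefix study
```

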