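# tfct — tensor-framelet iterative reconstruction for helical CT

`tfct` is a desk-scale toolkit for studying sparsity-regularized iterative
reconstruction of multislice **helical (spiral) cone-beam CT**, aimed at
researchers prototyping regularizers and solvers without vendor raw data.
It provides:

- a helical scan model with multi-row flat-panel detector, dimensionless
  pitch, and an optional (z and/or radial) flying-focal-spot schedule;
- a matched projector pair: a Joseph-style ray-driven forward projector
  `A` and its **exact numerical adjoint** `A^T`;
- the multilevel 3D **tensor framelet (TF)** transform `W` built from the
  piecewise-linear tight frame (masks ω₀ = ¼[1 2 1], ω₁ = √2/4[1 0 −1],
  ω₂ = ¼[−1 2 −1]) applied along each axis unfolding with weight 1/√3 and
  à-trous ("diluted") masks at deeper levels, satisfying `WᵀW = I` to
  machine precision;
- an **ADMM / split-Bregman** solver for

  `min_x ½‖Ax − y‖₂² + λ‖Wx‖₁`

  alternating a conjugate-gradient x-update (the tight-frame identity
  collapses the quadratic framelet term to μI), an isotropic shrinkage
  d-update, and a multiplier update — with isotropic **TV** available as
  the L = 1, (λ₁ > 0, λ₂ = 0) weight configuration, and a simplified
  helical **FDK** filtered-backprojection baseline;
- a synthetic-data module: analytic ellipsoid phantoms (including an
  accreditation-style cylinder with insert rods and an MTF edge block),
  Poisson transmission noise at selectable dose `I₀`, and the uniform
  sparse-view protocol (keep every 4th/8th/16th view);
- image-quality metrics: **UQI**, **SNR**, **CNR**, and **MTF** from an
  edge-spread profile.

## Worked example

```python
import numpy as np, tfct
from tfct.phantoms import (two_ellipsoid_phantom, simulate_scan, rasterize,
                           subsample_views, add_noise, NoiseModel)

grid = tfct.desk_grid()                    # 64 x 64 x 32 voxels at 2 mm
geom = tfct.desk_geometry(n_turns=2.0)     # pitch 1, 96 views/rotation, 16x96 panel
phantom = two_ellipsoid_phantom()
truth = rasterize(phantom, grid)

sino  = simulate_scan(phantom, geom, grid=grid)          # noiseless line integrals
noisy = add_noise(sino, NoiseModel(5e4, seed=7))         # Poisson, I0 = 5e4 photons
sub   = subsample_views(noisy, 8)                        # 12 views per rotation

cfg = tfct.ADMMConfig(weights=1e-3, mu=1.0, levels=2, outer_iterations=50)
tf_rec  = tfct.admm_reconstruct(sub, grid, cfg).volume
tv_rec  = tfct.tv_reconstruct(sub, grid, cfg).volume
fdk_rec = tfct.fdk_reconstruct(sub, grid)

tn = np.linalg.norm(truth.data)
for name, v in [("tf", tf_rec), ("tv", tv_rec), ("fdk", fdk_rec)]:
    print(name, round(100 * np.linalg.norm(v.data - truth.data) / tn, 1), "% RMSE")
```

prints (seed 7):

```
tf 6.5 % RMSE
tv 8.8 % RMSE
fdk 30.9 % RMSE
```

i.e. with 8x fewer views and realistic noise the TF reconstruction stays
within ~7% of ground truth while the analytic FDK baseline breaks down with
streaks; TV lands in between, and TF keeps sharper edges than TV at equal
regularization strength. On the same scan without noise and at full
sampling, TF reaches 0.3% RMSE within 50 outer iterations.

The same pipeline is available from the shell:

```bash
tfct run --geom geom.cfg --phantom phantom.txt --method tf \
         --dose 5e4 --step 8 --seed 7 --out results/
```

(`tfct simulate`, `subsample`, `reconstruct`, `evaluate` run the stages
individually; exit codes are 0/2/3 for ok/validation/solver failure.)

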