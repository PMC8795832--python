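# annealct

Simulated-annealing image reconstruction for ultralow-dose (sparse-view)
parallel-beam CT, with a benchmark of seven projection-domain cost
functions, wavelet-multiscale FBP initialization, FBP/ART baselines and
Student-t repetition statistics — exercised on a procedurally generated
lung phantom.

## The problem

CT dose scales with the number of projections. With only p = 18 views
over [0, π) (roughly a 10-fold dose reduction), the inverse Radon
problem is badly ill-posed and filtered back-projection (FBP) produces
streaky, low-fidelity images. This package reconstructs the
cross-section f(x, y) ∈ [0, 1]^{n×n} stochastically: starting from a
wavelet-domain FBP template, simulated annealing (SA) perturbs one
pixel at a time, re-projects incrementally, and accepts changes by the
Metropolis criterion

    h_k = exp(−ΔC / T_k),        T_k = (T0 − TN) / cosh(10 k / N) + TN,

where ΔC is the change in a cost C(P_M, P_P) between the measured
sinogram P_M(t, θ) and the postulated one P_P = R f̂_k. Because the
forward model is a binary line indicator (each pixel adds its value to
exactly one detector bin per view, t = round(x cos θ + y sin θ)), a
single-pixel move updates one bin per view — no backward projection is
ever required.

Seven cost functions are compared: MAE, RMSE, RMSLE, RSE, RAE
(error-type) and UIQI, SSIM (similarity-type, wrapped as 1 − index).
Reconstruction quality is scored by PSNR, relative Euclidean error
(EuE) and a noise-visibility-weighted PSNR (WPSNR). Repetition
statistics use Student-t margins of error E = t_{α/2} S / √n.

## Worked example

```python
import numpy as np
from annealct import *

truth = generate_lung_phantom(PhantomSpec(side=8, seed=7))
geom = ProjectionGeometry.uniform(18, side=8)         # p = 18 views
measured = radon_forward(truth, geom)

template = build_template(measured, side=8).image      # wavelet-FBP start
cfg = AnnealConfig(side=8, cost="rmsle", t_initial=0.1, t_final=1e-6,
                   n_iter=200_000, slab=1000, seed=1, stop_tolerance=0.0)
state = run_sa(measured, cfg, template=template)

print(f"template PSNR : {psnr(truth, template):.2f} dB")
print(f"SA(RMSLE) PSNR: {psnr(truth, state.best_estimate):.2f} dB")
print(f"EuE           : {euclidean_error(truth, state.best_estimate):.3f}")
print(f"WPSNR         : {wpsnr(truth, state.best_estimate):.2f} dB")
print(f"final cost    : {state.best_cost:.4g} after {state.k} iterations")
```

prints

```
template PSNR : 14.20 dB
SA(RMSLE) PSNR: 31.57 dB
EuE           : 0.059
WPSNR         : 30.94 dB
final cost    : 0.002155 after 200000 iterations
```

The wavelet template recovers the gross anatomy (14 dB); annealing
under the RMSLE cost closes most of the remaining sinogram misfit and
adds ~17 dB of fidelity at one-tenth the usual number of views. The
EuE of 0.059 says the remaining error is ~6 % of the image's energy.

The same machinery is scriptable from a shell:

```sh
annealct phantom --side 8 --seed 7 --out truth.csv
annealct project --image truth.csv --views 18 --out sino.csv
annealct reconstruct --sinogram sino.csv --side 8 --cost rmsle \
    --tn 1e-6 --stop-tol 0 --out recon.csv
annealct metrics --ref truth.csv --est recon.csv
annealct benchmark --side 8 --reps 5 --costs all --out table.csv
```

## Layout

| module | contents |
| --- | --- |
| `annealct.phantom` | seeded lung phantom, block-mean downsampling |
| `annealct.forward_model` | nearest-bin parallel-beam Radon projector |
| `annealct.wavelet_init` | wavelet-multiscale FBP template, universal threshold |
| `annealct.costs` | the seven cost functions and their aggregation |
| `annealct.annealer` | Metropolis/cooling engine with incremental updates |
| `annealct.metrics` | PSNR, EuE, WPSNR |
| `annealct.baselines` | FBP and Kaczmarz ART |
| `annealct.stats` | Student-t margins, intervals, APA records |
| `annealct.experiment` | repeated-run benchmark, convergence traces |

See `docs/methods.md` for the model details, parameter choices and
known limitations.
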