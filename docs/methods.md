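# Methods

## Forward model

The scanner is parallel-beam. An n×n image of absorption coefficients
f(x, y) ∈ [0, 1] is projected at M view angles θ_i = iπ/M onto a 1-D
detector of t_b unit-width bins centred on the grid. The projector is
a binary line indicator: pixel centres are measured from the grid
centre (x = col − (n−1)/2, y = (n−1)/2 − row) and each pixel adds its
full value to the single bin nearest to its rotated offset
t = x cos θ + y sin θ. Rounding is half-up (floor(t + 0.5)) so the
half-integer offsets of even-sided grids fall into distinct bins;
offsets are snapped to 9 decimals first so float noise in cos/sin
cannot flip an exact tie. Consequences used throughout: each view
conserves total image mass exactly, the map is linear, and a
single-pixel change touches exactly one bin per view — which is what
makes the annealer's incremental update exact rather than approximate.

The default detector width is the smallest odd integer ≥ √2·n, so
diagonal offsets never clip. No interpolating (Joseph/Siddon)
footprint is used and no noise is injected: the measured sinogram of a
phantom is exactly consistent with it. That choice matters for
interpreting baselines (below).

## Initial template

The annealer starts from a wavelet-multiscale filtered back-projection.
Per view: 1-D discrete wavelet decomposition (Daubechies-4 by default,
levels = ⌊log2 t_b⌋ − 2, at least 1, clipped to the wavelet's maximum
for the signal length; periodization boundary mode so the round trip
is exact), a hard universal threshold λ = σ̂·√(2 ln m) with
σ̂ = median(|finest detail|)/0.6745 and m the total coefficient count
applied to the detail bands, inverse transform, then the FBP ramp.
Because the wavelet transform is orthogonal, composing
inverse-transform-then-ramp equals the wavelet-domain filter
W R_fbp Wᵀ without assembling dense matrices, and with thresholding
off the pipeline reduces exactly to plain FBP (a unit test holds this
to 1e-6).

The ramp acts circularly on the t_b detector samples with response
2|f| (f in cycles/sample), which kills DC exactly; back-projection
uses linear interpolation between bins and the standard π/(2M) view
weighting. The template is clipped to [0, 1] and quantized to the
256-level intensity lattice.

## Cost functions

All costs act per view on (P_M, P_P) and are averaged over views;
similarity indices (UIQI, SSIM) are wrapped as 1 − mean(index) so that
one minimizer serves all seven. Projections are costed as raw line
integrals (no normalization). Definitions follow the standard forms:

- MAE, RMSE: mean absolute / root-mean-square difference over bins.
- RSE, RAE: squared/absolute error normalized by the measured view's
  variation about its own mean; undefined (rejected) for a constant
  measured view.
- RMSLE: √mean[(log(1+P_M) − log(1+P_P))²]. The log1p form is the
  standard definition and the only one defined for all non-negative
  data; it requires non-negative projections.
- UIQI: Wang–Bovik three-factor product (correlation × luminance ×
  contrast), sample moments with ddof = 1. The equivalent single-factor
  closed form 4σ_xy x̄ȳ/((σ_x²+σ_y²)(x̄²+ȳ²)) serves as the test
  oracle and as the numerically robust path inside the annealer.
- SSIM: l·c·s over the whole vector (projections are 1-D; no sliding
  window) with C1 = (0.01 L)², C2 = (0.03 L)², C3 = C2/2, where L is
  the dynamic range of the measured view (fallback 1 for a constant
  view).

## Annealing engine

Proposals draw a uniformly random pixel and a uniformly random level
on the {0, …, 255}/255 lattice. The postulated sinogram is maintained
incrementally (one bin per view receives the increment) and the
objective is tracked through per-view sufficient statistics — error
sums for the error costs; sums, squared sums and cross sums for
UIQI/SSIM — so one iteration costs O(M) regardless of t_b.
Accumulators are recomputed exactly from the arrays once per
temperature slab to bound floating-point drift; a dedicated test
verifies the incrementally maintained sinogram never departs from a
full reprojection by more than 1e-10 over 10⁴ moves.

Acceptance: improving moves always; worsening moves with probability
exp(−ΔC/T). The cooling profile T_k = (T0 − TN)/cosh(10k/N) + TN is
held constant within each slab (k truncated to the slab start). It
satisfies T(0) = T0 exactly and T(N) − TN = (T0 − TN)/cosh(10) ≈
9.1e-6·(T0 − TN)/1e-5 — within 1.1e-5 of TN for T0 = 0.1.

Defaults: T0 = 0.1, TN = 1.5e-3, slab = 1000, N = 3125·n² (2×10⁵ for
8×8, 8×10⁵ for 16×16), stop when the slab-over-slab best-cost
improvement of an error cost falls below stop_tolerance × best
(default 0.1), or at k = N. The best estimate seen so far is returned,
with the per-slab best-cost trace.

## Benchmark protocol

The cost-function sensitivity analysis forward-projects a seeded 8×8
phantom at p = 18 views and anneals every cost for five seeded
repetitions under one schedule: T0 = 0.1, TN = 1e-6, slab = 1000,
N = 2×10⁵, early stopping disabled (stop_tolerance = 0) so that every
cost experiences the identical, full schedule and convergence traces
span the whole cooling profile. TN = 1e-6 is the final temperature of
the comparison experiment itself (the cold tail is what lets the
error costs refine the last few intensity levels: at TN ≈ 1.5e-3 a
one-level flip of a single pixel changes an error cost by ~1e-3, so
the chain never freezes and all costs plateau well above their
achievable error). Five repetitions keep a full benchmark around two
minutes on one CPU; the per-cost spread at this size is 1–3 dB, so
orderings between adjacent costs (within ~1 dB) should be read with
that spread in mind.

Under this protocol the package reproduces the study's qualitative
findings at scale: the projection-error costs (RMSE, MAE, RMSLE) each
outperform the normalized/similarity costs (UIQI, SSIM, RSE, RAE) in
mean WPSNR, RMSLE ranks best, and its best-so-far cost falls below a
quarter (in practice, a few percent) of its initial value by k = N.

## Quality metrics

PSNR uses peak L = 1 and reports an infinity sentinel for identical
images. EuE is the relative Euclidean error ‖ref − est‖₂/‖ref‖₂
(undefined for an all-zero reference). WPSNR weights squared errors by
noise-visibility factors w = 1/(1 + σ²_local/σ²_global), where
σ²_local is the population variance over the border-clipped 3×3
neighbourhood of the reference and σ²_global its overall variance;
WMSE = Σw·d²/Σw. A constant reference degenerates to uniform weights,
making WPSNR = PSNR. EuE and WPSNR are this package's normative
definitions of those names; published absolute values computed with
other (unprinted) conventions are not comparable bit-for-bit, only in
ordering.

## Baselines

FBP: circular ramp per view, linear-interpolation back-projection,
min-max normalization, clip to [0, 1]. ART: unregularized Kaczmarz
over the (bin, view) equations of the nearest-bin system in cyclic
order, relaxation 0.25, 20 sweeps, non-negativity projection after
each sweep.

A consequence of the noiseless, exactly consistent study conditions:
the 18-view system for an 8×8 grid has ~234 equations for 64 unknowns
and admits the truth as an exact solution, so Kaczmarz converges
toward it and ART scores very high PSNR (~41 dB) — above SA's ~32 dB
at N = 2×10⁵ (and ~39 dB at N = 8×10⁵). On real measured data the
projection system is inconsistent at the reconstruction resolution and
ART stalls far earlier; the synthetic benchmark therefore overstates
ART relative to both SA and what is observed clinically. FBP remains
far below both (~14 dB) in every configuration tested.

## Phantom generator

A 2-D slice analogue of a fractal bronchial-tree phantom: thorax
ellipse (intensity 0.85) on zero background, two lung ellipses (0.15)
with a recursive bifurcating tree of bright segments (0.7) whose
length and width decay by 0.7 per generation, one large and one small
sprout per node, branch angles ±28° with seeded Gaussian jitter
(σ = 8°). Optional ground-glass blobs are seeded Gaussian bumps
(+0.3, σ ∈ [0.08, 0.15] in normalized units) placed peripherally in
the lung fields, mimicking the hazy peripheral densities seen in
COVID-19 chest CT. Geometry is rasterized at 4× supersampling and
block-averaged down, so sub-pixel jitter survives at small sides; the
result is clipped to [0, 1] and quantized to the intensity lattice.
Identical specs are bit-identical. What it does not emulate: detector
noise, beam hardening, scatter, anatomical variability, 3-D structure
— passing tests on it demonstrate algorithmic correctness and relative
cost-function behaviour, not clinical image quality.

## Statistics

Margins of error and confidence intervals use the Student-t quantile
from scipy. `margin_of_error` accepts an explicit critical value so a
published table quoting t_{α/2} at three decimals (2.093 for df = 19,
95 %) can be reproduced digit-for-digit; with the full-precision
quantile the recomputed margins differ from such a table in the sixth
decimal. The APA-style record for H0: μ = x̄ tested against the same
sample's mean is reproduced as a reporting convention; the test is
vacuous (always accepted) and the package does not endorse it as an
inference.

## Known limitations

- Parallel-beam only; fan-beam data must be rebinned upstream.
- The nearest-bin projector is exact for the SA bookkeeping but
  coarser than interpolating projectors; FBP/ART quality at small t_b
  reflects that.
- Run times in the benchmark table are wall-clock and
  hardware-dependent; they are reported but never compared against
  anything.
- At 8×8/16×16 with 18 views the quantized, noiseless problem is
  nearly (over)determined; conclusions about cost-function ordering at
  clinical resolutions require the full-scale setting.
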