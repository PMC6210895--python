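# Methods

`pssahcs` implements a prediction-based, spatial-spectral adaptive
compressive-sensing codec for hyperspectral image cubes, together with the
evaluation metrics used to judge it and a synthetic-cube generator that
reproduces the statistical structure the codec exploits. This note records
the model, the numerical choices, and what the synthetic experiments do and
do not demonstrate.

## The codec

A cube `f(x, y, z)` has `a` rows, `b` columns, `c` bands and integer DN
values of bit depth `n` (default 12). Encoding proceeds in five stages.

**1. Adaptive spatial blocking.** The discrete, normalized spatial
autocorrelation of band `z` at offset `(Δx, Δy)` is

    η(Δx, Δy, z) = Σ (f(x,y,z) − f̄_z)(f(x+Δx, y+Δy, z) − f̄_z)
                   / Σ (f(x,y,z) − f̄_z)²

with both sums over pixel pairs that lie inside the image, `f̄_z` the
band's global mean, and the result clipped to `[−1, 1]`. For each lag
`Δ = 1..lag_max` the row value `η(Δ,0,z)` and the column value `η(0,Δ,z)`
are averaged over a sample of 8 evenly spaced bands; the block size `M` is
the smallest lag whose mean falls in the window `[0.9, 0.95]` — the scale
on which blocks remain internally coherent. If every probed lag is above
the window the scene is smoother than the probe range and `M = lag_max`;
if the first lag is already below it the scene is noise-like and a minimum
practical block is used. The codec then floors `M` at `block_min = 32`
(see *Numerical choices*) and reflect-pads the grid so both dimensions are
multiples of `M`; padding is recorded and stripped after reconstruction.

**2. Spectral grouping.** Bands are partitioned by Lloyd k-means over
their vectorized images with the Euclidean distance
`D(z_i, z_c) = sqrt(Σ (f(x,y,z_i) − f(x,y,z_c))²)`. With `k = "auto"`
(default) the group count and the initial centroids come from the
adjacent-band spectral-correlation curve `ζ(z, z+1)`: every drop below
0.9 marks a group boundary — exactly the signature of atmospheric
absorption bands. With numeric `k`, seeded k-means++ initialization is
used. Assignment ties break toward the lower centroid index; an empty
cluster is re-seeded from the band farthest from its centroid; iteration
stops when assignments stop changing (cap 300). A width-3 majority
smoothing pass (default on) keeps groups contiguous in wavelength, which
is what prediction from a single in-group reference assumes.

**3. Key-band selection (LMLSD).** Within each group the least-noisy band
becomes the key band. A band is tiled into small sub-blocks (8×8 by
default — local statistics want many small windows, independent of the CS
block size); each sub-block contributes its mean `M_num` and sample
standard deviation `D_num` (divisor `ab − 1`). The range
`[min D, max D]` is split into 10 equal-width intervals; over the
sub-blocks of the most populated (modal) interval — the flattest common
texture, in practice the stage background — the band scores

    R = 20 · log10(M_mean / D_mean).

Noise inflates `D` in homogeneous sub-blocks, so the cleanest band has the
largest `R`. Ties (modal interval, argmax R) break toward the lower
index.

**4. Interband prediction.** Every non-key band `g` is modelled from its
group's key band as `f_g ≈ m·f_R + n`, with the closed-form least-squares
coefficients

    m = (E[f_R f_g] − E[f_R]E[f_g]) / (E[f_R²] − E[f_R]²),
    n = E[f_g] − m·E[f_R].

Prediction is *closed-loop*: the encoder first compresses and reconstructs
the key band, then fits `(m, n)` and forms residuals against the
prediction from the **reconstructed** key band — exactly what the decoder
will have, so there is no encoder/decoder drift. A constant reference
degenerates to `m = 0, n = mean(target)`, recorded in the package.
Residuals stay real-valued into the CS stage; integer rounding happens
once, at final cube output.

**5. Compressive sensing.** Each `M×M` block (key-band pixels or residual
values), raster-vectorized to `x ∈ R^N`, `N = M²`, is measured as
`y = Φx` with an i.i.d. Gaussian matrix `Φ ∈ R^{m×N}`, entries
`N(0, 1/m)`, regenerated from a recorded seed (the matrix itself is never
stored). The sparse basis `Ψ` is the separable orthonormal 2-D DCT
synthesis operator, so recovery solves `y ≈ (ΦΨ)θ` with stagewise
orthogonal matching pursuit: at each stage the matched filter
`c = Aᵀr` is compared with the formal noise level `σ = ‖r‖/√m`, all atoms
with `|c_j| > t·σ` join the running support (capped at `m`, keeping the
largest `|c|`), and least squares on the support columns updates the
residual; the loop stops at `max_stages`, at `‖r‖ ≤ tol·‖y‖`, or when no
new atom passes. Rank-deficient support solves return the minimum-norm
solution, and reconstruction is `Ψθ̂`, deterministic given `(y, seed,
parameters)`. Measurements are uniformly quantized per band with stored
min/max.

**Rate control.** The knob `bpp` is the fraction of the native cube bits
the stored measurements may occupy: each block receives
`m = round(bpp · N · n / q)` measurements of `q` bits, so stored bits
equal `bpp · N · n` per block exactly and the realized rate matches the
request to within one-measurement granularity. `budget_split` (default 2)
is the key/non-key per-band measurement ratio at *fixed total budget*:
under closed-loop prediction every non-key band's error is floored by its
key band's reconstruction error, so the key band is the group's rate
bottleneck and deserves a larger share; the ratio cancels when every band
is its own key band, which keeps the blocked-CS baseline at exactly the
target rate. Prediction coefficients (two 64-bit floats per non-key
band), quantizer ranges and seeds are side information, excluded from the
rate figure and reported separately (about 10 kbit for the default
preset, versus ~4 Mbit of measurements at `bpp 0.25`).

**Decoding** regenerates the operators from the recorded seeds,
reconstructs key bands, then residuals, re-adds predictions, clips to
`[0, 2ⁿ−1]`, rounds once, strips the padding. It reads nothing outside
the package; `compress → save → load → decompress` is bit-exact across
runs, and the container bytes themselves are reproducible.

**Baseline.** `baseline_blocked_cs` runs the same block plan, CS engine
and per-band budget with every band its own key band — no grouping, no
prediction — and is bit-identical to the full codec configured with
`k = c`.

## Evaluation metrics

Aggregate PSNR uses the 3-D MSE over all `a·b·c` voxels against the peak
`(2ⁿ−1)²`; identical cubes are flagged rather than scored. Per-band PSNR
is reported alongside, since the two differ whenever band quality varies.
Spatial fidelity is judged by row/column autocorrelation curves
`η(Δ,0,z)`, `η(0,Δ,z)` of showcase bands (nearest 440/620/980 nm when
wavelengths are present — a blue, a red and a NIR absorption band — else
first/middle/last). Spectral fidelity uses the Pearson band correlation
`ζ(z₁, z₂)` and mean spectral profiles. `evaluate` aggregates everything
into a JSON-serializable report.

## The synthetic generator

`tea_like_spec` emulates the statistics of a visible/NIR leaf
acquisition at desk scale: a 128×256×40 12-bit cube spanning 380–1030 nm,
three contiguous spectral groups, and absorption-like noisy bands (std 60
DN) at both spectral ends. Each group has one latent scene: a separable
AR(1) Gaussian field (per-step correlation ρ = 0.97) shaped by a smooth
elliptical "leaf on a homogeneous stage background" envelope and scaled
into the central ~80% of the DN range. Band `z` of the group is
`intercept_z + slope_z · scene` with slopes drifting a few percent
(0.98–1.02) across the group and per-group brightness levels — so bands
are exactly affine-predictable within a group before noise, adjacent-band
correlation is ≥ 0.95 inside groups and ≈ 0 across group boundaries, and
the generator returns the clean cube, the planted grouping and the
planted coefficients as ground truth.

Two statistical design points matter. The AR(1) fields are built by exact
stationary coloring (the first sample *is* the innovation), giving the
exact separable covariance with no warm-up waste and an analytic
`ρ^Δ` target for the lag-correlation tests. And the leaf envelope is
essential to LMLSD: on an unmasked AR(1) field the sub-block
standard-deviation distribution is broad and unimodal, so the modal
histogram interval flips between adjacent bins on count jitter and the
noise score is structurally unreliable; the near-flat background provides
the sharp low-`D` mode that real leaf-on-stage frames have. For the same
reason the within-group gain drift is kept small: a wide gain spread
makes texture differences between bands exceed the noise being detected.

**What passing tests on this generator do not show.** The scenes are
Gaussian and stationary inside the leaf; real leaves have veins, specular
highlights, and non-Gaussian reflectance statistics, and real band images
are not exactly affine functions of a reference band. Recovery rates and
PSNR values on the synthetic preset therefore characterize the pipeline's
correctness and its qualitative orderings (rate-distortion monotonicity,
prediction gain over blocked CS, absorption-band denoising), not absolute
performance on any real crop dataset.

## Numerical choices

- **StOMP threshold `t`.** The solver's own default is 2.5, the middle of
  the recommended 2–3 range of the algorithm's authors. The codec config
  uses 3.0, calibrated once on clean leaf cubes before the test values
  were frozen: with `N` atoms, roughly `2N·Q(t)` atoms cross the stage
  threshold by aliasing noise alone each stage (≈ 1% of `N` at `t = 2.5`
  versus ≈ 0.3% at `t = 3.0`), and the spurious selections cost 1–2 dB at
  every operating point. `max_stages = 10`, `tol = 1e−6`.
- **Minimum block size 32.** The stage threshold is `t/√m` in units of
  `‖r‖`; with 8×8 blocks the rate mapping yields `m ≤ 16` measurements,
  where `t/√m ≥ 0.75` means selection is unreliable by construction (at
  the lowest operating point `m = 6` and `t/√m > 1`: no atom can ever
  pass and blocks reconstruct as zero). 32×32 blocks put the solver in
  its intended regime and make the one-measurement rate granularity
  negligible. The ceiling stays at 64 (StOMP cost grows fast beyond).
- **Measurement quantizer 8 bits.** At fixed bit budget, quantizer depth
  trades measurement count against measurement precision. The 8-bit
  quantizer's noise floor (~50 dB) sits far above the solver's
  reconstruction error (26–40 dB here), so spending the saved bits on
  1.5× more measurements is strictly better at every operating point
  (+1.7 to +3.7 dB versus a 12-bit quantizer in the calibration runs).
- **budget_split 2.** See *Rate control*; equal split wastes the residual
  budget on reconstructing the key band's unstructured estimation error
  and forfeits the prediction advantage entirely (−0.1 dB versus the
  baseline, against +2 to +4 dB at ratio 2).
- **Autocorrelation estimator bias.** η subtracts the band's global
  sample mean, so for fields whose correlation length approaches the
  image size the estimate is biased low by order
  `(1+ρ)(1−ρ^Δ)/(n(1−ρ))`. At ρ = 0.99 on 256-pixel images this shifts
  the `[0.9, 0.95]` crossing from the analytic lag 6 to measured lag ~4
  regardless of band averaging — a property of the estimator, not of the
  selection rule, which is verified separately against the measured
  curve.
- **Degenerate inputs.** Constant bands raise a typed error in
  autocorrelation, spectral correlation and LMLSD (never NaN); a constant
  prediction reference falls back to the mean predictor; an all-constant
  quantizer range encodes exactly; an infeasible rate raises an error
  naming the minimum achievable rate; empty first StOMP selection returns
  the zero vector.
- **Tie-breaks.** All ties (k-means assignment, modal interval, argmax
  R, k-means++ given the seed) resolve toward the lower index, making
  every stage deterministic given its seeds.

## Problem sizes in the test suite

Formula-level tests run on ~10×10 images (100 instances per formula
against literal-transcription oracles). Structural recovery (grouping,
key bands, denoising, rate-distortion) runs on the full 128×256×40 preset
with fixed seed lists; the codec-versus-baseline comparison runs 20 seeds
on a 64×64×12 reduction of the preset. The whole suite completes in a few
minutes on one CPU; `scripts/acceptance.py` recomputes the headline
quantities from scratch in about two minutes.

## Known limitations

- Integer DN cubes only (no floating-point radiance), ENVI BSQ written
  natively with BIL/BIP converted on read.
- One affine predictor per non-key band from a single reference; no
  multi-reference or per-block prediction.
- No entropy coding of the quantized measurements; rates are measurement
  bits only.
- StOMP with least squares on the accumulated support is the only solver;
  on compressible (not exactly sparse) blocks its support selection is
  noticeably below oracle-support least squares, which bounds the
  achievable PSNR at a given rate.
- The LMLSD noise score needs a sizeable homogeneous image fraction; on
  scenes that are textured everywhere its modal interval is unstable at
  realistic sub-block counts.
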