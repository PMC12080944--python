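# Methods

This note documents the models, estimators and design decisions behind
`patchsmlm`, in the spirit of a methods section: what is computed, under
which assumptions, and where the known limits are.

## Image formation model (simulator)

A video is a stack of T frames of nonnegative counts. Per frame:

* **Placement.** Active emitters follow a homogeneous spatial Poisson
  process: the per-frame count is Poisson(ρ·A) for density ρ (emitters/µm²)
  and field-of-view area A; positions are uniform over the half-open FOV.
  Emitters are independent across frames (memoryless blinking; no on/off
  kinetics, no photobleaching).
* **PSF.** Each emitter deposits `photons ×` the per-pixel integral of a
  symmetric 2D Gaussian (difference of error functions along each axis) —
  the pixel-integrated model, which keeps photon accounting exact even for
  sub-pixel widths. The toy 3D mode uses the standard astigmatic defocus
  model σ_x(z) = σ₀√(1+((z−γ)/d)²), σ_y(z) = σ₀√(1+((z+γ)/d)²).
* **Noise.** A constant background (default 20 photons/pixel) is added, the
  image is Poisson-sampled, and Gaussian read noise (default mean 100, std
  10 counts) is added; negative values clip to zero. The combined noise
  floor is σ_n = √(σ_read² + background) ≈ 11 counts at the defaults.

Default optics follow a DNA-PAINT-style acquisition: 233 nm pixels, 670 nm
emission, NA 1.49, super-resolution upsampling factor 8. The default PSF
width is 0.5 px (117 nm) — the diffraction-limited width at these optics;
the PSF is deliberately under-sampled, as real data at this pixel pitch is.
Emitter brightness is lognormal with a configurable mean and a default
coefficient of variation of 0.3 (dye heterogeneity). When a simulation is
specified by SNR instead of photons, the photon budget is chosen so the
expected peak-pixel amplitude of a pixel-centered emitter equals SNR·σ_n —
the same definition the estimator targets.

What the simulator does **not** emulate: structured specimens (filaments,
rings) except as an optional phantom, blinking kinetics and rebinding,
drift, sCMOS pixel-dependent noise, vectorial/aberrated PSFs. Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not performance on real tissue data.

## Background statistics

All thresholds and signal estimates are referenced to the background (noise)
mean and std of the video. Emission signal is strictly positive, so the
background is the lower component of the pooled intensity histogram; it is
estimated by anchoring at the half-sample mode, taking the second moment of
the below-mode half, and refining with a truncated-Gaussian fit of the
sample below a fixed cut (the one-sided truncation relations are inverted by
fixed-point iteration, so the result is insensitive to the exact cut
position). If the robust values agree with the plain mean/std, the plain
values are returned — they are more efficient, and the video is then
signal-free to within sampling error. Fields of view larger than 64 px are
additionally split into 64-px tiles and the tile with the lowest robust
background mean is adopted when it clearly undercuts the pooled estimate:
real acquisitions contain structure-free regions, and anchoring there
removes the upward bias dense regions impose. Samples below ~5000 values use
sigma-clipped statistics instead (the mode estimator is too noisy there).

**Limitation:** in a field of view that is uniformly dense and dim
everywhere (no sparser region at all), part of the diffuse signal pedestal
is absorbed into the background mean and the density estimate degrades
toward underestimation. The estimator-accuracy tests therefore simulate the
condition under study next to a near-empty region, as real FOVs provide.

## Peak detection

The detection rule is: local maxima with intensity above the full-FOV mean
plus two standard deviations. Implemented as raw local maxima
(non-maximum-suppressed at `ceil(2σ)` px, minimum 1) validated on a
matched-filtered copy of the patch — a Gaussian smoothing of width 0.65 px,
computed by normalized convolution with border deamplification so the
false-positive rate is uniform across the patch. Validating on the smoothed
copy suppresses single-pixel noise excursions (a raw 2σ threshold would fire
on ~2% of noise pixels) while raw-resolution candidates preserve the ability
to resolve neighbouring emitters. The filter width trades false positives
against missed detections under the fixed 2σ threshold; 0.65 px minimizes
the combined error at the default optics and was fixed once from pure-noise
and single-emitter simulations.

## Per-patch density and SNR

Counting local maxima underestimates density as soon as PSFs overlap
(at ρ = 2/µm² and 233 nm pixels the mean nearest-neighbour distance is
~1.5 px) and misses sub-threshold emitters at low SNR. The per-patch
estimates therefore use a **method-of-moments channel** that needs no
per-emitter detection:

* excess mean over background: E = mean(patch) − µ_bg = λ·N
* excess spatial variance: V = var(patch) − σ_bg² − E = λ·N²·(1+κ²)·G₂

with λ the density per px², N the mean photons per emitter, κ = 0.3 the
nominal brightness CV, and G₂ the offset-averaged sum of squared pixel
masses of the unit PSF (computed numerically from the characterized width).
Inverting gives N = V/(E·G₂·(1+κ²)) and λ = E/N at any SNR, including
regimes where single emitters are invisible. The SNR is then the
centered-peak amplitude N·pf(σ) over the noise std of the patch's noise
pixels, where pf(σ) = erf(0.5/σ√2)² is the peak-pixel fraction; the
noise-pixel statistics are themselves estimated robustly because the 2σ-disk
signal mask cannot remove sub-threshold emitters or far PSF tails. The
signal mask uses radius `max(2, ceil(2σ))` px — the 2 px floor keeps the near
tails of sub-pixel PSFs out of the noise pixels.

When the moment channel reports no excess signal, the density falls back to
the detected count corrected for PSF-overlap merging by inverting the
Poisson-thinning relation n = λ·exp(−λa) (Lambert W, lower branch) with an
effective merge footprint a = 0.68·π(2σ_c)², σ_c = √(σ² + σ_f²); the 0.68
coefficient was calibrated once against simulated homogeneous fields (noise
splits marginally merged clusters back apart). The plain count-over-area
value is always available as `PatchStats.raw_density_um2`.

Measured accuracy at the four registry operating points (64×64 patch beside
a near-empty region, 30 frames): density 0.52 / 0.98 / 1.46 / 1.96 at true
0.5 / 1.0 / 1.5 / 2.0; SNR 7.8 / 5.9 / 4.0 / 1.9 at true 8 / 6 / 4 / 2. The
correct model is selected in ≥ 93 % of repeats at every operating point.

## PSF characterization

The first 100 detected emission events are fitted with a pixel-integrated
2D Gaussian (free: total flux, center, isotropic σ, offset) by nonlinear
least squares. Candidate events must be isolated — no neighbour within the
fit window, checked against a laxer (mean + 1.5 std) detection set so dim
neighbours also disqualify a window — and fits with residual RMS above
1.5 σ_bg are rejected (overlapping or distorted spots). The reported width
is the mean over fits after removing outliers beyond 2 robust standard
deviations of the fitted widths. Recovery: within 0.5 % noiselessly, within
2 % at SNR 8, and within ~8 % on a harsh composite video.

## Classical localizer backend

A stand-in for learned reconstruction backends, behind the same contract
(patch stack in; f-upsampled map plus emitter list out). Per frame it runs
two detect–fit–subtract passes: candidates from two detection scales (a
near-matched filter and a broadened one, because the under-sampled PSF loses
up to ~40 % of its peak response off-center), sub-pixel refinement by
pixel-integrated Gaussian fits on border-clipped windows, plausibility
filters (fitted σ within [0.25, 3.5]·σ_PSF; fitted flux able to explain the
detection response), duplicate suppression within max(1.5, 2σ) px, then
subtraction of the fitted spots and one more pass to recover merged pairs.
The default threshold is 3.75 noise-sigmas of the matched filter. At
ρ = 0.1/µm², SNR 8 this gives recall ≈ 0.91 and precision ≈ 0.93 with a
single-emitter localization RMSE of 0.19 raw pixels; residual misses are
dominated by FOV-edge emitters and sub-pixel-separation pairs. The four
registry models are four parameterizations of this backend (detection
threshold 4.5 / 4.0 / 3.75 / 3.5 for models 1–4).

## Model selection and rescaling

Difficulty levels use nearest-center assignment with midpoints rounding
toward the harder level; the two levels are averaged with half-integers
rounding up (prefer the model trained for harder conditions: an overpowered
model degrades gracefully, an underpowered one does not). SNR 0 (no signal)
maps to the hardest SNR level, the noiseless +∞ sentinel to the easiest; an
empty patch (density level 1, SNR level 4) therefore selects model 3.

Optics mismatches are absorbed by resampling frames by the factor
s = [(λ_e/NA_e)/(λ_m/NA_m)]·(p_m/p_e) — the ratio of the experimental to the
model diffraction-spot extent in pixels — with cubic interpolation,
anti-aliasing when shrinking, and renormalization so total intensity is
preserved. Factors outside [0.25, 4] warn as extrapolation.

## Pipeline

Patches are 64 px with zero overlap by default; the right/bottom edges are
zero-padded to a multiple of the stride, recorded in the grid so edge
patches can be down-weighted. Model selection runs once per video from the
leading frames (default 50). Overlapping reassembly averages uniformly.
A patch whose backend raises is left empty and flagged; a video with no
detectable emission events at all yields an all-zero reconstruction.

## Metrics

Images are preprocessed for comparison by clipping to the [0th, 99th]
percentile range, min-max normalization, and a Gaussian blur of σ = 2
super-resolution pixels. PSNR uses peak 1 after normalization; NRMSE is
normalized by the mean of the reference (ground-truth) image; MS-SSIM is the
standard five-scale construction (11-px Gaussian window, σ = 1.5, K₁ = 0.01,
K₂ = 0.03, exponents 0.0448/0.2856/0.3001/0.2363/0.1333, luminance only at
the coarsest scale; fewer scales with renormalized weights for small
images). Localization matching is optimal one-to-one assignment (Hungarian)
gated at 250 nm laterally and 500 nm axially by default, per frame; greedy
matching is available as a cross-check.

## 3D SNR characterization

Per-pixel time series are taken over the last 1000 frames of a sparse ROI.
The minimum-mean pixel supplies the additive-Gaussian noise mean and std
(ties break to the lowest row/col index); under the simulator's camera
model this "Gaussian" std includes the shot noise of the constant
background, which is what a training-data synthesizer needs. The maximum
pixel value (taken over the temporal maximum of the ROI, background-
subtracted) is converted to photons through the peak of the unit-photon PSF
at the central z position. Training parameters are drawn uniformly from
(1.0, 1.4)× the noise statistics and (0.5, 1.1)× the photon count. The MPV
is an extreme statistic: with heterogeneous emitter brightness it tracks the
bright tail rather than the mean, so photon recovery is validated with a
fixed per-emitter budget; a temporal-quantile option is provided as a robust
alternative.

## Gaussian-voxel representation

Emitters are encoded on a 3D voxel grid either as a 1 in the containing
voxel (binary) or as a unit-mass separable Gaussian of width 1 voxel per
axis centered at the continuous position. Decoding thresholds the grid at
0.1× the per-emitter peak, extracts 26-connected components of ≥ 2 voxels
(single-voxel components are kept for binary-valued grids), and reports each
component's intensity-weighted center of mass. Per-axis decoding RMSE is
~0.02 voxels for the Gaussian encoding versus the voxel/√12 ≈ 0.289-voxel
quantization limit of binary encoding — a ~14× precision advantage, which
is the representational point: a grid with 2× coarser voxels under Gaussian
encoding still outperforms the fine binary grid by more than 3×. Both
errors scale linearly with voxel size (every error source of the decoder is
proportional to the pitch). Emitters closer than ~2σ merge into one decoded
cluster; the count-preservation guarantee assumes ≥ 6σ separation.

## Problem sizes and numerical choices

Simulation-backed tests run at desk scale: 64–256 px fields of view, 20–40
frames for per-patch statistics, hundreds of repeats for rate estimates, and
10,000 draws/frames where a distributional mean is asserted. Tolerances
follow the quantity's sampling error (3 standard errors for means) or the
stated estimator accuracy bands. All randomness flows through
`numpy.random.default_rng` with explicit seeds; reruns are bit-identical.
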