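# patchsmlm

Patch-wise automated analysis for single-molecule localization microscopy
(SMLM).

High-density SMLM reconstruction methods are trained (or tuned) for a
particular emitter density and signal-to-noise ratio, but real acquisitions —
DNA-PAINT images of tissue especially — are heterogeneous: dense, dim
filament bundles sit next to sparse, bright background regions in the same
field of view. `patchsmlm` automates the operator decisions this creates:

* **Parameter extraction** — PSF width by nonlinear least-squares Gaussian
  fitting of the first ~100 isolated emission events; per-patch emitter
  density ρ (emitters/µm²) and SNR (mean signal amplitude over the noise
  standard deviation) from cheap image statistics.
* **Model selection** — each 64 × 64-pixel patch (14.9 µm at 233 nm pixels)
  is mapped to a difficulty level 1–4 by averaging its density-based and
  SNR-based levels against a registry of four pre-characterized operating
  points: (ρ, SNR) = (0.5, 8), (1.0, 6), (1.5, 4), (2.0, 2).
* **Patch pipeline** — tile, localize each patch with its selected model's
  backend, reassemble the 8×-upsampled per-patch maps. Backends are
  pluggable; a classical matched-filter + Gaussian-fit localizer ships with
  the package so everything runs without trained network weights.
* **Evaluation** — PSNR / NRMSE / MS-SSIM on preprocessed images, and
  Jaccard index plus lateral/axial RMSE from optimal one-to-one localization
  matching.
* **3D support** — SNR characterization from per-pixel time series of a
  sparse ROI (noise from the minimum-mean pixel, photon count from the
  maximum pixel value via the unit-photon PSF peak), and a Gaussian-voxel 3D
  emitter representation whose center-of-mass decoding localizes far below
  the voxel size.
* **Simulator** — synthetic videos with known ground truth: Poisson-placed
  emitters, pixel-integrated Gaussian (or astigmatic) PSFs, Poisson shot
  noise plus Gaussian read noise.

## The selection rule

A patch with estimated density ρ̂ and SNR ŝ is assigned

```
density level = level of the nearest registry density   (midpoints round harder)
snr level     = level of the nearest registry SNR       (midpoints round harder)
model         = round_half_up( (density level + snr level) / 2 )
```

so (ρ̂, ŝ) = (2.0, 2) → model 4 (hardest) and (0.5, 8) → model 1 (easiest).

## Worked example

Simulate a composite acquisition — easy conditions (ρ = 0.5/µm², SNR 8) on
the left half, hard conditions (ρ = 2.0/µm², SNR 2) on the right — and let
the pipeline pick models per patch:

```python
from patchsmlm import SimulationConfig, reconstruct, model_usage_histogram
from patchsmlm.simulator import simulate_two_region_video

easy = SimulationConfig(width_px=128, height_px=128, n_frames=30, density_um2=0.5, snr=8.0)
hard = easy.replace(density_um2=2.0, snr=2.0)
video, truth = simulate_two_region_video(easy, hard, seed=1)

sr, table, found = reconstruct(video, stats_frames=30, psf_sigma_guess=1.0)
print(table[["patch_row", "patch_col", "model_id", "density_um2", "snr"]].round(2))
```

```
 patch_row  patch_col  model_id  density_um2  snr
         0          0         1         0.35 9.32
         0          1         1         0.36 8.87
         0          2         4         1.38 2.24
         0          3         4         1.39 2.23
         1          0         1         0.34 9.20
         1          1         1         0.36 7.91
         1          2         4         1.44 2.21
         1          3         4         1.39 1.96
```

Every left-half patch selects model 1 and every right-half patch model 4:
the estimated SNR tracks the simulated value closely (≈ 9 vs 8, ≈ 2.2 vs 2),
and the density estimate separates the two regimes cleanly (the hard side is
underestimated — at SNR 2 most emitters are individually invisible and the
density is inferred from the patch's excess intensity moments). `sr.data`
holds the assembled 1024 × 2048 super-resolution map and `found` the
localization list; matching the easy side against ground truth gives a
Jaccard index of 0.77 and a lateral RMSE of 74 nm (0.32 raw pixels).

The command line mirrors the library:

```
patchsmlm simulate --out stack.tif --truth gt.csv --frames 50 --density 0.5 --snr 8
patchsmlm analyze  --input stack.tif --out recon.tif --table selections.csv
patchsmlm metrics  --pred recon.tif --truth reference.tif
patchsmlm match    --pred locs.csv --truth gt.csv --radius 250
patchsmlm snr3d    --input stack.tif --roi 0,0,16,16 --psf-peak 0.466 --out snr.json
```

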