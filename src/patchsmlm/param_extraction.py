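"""Automated experimental-parameter extraction from raw SMLM videos.

Two layers, mirroring the pipeline's workflow:

* **Global characterization** — full field-of-view background (noise)
  statistics and a PSF width/amplitude estimate obtained by nonlinear
  least-squares Gaussian fits of the first detected emission events (100 by
  default). Gaussian fitting is expensive, so it is only used for this
  one-off characterization.
* **Per-patch statistics** — emitters in each patch are found with a cheap
  local-maxima rule (intensity above the full-FOV mean plus two standard
  deviations), giving the emitter density; a binary signal/noise mask around
  the peaks yields noise and signal statistics and the SNR (mean signal
  amplitude, i.e. peak height above the noise mean, over the noise standard
  deviation).

Emission signal is strictly positive, so the global mean/std are estimated
robustly from the lower (signal-free) component of the intensity histogram;
candidate peaks are raw local maxima validated on a matched-filtered
(Gaussian-smoothed) copy of the patch, which suppresses single-pixel noise
excursions. Raw local-maxima counts undercount at high density (overlapping
PSFs merge) and at low SNR (sub-threshold emitters); the per-patch density
and brightness therefore come primarily from a method-of-moments channel
(excess mean and excess spatial variance of the patch), which needs no
per-emitter detection, with the overlap-corrected count as fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from scipy.special import erf, lambertw
from scipy.stats import norm
from skimage.feature import peak_local_max

from .simulator import VideoStack

_SQRT2 = math.sqrt(2.0)

#: Width (px) of the Gaussian matched filter used to validate candidate peaks.
DEFAULT_SMOOTH_SIGMA = 0.65

#: Empirical shrinkage of the analytic merge footprint pi*(2*sigma_c)^2: noise
#: splits marginally-merged clusters back into separate maxima. Calibrated once
#: against simulated homogeneous fields.
MERGE_AREA_COEF = 0.68


@dataclass(frozen=True)
class PSFStats:
    """PSF width and brightness from Gaussian fits of isolated emission events."""

    sigma_mean: float
    sigma_std: float
    amp_mean: float
    amp_std: float
    n_fits: int
    n_failed: int = 0

    def __post_init__(self):
        if self.sigma_mean <= 0:
            raise ValueError("sigma_mean must be > 0")
        if self.n_fits < 1:
            raise ValueError("n_fits must be >= 1")


@dataclass(frozen=True)
class GlobalFrameStats:
    """Full field-of-view background statistics and a rough density estimate.

    ``image_mean``/``image_std`` characterize the signal-free (background)
    intensity distribution of the video; the detection threshold is their
    mean-plus-two-standard-deviations combination.
    """

    image_mean: float
    image_std: float
    rough_density_um2: float = float("nan")

    def __post_init__(self):
        if self.image_std < 0:
            raise ValueError("image_std must be >= 0")

    @property
    def peak_threshold(self) -> float:
        """Detection threshold: mean intensity plus two standard deviations."""
        return self.image_mean + 2.0 * self.image_std


@dataclass(frozen=True)
class PatchStats:
    """Per-patch density, SNR and signal/noise statistics driving model selection.

    ``n_peaks`` is the mean raw detected peak count per analyzed frame;
    ``density_um2`` is the bias-corrected density estimate (see
    :func:`correct_density`). The uncorrected count-over-area value is
    ``n_peaks / patch_area_um2``.
    """

    density_um2: float
    snr: float
    noise_mean: float
    noise_std: float
    signal_mean: float
    signal_std: float
    n_peaks: float
    patch_area_um2: float

    def __post_init__(self):
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")

    @property
    def raw_density_um2(self) -> float:
        """Uncorrected peak count divided by patch area."""
        return self.n_peaks / self.patch_area_um2


def _clipped_stats(values: np.ndarray, clip: float = 3.0, iters: int = 5):
    """Iterative sigma-clipped mean/std (symmetric clip, so unbiased on a Gaussian)."""
    x = np.asarray(values, float).ravel()
    mu, sd = float(x.mean()), float(x.std())
    for _ in range(iters):
        if sd == 0:
            break
        keep = np.abs(x - mu) < clip * sd
        if not keep.any():
            break
        mu, sd = float(x[keep].mean()), float(x[keep].std())
    return mu, sd


def _half_sample_mode(sorted_x: np.ndarray) -> float:
    """Mode via the recursive half-sample (shortest half interval) estimator."""
    x = sorted_x
    while x.size > 3:
        k = (x.size + 1) // 2
        widths = x[k - 1 :] - x[: x.size - k + 1]
        i = int(np.argmin(widths))
        x = x[i : i + k]
    return float(x.mean())


def _robust_background_1d(x: np.ndarray):
    """Mode-anchored robust background mean/std of a pooled sample."""
    mu0, sd0 = float(x.mean()), float(x.std())
    if sd0 == 0:
        return mu0, 0.0
    if x.size < 5000:
        # the half-sample mode is too noisy on small samples
        return _clipped_stats(x)
    mode = _half_sample_mode(np.sort(x))
    below = x[x <= mode]
    if below.size < 20:
        return mu0, sd0
    sd = float(np.sqrt(np.mean((below - mode) ** 2)))
    mu = float(below.mean()) + math.sqrt(2.0 / math.pi) * sd
    if sd0 <= 1.08 * sd and abs(mu0 - mu) <= 0.15 * sd:
        return mu0, sd0
    return _truncated_gaussian_stats(x, mode + 0.25 * sd, mu, sd)


def background_stats(frames: np.ndarray, max_samples: int = 200_000, block_px: int = 64):
    """Estimate the background (noise) mean and std of a stack.

    Emission signal is strictly positive, so the background is the dominant
    lower component of the pooled intensity histogram: the half-sample mode
    anchors it, the second moment of the below-mode half gives its std, and a
    truncated-Gaussian refinement recovers mean and std efficiently. When the
    plain mean/std agree with the robust values the plain ones are returned
    (more efficient, and the video is signal-free to within sampling error).

    Fields of view larger than one block are additionally split into
    ``block_px`` tiles, each estimated robustly, and the tile with the lowest
    background mean adopted when it clearly undercuts the pooled estimate:
    real acquisitions contain structure-free (or at least sparser) regions,
    and anchoring the background there avoids the upward bias that dense
    regions impose on pooled statistics.
    """
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    x = frames.ravel()
    if x.size > max_samples:
        x = x[:: x.size // max_samples + 1]
    mu, sd = _robust_background_1d(x)
    t, h, w = frames.shape
    n_by, n_bx = h // block_px, w // block_px
    if n_by * n_bx > 1:
        estimates = []
        for i in range(n_by):
            for j in range(n_bx):
                xb = frames[:, i * block_px : (i + 1) * block_px, j * block_px : (j + 1) * block_px].ravel()
                if xb.size > max_samples // 4:
                    xb = xb[:: xb.size // (max_samples // 4) + 1]
                estimates.append(_robust_background_1d(xb))
        mu_b, sd_b = min(estimates, key=lambda e: e[0])
        if mu - mu_b > 0.02 * max(sd_b, 1e-12):
            mu, sd = mu_b, sd_b
    return mu, sd


def _truncated_gaussian_stats(x: np.ndarray, cut: float, mu0: float, sd0: float, iters: int = 10):
    """Gaussian mean/std from the sample below a fixed cut, truncation-corrected.

    Solves the one-sided truncation relations
    ``E[X | X <= c] = mu - sigma lam(k)`` and
    ``Var[X | X <= c] = sigma^2 (1 - k lam - lam^2)`` with
    ``k = (c - mu)/sigma`` and ``lam = phi(k)/Phi(k)`` by fixed-point
    iteration. Efficient (root-n) and insensitive to the exact cut position,
    which only needs to sit below the signal.
    """
    kept = x[x <= cut]
    if kept.size < 20:
        return mu0, sd0
    m_k, v_k = float(kept.mean()), float(kept.var())
    mu, sd = mu0, sd0
    for _ in range(iters):
        if sd <= 0:
            return mu0, sd0
        k = min((cut - mu) / sd, 4.0)
        lam = norm.pdf(k) / max(norm.cdf(k), 1e-12)
        var_factor = 1.0 - k * lam - lam**2
        if var_factor <= 0.05:
            break
        sd_new = math.sqrt(v_k / var_factor)
        mu_new = m_k + lam * sd_new
        if abs(mu_new - mu) < 1e-8 and abs(sd_new - sd) < 1e-8:
            mu, sd = mu_new, sd_new
            break
        mu, sd = mu_new, sd_new
    return float(mu), float(sd)


def global_stats(video: VideoStack, n_frames: int = 50, min_separation: int = 1) -> GlobalFrameStats:
    """Background mean/std over the leading frames plus a rough density estimate.

    The rough density counts above-threshold local maxima per frame, corrects
    them for PSF-overlap merging, and divides by the field-of-view area.
    """
    t = min(video.n_frames, n_frames)
    sub = np.asarray(video.frames[:t], float)
    mu, sd = background_stats(sub)
    stats = GlobalFrameStats(image_mean=mu, image_std=sd)
    counts = [len(detect_peaks(frame, stats, min_separation=min_separation)) for frame in sub]
    area_px = sub.shape[1] * sub.shape[2]
    px_area_um2 = video.fov_um2 / area_px
    lam_px = correct_count_overlap(float(np.mean(counts)) / area_px, merge_area_px2=None)
    return GlobalFrameStats(image_mean=mu, image_std=sd, rough_density_um2=lam_px / px_area_um2)


@lru_cache(maxsize=64)
def _border_factors(n: int, smooth_sigma: float):
    """1D normalized-convolution mass and noise-deamplification per position.

    Near the patch border the smoothing kernel averages fewer pixels, which
    raises its noise variance; the deamplification factor rescales border
    responses so the false-positive rate is uniform across the patch.
    """
    from scipy.ndimage import gaussian_filter1d

    k = gaussian_filter1d(np.eye(n), smooth_sigma, axis=1, mode="constant")
    mass = k.sum(axis=1)
    energy = (k**2).sum(axis=1)
    mid = n // 2
    rel_noise = np.sqrt(energy) / np.maximum(mass, 1e-12)
    deamp = rel_noise[mid] / np.maximum(rel_noise, 1e-12)
    return mass, np.minimum(deamp, 1.0)


def matched_filter_response(patch: np.ndarray, baseline: float, smooth_sigma: float) -> np.ndarray:
    """Gaussian matched-filter response above ``baseline``, border-corrected.

    Uses normalized convolution against a constant background so border
    responses are unbiased, then deamplifies them to equalize the noise level
    across the patch.
    """
    h, w = patch.shape
    my, dy = _border_factors(h, smooth_sigma)
    mx, dx = _border_factors(w, smooth_sigma)
    filt = gaussian_filter(patch - baseline, smooth_sigma, mode="constant", cval=0.0)
    filt /= np.outer(my, mx)
    filt *= np.outer(dy, dx)
    return filt


def detect_peaks(
    patch: np.ndarray,
    stats: GlobalFrameStats,
    min_separation: int = 1,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
) -> np.ndarray:
    """Local maxima whose matched-filter response exceeds the global threshold.

    Candidates are raw local maxima (non-maximum-suppressed at
    ``min_separation`` px); a candidate is kept when the Gaussian-smoothed
    patch exceeds the global mean-plus-two-standard-deviations threshold at
    its position, which rejects single-pixel noise excursions while keeping
    sub-pixel-scale resolution between neighbouring emitters. Returns an
    ``(n, 2)`` array of (row, col) coordinates.
    """
    patch = np.asarray(patch, float)
    if patch.size == 0:
        raise ValueError("patch must be nonempty")
    thr = stats.peak_threshold
    peaks = peak_local_max(
        patch,
        min_distance=max(1, int(min_separation)),
        exclude_border=False,
    )
    if len(peaks) == 0:
        return peaks.reshape(0, 2)
    if smooth_sigma > 0:
        filt = stats.image_mean + matched_filter_response(patch, stats.image_mean, smooth_sigma)
    else:
        filt = patch
    keep = filt[peaks[:, 0], peaks[:, 1]] > thr
    return peaks[keep]


def merge_area_px2(psf_sigma_px: float, smooth_sigma: float = DEFAULT_SMOOTH_SIGMA) -> float:
    """Effective footprint within which two emitters yield one local maximum.

    Two blobs of combined width ``sigma_c = hypot(sigma_psf, sigma_filter)``
    merge when closer than about ``2 sigma_c``; the empirical coefficient
    accounts for noise re-splitting marginal merges.
    """
    sigma_c = math.hypot(psf_sigma_px, smooth_sigma)
    return MERGE_AREA_COEF * math.pi * (2.0 * sigma_c) ** 2


def correct_count_overlap(count_px: float, merge_area_px2: float | None = None) -> float:
    """Invert Poisson thinning: observed maxima density -> emitter density.

    For a homogeneous field of density lambda, maxima merge within an
    effective area ``a``, so the observed count density is
    ``lambda * exp(-lambda a)``. The inverse uses the Lambert W function
    (lower branch, lambda < 1/a); counts beyond the turnover saturate at
    ``1/a``.
    """
    if merge_area_px2 is None:
        merge_area_px2 = merge_area_px2_default()
    a = merge_area_px2
    if count_px <= 0 or a <= 0:
        return max(count_px, 0.0)
    arg = -a * count_px
    if arg <= -1.0 / math.e:
        return 1.0 / a
    lam = -float(np.real(lambertw(arg, k=0))) / a
    return lam


def merge_area_px2_default() -> float:
    return merge_area_px2(0.5)


def estimate_density(peaks, patch_area_um2: float) -> float:
    """Emitter density: detected peak count divided by the analyzed patch area.

    ``peaks`` may be a single peak array or a list of per-frame peak arrays
    (the count is then averaged over frames). This is the uncorrected
    count-over-area estimate; :func:`patch_stats` additionally corrects for
    overlap merging and sub-threshold emitters.
    """
    if patch_area_um2 <= 0:
        raise ValueError(f"patch_area_um2 must be > 0, got {patch_area_um2}")
    if isinstance(peaks, (list, tuple)):
        count = float(np.mean([len(p) for p in peaks])) if peaks else 0.0
    else:
        count = float(len(peaks))
    return count / patch_area_um2


def signal_noise_mask(patch_shape: tuple, peaks: np.ndarray, psf: PSFStats) -> np.ndarray:
    """Binary mask: 1 on signal pixels (within 2 sigma of a peak), 0 on noise.

    The radius has a 2 px floor so that sub-pixel PSFs still exclude their
    near tails from the noise statistics.
    """
    h, w = patch_shape
    mask = np.zeros((h, w), bool)
    peaks = np.asarray(peaks)
    if peaks.size == 0:
        return mask
    r = max(2, int(math.ceil(2.0 * psf.sigma_mean)))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = yy**2 + xx**2 <= r**2
    for row, col in peaks:
        r0, r1 = max(0, row - r), min(h, row + r + 1)
        c0, c1 = max(0, col - r), min(w, col + r + 1)
        mask[r0:r1, c0:c1] |= disk[r0 - (row - r) : r1 - (row - r), c0 - (col - r) : c1 - (col - r)]
    return mask


_TOP_SNR_SENTINEL = float("inf")


def estimate_snr(patch: np.ndarray, mask: np.ndarray, peaks: np.ndarray) -> PatchStats:
    """Noise/signal statistics and SNR for one patch frame.

    The SNR is the mean detected-peak amplitude (peak pixel value minus the
    noise mean) over the noise standard deviation. Density and patch area are
    left NaN; :func:`patch_stats` fills them when aggregating over frames. No
    signal pixels gives SNR 0; a noiseless patch with signal gives the +inf
    sentinel (mapped to the top SNR bin by the selector).
    """
    patch = np.asarray(patch, float)
    mask = np.asarray(mask, bool)
    if mask.shape != patch.shape:
        raise ValueError(f"mask shape {mask.shape} does not match patch shape {patch.shape}")
    noise_px = patch[~mask]
    signal_px = patch[mask]
    mu_n = float(noise_px.mean()) if noise_px.size else 0.0
    sd_n = float(noise_px.std()) if noise_px.size else 0.0
    if signal_px.size == 0:
        snr = 0.0
        sig_mu = sig_sd = 0.0
    else:
        sig_mu = float(signal_px.mean())
        sig_sd = float(signal_px.std())
        peaks = np.asarray(peaks)
        amp = float(patch[peaks[:, 0], peaks[:, 1]].mean()) - mu_n if peaks.size else sig_mu - mu_n
        snr = max(0.0, amp / sd_n) if sd_n > 0 else _TOP_SNR_SENTINEL
    return PatchStats(
        density_um2=float("nan"),
        snr=snr,
        noise_mean=mu_n,
        noise_std=sd_n,
        signal_mean=sig_mu,
        signal_std=sig_sd,
        n_peaks=float(len(peaks)),
        patch_area_um2=float("nan"),
    )


#: Nominal coefficient of variation of single-emitter brightness assumed by
#: the moment-based estimator (dye brightness heterogeneity).
BRIGHTNESS_CV = 0.3


@lru_cache(maxsize=64)
def _response_factors(psf_sigma_px: float, smooth_sigma: float):
    """Per-photon responses of the detection chain for one PSF width.

    Returns ``(pf_centered, mf_expected, g2)``: the raw peak-pixel fraction
    of a pixel-centered emitter, the expected matched-filter peak response
    averaged over uniform sub-pixel offsets, and the offset-averaged sum of
    squared pixel masses of the unit PSF (the energy factor of the variance
    channel). All computed by rendering a unit emitter numerically, so they
    track the pixel-integrated PSF model.
    """
    half = max(6, int(math.ceil(4 * (psf_sigma_px + smooth_sigma))))
    size = 2 * half + 1
    edges = np.arange(size + 1, dtype=float)
    pf_centered = float(erf(0.5 / (psf_sigma_px * _SQRT2)) ** 2)
    responses, g2s = [], []
    offsets = (np.arange(4) + 0.5) / 8.0  # uniform over [0, 0.5) by symmetry
    for dx in offsets:
        for dy in offsets:
            cx, cy = half + 0.5 + dx, half + 0.5 + dy
            gx = 0.5 * np.diff(erf((edges - cx) / (psf_sigma_px * _SQRT2)))
            gy = 0.5 * np.diff(erf((edges - cy) / (psf_sigma_px * _SQRT2)))
            img = np.outer(gy, gx)
            g2s.append(float((img**2).sum()))
            filt = gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
            responses.append(float(filt.max()))
    return pf_centered, float(np.mean(responses)), float(np.mean(g2s))


def moment_density_brightness(
    patch_frames: np.ndarray,
    stats: GlobalFrameStats,
    psf_sigma_px: float,
    kappa: float = BRIGHTNESS_CV,
):
    """Density and per-emitter brightness from the first two spatial moments.

    For emitters placed by a homogeneous Poisson process of density
    ``lambda`` (per px^2) with mean brightness ``N`` photons, the excess mean
    over the background is ``E = lambda N`` and the excess spatial variance is
    ``V = lambda N^2 (1 + kappa^2) G2`` with ``G2`` the sum of squared pixel
    masses of the unit PSF; signal shot noise contributes a further ``E`` to
    the variance. Inverting gives threshold-free estimates that work at any
    SNR, including regimes where emitters cannot be counted individually.
    Accuracy rests on the background statistics: the estimate degrades toward
    underestimation when the field of view has no signal-free region to anchor
    them. Returns ``(lambda_px2, photons)`` or ``(0.0, nan)`` when no excess
    signal is present.
    """
    frames = np.asarray(patch_frames, float)
    e1 = float(frames.mean()) - stats.image_mean
    var_excess = float(frames.var()) - stats.image_std**2 - max(e1, 0.0)
    _, _, g2 = _response_factors(round(psf_sigma_px, 3), 0.0)
    if e1 <= 0.05 * max(stats.image_std, 1e-12) or var_excess <= 0:
        return 0.0, float("nan")
    photons = var_excess / (e1 * g2 * (1.0 + kappa**2))
    lam = e1 / photons
    return lam, photons


def _integrated_gaussian_window(params, yy_edges, xx_edges):
    amp, x0, y0, sigma, offset = params
    gx = 0.5 * np.diff(erf((xx_edges - x0) / (sigma * _SQRT2)))
    gy = 0.5 * np.diff(erf((yy_edges - y0) / (sigma * _SQRT2)))
    return amp * np.outer(gy, gx) + offset


def fit_gaussian_spot(window: np.ndarray, sigma_guess: float = 1.5):
    """Least-squares fit of a pixel-integrated 2D Gaussian to one spot window.

    Free parameters: total intensity, center x/y, isotropic sigma, constant
    offset. Returns ``(amp, x0, y0, sigma, offset, residual_rms)`` in window
    pixel units (amp = fitted total photon count of the spot) or raises on
    failure.
    """
    window = np.asarray(window, float)
    h, w = window.shape
    yy_edges = np.arange(h + 1, dtype=float)
    xx_edges = np.arange(w + 1, dtype=float)
    offset0 = float(window.min())
    amp0 = max(float(window.sum() - offset0 * window.size), 1.0)
    r0, c0 = np.unravel_index(np.argmax(window), window.shape)
    p0 = [amp0, c0 + 0.5, r0 + 0.5, sigma_guess, offset0]

    def residuals(p):
        return (_integrated_gaussian_window(p, yy_edges, xx_edges) - window).ravel()

    res = least_squares(
        residuals,
        p0,
        bounds=([0.0, -1.0, -1.0, 0.15, -np.inf], [np.inf, w + 1.0, h + 1.0, max(h, w), np.inf]),
        max_nfev=200,
    )
    if not res.success:
        raise RuntimeError("Gaussian fit did not converge")
    amp, x0, y0, sigma, offset = res.x
    if not (0.15 < sigma < max(h, w) / 2):
        raise RuntimeError(f"fit sigma {sigma:.2f} outside plausible range")
    rms = math.sqrt(2.0 * res.cost / window.size)
    return float(amp), float(x0), float(y0), float(sigma), float(offset), float(rms)


def characterize_psf(
    video: VideoStack,
    max_events: int = 100,
    sigma_guess: float = 1.5,
    window_half: int = 5,
    stats: GlobalFrameStats | None = None,
) -> PSFStats:
    """Fit the first ``max_events`` emission events with a 2D Gaussian.

    Events are detected frame by frame with the global threshold rule; only
    isolated spots (no neighbouring detection inside the fit window, window
    fully inside the frame) are fitted. Fits with large residuals (overlapping
    or distorted spots) are rejected, and the width/amplitude averages exclude
    outliers beyond two robust standard deviations of the fitted widths;
    failures are excluded and counted.
    """
    if stats is None:
        mu, sd = background_stats(video.frames[: min(video.n_frames, 50)])
        stats = GlobalFrameStats(image_mean=mu, image_std=sd)
    h, w = video.frames.shape[1:]
    sigmas, amps = [], []
    n_failed = 0
    min_sep = max(1, int(math.ceil(2 * sigma_guess)))
    for t in range(video.n_frames):
        if len(sigmas) >= max_events:
            break
        frame = np.asarray(video.frames[t], float)
        peaks = detect_peaks(frame, stats, min_separation=min_sep)
        if len(peaks) == 0:
            continue
        # isolation is vetted against a laxer (mean + 1.5 std) detection set so
        # that dim neighbours, invisible to the main threshold, still disqualify
        # a window from the PSF fit
        if stats.image_std > 0:
            cand = peak_local_max(frame, min_distance=1, exclude_border=False)
            resp = matched_filter_response(frame, stats.image_mean, DEFAULT_SMOOTH_SIGMA)
            veto = cand[resp[cand[:, 0], cand[:, 1]] > 1.5 * stats.image_std]
        else:
            veto = peaks
        for row, col in peaks:
            if len(sigmas) >= max_events:
                break
            if not (window_half <= row < h - window_half and window_half <= col < w - window_half):
                continue
            others = veto[(veto[:, 0] != row) | (veto[:, 1] != col)]
            if len(others) and np.max(np.abs(others - [row, col]), axis=1).min() <= window_half + 1:
                continue
            window = frame[row - window_half : row + window_half + 1, col - window_half : col + window_half + 1]
            try:
                amp, _, _, sigma, _, rms = fit_gaussian_spot(window, sigma_guess=sigma_guess)
            except RuntimeError:
                n_failed += 1
                continue
            if stats.image_std > 0 and rms > 1.5 * stats.image_std:
                n_failed += 1  # residual too large: overlapping or distorted spot
                continue
            sigmas.append(sigma)
            amps.append(amp)
    if not sigmas:
        raise ValueError("no emission events found")
    if len(sigmas) < max_events:
        warnings.warn(
            f"only {len(sigmas)} emission events available (requested {max_events}); using all",
            stacklevel=2,
        )
    # average over fits robustly: residual outliers (overlapping spots that
    # still fit acceptably) would otherwise drag the width up
    sigmas = np.asarray(sigmas)
    amps = np.asarray(amps)
    med = np.median(sigmas)
    mad = np.median(np.abs(sigmas - med))
    keep = np.abs(sigmas - med) <= max(2.0 * 1.4826 * mad, 0.05 * med)
    return PSFStats(
        sigma_mean=float(sigmas[keep].mean()),
        sigma_std=float(sigmas[keep].std()),
        amp_mean=float(amps[keep].mean()),
        amp_std=float(amps[keep].std()),
        n_fits=int(keep.sum()),
        n_failed=n_failed + int((~keep).sum()),
    )


def patch_stats(
    patch_frames: np.ndarray,
    stats: GlobalFrameStats,
    psf: PSFStats,
    pixel_size_nm: float,
    n_frames: int = 50,
    min_separation: int | None = None,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    bias_correction: bool = True,
) -> PatchStats:
    """Aggregate per-patch statistics over the leading frames of a patch stack.

    Peak counts, peak amplitudes and noise pixels are pooled across
    ``min(n_frames, len(patch_frames))`` frames. With ``bias_correction`` the
    density estimate de-biases the raw count for sub-threshold emitters
    (truncated-Gaussian detection probability from the matched-filter
    amplitudes) and for PSF-overlap merging (Poisson-thinning inversion); the
    SNR amplitude is de-biased for the same threshold truncation.
    """
    patch_frames = np.asarray(patch_frames, float)
    if patch_frames.ndim == 2:
        patch_frames = patch_frames[None]
    t = min(len(patch_frames), n_frames)
    if min_separation is None:
        min_separation = max(1, int(math.ceil(2 * psf.sigma_mean)))
    h, w = patch_frames.shape[1:]
    area_um2 = h * w * (pixel_size_nm / 1000.0) ** 2
    counts, peak_vals, noise_vals, signal_vals = [], [], [], []
    for k in range(t):
        frame = patch_frames[k]
        peaks = detect_peaks(frame, stats, min_separation=min_separation, smooth_sigma=smooth_sigma)
        counts.append(len(peaks))
        mask = signal_noise_mask(frame.shape, peaks, psf)
        noise_vals.append(frame[~mask])
        signal_vals.append(frame[mask])
        if len(peaks):
            peak_vals.append(frame[peaks[:, 0], peaks[:, 1]])
    noise_px = np.concatenate(noise_vals) if noise_vals else np.empty(0)
    signal_px = np.concatenate(signal_vals) if signal_vals else np.empty(0)
    # robust statistics: the mask cannot remove sub-threshold emitters or far
    # PSF tails, which would otherwise inflate the noise std
    mu_n, sd_n = _robust_background_1d(noise_px) if noise_px.size else (0.0, 0.0)
    mean_count = float(np.mean(counts))

    lam_px = mean_count / (h * w)
    amp = float(np.concatenate(peak_vals).mean()) - mu_n if peak_vals else 0.0
    if bias_correction:
        lam_mom, photons = moment_density_brightness(patch_frames[:t], stats, psf.sigma_mean)
        if lam_mom > 0 and np.isfinite(photons):
            pf_centered, _, _ = _response_factors(round(psf.sigma_mean, 3), smooth_sigma)
            lam_px = lam_mom
            amp = photons * pf_centered
        else:
            lam_px = correct_count_overlap(lam_px, merge_area_px2(psf.sigma_mean, smooth_sigma))
    if amp > 0 and (peak_vals or lam_px > 0):
        snr = amp / sd_n if sd_n > 0 else _TOP_SNR_SENTINEL
    else:
        snr = 0.0
    density = lam_px * h * w / area_um2

    return PatchStats(
        density_um2=density,
        snr=snr,
        noise_mean=mu_n,
        noise_std=sd_n,
        signal_mean=float(signal_px.mean()) if signal_px.size else 0.0,
        signal_std=float(signal_px.std()) if signal_px.size else 0.0,
        n_peaks=mean_count,
        patch_area_um2=area_um2,
    )
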