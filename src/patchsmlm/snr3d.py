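"""SNR characterization for 3D reconstruction training-data synthesis.

From a sparse region of interest the workflow extracts per-pixel time series
over the last 1000 frames, takes the minimum-mean pixel as a pure-noise pixel
to estimate the additive Gaussian noise, and converts the maximum pixel value
(MPV) into a photon count via the peak of the unit-photon PSF at the central
z position. Training parameters are then drawn uniformly from fixed
multiplier ranges around the estimates: (1.0, 1.4) for the noise statistics
and (0.5, 1.1) for the photon count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Callable, Optional, Tuple

import numpy as np

from .simulator import VideoStack

NOISE_MULTIPLIER_RANGE = (1.0, 1.4)
PHOTON_MULTIPLIER_RANGE = (0.5, 1.1)


@dataclass(frozen=True)
class Snr3dResult:
    """Estimated noise statistics and photon count with their sampling ranges."""

    noise_mean: float
    noise_std: float
    photon_count: float
    mpv: float
    linear_factor: float
    noise_pixel: Tuple[int, int] = (0, 0)
    series_length: int = 1000
    noise_multiplier_range: Tuple[float, float] = NOISE_MULTIPLIER_RANGE
    photon_range_multipliers: Tuple[float, float] = PHOTON_MULTIPLIER_RANGE

    def __post_init__(self):
        if self.photon_count <= 0:
            raise ValueError("photon_count must be > 0")
        if self.linear_factor <= 0:
            raise ValueError("linear_factor must be > 0")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def build_pixel_series(video: VideoStack, roi: Tuple[int, int, int, int], n_frames: int = 1000) -> np.ndarray:
    """Per-pixel time series over the last ``n_frames`` frames of an ROI.

    ``roi`` is ``(x, y, w, h)`` in pixels. Returns an array of shape
    ``(h, w, L)`` with ``L = min(T, n_frames)``; stacks shorter than
    ``n_frames`` use all frames with a warning.
    """
    x, y, w, h = roi
    if w <= 0 or h <= 0:
        raise ValueError("ROI must be nonempty")
    fh, fw = video.frames.shape[1:]
    if x < 0 or y < 0 or x + w > fw or y + h > fh:
        raise ValueError(f"ROI {roi} outside the {fh}x{fw} field of view")
    t = video.n_frames
    if t < n_frames:
        warnings.warn(f"stack has only {t} frames (< {n_frames}); using all", stacklevel=2)
    crop = np.asarray(video.frames[-min(t, n_frames) :, y : y + h, x : x + w], float)
    return np.moveaxis(crop, 0, -1)


def noise_from_series(series: np.ndarray) -> Tuple[float, float, Tuple[int, int]]:
    """Gaussian-noise statistics from the minimum-mean ("noise") pixel.

    Ties on the minimum mean break toward the lowest (row, col) index.
    Returns ``(mean, std, (row, col))``.
    """
    series = np.asarray(series, float)
    if series.ndim == 1:
        series = series[None, None, :]
    if series.size == 0:
        raise ValueError("series set is empty")
    means = series.mean(axis=-1)
    idx = np.unravel_index(np.argmin(means), means.shape)  # argmin is first-minimum: row-major tie-break
    pix = series[idx]
    return float(pix.mean()), float(pix.std()), (int(idx[0]), int(idx[1]))


def photon_from_mpv(mpv: float, psf_peak: Callable[[float], float] | float, z_center_nm: float = 0.0):
    """Convert the maximum pixel value into a photon count via the PSF peak.

    ``psf_peak`` is the maximum pixel value of the *unit-photon* PSF, either
    as a number or a callable of z evaluated at the central z position; it is
    the linear factor between photons and counts. Returns
    ``(photon_count, linear_factor)``.
    """
    factor = float(psf_peak(z_center_nm)) if callable(psf_peak) else float(psf_peak)
    if factor <= 0:
        raise ValueError(f"linear factor must be > 0, got {factor}")
    return float(mpv) / factor, factor


def characterize_snr3d(
    video: VideoStack,
    roi: Tuple[int, int, int, int],
    psf_peak,
    z_center_nm: float = 0.0,
    n_frames: int = 1000,
    mpv_quantile: Optional[float] = None,
) -> Snr3dResult:
    """Full ROI workflow: noise pixel statistics plus MPV-derived photon count.

    The MPV is taken over the temporal-maximum projection of the ROI, after
    subtracting the estimated noise mean. ``mpv_quantile`` replaces the
    literal maximum by a temporal quantile (e.g. 0.999) as a robust option.
    """
    series = build_pixel_series(video, roi, n_frames=n_frames)
    mu_g, sigma_g, pixel = noise_from_series(series)
    if mpv_quantile is None:
        mpv = float(series.max()) - mu_g
    else:
        mpv = float(np.quantile(series, mpv_quantile)) - mu_g
    photons, factor = photon_from_mpv(mpv, psf_peak, z_center_nm)
    return Snr3dResult(
        noise_mean=mu_g,
        noise_std=sigma_g,
        photon_count=photons,
        mpv=mpv,
        linear_factor=factor,
        noise_pixel=pixel,
        series_length=series.shape[-1],
    )


def sample_training_ranges(result: Snr3dResult, n: int, seed=None):
    """Uniform draws of training parameters around the characterized values.

    Returns a dict of arrays ``noise_mean``, ``noise_std``, ``photons``:
    noise statistics scaled by multipliers uniform in (1.0, 1.4), photon
    counts by multipliers uniform in (0.5, 1.1). Reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    lo_n, hi_n = result.noise_multiplier_range
    lo_p, hi_p = result.photon_range_multipliers
    m_mean = rng.uniform(lo_n, hi_n, size=n)
    m_std = rng.uniform(lo_n, hi_n, size=n)
    m_phot = rng.uniform(lo_p, hi_p, size=n)
    return {
        "noise_mean": result.noise_mean * m_mean,
        "noise_std": result.noise_std * m_std,
        "photons": result.photon_count * m_phot,
        "noise_mean_multiplier": m_mean,
        "noise_std_multiplier": m_std,
        "photon_multiplier": m_phot,
    }
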