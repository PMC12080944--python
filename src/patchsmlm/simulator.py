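"""Synthetic SMLM video generation with known ground truth.

Emitters are placed by a homogeneous spatial Poisson process, rendered with a
pixel-integrated 2D Gaussian PSF (or an astigmatic elliptical Gaussian for the
toy 3D mode), and corrupted with Poisson shot noise plus additive Gaussian
read noise — the statistical structure the downstream parameter-extraction
and model-selection stages assume.

Conventions
-----------
* Lengths are nanometres unless a name says otherwise (``*_px`` is camera
  pixels).
* ``x`` maps to array columns and ``y`` to rows; pixel ``(i, j)`` covers the
  half-open square ``[j, j+1) x [i, i+1)`` in pixel units, so the centre of
  pixel ``(0, 0)`` sits at physical ``(0.5 p, 0.5 p)`` for pixel pitch ``p``.
* Emitter lists use the shared CSV schema
  ``frame, x_nm, y_nm, z_nm, photons``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import erf

from . import io as _io

_SQRT2 = math.sqrt(2.0)

EMITTER_COLUMNS = ["frame", "x_nm", "y_nm", "z_nm", "photons"]


@dataclass(frozen=True)
class OpticalConfig:
    """Camera and objective parameters attached to every video.

    Parameters
    ----------
    pixel_size_nm : float
        Camera pixel pitch projected to sample space, nm per pixel.
    wavelength_nm : float
        Emission wavelength, nm.
    na : float
        Numerical aperture of the objective, in (0, 1.7].
    upsampling_factor : int
        Ratio between the camera pixel pitch and the super-resolution grid
        pitch (default 8).
    """

    pixel_size_nm: float = 233.0
    wavelength_nm: float = 670.0
    na: float = 1.49
    upsampling_factor: int = 8

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if self.wavelength_nm <= 0:
            raise ValueError(f"wavelength_nm must be > 0, got {self.wavelength_nm}")
        if not 0 < self.na <= 1.7:
            raise ValueError(f"na must be in (0, 1.7], got {self.na}")
        if int(self.upsampling_factor) < 1 or self.upsampling_factor != int(self.upsampling_factor):
            raise ValueError(f"upsampling_factor must be a positive integer, got {self.upsampling_factor}")


@dataclass(frozen=True)
class NoiseParams:
    """Camera noise model: Poisson shot noise plus additive Gaussian noise.

    ``background_photons`` is the mean background level per pixel (subject to
    shot noise when ``poisson_enabled``); the Gaussian component models read
    noise and camera offset with mean ``gauss_mean`` and standard deviation
    ``gauss_std`` in counts.
    """

    background_photons: float = 20.0
    gauss_mean: float = 100.0
    gauss_std: float = 10.0
    poisson_enabled: bool = True

    def __post_init__(self) -> None:
        if self.background_photons < 0:
            raise ValueError(f"background_photons must be >= 0, got {self.background_photons}")
        if self.gauss_std < 0:
            raise ValueError(f"gauss_std must be >= 0, got {self.gauss_std}")

    @property
    def total_noise_std(self) -> float:
        """Std of the combined noise floor (shot noise on background + read noise)."""
        var = self.gauss_std**2
        if self.poisson_enabled:
            var += self.background_photons
        return math.sqrt(var)


class EmitterList:
    """Ground-truth or recovered emitter records.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``frame, x_nm, y_nm, z_nm, photons``. ``z_nm`` is NaN for 2D data.
    """

    def __init__(self, df: Optional[pd.DataFrame] = None):
        if df is None:
            df = pd.DataFrame({c: pd.Series(dtype=float) for c in EMITTER_COLUMNS})
        missing = [c for c in EMITTER_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"emitter table missing columns: {missing}")
        df = df[EMITTER_COLUMNS].reset_index(drop=True)
        if len(df) and (df["photons"] <= 0).any():
            raise ValueError("photons must be > 0 for every emitter")
        if len(df) and (df["frame"] < 0).any():
            raise ValueError("frame indices must be >= 0")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"EmitterList({len(self)} records, {self.df['frame'].nunique() if len(self) else 0} frames)"

    @classmethod
    def from_arrays(cls, frame, x_nm, y_nm, photons, z_nm=None) -> "EmitterList":
        n = len(np.atleast_1d(x_nm))
        z = np.full(n, np.nan) if z_nm is None else np.asarray(z_nm, float)
        return cls(
            pd.DataFrame(
                {
                    "frame": np.asarray(frame, int),
                    "x_nm": np.asarray(x_nm, float),
                    "y_nm": np.asarray(y_nm, float),
                    "z_nm": z,
                    "photons": np.asarray(photons, float),
                }
            )
        )

    def for_frame(self, t: int) -> pd.DataFrame:
        return self.df[self.df["frame"] == t]

    @property
    def is_3d(self) -> bool:
        return bool(len(self.df)) and bool(self.df["z_nm"].notna().any())

    def to_csv(self, path) -> None:
        _io.write_emitter_csv(self.df, path)

    @classmethod
    def from_csv(cls, path) -> "EmitterList":
        return cls(_io.read_emitter_csv(path))


@dataclass
class VideoStack:
    """A time-ordered stack of raw camera frames plus optical metadata."""

    frames: np.ndarray
    optics: OpticalConfig = field(default_factory=OpticalConfig)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(f"frames must be a T x H x W array with T >= 1, got shape {self.frames.shape}")
        if np.any(self.frames < 0):
            raise ValueError("frames must be nonnegative counts")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def fov_um2(self) -> float:
        h, w = self.frames.shape[1:]
        p_um = self.optics.pixel_size_nm / 1000.0
        return (h * p_um) * (w * p_um)

    def to_tiff(self, path, dtype=np.uint16) -> None:
        _io.write_stack(path, self.frames, self.optics, dtype=dtype)

    @classmethod
    def from_tiff(cls, path, optics: Optional[OpticalConfig] = None) -> "VideoStack":
        frames, meta_optics = _io.read_stack(path)
        return cls(frames=frames, optics=optics or meta_optics or OpticalConfig())


@dataclass(frozen=True)
class AstigmaticCalibration:
    """Axially varying PSF widths for the toy astigmatic 3D mode.

    The standard defocus model
    ``sigma_x(z) = sigma0 * sqrt(1 + ((z - gamma)/d)^2)`` and
    ``sigma_y(z) = sigma0 * sqrt(1 + ((z + gamma)/d)^2)``
    with focal-plane separation ``2*gamma`` introduced by the cylindrical
    lens and depth-of-focus parameter ``d``. ``gamma = 0`` collapses to the
    symmetric (2D) PSF at every z.
    """

    sigma0_px: float = 1.3
    gamma_nm: float = 250.0
    depth_nm: float = 400.0
    z_range_nm: tuple = (-750.0, 750.0)

    def sigma_x(self, z_nm):
        z = np.asarray(z_nm, float)
        return self.sigma0_px * np.sqrt(1.0 + ((z - self.gamma_nm) / self.depth_nm) ** 2)

    def sigma_y(self, z_nm):
        z = np.asarray(z_nm, float)
        return self.sigma0_px * np.sqrt(1.0 + ((z + self.gamma_nm) / self.depth_nm) ** 2)

    def check_z(self, z_nm) -> None:
        z = np.asarray(z_nm, float)
        lo, hi = self.z_range_nm
        if np.any((z < lo) | (z > hi)):
            raise ValueError(f"z outside calibrated range [{lo}, {hi}] nm")


def _integrated_gaussian_1d(edges_minus_center: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Mass of a unit 1D Gaussian inside pixels given edge offsets from the center."""
    e = erf(edges_minus_center / (sigma * _SQRT2))
    return 0.5 * np.diff(e, axis=-1)


def accumulate_gaussians(
    shape: tuple,
    x_px: np.ndarray,
    y_px: np.ndarray,
    photons: np.ndarray,
    sigma_x_px,
    sigma_y_px=None,
) -> np.ndarray:
    """Render pixel-integrated Gaussians onto a frame, vectorized over emitters.

    Each emitter deposits ``photons`` times the per-pixel integral of a unit
    Gaussian (difference of error functions along each axis), evaluated on a
    window of +/- 4 sigma around its position; mass outside the frame is lost.
    """
    H, W = shape
    x_px = np.atleast_1d(np.asarray(x_px, float))
    y_px = np.atleast_1d(np.asarray(y_px, float))
    photons = np.atleast_1d(np.asarray(photons, float))
    n = x_px.size
    if n == 0:
        return np.zeros(shape, float)
    sx = np.broadcast_to(np.asarray(sigma_x_px, float), (n,)).astype(float)
    sy = sx if sigma_y_px is None else np.broadcast_to(np.asarray(sigma_y_px, float), (n,)).astype(float)
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("PSF sigma must be > 0")

    half = int(np.ceil(4.0 * max(sx.max(), sy.max()))) + 1
    k = 2 * half + 1
    offs = np.arange(k)
    cols = np.floor(x_px).astype(int)[:, None] - half + offs[None, :]  # n x k
    rows = np.floor(y_px).astype(int)[:, None] - half + offs[None, :]
    edge = np.arange(k + 1)
    ex = _integrated_gaussian_1d(
        (np.floor(x_px)[:, None] - half + edge[None, :]) - x_px[:, None], sx[:, None]
    )  # n x k
    ey = _integrated_gaussian_1d(
        (np.floor(y_px)[:, None] - half + edge[None, :]) - y_px[:, None], sy[:, None]
    )
    w = photons[:, None, None] * ey[:, :, None] * ex[:, None, :]  # n x k x k
    rr = np.broadcast_to(rows[:, :, None], w.shape)
    cc = np.broadcast_to(cols[:, None, :], w.shape)
    valid = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    flat_idx = (rr[valid] * W + cc[valid]).ravel()
    frame = np.bincount(flat_idx, weights=w[valid].ravel(), minlength=H * W)
    return frame.reshape(H, W)


def peak_pixel_fraction(sigma_px: float) -> float:
    """Fraction of one emitter's photons landing in its (centered) peak pixel."""
    return float(erf(0.5 / (sigma_px * _SQRT2)) ** 2)


def photons_for_peak_snr(snr: float, sigma_px: float, noise: NoiseParams) -> float:
    """Photon budget so the expected peak amplitude is ``snr`` noise-sigmas.

    SNR here follows the estimator's definition: mean signal amplitude (peak
    pixel value above the background level) divided by the noise standard
    deviation (read noise plus shot noise on the background).
    """
    if snr < 0:
        raise ValueError("snr must be >= 0")
    return snr * noise.total_noise_std / peak_pixel_fraction(sigma_px)


def simulate_emitters(
    fov_w_nm: float,
    fov_h_nm: float,
    density_um2: float,
    n_frames: int,
    seed=None,
    mean_photons: float = 1500.0,
    photon_cv: float = 0.3,
) -> EmitterList:
    """Place emitters by a per-frame homogeneous Poisson process.

    Counts per frame are Poisson(density * area), positions uniform over the
    half-open field of view, photons lognormal around ``mean_photons`` with
    coefficient of variation ``photon_cv``.
    """
    if density_um2 < 0:
        raise ValueError(f"density must be >= 0, got {density_um2}")
    if fov_w_nm <= 0 or fov_h_nm <= 0:
        raise ValueError("field-of-view dimensions must be > 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    area_um2 = (fov_w_nm / 1000.0) * (fov_h_nm / 1000.0)
    counts = rng.poisson(density_um2 * area_um2, size=n_frames)
    total = int(counts.sum())
    frame_idx = np.repeat(np.arange(n_frames), counts)
    x = rng.uniform(0.0, fov_w_nm, size=total)
    y = rng.uniform(0.0, fov_h_nm, size=total)
    if photon_cv > 0:
        sig2 = math.log(1.0 + photon_cv**2)
        mu = math.log(mean_photons) - 0.5 * sig2
        photons = rng.lognormal(mu, math.sqrt(sig2), size=total)
    else:
        photons = np.full(total, float(mean_photons))
    return EmitterList.from_arrays(frame_idx, x, y, photons)


def _apply_noise(signal: np.ndarray, noise: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    img = signal + noise.background_photons
    if noise.poisson_enabled:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if noise.gauss_std > 0 or noise.gauss_mean != 0:
        img = img + rng.normal(noise.gauss_mean, noise.gauss_std, size=img.shape)
    return np.clip(img, 0.0, None)


def render_frame(
    emitters: pd.DataFrame,
    psf_sigma_px: float,
    noise: NoiseParams,
    optics: OpticalConfig,
    shape: tuple,
    seed=None,
) -> np.ndarray:
    """Render one camera frame from the emitters active in it.

    ``emitters`` is a slice of the shared emitter table (one frame). The PSF
    is an isotropic pixel-integrated Gaussian of width ``psf_sigma_px``.
    """
    if psf_sigma_px <= 0:
        raise ValueError(f"psf_sigma_px must be > 0, got {psf_sigma_px}")
    rng = np.random.default_rng(seed)
    p = optics.pixel_size_nm
    signal = accumulate_gaussians(
        shape,
        np.asarray(emitters["x_nm"], float) / p,
        np.asarray(emitters["y_nm"], float) / p,
        np.asarray(emitters["photons"], float),
        psf_sigma_px,
    )
    return _apply_noise(signal, noise, rng)


def render_frame_3d(
    emitters: pd.DataFrame,
    calibration: AstigmaticCalibration,
    noise: NoiseParams,
    optics: OpticalConfig,
    shape: tuple,
    seed=None,
) -> np.ndarray:
    """Render one frame with the astigmatic (z-dependent elliptical) PSF."""
    rng = np.random.default_rng(seed)
    z = np.asarray(emitters["z_nm"], float)
    z = np.where(np.isnan(z), 0.0, z)
    calibration.check_z(z)
    p = optics.pixel_size_nm
    signal = accumulate_gaussians(
        shape,
        np.asarray(emitters["x_nm"], float) / p,
        np.asarray(emitters["y_nm"], float) / p,
        np.asarray(emitters["photons"], float),
        calibration.sigma_x(z),
        calibration.sigma_y(z),
    )
    return _apply_noise(signal, noise, rng)


@dataclass
class SimulationConfig:
    """Full specification of a synthetic acquisition.

    Defaults emulate a DNA-PAINT-style acquisition on the pipeline's training
    optics: 233 nm pixels, PSF sigma 1.3 px, lognormal photon budgets, Poisson
    + Gaussian camera noise. Either ``mean_photons`` or ``snr`` fixes the
    brightness; when ``snr`` is given the photon budget is derived so the
    expected peak amplitude is ``snr`` times the noise floor.
    """

    width_px: int = 64
    height_px: int = 64
    n_frames: int = 50
    density_um2: float = 0.5
    snr: Optional[float] = 8.0
    mean_photons: Optional[float] = None
    photon_cv: float = 0.3
    psf_sigma_px: float = 0.5
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    noise: NoiseParams = field(default_factory=NoiseParams)
    z_mode: bool = False
    calibration: AstigmaticCalibration = field(default_factory=AstigmaticCalibration)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("frame dimensions must be >= 1 pixel")
        if self.snr is None and self.mean_photons is None:
            raise ValueError("one of snr or mean_photons must be set")

    def resolved_mean_photons(self) -> float:
        if self.mean_photons is not None:
            return float(self.mean_photons)
        sigma = self.calibration.sigma0_px if self.z_mode else self.psf_sigma_px
        return photons_for_peak_snr(self.snr, sigma, self.noise)

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def simulate_video(
    config: SimulationConfig,
    seed=None,
    tiff_path=None,
    csv_path=None,
):
    """Simulate a full stack with ground truth; optionally write fixtures.

    Returns ``(VideoStack, EmitterList)``. When paths are given, the stack is
    written as a 16-bit multi-page TIFF with a YAML metadata sidecar and the
    ground truth as the shared CSV schema; the written files round-trip
    bit-exactly through the package readers.
    """
    rng = np.random.default_rng(seed)
    p = config.optics.pixel_size_nm
    fov_w_nm = config.width_px * p
    fov_h_nm = config.height_px * p
    emitters = simulate_emitters(
        fov_w_nm,
        fov_h_nm,
        config.density_um2,
        config.n_frames,
        seed=rng,
        mean_photons=config.resolved_mean_photons(),
        photon_cv=config.photon_cv,
    )
    if config.z_mode:
        lo, hi = config.calibration.z_range_nm
        emitters.df["z_nm"] = rng.uniform(lo, hi, size=len(emitters))
    frames = np.empty((config.n_frames, config.height_px, config.width_px), float)
    shape = (config.height_px, config.width_px)
    for t in range(config.n_frames):
        sub = emitters.for_frame(t)
        if config.z_mode:
            frames[t] = render_frame_3d(sub, config.calibration, config.noise, config.optics, shape, seed=rng)
        else:
            frames[t] = render_frame(sub, config.psf_sigma_px, config.noise, config.optics, shape, seed=rng)
    video = VideoStack(frames=frames, optics=config.optics)
    if tiff_path is not None:
        video.to_tiff(tiff_path)
        video = VideoStack.from_tiff(tiff_path)
    if csv_path is not None:
        emitters.to_csv(csv_path)
    return video, emitters


def simulate_two_region_video(
    config_left: SimulationConfig,
    config_right: SimulationConfig,
    seed=None,
    tiff_path=None,
    csv_path=None,
):
    """Simulate a video whose left and right halves have different conditions.

    The two configs must agree on frame count, height and optics; the camera
    noise model of the left config applies everywhere. Useful both for
    composite-condition pipelines and for placing a dense test patch inside a
    field of view that, like real acquisitions, also contains signal-free
    background. Returns ``(VideoStack, EmitterList)`` with right-half emitter
    coordinates offset by the left width.
    """
    if config_left.n_frames != config_right.n_frames or config_left.height_px != config_right.height_px:
        raise ValueError("two-region configs must agree on n_frames and height_px")
    rng = np.random.default_rng(seed)
    p = config_left.optics.pixel_size_nm
    h = config_left.height_px
    w_l, w_r = config_left.width_px, config_right.width_px
    parts = []
    for cfg, x_off in ((config_left, 0.0), (config_right, w_l * p)):
        em = simulate_emitters(
            cfg.width_px * p,
            h * p,
            cfg.density_um2,
            cfg.n_frames,
            seed=rng,
            mean_photons=cfg.resolved_mean_photons(),
            photon_cv=cfg.photon_cv,
        )
        em.df["x_nm"] += x_off
        parts.append(em.df)
    emitters = EmitterList(pd.concat(parts, ignore_index=True))
    frames = np.empty((config_left.n_frames, h, w_l + w_r), float)
    shape = (h, w_l + w_r)
    for t in range(config_left.n_frames):
        frames[t] = render_frame(
            emitters.for_frame(t), config_left.psf_sigma_px, config_left.noise, config_left.optics, shape, seed=rng
        )
    video = VideoStack(frames=frames, optics=config_left.optics)
    if tiff_path is not None:
        video.to_tiff(tiff_path)
        video = VideoStack.from_tiff(tiff_path)
    if csv_path is not None:
        emitters.to_csv(csv_path)
    return video, emitters


def line_phantom_emitters(
    fov_w_nm: float,
    fov_h_nm: float,
    n_frames: int,
    emitters_per_frame: int,
    seed=None,
    mean_photons: float = 1500.0,
    jitter_nm: float = 20.0,
) -> EmitterList:
    """Structured preset: emitters scattered along a diagonal line, for visual checks."""
    rng = np.random.default_rng(seed)
    total = n_frames * emitters_per_frame
    t = rng.uniform(0.1, 0.9, size=total)
    x = t * fov_w_nm + rng.normal(0, jitter_nm, total)
    y = t * fov_h_nm + rng.normal(0, jitter_nm, total)
    x = np.clip(x, 0, np.nextafter(fov_w_nm, 0))
    y = np.clip(y, 0, np.nextafter(fov_h_nm, 0))
    frame = np.repeat(np.arange(n_frames), emitters_per_frame)
    photons = np.full(total, mean_photons)
    return EmitterList.from_arrays(frame, x, y, photons)
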