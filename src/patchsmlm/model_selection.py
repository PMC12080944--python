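"""Difficulty-level model selection and optics rescaling.

A small registry of pre-characterized reconstruction models covers the
(density, SNR) plane with four operating points; density increases and SNR
decreases with the difficulty level:

==========  =======================  =====
model       density (emitters/µm²)   SNR
==========  =======================  =====
1           0.5                      8
2           1.0                      6
3           1.5                      4
4           2.0                      2
==========  =======================  =====

Each patch is mapped to the level whose registry density is nearest to its
estimated density, likewise for SNR, and the two levels are averaged (halves
rounding up, i.e. toward the harder model) to pick the model. Optics
mismatches between an experiment and a model's training conditions are
absorbed by rescaling the frames so the diffraction-limited spot covers the
same number of pixels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import yaml
from skimage.transform import resize

from .simulator import OpticalConfig


@dataclass(frozen=True)
class ModelSpec:
    """One pre-characterized reconstruction model (a (density, SNR) operating point)."""

    model_id: int
    train_density_um2: float
    train_snr: float
    backend_handle: str = "classical"


@dataclass
class ModelRegistry:
    """Ordered model list plus the optics the models were characterized at.

    The default registry holds the four standard operating points; densities
    must be strictly increasing and SNRs strictly decreasing with model id.
    """

    models: List[ModelSpec]
    training_optics: OpticalConfig = field(default_factory=OpticalConfig)

    def __post_init__(self):
        if not self.models:
            raise ValueError("registry must contain at least one model")
        self.models = sorted(self.models, key=lambda m: m.model_id)
        dens = [m.train_density_um2 for m in self.models]
        snrs = [m.train_snr for m in self.models]
        if len(self.models) > 1:
            if not all(a < b for a, b in zip(dens, dens[1:])):
                raise ValueError("registry densities must be strictly increasing with model_id")
            if not all(a > b for a, b in zip(snrs, snrs[1:])):
                raise ValueError("registry SNRs must be strictly decreasing with model_id")

    def __len__(self):
        return len(self.models)

    def __getitem__(self, model_id: int) -> ModelSpec:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(f"no model with id {model_id}")

    @property
    def densities(self) -> np.ndarray:
        return np.array([m.train_density_um2 for m in self.models])

    @property
    def snrs(self) -> np.ndarray:
        return np.array([m.train_snr for m in self.models])

    def to_yaml(self, path) -> None:
        data = {
            "training_optics": {
                "pixel_size_nm": self.training_optics.pixel_size_nm,
                "wavelength_nm": self.training_optics.wavelength_nm,
                "na": self.training_optics.na,
                "upsampling_factor": self.training_optics.upsampling_factor,
            },
            "models": [
                {
                    "model_id": m.model_id,
                    "density": m.train_density_um2,
                    "snr": m.train_snr,
                    "backend": m.backend_handle,
                }
                for m in self.models
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelRegistry":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        opt = data.get("training_optics", {})
        return cls(
            models=[
                ModelSpec(
                    model_id=int(m["model_id"]),
                    train_density_um2=float(m["density"]),
                    train_snr=float(m["snr"]),
                    backend_handle=m.get("backend", "classical"),
                )
                for m in data["models"]
            ],
            training_optics=OpticalConfig(
                pixel_size_nm=opt.get("pixel_size_nm", 233.0),
                wavelength_nm=opt.get("wavelength_nm", 670.0),
                na=opt.get("na", 1.49),
                upsampling_factor=opt.get("upsampling_factor", 8),
            ),
        )


#: The four standard operating points.
DEFAULT_OPERATING_POINTS = ((1, 0.5, 8.0), (2, 1.0, 6.0), (3, 1.5, 4.0), (4, 2.0, 2.0))


def default_registry(backend_handle: Optional[str] = None) -> ModelRegistry:
    """Registry with the four standard (density, SNR) operating points.

    By default each model points at its own per-regime parameterization of
    the classical backend (``classical-m<i>``); pass a name to route every
    model to a single backend instead.
    """
    return ModelRegistry(
        models=[
            ModelSpec(mid, rho, snr, backend_handle or f"classical-m{mid}")
            for mid, rho, snr in DEFAULT_OPERATING_POINTS
        ]
    )


def density_level(density_um2: float, registry: ModelRegistry) -> int:
    """Difficulty level of the registry density nearest to the estimate.

    Exact midpoints round toward the harder (higher-density) level.
    """
    if density_um2 < 0 or not np.isfinite(density_um2):
        raise ValueError(f"density must be finite and >= 0, got {density_um2}")
    centers = registry.densities  # ascending
    midpoints = (centers[:-1] + centers[1:]) / 2.0
    return int(1 + np.sum(density_um2 >= midpoints))


def snr_level(snr: float, registry: ModelRegistry) -> int:
    """Difficulty level of the registry SNR nearest to the estimate.

    Midpoints round toward the harder (lower-SNR) level; SNR 0 (the no-signal
    convention) maps to the hardest level and the +inf noiseless sentinel to
    the easiest.
    """
    if snr < 0:
        raise ValueError(f"snr must be >= 0, got {snr}")
    if math.isinf(snr):
        return 1
    centers = registry.snrs  # descending
    midpoints = (centers[:-1] + centers[1:]) / 2.0
    return int(1 + np.sum(snr <= midpoints))


def select_model(stats, registry: ModelRegistry) -> int:
    """Average the density- and SNR-based difficulty levels to pick a model.

    ``stats`` is anything with ``density_um2`` and ``snr`` attributes (a
    :class:`~patchsmlm.param_extraction.PatchStats`). Half-integer averages
    round up, preferring the model trained for harder conditions.
    """
    dl = density_level(stats.density_um2, registry)
    sl = snr_level(stats.snr, registry)
    return (dl + sl + 1) // 2


def rescale_for_model(
    frames: np.ndarray,
    optics_exp: OpticalConfig,
    optics_model: OpticalConfig,
):
    """Resample frames so the experimental PSF extent in pixels matches the model's.

    The diffraction-limited spot spans ``(lambda/NA) / p`` pixels; the scale
    factor ``s = [(λ_e/NA_e)/(λ_m/NA_m)] * (p_m/p_e)`` is the ratio of the
    experimental to the model spot extent, so frames are resampled by ``1/s``
    (s > 1 shrinks the image). Total intensity is preserved. Returns
    ``(rescaled_frames, s)``.
    """
    s = ((optics_exp.wavelength_nm / optics_exp.na) / (optics_model.wavelength_nm / optics_model.na)) * (
        optics_model.pixel_size_nm / optics_exp.pixel_size_nm
    )
    if not 0.25 <= s <= 4.0:
        warnings.warn(f"rescale factor {s:.3g} outside validated range [0.25, 4]", stacklevel=2)
    frames = np.asarray(frames, float)
    if abs(s - 1.0) < 1e-12:
        return frames, 1.0
    squeeze = frames.ndim == 2
    if squeeze:
        frames = frames[None]
    h, w = frames.shape[1:]
    out_shape = (max(1, round(h / s)), max(1, round(w / s)))
    out = np.empty((frames.shape[0],) + out_shape, float)
    for k, f in enumerate(frames):
        g = resize(f, out_shape, order=3, mode="reflect", anti_aliasing=s > 1)
        total_in, total_out = f.sum(), g.sum()
        if total_out > 0 and total_in > 0:
            g = g * (total_in / total_out)
        out[k] = np.clip(g, 0.0, None)
    return (out[0] if squeeze else out), float(s)
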