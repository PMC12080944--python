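"""Tile, dispatch, reassemble: the patch-wise reconstruction pipeline.

The field of view is divided into fixed-size patches (64 x 64 pixels by
default, 14.9 µm at 233 nm pixels). Each patch gets its own parameter
estimate and its own best-matched model from the registry; the selected
backend localizes the patch stack and the per-patch super-resolution maps are
reassembled at their f-scaled positions. Model selection runs once per video,
from the leading frames.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import param_extraction as pe
from .localizer_backend import BackendRegistry, default_backend_set
from .model_selection import ModelRegistry, default_registry, rescale_for_model, select_model
from .simulator import EmitterList, OpticalConfig, VideoStack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatchGrid:
    """Geometry of the patch tiling: origins, stride, padding bookkeeping."""

    patch_px: int
    overlap_px: int
    raw_shape: Tuple[int, int]
    n_rows: int
    n_cols: int

    @property
    def stride(self) -> int:
        return self.patch_px - self.overlap_px

    @property
    def padded_shape(self) -> Tuple[int, int]:
        return (
            self.n_rows * self.stride + self.overlap_px,
            self.n_cols * self.stride + self.overlap_px,
        )

    @property
    def origins(self) -> List[Tuple[int, int, int]]:
        """(patch_row, patch_col, flattened index) origin offsets in pixels."""
        return [(i * self.stride, j * self.stride, i * self.n_cols + j) for i in range(self.n_rows) for j in range(self.n_cols)]

    def is_edge(self, i: int, j: int) -> bool:
        """Whether patch (i, j) contains zero padding."""
        h, w = self.raw_shape
        return (i + 1) * self.stride + self.overlap_px > h or (j + 1) * self.stride + self.overlap_px > w


@dataclass
class SRImage:
    """Reassembled super-resolution canvas plus per-patch provenance."""

    data: np.ndarray
    upsampling_factor: int
    grid: PatchGrid
    model_map: Optional[np.ndarray] = None  # n_rows x n_cols of model ids (-1 = failed)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if np.any(self.data < 0):
            raise ValueError("SR intensities must be >= 0")
        h, w = self.grid.raw_shape
        f = self.upsampling_factor
        if self.data.shape != (h * f, w * f):
            raise ValueError(f"SR shape {self.data.shape} != f x raw {(h * f, w * f)}")


def tile(frames: np.ndarray, patch_px: int = 64, overlap_px: int = 0):
    """Split frames into patch stacks, zero-padding the right/bottom edges.

    Returns ``(grid, patches)`` with ``patches`` of shape
    ``(n_patches, T, patch_px, patch_px)`` ordered row-major.
    """
    if patch_px < 8:
        raise ValueError(f"patch_px must be >= 8, got {patch_px}")
    if not 0 <= overlap_px < patch_px:
        raise ValueError("overlap_px must be in [0, patch_px)")
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    t, h, w = frames.shape
    if patch_px > h or patch_px > w:
        warnings.warn(
            f"patch size {patch_px} exceeds the field of view {h}x{w}; using a single padded patch",
            stacklevel=2,
        )
    stride = patch_px - overlap_px
    n_rows = max(1, math.ceil(max(h - overlap_px, 1) / stride))
    n_cols = max(1, math.ceil(max(w - overlap_px, 1) / stride))
    grid = PatchGrid(patch_px=patch_px, overlap_px=overlap_px, raw_shape=(h, w), n_rows=n_rows, n_cols=n_cols)
    ph, pw = grid.padded_shape
    padded = np.zeros((t, ph, pw), frames.dtype)
    padded[:, :h, :w] = frames
    patches = np.empty((n_rows * n_cols, t, patch_px, patch_px), frames.dtype)
    for r0, c0, k in grid.origins:
        patches[k] = padded[:, r0 : r0 + patch_px, c0 : c0 + patch_px]
    return grid, patches


def reassemble_patches(grid: PatchGrid, patches: np.ndarray, f: int = 1, crop: bool = True) -> np.ndarray:
    """Place per-patch maps at f-scaled origins, averaging overlaps uniformly.

    With ``f = 1`` and raw patches this inverts :func:`tile` bit-exactly at
    zero overlap. ``patches`` is ``(n_patches, f*patch, f*patch)``.
    """
    ph, pw = grid.padded_shape
    canvas = np.zeros((ph * f, pw * f), float)
    weight = np.zeros((ph * f, pw * f), float)
    fp = grid.patch_px * f
    for r0, c0, k in grid.origins:
        r, c = r0 * f, c0 * f
        canvas[r : r + fp, c : c + fp] += patches[k]
        weight[r : r + fp, c : c + fp] += 1.0
    out = canvas / np.maximum(weight, 1.0)
    if crop:
        h, w = grid.raw_shape
        out = out[: h * f, : w * f]
    return out


def reconstruct(
    video: VideoStack,
    registry: Optional[ModelRegistry] = None,
    backends: Optional[BackendRegistry] = None,
    patch_px: int = 64,
    overlap_px: int = 0,
    stats_frames: int = 50,
    psf: Optional[pe.PSFStats] = None,
    psf_sigma_guess: float = 1.5,
    rescale: bool = True,
):
    """Run the full patch-wise pipeline on a video.

    Per patch: estimate statistics from the leading frames, select the
    best-matched model, localize every frame with that model's backend, and
    place the upsampled map back at its original position. Returns
    ``(SRImage, selection_table, EmitterList)`` where the selection table has
    one row per patch with its statistics and chosen model.
    """
    registry = registry or default_registry()
    backends = backends or default_backend_set()
    optics = video.optics
    frames = np.asarray(video.frames, float)

    if rescale:
        frames, s = rescale_for_model(frames, optics, registry.training_optics)
        if s != 1.0:
            optics = OpticalConfig(
                pixel_size_nm=optics.pixel_size_nm * s,
                wavelength_nm=registry.training_optics.wavelength_nm,
                na=registry.training_optics.na,
                upsampling_factor=optics.upsampling_factor,
            )
            video = VideoStack(frames=np.clip(frames, 0, None), optics=optics)

    gstats = pe.global_stats(video, n_frames=stats_frames)
    no_events = False
    if psf is None:
        try:
            psf = pe.characterize_psf(video, stats=gstats, sigma_guess=psf_sigma_guess)
        except ValueError:
            logger.warning("no emission events found; skipping localization")
            no_events = True
            psf = pe.PSFStats(sigma_mean=psf_sigma_guess, sigma_std=0.0, amp_mean=1.0, amp_std=0.0, n_fits=1)

    grid, patches = tile(frames, patch_px=patch_px, overlap_px=overlap_px)
    f = optics.upsampling_factor
    fp = grid.patch_px * f
    sr_patches = np.zeros((len(patches), fp, fp), float)
    model_map = np.full((grid.n_rows, grid.n_cols), -1, int)
    rows = []
    all_emitters = []
    p_nm = optics.pixel_size_nm
    for r0, c0, k in grid.origins:
        i, j = divmod(k, grid.n_cols)
        stats = pe.patch_stats(patches[k], gstats, psf, p_nm, n_frames=stats_frames)
        model_id = select_model(stats, registry)
        spec = registry[model_id]
        failed = False
        try:
            if not no_events:
                backend = backends.get(spec.backend_handle)
                sr, emitters = backend(patches[k], optics, psf, f)
                sr_patches[k] = sr
                if len(emitters):
                    df = emitters.df.copy()
                    df["x_nm"] += c0 * p_nm
                    df["y_nm"] += r0 * p_nm
                    df["model_id"] = model_id
                    all_emitters.append(df)
        except Exception:  # noqa: BLE001 - per-patch isolation
            logger.exception("backend failed on patch (%d, %d); leaving it empty", i, j)
            failed = True
        model_map[i, j] = -1 if failed else model_id
        rows.append(
            dict(
                patch_row=i,
                patch_col=j,
                model_id=model_id,
                density_um2=stats.density_um2,
                snr=stats.snr,
                noise_mean=stats.noise_mean,
                noise_std=stats.noise_std,
                signal_mean=stats.signal_mean,
                signal_std=stats.signal_std,
                n_peaks=stats.n_peaks,
                edge=grid.is_edge(i, j),
                failed=failed,
            )
        )
    sr = reassemble_patches(grid, sr_patches, f=f)
    table = pd.DataFrame(rows)
    if all_emitters:
        merged = pd.concat(all_emitters, ignore_index=True)
        h_nm, w_nm = grid.raw_shape[0] * p_nm, grid.raw_shape[1] * p_nm
        merged = merged[(merged["x_nm"] < w_nm) & (merged["y_nm"] < h_nm)]
        emitter_list = EmitterList(merged.drop(columns=["model_id"]))
        emitter_list.df["model_id"] = merged["model_id"].to_numpy()
    else:
        emitter_list = EmitterList()
    return SRImage(data=sr, upsampling_factor=f, grid=grid, model_map=model_map), table, emitter_list


def model_usage_histogram(selection_table: pd.DataFrame) -> pd.Series:
    """Patch counts per selected model; the counts sum to the patch count."""
    if selection_table is None or len(selection_table) == 0:
        raise ValueError("selection table is empty")
    return selection_table["model_id"].value_counts().sort_index()
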