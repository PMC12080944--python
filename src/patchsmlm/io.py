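"""Readers and writers for the package's on-disk formats.

Stacks are multi-page TIFFs (16-bit unsigned by default) with a YAML sidecar
(`<stem>.meta.yaml`) carrying the optical metadata; emitter tables are UTF-8
CSV with header ``frame,x_nm,y_nm,z_nm,photons`` and "." as decimal separator.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

EMITTER_COLUMNS = ["frame", "x_nm", "y_nm", "z_nm", "photons"]


def _sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.yaml") if path.suffix == "" else path.with_name(path.stem + ".meta.yaml")


def write_stack(path, frames: np.ndarray, optics=None, dtype=np.uint16) -> None:
    frames = np.asarray(frames)
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.rint(frames), info.min, info.max).astype(dtype)
    else:
        data = frames.astype(dtype)
    tifffile.imwrite(str(path), data, photometric="minisblack")
    if optics is not None:
        meta = {
            "pixel_size_nm": float(optics.pixel_size_nm),
            "wavelength_nm": float(optics.wavelength_nm),
            "na": float(optics.na),
            "upsampling_factor": int(optics.upsampling_factor),
        }
        _sidecar_path(path).write_text(yaml.safe_dump(meta), encoding="utf-8")


def read_stack(path) -> Tuple[np.ndarray, Optional[object]]:
    """Read a multi-page TIFF and, when present, its optics sidecar."""
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None, ...]
    optics = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        from .simulator import OpticalConfig

        meta = yaml.safe_load(sidecar.read_text(encoding="utf-8"))
        optics = OpticalConfig(
            pixel_size_nm=meta["pixel_size_nm"],
            wavelength_nm=meta["wavelength_nm"],
            na=meta["na"],
            upsampling_factor=meta.get("upsampling_factor", 8),
        )
    return np.asarray(frames), optics


def write_emitter_csv(df: pd.DataFrame, path) -> None:
    out = df[EMITTER_COLUMNS].copy()
    out["frame"] = out["frame"].astype(int)
    out.to_csv(path, index=False, encoding="utf-8")


def read_emitter_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in EMITTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"emitter CSV {path} missing columns: {missing}")
    return df[list(df.columns)]


def write_sr_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, np.float32), photometric="minisblack")


def read_sr_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), float)
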