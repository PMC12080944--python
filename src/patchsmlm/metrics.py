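"""Evaluation metrics for super-resolution reconstructions and localizations.

Image-level: frames are preprocessed (percentile clipping, min-max
normalization, Gaussian blur) and compared with PSNR, NRMSE and the
multi-scale structural similarity index. Localization-level: predictions and
ground truth are matched one-to-one by optimal assignment within gating
radii, giving the Jaccard index and lateral/axial RMSE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment
from skimage.metrics import normalized_root_mse, peak_signal_noise_ratio

from .simulator import EmitterList


def preprocess_for_comparison(image: np.ndarray, blur_sigma: float = 2.0) -> np.ndarray:
    """Clip to the [0th, 99th] percentile range, min-max normalize, blur.

    The blur sigma is in super-resolution pixels (default 2). A constant image
    normalizes to all zeros with a warning.
    """
    image = np.asarray(image, float)
    if image.size == 0:
        raise ValueError("image must be nonempty")
    lo, hi = np.percentile(image, [0.0, 99.0])
    out = np.clip(image, lo, hi)
    if hi > lo:
        out = (out - lo) / (hi - lo)
    else:
        warnings.warn("constant image: normalized to all zeros", stacklevel=2)
        out = np.zeros_like(out)
    if blur_sigma > 0:
        out = gaussian_filter(out, blur_sigma)
    return out


def _check_shapes(a: np.ndarray, b: np.ndarray):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    a, b = _check_shapes(a, b)
    if np.array_equal(a, b):
        return float("inf")
    return float(peak_signal_noise_ratio(b, a, data_range=data_range))


def nrmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error of ``a`` against reference ``b``, over mean(b)."""
    a, b = _check_shapes(a, b)
    return float(normalized_root_mse(b, a, normalization="mean"))


_MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def _ssim_components(a, b, data_range, sigma=1.5, k1=0.01, k2=0.03):
    """Mean luminance and contrast-structure SSIM terms with a Gaussian window."""
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a = gaussian_filter(a, sigma, truncate=3.5)
    mu_b = gaussian_filter(b, sigma, truncate=3.5)
    var_a = gaussian_filter(a * a, sigma, truncate=3.5) - mu_a**2
    var_b = gaussian_filter(b * b, sigma, truncate=3.5) - mu_b**2
    cov = gaussian_filter(a * b, sigma, truncate=3.5) - mu_a * mu_b
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    cs = (2 * cov + c2) / (var_a + var_b + c2)
    return float(lum.mean()), float(cs.mean()), float((lum * cs).mean())


def _downsample2(img):
    h, w = img.shape
    img = img[: h - h % 2, : w - w % 2]
    return 0.25 * (img[0::2, 0::2] + img[1::2, 0::2] + img[0::2, 1::2] + img[1::2, 1::2])


def ms_ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0, weights=_MSSSIM_WEIGHTS) -> float:
    """Multi-scale SSIM: contrast-structure terms over a dyadic pyramid.

    The standard five-scale construction with the conventional exponents;
    luminance enters only at the coarsest scale. Images too small for five
    scales use as many scales as fit (weights renormalized).
    """
    a, b = _check_shapes(a, b)
    n_scales = len(weights)
    max_scales = max(1, int(math.floor(math.log2(min(a.shape) / 11))) + 1)
    if max_scales < n_scales:
        weights = np.asarray(weights[:max_scales])
        weights = weights / weights.sum()
        n_scales = max_scales
    vals = []
    x, y = a, b
    for s in range(n_scales):
        lum, cs, ssim_full = _ssim_components(x, y, data_range)
        vals.append(ssim_full if s == n_scales - 1 else cs)
        if s < n_scales - 1:
            x, y = _downsample2(x), _downsample2(y)
    vals = np.clip(np.asarray(vals), 1e-12, None)
    return float(np.prod(vals ** np.asarray(weights[: len(vals)])))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one-to-one localization matching within gating radii."""

    tp: int
    fp: int
    fn: int
    rmse_lateral_nm: float
    rmse_axial_nm: float
    pairs: Tuple[Tuple[int, int], ...] = field(default=(), repr=False)

    @property
    def jaccard(self) -> float:
        denom = self.tp + self.fp + self.fn
        return 1.0 if denom == 0 else self.tp / denom

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return 1.0 if denom == 0 else self.tp / denom

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return 1.0 if denom == 0 else self.tp / denom


def _coords(df, use_z):
    if use_z:
        z = np.nan_to_num(np.asarray(df["z_nm"], float), nan=0.0)
        return np.column_stack([df["x_nm"], df["y_nm"]]).astype(float), z
    return np.column_stack([df["x_nm"], df["y_nm"]]).astype(float), None


def match_localizations(
    pred: EmitterList,
    truth: EmitterList,
    radius_lat_nm: float = 250.0,
    radius_ax_nm: float = 500.0,
    per_frame: bool = True,
    greedy: bool = False,
) -> MatchResult:
    """Match predictions to ground truth one-to-one and score the result.

    Candidate pairs must lie within the lateral gating radius (and the axial
    radius when either list carries z). The assignment minimizes the total
    lateral distance (Hungarian algorithm); ``greedy=True`` instead matches
    nearest pairs first, as a cross-check. Matching is per frame by default.
    """
    pred_df, truth_df = pred.df, truth.df
    use_z = pred.is_3d or truth.is_3d
    tp = 0
    sq_lat: List[float] = []
    sq_ax: List[float] = []
    pairs: List[Tuple[int, int]] = []
    if per_frame:
        frames = sorted(set(pred_df["frame"].astype(int)) | set(truth_df["frame"].astype(int)))
        groups = [
            (pred_df[pred_df["frame"] == t], truth_df[truth_df["frame"] == t]) for t in frames
        ]
    else:
        groups = [(pred_df, truth_df)]
    for p_df, t_df in groups:
        if len(p_df) == 0 or len(t_df) == 0:
            continue
        p_xy, p_z = _coords(p_df, use_z)
        t_xy, t_z = _coords(t_df, use_z)
        d = np.linalg.norm(p_xy[:, None, :] - t_xy[None, :, :], axis=-1)
        ok = d <= radius_lat_nm
        if use_z:
            dz = np.abs(p_z[:, None] - t_z[None, :])
            ok &= dz <= radius_ax_nm
        else:
            dz = None
        if not ok.any():
            continue
        big = radius_lat_nm * 1e6
        cost = np.where(ok, d, big)
        if greedy:
            taken_p, taken_t = set(), set()
            order = np.argsort(d, axis=None)
            for flat in order:
                i, j = np.unravel_index(flat, d.shape)
                if not ok[i, j]:
                    break
                if i in taken_p or j in taken_t:
                    continue
                taken_p.add(i)
                taken_t.add(j)
                tp += 1
                sq_lat.append(d[i, j] ** 2)
                if dz is not None:
                    sq_ax.append(dz[i, j] ** 2)
                pairs.append((int(p_df.index[i]), int(t_df.index[j])))
        else:
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if ok[i, j]:
                    tp += 1
                    sq_lat.append(d[i, j] ** 2)
                    if dz is not None:
                        sq_ax.append(dz[i, j] ** 2)
                    pairs.append((int(p_df.index[i]), int(t_df.index[j])))
    fp = len(pred_df) - tp
    fn = len(truth_df) - tp
    return MatchResult(
        tp=tp,
        fp=fp,
        fn=fn,
        rmse_lateral_nm=float(np.sqrt(np.mean(sq_lat))) if sq_lat else 0.0,
        rmse_axial_nm=float(np.sqrt(np.mean(sq_ax))) if sq_ax else 0.0,
        pairs=tuple(pairs),
    )
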