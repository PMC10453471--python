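"""CT preprocessing: smoothing, HU clamping, normalization, grid resizing.

The pipeline order is fixed: reorient -> smooth -> clamp -> resize ->
normalize (image only; label maps are only reoriented and resized, with
nearest-neighbour interpolation so no new labels can appear).

Four intensity normalization modes are supported:

``CLAMPED_HU``
    clamp to [clamp_lo, clamp_hi] and feed the network raw HU;
``ZERO_MEAN``
    per-volume standardisation to mean 0 / sd 1 (constant volumes map to 0);
``UNIT_RANGE``
    affine map of [clamp_lo, clamp_hi] onto [0, 1];
``SYMMETRIC_RANGE``
    affine map of [clamp_lo, clamp_hi] onto [-1, 1].

The range maps use the fixed clamp bounds rather than per-volume extrema so
the mapping is identical for every scan in a dataset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nifti_io import LabelMap, Volume


class NormalizationMode(enum.Enum):
    CLAMPED_HU = "clamped_hu"
    ZERO_MEAN = "zero_mean"
    UNIT_RANGE = "unit_range"
    SYMMETRIC_RANGE = "symmetric_range"


@dataclass
class PreprocessConfig:
    clamp_lo: float = -1000.0
    clamp_hi: float = 800.0
    smooth_sigma: float = 0.75          # mm
    target_inplane: tuple[int, int] = (256, 256)
    target_depth: int | str = "keep"    # slices, or "keep"
    mode: NormalizationMode = NormalizationMode.CLAMPED_HU

    def __post_init__(self):
        if isinstance(self.mode, str):
            self.mode = NormalizationMode(self.mode)
        if self.clamp_lo >= self.clamp_hi:
            raise ValueError("clamp_lo must be < clamp_hi")
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")


def clamp_hu(v: Volume, lo: float = -1000.0, hi: float = 800.0) -> Volume:
    """Clip every voxel into [lo, hi]; in-range values are untouched."""
    if lo >= hi:
        raise ValueError(f"invalid clamp range [{lo}, {hi}]")
    return v.with_data(np.clip(v.data, lo, hi))


def smooth(v: Volume, sigma_mm: float) -> Volume:
    """Gaussian smoothing with a physical sigma, converted per axis."""
    if sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_mm == 0:
        return v
    sigma_vox = sigma_mm / v.spacing
    return v.with_data(ndimage.gaussian_filter(
        v.data.astype(np.float64), sigma=sigma_vox).astype(v.data.dtype
        if np.issubdtype(v.data.dtype, np.floating) else np.float64))


def normalize(v: Volume, mode: NormalizationMode,
              lo: float = -1000.0, hi: float = 800.0) -> Volume:
    """Apply one of the four intensity normalization modes."""
    mode = NormalizationMode(mode)
    x = v.data.astype(np.float64)
    if mode is NormalizationMode.CLAMPED_HU:
        return v.with_data(x)
    if mode is NormalizationMode.ZERO_MEAN:
        sd = x.std()
        return v.with_data(np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd)
    unit = (x - lo) / (hi - lo)
    if mode is NormalizationMode.UNIT_RANGE:
        return v.with_data(unit)
    return v.with_data(2.0 * unit - 1.0)  # SYMMETRIC_RANGE


def _nearest_indices(n_out: int, n_in: int) -> np.ndarray:
    pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    return np.clip(np.round(pos), 0, n_in - 1).astype(int)


def _linear_matrix(n_out: int, n_in: int) -> np.ndarray:
    pos = np.clip((np.arange(n_out) + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = pos - lo
    M = np.zeros((n_out, n_in))
    M[np.arange(n_out), lo] += 1 - t
    M[np.arange(n_out), hi] += t
    return M


def _resize_array(data: np.ndarray, shape_out: tuple[int, ...],
                  nearest: bool) -> np.ndarray:
    """Separable center-aligned resize, linear or nearest per axis."""
    out = data
    for ax, n_out in enumerate(shape_out):
        n_in = out.shape[ax]
        if n_in == n_out:
            continue
        if nearest:
            idx = _nearest_indices(n_out, n_in)
            out = np.take(out, idx, axis=ax)
        else:
            M = _linear_matrix(n_out, n_in)
            out = np.moveaxis(np.moveaxis(out, ax, -1) @ M.T, -1, ax)
    return np.ascontiguousarray(out)


def _rescaled_affine(affine: np.ndarray, shape_in, shape_out) -> np.ndarray:
    f = np.asarray(shape_in, dtype=float) / np.asarray(shape_out, dtype=float)
    new = affine.copy()
    new[:3, :3] = affine[:3, :3] * f[np.newaxis, :]
    # voxel centers: out index i maps to in index i*f + (f-1)/2
    new[:3, 3] = affine[:3, 3] + affine[:3, :3] @ ((f - 1.0) / 2.0)
    return new


def resize_to_grid(v: Volume, cfg: PreprocessConfig) -> Volume:
    """Resample to the working grid; physical extent is preserved via the affine."""
    ty, tx = cfg.target_inplane
    if ty <= 0 or tx <= 0:
        raise ValueError("target sizes must be positive")
    tz = v.shape[0] if cfg.target_depth == "keep" else int(cfg.target_depth)
    if tz <= 0:
        raise ValueError("target depth must be positive")
    shape_out = (tz, ty, tx)
    if shape_out == v.shape:
        return v
    nearest = isinstance(v, LabelMap)
    data = _resize_array(v.data, shape_out, nearest=nearest)
    if nearest:
        data = data.astype(v.data.dtype)
    return v.with_data(data, _rescaled_affine(v.affine, v.shape, shape_out))


def preprocess_pipeline(v: Volume, m: LabelMap | None,
                        cfg: PreprocessConfig) -> tuple[Volume, LabelMap | None]:
    """reorient -> smooth -> clamp -> resize -> normalize; labels stay aligned."""
    from .nifti_io import reorient_canonical

    v = reorient_canonical(v)
    v = smooth(v, cfg.smooth_sigma)
    v = clamp_hu(v, cfg.clamp_lo, cfg.clamp_hi)
    v = resize_to_grid(v, cfg)
    v = normalize(v, cfg.mode, cfg.clamp_lo, cfg.clamp_hi)
    if m is not None:
        m = reorient_canonical(m)
        m = resize_to_grid(m, cfg)
        if m.shape != v.shape:
            raise ValueError("label map failed to stay aligned with the image")
    return v, m
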