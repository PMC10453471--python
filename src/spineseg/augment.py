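"""Joint image/label geometric augmentation: flips, in-plane rotation, scaling.

All transforms apply the same parameters to the image and its label map; the
image is interpolated linearly, labels with nearest neighbour (so no new
labels can appear), and the output grid shape never changes.  "In-plane"
means the last two array axes, which for a 2D slice is the slice itself and
for a canonical (z, y, x) volume is the axial plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nifti_io import LabelMap, Volume

#: fill value for out-of-field image voxels (air)
DEFAULT_IMAGE_FILL = -1000.0


@dataclass
class AugmentationSpec:
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    flip_lr: bool = True
    p_scale: float = 0.5
    p_rotate: float = 0.5
    p_flip: float = 0.5
    image_fill: float = DEFAULT_IMAGE_FILL

    def __post_init__(self):
        if self.scale_range[0] <= 0:
            raise ValueError("scale range must be positive")
        for p in (self.p_scale, self.p_rotate, self.p_flip):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def _core(v) -> tuple[np.ndarray, bool]:
    if isinstance(v, Volume):
        return v.data, isinstance(v, LabelMap)
    a = np.asarray(v)
    # bare integer arrays are treated as label grids (nearest interpolation)
    return a, np.issubdtype(a.dtype, np.integer)


def _rewrap(v, data: np.ndarray):
    if isinstance(v, Volume):
        return v.with_data(data)
    return data


def flip(v, axis: int = -1):
    """Mirror along one axis; pure permutation, no interpolation."""
    data, _ = _core(v)
    if not -data.ndim <= axis < data.ndim:
        raise ValueError(f"invalid axis {axis} for rank {data.ndim}")
    return _rewrap(v, np.ascontiguousarray(np.flip(data, axis=axis)))


def _affine_inplane(data: np.ndarray, matrix2: np.ndarray, nearest: bool,
                    fill: float) -> np.ndarray:
    """Apply a 2x2 in-plane map about the centre of the last two axes."""
    nd = data.ndim
    full = np.eye(nd)
    full[nd - 2:, nd - 2:] = matrix2
    center = (np.asarray(data.shape) - 1) / 2.0
    offset = center - full @ center
    order = 0 if nearest else 1
    out = ndimage.affine_transform(
        data.astype(float), full, offset=offset, order=order,
        mode="constant", cval=fill)
    return np.round(out).astype(data.dtype) if nearest else out


def rotate(v, angle_deg: float, fill: float | None = None):
    """In-plane rotation about the slice centre."""
    data, nearest = _core(v)
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    if angle_deg == 0:
        return _rewrap(v, data.copy())
    if fill is None:
        fill = 0.0 if nearest else DEFAULT_IMAGE_FILL
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return _rewrap(v, _affine_inplane(data, rot, nearest, fill))


def scale(v, factor: float, fill: float | None = None):
    """In-plane zoom about the centre; the grid shape is unchanged."""
    data, nearest = _core(v)
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    if factor == 1.0:
        return _rewrap(v, data.copy())
    if fill is None:
        fill = 0.0 if nearest else DEFAULT_IMAGE_FILL
    mat = np.eye(2) / factor  # output->input map
    return _rewrap(v, _affine_inplane(data, mat, nearest, fill))


def random_augment(v, m, spec: AugmentationSpec, rng: np.random.Generator):
    """Sample one transform from `spec` and apply it to image and labels alike."""
    vdata, _ = _core(v)
    mdata, _ = _core(m)
    if vdata.shape != mdata.shape:
        raise ValueError(
            f"image {vdata.shape} and labels {mdata.shape} are misaligned")
    # draw all parameters first so the consumption of randomness is fixed
    do_flip = spec.flip_lr and rng.random() < spec.p_flip
    do_rot = rng.random() < spec.p_rotate
    angle = rng.uniform(*spec.rotation_range_deg)
    do_scale = rng.random() < spec.p_scale
    factor = rng.uniform(*spec.scale_range)
    if do_flip:
        v, m = flip(v, -1), flip(m, -1)
    if do_rot and angle != 0:
        v, m = rotate(v, angle, spec.image_fill), rotate(m, angle)
    if do_scale and factor != 1.0:
        v, m = scale(v, factor, spec.image_fill), scale(m, factor)
    return v, m
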