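"""NIfTI volume / label-map containers and canonical reorientation.

The package works in a single canonical frame everywhere: the world frame is
RAS+ and the array axis order is (z, y, x) = (superior -> inferior slices,
anterior -> posterior rows, left -> right columns), i.e. axis direction codes
('I', 'P', 'R') in increasing-index terms.  Reorientation only permutes and
flips voxels; it never interpolates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Direction (toward which anatomical pole the index increases) of each array
#: axis in the canonical frame.
CANONICAL_AXCODES = ("I", "P", "R")


class DimensionalityError(ValueError):
    """Image does not have exactly three spatial dimensions."""


class FormatError(ValueError):
    """File or header is not a valid/supported NIfTI-1 image."""


def default_affine(spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Voxel-to-world map realising the canonical ('I','P','R') layout."""
    sz, sy, sx = [float(s) for s in spacing]
    aff = np.zeros((4, 4))
    aff[0, 2] = sx    # world x (R) grows with array axis 2
    aff[1, 1] = -sy   # world y (A) shrinks as rows go posterior
    aff[2, 0] = -sz   # world z (S) shrinks as slices go inferior
    aff[3, 3] = 1.0
    return aff


@dataclass
class Volume:
    """A 3D scalar grid of Hounsfield-unit (or normalized) intensities."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=default_affine)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D grid, got rank {self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def spacing(self) -> np.ndarray:
        """mm per voxel along each array axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def orientation(self) -> tuple[str, str, str]:
        """Axis direction codes (toward which pole each index increases)."""
        # nibabel's codes name the direction of travel in RAS terms
        return nib.orientations.aff2axcodes(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, affine: np.ndarray | None = None):
        return type(self)(data, self.affine if affine is None else affine)


@dataclass
class LabelMap(Volume):
    """Integer grid aligned with a Volume: 0 = background, k = vertebra k."""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label map values must be integers")
            self.data = np.round(self.data).astype(np.int32)
        super().__post_init__()
        if self.data.min() < 0:
            raise ValueError("label values must be nonnegative")

    def labels(self) -> np.ndarray:
        return np.unique(self.data)


def read_volume(path) -> Volume:
    """Read a NIfTI-1 image as a Volume, intensities unmodified."""
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed header / unknown format
        raise FormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected 3D image, got {data.ndim}D")
    return Volume(np.asarray(data), np.asarray(img.affine))


def read_labelmap(path) -> LabelMap:
    v = read_volume(path)
    return LabelMap(v.data, v.affine)


def write_volume(v: Volume, path) -> None:
    """Write to NIfTI-1; LabelMaps get an integer on-disk type."""
    if isinstance(v, LabelMap):
        data = v.data.astype(np.int16)
    else:
        data = v.data.astype(np.float32)
    img = nib.Nifti1Image(data, v.affine)
    nib.save(img, str(path))


def reorient_canonical(v: Volume) -> Volume:
    """Permute/flip axes into the canonical ('I','P','R') layout."""
    try:
        src = nib.orientations.io_orientation(v.affine)
        dst = nib.orientations.axcodes2ornt(CANONICAL_AXCODES)
        xform = nib.orientations.ornt_transform(src, dst)
    except Exception as exc:
        raise FormatError(f"unknown orientation: {exc}") from exc
    if np.array_equal(xform, [[0, 1], [1, 1], [2, 1]]):
        return v  # already canonical
    data = nib.orientations.apply_orientation(v.data, xform)
    affine = v.affine @ nib.orientations.inv_ornt_aff(xform, v.data.shape)
    return v.with_data(np.ascontiguousarray(data), affine)
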