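"""Synthetic spine CT phantoms with vertebra labels and centroids.

A phantom is a HU-valued volume holding a soft-tissue ellipsoid "torso" in
air, with a cranio-caudal stack of ellipsoidal vertebra-like bodies inside
it.  The stack follows a sinusoidal centreline (a crude scoliotic curve),
bodies are separated by disc-like gaps, and additive Gaussian noise models
detector noise.  Each body k is marked k in the label map and its exact
label-mass centre (in world mm) is recorded, mirroring the
centroids-plus-masks annotation style of public vertebra challenge data.

Phantoms are deliberately simple shapes: they exercise geometry, intensity
handling and the learning machinery, not anatomical realism.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nifti_io import LabelMap, Volume, default_affine, write_volume


@dataclass
class PhantomSpec:
    grid: tuple[int, int, int] = (64, 96, 96)     # (z, y, x) voxels
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    n_vertebrae: int = 6
    body_radius_mm: tuple[float, float] = (8.0, 12.0)
    disc_gap_mm: tuple[float, float] = (3.0, 5.0)
    curvature_amp_mm: float = 6.0
    hu_bone: float = 700.0
    hu_soft: float = 40.0
    hu_air: float = -1000.0
    noise_sd: float = 25.0
    posterior_process: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_vertebrae < 1:
            raise ValueError("need at least one vertebra")
        if not (self.hu_air < self.hu_soft < self.hu_bone):
            raise ValueError("HU levels must satisfy air < soft < bone")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhantomSample:
    volume: Volume
    labels: LabelMap
    centroids: dict[int, tuple[float, float, float]]  # label -> world mm

    def spine_mask(self) -> LabelMap:
        """Binary union of all vertebra labels: the stage-1 ground truth."""
        return LabelMap((self.labels.data > 0).astype(np.int16),
                        self.labels.affine)


def generate_phantom(spec: PhantomSpec,
                     rng: np.random.Generator | None = None) -> PhantomSample:
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid
    sz, sy, sx = spec.spacing
    z_mm = np.arange(nz) * sz
    y_mm = np.arange(ny) * sy
    x_mm = np.arange(nx) * sx
    Z, Y, X = np.meshgrid(z_mm, y_mm, x_mm, indexing="ij")
    extent = (nz * sz, ny * sy, nx * sx)

    # soft-tissue torso ellipsoid spanning the grid
    cy, cx = extent[1] / 2, extent[2] / 2
    ry, rx = 0.45 * extent[1], 0.45 * extent[2]
    torso = ((Y - cy) / ry) ** 2 + ((X - cx) / rx) ** 2 <= 1.0

    # vertebral bodies stacked along z on a sinusoidal centreline
    n = spec.n_vertebrae
    gaps = rng.uniform(*spec.disc_gap_mm, size=n + 1)
    margin = 0.05 * extent[0]
    usable = extent[0] - 2 * margin - gaps.sum()
    half_h = usable / n / 2.0
    if half_h < sz:
        raise ValueError(
            f"{n} bodies with gaps {gaps.sum():.0f} mm cannot fit a "
            f"{extent[0]:.0f} mm grid")
    # vertebral bodies grow cranio-caudally (cervical small, lumbar large),
    # so body size is a local cue to vertebra identity, as in real spines;
    # jitter keeps the progression from being perfectly deterministic
    lo, hi = spec.body_radius_mm
    radii = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
    radii = np.clip(radii + rng.uniform(-0.05, 0.05, size=n) * (hi - lo),
                    lo, hi)
    if radii.max() * 2 > min(extent[1], extent[2]) * 0.9:
        raise ValueError("vertebral bodies do not fit the grid in-plane")

    volume = np.full(spec.grid, spec.hu_air, dtype=np.float64)
    volume[torso] = spec.hu_soft
    labels = np.zeros(spec.grid, dtype=np.int16)

    z_cursor = margin
    phase = rng.uniform(0, 2 * np.pi)
    for k in range(1, n + 1):
        z_cursor += gaps[k - 1]
        zc = z_cursor + half_h
        z_cursor += 2 * half_h
        # centreline: sinusoidal lateral (x) sway, fixed posterior offset in y
        xc = cx + spec.curvature_amp_mm * np.sin(
            2 * np.pi * zc / extent[0] + phase)
        yc = cy + 0.15 * extent[1]
        r = radii[k - 1]
        body = (((Z - zc) / half_h) ** 2 + ((Y - yc) / r) ** 2
                + ((X - xc) / r) ** 2) <= 1.0
        if spec.posterior_process:
            proc = (((Z - zc) / (0.6 * half_h)) ** 2
                    + ((Y - (yc + 1.4 * r)) / (0.5 * r)) ** 2
                    + ((X - xc) / (0.35 * r)) ** 2) <= 1.0
            body |= proc
        if not body.any():
            raise ValueError("vertebral body fell outside the grid")
        volume[body] = spec.hu_bone
        labels[body] = k

    if spec.noise_sd > 0:
        volume = volume + rng.normal(0.0, spec.noise_sd, size=spec.grid)

    affine = default_affine(spec.spacing)
    vol = Volume(volume, affine)
    lab = LabelMap(labels, affine)
    centroids = {}
    for k in range(1, n + 1):
        idx = np.argwhere(labels == k)
        cvox = idx.mean(axis=0)
        world = affine[:3, :3] @ cvox + affine[:3, 3]
        centroids[k] = tuple(float(w) for w in world)
    return PhantomSample(vol, lab, centroids)


def generate_dataset(n: int, spec: PhantomSpec, seed: int,
                     outdir) -> list[dict]:
    """Write n phantoms (image, labels, centroid sidecar) plus a manifest.

    Per-sample seeds are spawned deterministically from the master seed, so
    regenerating with the same seed is byte-identical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]
    for i, sample_seed in enumerate(child_seeds):
        sample = generate_phantom(spec, np.random.default_rng(sample_seed))
        sid = f"phantom_{i:03d}"
        image_path = outdir / f"{sid}_ct.nii.gz"
        label_path = outdir / f"{sid}_seg.nii.gz"
        ctd_path = outdir / f"{sid}_ctd.json"
        write_volume(sample.volume, image_path)
        write_volume(sample.labels, label_path)
        with open(ctd_path, "w") as fh:
            json.dump([{"label": k, "x_mm": c[0], "y_mm": c[1], "z_mm": c[2]}
                       for k, c in sample.centroids.items()], fh, indent=2)
        manifest.append({"sample_id": sid, "image_path": str(image_path),
                         "label_path": str(label_path),
                         "centroid_path": str(ctd_path), "seed": sample_seed})
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(manifest[0].keys()))
        w.writeheader()
        w.writerows(manifest)
    return manifest
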