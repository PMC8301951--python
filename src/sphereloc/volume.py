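"""Volume data model, I/O, resampling, normalization and local-maxima search.

All public coordinates are physical millimetres. A :class:`Volume` couples a
3D intensity grid with per-axis voxel spacing and the physical position of
the centre of voxel ``(0, 0, 0)`` (the origin), so voxel index ``(i, j, k)``
maps to ``origin + (i*sx, j*sy, k*sz)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


class VolumeIOError(IOError):
    """Raised when a volume file is unreadable or carries invalid metadata."""


class DegenerateInputError(ValueError):
    """Raised when an operation receives input it is undefined for
    (e.g. normalizing a constant volume)."""


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing (mm) and origin (mm).

    Parameters
    ----------
    data : ndarray
        3D array of intensities (arbitrary units).
    spacing : sequence of 3 floats
        Per-axis voxel size in mm; all components must be positive.
    origin : sequence of 3 floats
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError(f"origin must have 3 components, got {self.origin}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0]))

    def voxel_to_physical(self, idx) -> np.ndarray:
        """Physical mm position of voxel centre(s) ``idx`` (…, 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_voxel(self, pos) -> np.ndarray:
        """Continuous voxel index of physical position(s) ``pos`` (…, 3)."""
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def physical_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) physical corners of the voxel-centre grid."""
        lo = self.voxel_to_physical((0, 0, 0))
        hi = self.voxel_to_physical(np.asarray(self.shape) - 1)
        return lo, hi


@dataclass
class SphereCandidate:
    """A putative sphere centre produced by one of the detectors.

    ``score`` is method specific: accumulator votes (hough), convolution
    response (kernel), roundness (cca) or DoH response (blob).
    """

    position: np.ndarray
    score: float
    method: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.score = float(self.score)


def load_volume(path) -> Volume:
    """Load a volume from a NIfTI file (``.nii``/``.nii.gz``) or a raw
    ``.npy`` array with a JSON sidecar ``{"spacing_mm": [sx, sy, sz]}``.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    if path.suffix == ".npy":
        data = np.load(path)
        sidecar = path.with_suffix(".json")
        spacing = (1.0, 1.0, 1.0)
        origin = (0.0, 0.0, 0.0)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = tuple(meta.get("spacing_mm", spacing))
            origin = tuple(meta.get("origin_mm", origin))
        try:
            return Volume(data, spacing, origin)
        except ValueError as exc:
            raise VolumeIOError(f"invalid metadata for {path}: {exc}") from exc
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeIOError(f"non-positive voxel spacing in header of {path}: {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    try:
        return Volume(data, tuple(float(z) for z in zooms), origin)
    except ValueError as exc:
        raise VolumeIOError(f"invalid volume in {path}: {exc}") from exc


def save_volume(v: Volume, path) -> None:
    """Write a volume as NIfTI-1 with a diagonal spacing affine."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(v.spacing) + [1.0])
    affine[:3, 3] = v.origin
    nib.save(nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), affine), str(path))


def resample_isotropic(v: Volume, target: float, order: int = 1) -> Volume:
    """Resample a volume onto an isotropic grid of spacing ``target`` mm.

    Linear interpolation by default; the physical extent is preserved to
    within one voxel and the origin (first voxel centre) is unchanged.
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    spacing = np.asarray(v.spacing)
    shape = np.asarray(v.shape)
    # number of target-spaced samples that stay inside the source grid
    new_shape = np.floor((shape - 1) * spacing / target).astype(int) + 1
    new_shape = np.maximum(new_shape, 1)
    grids = np.meshgrid(
        *[np.arange(n) * target / s for n, s in zip(new_shape, spacing)],
        indexing="ij",
    )
    data = ndimage.map_coordinates(
        np.asarray(v.data, dtype=float), np.stack(grids), order=order, mode="nearest"
    )
    return Volume(data, (target, target, target), v.origin)


def normalize_intensity(v: Volume) -> Volume:
    """Shift/scale intensities to mean 0 and standard deviation 1."""
    data = np.asarray(v.data, dtype=float)
    sd = data.std()
    if sd == 0:
        raise DegenerateInputError("constant volume: intensity standard deviation is 0")
    return Volume((data - data.mean()) / sd, v.spacing, v.origin)


def find_local_maxima(
    v: Volume, min_distance: float, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Find local maxima of a volume, in physical mm.

    A voxel qualifies if its value exceeds ``threshold`` and is >= every
    voxel whose centre lies within ``min_distance`` mm (Euclidean) of its
    own centre. Surviving maxima are then greedily thinned (descending
    value, ties broken by lexicographic index) so that no two returned
    positions are closer than ``min_distance`` mm.

    Returns
    -------
    positions : (n, 3) ndarray of mm coordinates (voxel centres)
    values : (n,) ndarray of the map values at those voxels
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be positive")
    data = np.asarray(v.data, dtype=float)
    spacing = np.asarray(v.spacing)
    # prefilter with the box inscribed in the ball (superset of ball maxima)
    half_in = [max(1, int(np.floor(min_distance / (np.sqrt(3.0) * s)))) for s in spacing]
    size = [2 * h + 1 for h in half_in]
    local_max = data == ndimage.maximum_filter(data, size=size, mode="nearest")
    mask = local_max & (data > threshold)
    idx = np.argwhere(mask)
    if idx.size == 0:
        return np.empty((0, 3)), np.empty((0,))
    # exact check against the full Euclidean ball
    half_out = [int(np.ceil(min_distance / s)) for s in spacing]
    offs = np.stack(
        np.meshgrid(*[np.arange(-h, h + 1) for h in half_out], indexing="ij"), -1
    ).reshape(-1, 3)
    offs = offs[np.linalg.norm(offs * spacing, axis=1) <= min_distance]
    shape = np.asarray(data.shape)
    ok = np.ones(len(idx), dtype=bool)
    vals0 = data[tuple(idx.T)]
    for off in offs:
        nb = idx + off
        inb = np.all((nb >= 0) & (nb < shape), axis=1)
        if not inb.any():
            continue
        bad = data[tuple(nb[inb].T)] > vals0[inb]
        sub = ok[inb]
        sub[bad] = False
        ok[inb] = sub
    idx = idx[ok]
    if idx.size == 0:
        return np.empty((0, 3)), np.empty((0,))
    vals = data[tuple(idx.T)]
    # descending value; ties resolved by lexicographically smallest index
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -vals))
    idx, vals = idx[order], vals[order]
    pos = v.voxel_to_physical(idx)
    keep: list[int] = []
    tree = cKDTree(pos)
    suppressed = np.zeros(len(pos), dtype=bool)
    for i in range(len(pos)):
        if suppressed[i]:
            continue
        keep.append(i)
        for j in tree.query_ball_point(pos[i], min_distance):
            if j != i:
                suppressed[j] = True
    keep_arr = np.asarray(keep, dtype=int)
    return pos[keep_arr], vals[keep_arr]
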