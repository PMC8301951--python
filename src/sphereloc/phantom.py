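"""Synthetic head-and-marker phantom generator with exact ground truth.

Emulates the study conditions the detectors are meant for: a bright
head-sized background object, and fiducial markers each consisting of two
bright spheres (r = 3.5 mm) held 11 mm apart inside a dark housing shell,
attached outside the head surface at arbitrary orientation. Ground truth
records the exact continuous-space sphere centres (not snapped to the
voxel grid), grouped into marker pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import Volume


class PlacementError(RuntimeError):
    """Raised when markers cannot be placed without violating separation."""


@dataclass
class PhantomSpec:
    """Parameters of the synthetic phantom.

    Defaults mirror the physical marker (sphere radius 3.5 mm, pair spacing
    11 mm, five markers per volume) and a mid-range isotropic voxel size.
    Intensities are pre-normalization arbitrary units: dark background,
    mid-bright head, dark housing shell, bright spheres.
    """

    voxel_size: float = 1.0
    n_markers: int = 5
    sphere_radius: float = 3.5
    pair_spacing: float = 11.0
    sphere_intensity: float = 1.0
    shell_intensity: float = 0.1
    head_intensity: float = 0.5
    background_intensity: float = 0.0
    noise_sd: float = 0.02
    seed: int = 0
    size_mm: float = 104.0
    shell_thickness: float = 1.5
    head_semiaxes: tuple[float, float, float] = (26.0, 22.0, 20.0)
    standoff_mm: float = 12.0

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if self.pair_spacing <= 2 * self.sphere_radius:
            raise ValueError("pair_spacing must exceed the sphere diameter")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.n_markers < 1:
            raise ValueError("need at least one marker")


@dataclass
class GroundTruth:
    """Exact sphere centres (mm), their pairing into markers, and the unit
    axis direction of each marker."""

    sphere_centers: np.ndarray  # (2*n_markers, 3) mm
    pairs: list[tuple[int, int]]
    directions: np.ndarray  # (n_markers, 3) unit vectors

    def __post_init__(self) -> None:
        self.sphere_centers = np.asarray(self.sphere_centers, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        self.pairs = [tuple(int(i) for i in p) for p in self.pairs]
        used = [i for p in self.pairs for i in p]
        if sorted(used) != list(range(len(self.sphere_centers))):
            raise ValueError("every sphere centre must belong to exactly one pair")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "spheres_mm": self.sphere_centers.tolist(),
                    "pairs": [list(p) for p in self.pairs],
                    "directions": self.directions.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        meta = json.loads(Path(path).read_text())
        return cls(
            np.asarray(meta["spheres_mm"]),
            [tuple(p) for p in meta["pairs"]],
            np.asarray(meta.get("directions", np.zeros((len(meta["pairs"]), 3)))),
        )


def voxelize_sphere(
    v: Volume,
    center,
    radius: float,
    value: float,
    partial_volume: bool = True,
    subsamples: int = 3,
) -> Volume:
    """Paint a solid sphere into ``v`` (in place) and return it.

    Voxels whose centre lies inside the sphere are set to ``value``. With
    ``partial_volume`` enabled, boundary voxels are blended between their
    current value and ``value`` by the inside-fraction estimated from a
    ``subsamples``³ regular subgrid, which gives the smooth edges real
    scans show at coarse voxel sizes.
    """
    center = np.asarray(center, dtype=float)
    spacing = np.asarray(v.spacing)
    origin = np.asarray(v.origin)
    lo_idx = np.floor((center - radius - origin) / spacing - 1).astype(int)
    hi_idx = np.ceil((center + radius - origin) / spacing + 1).astype(int)
    lo_c = np.maximum(lo_idx, 0)
    hi_c = np.minimum(hi_idx, np.asarray(v.shape) - 1)
    if np.any(lo_c > hi_c):
        warnings.warn("sphere lies entirely outside the volume; nothing painted")
        return v
    axes = [np.arange(lo_c[a], hi_c[a] + 1) for a in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    pos = np.stack(grid, axis=-1) * spacing + origin
    d = np.linalg.norm(pos - center, axis=-1)
    region = tuple(np.s_[lo_c[a] : hi_c[a] + 1] for a in range(3))
    sub = v.data[region]
    half_diag = 0.5 * float(np.linalg.norm(spacing))
    inside = d <= radius - half_diag if partial_volume else d <= radius
    sub[inside] = value
    if partial_volume:
        band = (d > radius - half_diag) & (d < radius + half_diag)
        if np.any(band):
            offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
            off_grid = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), -1)
            off_mm = (off_grid * spacing).reshape(-1, 3)
            band_pos = pos[band]
            frac = np.zeros(len(band_pos))
            for o in off_mm:
                frac += np.linalg.norm(band_pos + o - center, axis=1) <= radius
            frac /= len(off_mm)
            sub[band] = frac * value + (1.0 - frac) * sub[band]
    if not np.any(inside) and not (partial_volume and np.any(d < radius + half_diag)):
        warnings.warn("sphere does not cover any voxel centre")
    return v


def _ellipsoid_radius(direction: np.ndarray, semiaxes: np.ndarray) -> float:
    """Distance from the ellipsoid centre to its surface along ``direction``."""
    return 1.0 / np.sqrt(np.sum((direction / semiaxes) ** 2))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    u = rng.normal(size=3)
    n = np.linalg.norm(u)
    while n < 1e-12:
        u = rng.normal(size=3)
        n = np.linalg.norm(u)
    return u / n


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Generate a phantom volume and its exact ground truth.

    The head is an axis-aligned ellipsoid at ``head_intensity``; each
    marker is two spheres at ``sphere_intensity``, each wrapped in a
    concentric shell at ``shell_intensity`` (the housing), placed outside
    the head on a ray from the head centre with a seeded random marker
    axis. Additive Gaussian noise of sd ``noise_sd`` is applied last.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.voxel_size
    n = int(round(spec.size_mm / s))
    data = np.full((n, n, n), float(spec.background_intensity))
    vol = Volume(data, (s, s, s), (0.0, 0.0, 0.0))
    center = np.full(3, (n - 1) * s / 2.0)
    semi = np.asarray(spec.head_semiaxes, dtype=float)

    # head ellipsoid (binary paint; its edge sharpness is not under test)
    axes = [np.arange(n) * s for _ in range(3)]
    gx = np.meshgrid(*axes, indexing="ij")
    g = sum(((gx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    vol.data[g <= 1.0] = spec.head_intensity

    shell_outer = spec.sphere_radius + spec.shell_thickness
    half = spec.pair_spacing / 2.0
    bound_margin = shell_outer + 1.0
    lo_b = np.zeros(3) + bound_margin
    hi_b = np.full(3, (n - 1) * s) - bound_margin
    min_cross = spec.pair_spacing + 2.0  # keeps greedy pairing unambiguous

    centers: list[np.ndarray] = []
    pairs: list[tuple[int, int]] = []
    dirs: list[np.ndarray] = []
    placed: list[np.ndarray] = []
    for _ in range(spec.n_markers):
        ok = False
        for _attempt in range(2000):
            u = _random_unit(rng)
            axis = _random_unit(rng)
            p = center + (_ellipsoid_radius(u, semi) + spec.standoff_mm) * u
            a = p - half * axis
            b = p + half * axis
            cand = [a, b]
            if any(np.any(q < lo_b) or np.any(q > hi_b) for q in cand):
                continue
            # dilated-ellipsoid clearance check against the head
            dil = semi + shell_outer + 1.0
            if any(np.sum(((q - center) / dil) ** 2) <= 1.0 for q in cand):
                continue
            if any(
                np.linalg.norm(q - r) < min_cross for q in cand for r in placed
            ):
                continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place marker {len(pairs) + 1} of {spec.n_markers} "
                "without violating separation constraints"
            )
        i = len(centers)
        centers.extend([a, b])
        pairs.append((i, i + 1))
        dirs.append(axis)
        placed.extend([a, b])
        for q in cand:
            voxelize_sphere(vol, q, shell_outer, spec.shell_intensity)
        for q in cand:
            voxelize_sphere(vol, q, spec.sphere_radius, spec.sphere_intensity)

    if spec.noise_sd > 0:
        vol.data += rng.normal(0.0, spec.noise_sd, vol.shape)
    gt = GroundTruth(np.asarray(centers), pairs, np.asarray(dirs))
    return vol, gt
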