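"""Convolution-based sphere detector with a signed two-valued kernel.

The marker spheres appear as bright balls inside a dark housing, so a
matched kernel with weight ``kin = +1`` inside an imaginary sphere and a
negative weight ``kout`` outside produces a sharp response peak at sphere
centres of a mean-0/sd-1 normalized volume. ``kout`` adapts to the voxel
spacing through a logistic law with range (-1.5, -0.5): coarse grids (few
outside voxels per kernel) get a milder penalty, fine grids a stronger one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve

from .volume import SphereCandidate, Volume, find_local_maxima, normalize_intensity

STEEPNESS_C = 3.0  # steepness of the kout logistic


def kout_value(sv: float, c: float = STEEPNESS_C) -> float:
    """Outside-kernel weight as a function of voxel spacing ``sv`` (mm).

    kout(sv) = -0.5 - 1 / (1 + exp(-c (1 - sv)))

    Monotonically increasing in sv with open range (-1.5, -0.5) and
    midpoint kout(1 mm) = -1.
    """
    if sv <= 0:
        raise ValueError("voxel spacing must be positive")
    return -0.5 - 1.0 / (1.0 + np.exp(-c * (1.0 - sv)))


@dataclass
class SphereKernel:
    """Two-valued convolution kernel: ``kin`` inside the sphere, ``kout``
    outside. Odd-sized on every axis; cuboidal for anisotropic spacing."""

    weights: np.ndarray
    kin: float
    kout: float
    spacing: tuple[float, float, float]

    @property
    def half_size(self) -> tuple[int, int, int]:
        return tuple((n - 1) // 2 for n in self.weights.shape)


def build_sphere_kernel(
    radius_mm: float, spacing, kin: float = 1.0, kout: float | None = None
) -> SphereKernel:
    """Build the two-valued spherical kernel for a given physical radius.

    The per-axis half-size is ``floor(radius_mm / spacing_axis)`` (7x7x7
    for r = 3.5 mm at 1 mm isotropic voxels, cuboidal for anisotropic
    spacing); elements whose centre lies within ``radius_mm`` of the
    kernel centre get ``kin``, the rest ``kout``. The inside ball is
    intersected with the kernel cube rather than shrunk to fit: a shrunk
    ball leaves slack between kernel and sphere that flattens the response
    peak into a plateau and costs localization accuracy at fine voxel
    sizes.
    """
    spacing = tuple(float(s) for s in spacing)
    if radius_mm <= max(spacing) / 2:
        raise ValueError("radius_mm must exceed half the largest voxel size")
    if kout is None:
        kout = kout_value(min(spacing))
    if not -1.5 < kout < -0.5:
        raise ValueError(f"kout must lie in (-1.5, -0.5), got {kout}")
    half = tuple(max(1, int(np.floor(radius_mm / s))) for s in spacing)
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    d2 = sum(g * g for g in grids)
    weights = np.where(d2 <= radius_mm * radius_mm, float(kin), float(kout))
    return SphereKernel(weights, float(kin), float(kout), spacing)


def convolve3d(v: Volume, k: SphereKernel, rescale: bool = True) -> Volume:
    """Valid-region discrete convolution of a volume with the kernel.

    The output is cropped by the kernel half-size on each face (regions
    needing out-of-bounds voxels are skipped); the origin is shifted
    accordingly so positions stay in the original physical frame. The
    kernel is symmetric, so this equals cross-correlation. With
    ``rescale`` the response is min-max mapped to [0, 1].
    """
    if any(kn >= vn for kn, vn in zip(k.weights.shape, v.shape)):
        raise ValueError("kernel must be strictly smaller than the volume")
    out = convolve(np.asarray(v.data, dtype=float), k.weights, mode="valid")
    if rescale:
        lo, hi = out.min(), out.max()
        if hi > lo:
            out = (out - lo) / (hi - lo)
        else:
            out = np.zeros_like(out)
    origin = tuple(
        o + h * s for o, h, s in zip(v.origin, k.half_size, v.spacing)
    )
    return Volume(out, v.spacing, origin)


def detect_spheres_kernel(
    v: Volume, radius_mm: float = 3.5, threshold_rel: float = 0.8
) -> list[SphereCandidate]:
    """Normalize, convolve with the spherical kernel and return thresholded
    local maxima of the response as candidates (physical mm)."""
    if not 0 < threshold_rel <= 1:
        raise ValueError("threshold_rel must be in (0, 1]")
    norm = normalize_intensity(v)
    kern = build_sphere_kernel(radius_mm, v.spacing)
    resp = convolve3d(norm, kern)
    vmax = resp.data.max()
    if vmax <= 0:
        return []
    pos, vals = find_local_maxima(
        resp, min_distance=2.0 * radius_mm, threshold=threshold_rel * vmax
    )
    return [SphereCandidate(p, s, "kernel") for p, s in zip(pos, vals)]
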