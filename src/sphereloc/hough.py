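"""Bidirectional slice-wise circular Hough transform sphere detector.

Spheres intersect every slice stack as circles, so a 2D circular Hough
transform (CHT) is run slice-wise along two orthogonal axes. Gradient
directions from a first-order derivative of Gaussian restrict voting to a
small arc around the gradient (both inward and outward), and the known
physical radius restricts the radius set to a few voxel radii collected in
a single 2D accumulator per slice. Per-slice accumulators are restacked
into 3D per axis and the (normalized) stacks are blended by elementwise
multiplication: a sphere is circular in every stack and is reinforced,
while e.g. a cylinder is circular in only one and is attenuated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import SphereCandidate, Volume, find_local_maxima


class AnisotropicVolumeError(ValueError):
    """Raised when a slice-wise detector gets an anisotropic volume."""


@dataclass
class Accumulator:
    """Blended 3D vote grid aligned with the source volume."""

    votes: Volume
    radii: tuple[int, ...]


def gaussian_gradient(slice2d: np.ndarray, sigma: float = 1.0):
    """First-order derivative-of-Gaussian edge detection on a 2D slice.

    Returns (magnitude, direction) where direction is the per-pixel
    gradient angle atan2(g1, g0) in radians.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(slice2d, dtype=float)
    g0 = ndimage.gaussian_filter(img, sigma, order=(1, 0), mode="nearest")
    g1 = ndimage.gaussian_filter(img, sigma, order=(0, 1), mode="nearest")
    return np.hypot(g0, g1), np.arctan2(g1, g0)


def cht_slice(
    magnitude: np.ndarray,
    direction: np.ndarray,
    radii,
    arc_halfwidth: float = 0.35,
    edge_percentile: float = 95.0,
) -> np.ndarray:
    """Gradient-limited CHT of one slice; all radii share one accumulator.

    Pixels whose gradient magnitude exceeds the ``edge_percentile`` of the
    nonzero magnitudes vote along their gradient direction +- the arc
    half-width, at every radius, both inward and outward.
    """
    radii = sorted({int(r) for r in radii})
    if not radii or radii[0] < 1:
        raise ValueError("radii must be a non-empty set of voxel radii >= 1")
    acc = np.zeros_like(magnitude, dtype=float)
    nz = magnitude[magnitude > 1e-12]
    if nz.size == 0:
        return acc
    thr = np.percentile(nz, edge_percentile)
    ei, ej = np.nonzero(magnitude >= thr)
    if ei.size == 0:
        return acc
    ang = direction[ei, ej]
    shape = acc.shape
    for r in radii:
        n_arc = max(3, int(np.ceil(4.0 * arc_halfwidth * r)) + 1)
        for phi in np.linspace(-arc_halfwidth, arc_halfwidth, n_arc):
            for sign in (1.0, -1.0):
                ci = ei + sign * r * np.cos(ang + phi)
                cj = ej + sign * r * np.sin(ang + phi)
                _splat_bilinear(acc, ci, cj, 1.0 / n_arc)
    return acc


def _splat_bilinear(acc: np.ndarray, ci: np.ndarray, cj: np.ndarray, w: float) -> None:
    """Deposit votes at fractional positions, bilinearly split over the four
    surrounding accumulator cells (avoids rasterization bias)."""
    i0 = np.floor(ci).astype(int)
    j0 = np.floor(cj).astype(int)
    fi, fj = ci - i0, cj - j0
    for di, dj, wt in (
        (0, 0, (1 - fi) * (1 - fj)),
        (1, 0, fi * (1 - fj)),
        (0, 1, (1 - fi) * fj),
        (1, 1, fi * fj),
    ):
        ii, jj = i0 + di, j0 + dj
        ok = (ii >= 0) & (ii < acc.shape[0]) & (jj >= 0) & (jj < acc.shape[1])
        np.add.at(acc, (ii[ok], jj[ok]), w * wt[ok])


def radii_for(radius_mm: float, voxel_size: float) -> tuple[int, ...]:
    """Voxel radius set {r/s - 1, r/s, r/s + 1}, rounded, floored at 1."""
    r = radius_mm / voxel_size
    # round half away from zero: a physical radius of 3.5 voxels probes {3,4,5}
    return tuple(sorted({max(1, int(np.floor(r + d + 0.5))) for d in (-1.0, 0.0, 1.0)}))


def cht_bidirectional(
    v: Volume,
    radius_mm: float,
    axes: tuple[int, ...] = (0, 1),
    arc_halfwidth: float = 0.35,
    sigma: float = 1.0,
    edge_percentile: float = 95.0,
) -> Accumulator:
    """Slice-wise CHT over two (or more) orthogonal axis stacks, blended
    by elementwise multiplication of the raw per-stack vote counts.

    The stacks are deliberately not normalized before blending: dividing
    each stack by its own peak rescales every object by its own strongest
    response, which cancels exactly the relative advantage spheres (strong
    in every stack) hold over elongated objects (strong in one stack) —
    the reason multiplication is used in the first place. Detection
    thresholds are taken relative to the blended maximum, so absolute
    scale does not matter downstream.
    """
    if not v.isotropic:
        raise AnisotropicVolumeError(
            "bidirectional CHT requires isotropic voxels; resample first"
        )
    s = v.spacing[0]
    if radius_mm <= s:
        raise ValueError("radius_mm must exceed the voxel size")
    radii = radii_for(radius_mm, s)
    blended = None
    for axis in axes:
        acc3 = np.zeros(v.shape, dtype=float)
        for k in range(v.shape[axis]):
            sl = np.take(v.data, k, axis=axis)
            mag, ang = gaussian_gradient(sl, sigma)
            acc2 = cht_slice(mag, ang, radii, arc_halfwidth, edge_percentile)
            if axis == 0:
                acc3[k, :, :] = acc2
            elif axis == 1:
                acc3[:, k, :] = acc2
            else:
                acc3[:, :, k] = acc2
        blended = acc3 if blended is None else blended * acc3
    return Accumulator(Volume(blended, v.spacing, v.origin), radii)


def detect_spheres_hough(
    v: Volume,
    radius_mm: float = 3.5,
    threshold_rel: float = 0.3,
    axes: tuple[int, ...] = (0, 1),
    **cht_kwargs,
) -> list[SphereCandidate]:
    """Detect sphere centres as thresholded local maxima of the blended
    accumulator; positions are returned in physical mm."""
    if not 0 < threshold_rel <= 1:
        raise ValueError("threshold_rel must be in (0, 1]")
    acc = cht_bidirectional(v, radius_mm, axes=axes, **cht_kwargs)
    vmax = acc.votes.data.max()
    if vmax <= 0:
        return []
    pos, vals = find_local_maxima(
        acc.votes, min_distance=2.0 * radius_mm, threshold=threshold_rel * vmax
    )
    return [SphereCandidate(p, s, "hough") for p, s in zip(pos, vals)]
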