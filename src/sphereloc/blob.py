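"""Determinant-of-Hessian (DoH) blob detector with moment-based filtering.

Blob responses are computed slice-wise in 2D at a single characteristic
scale index t (the Gaussian variance) derived from the known sphere
radius, then stacked into 3D. Candidate generation is deliberately
permissive (all positive local maxima in a marker-radius-sized
neighbourhood), so candidates are filtered by a descriptor built from the
normalized second-order central image moments of a marker-sized 3D
neighbourhood: true spheres share a characteristic moment signature
(trace 3R^2/5 for a solid ball of radius R), and k-means clustering with a
knee-selected cluster count isolates that group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .volume import SphereCandidate, Volume, find_local_maxima


@dataclass
class DoHResponse:
    """Stacked per-slice normalized DoH values at a single scale index."""

    response: Volume
    scale_t: float


@dataclass
class MomentDescriptor:
    """Normalized second-order central moments (mm^2) of the intensity in
    a marker-radius-sized neighbourhood; symmetric PSD 3x3 matrix for
    non-negative intensities."""

    moments: np.ndarray  # (3, 3)
    degenerate: bool = False

    @property
    def vector(self) -> np.ndarray:
        m = self.moments
        return np.asarray([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]])

    @property
    def size(self) -> float:
        return float(np.trace(self.moments))


def scale_space_slice(slice2d: np.ndarray, t: float) -> np.ndarray:
    """Scale-space representation L(.; t): Gaussian smoothing with
    variance sigma^2 = t."""
    if t <= 0:
        raise ValueError("scale index t must be positive")
    return ndimage.gaussian_filter(np.asarray(slice2d, dtype=float), np.sqrt(t),
                                   mode="nearest")


def doh_response(L: np.ndarray, t: float) -> np.ndarray:
    """Scale-normalized determinant of the Hessian: t^2 (Lxx Lyy - Lxy^2),
    second derivatives by central differences."""
    L = np.asarray(L, dtype=float)
    lxx = ndimage.correlate1d(L, [1.0, -2.0, 1.0], axis=0, mode="nearest")
    lyy = ndimage.correlate1d(L, [1.0, -2.0, 1.0], axis=1, mode="nearest")
    lx = ndimage.correlate1d(L, [0.5, 0.0, -0.5], axis=0, mode="nearest")
    lxy = ndimage.correlate1d(lx, [0.5, 0.0, -0.5], axis=1, mode="nearest")
    return t * t * (lxx * lyy - lxy * lxy)


def scale_for_radius(radius_vox: float) -> float:
    """Characteristic scale index for a blob of the given voxel radius:
    t = r^2 / 2 (equivalently r = sigma sqrt(2))."""
    return radius_vox * radius_vox / 2.0


def doh_volume(v: Volume, radius_mm: float, scale_index: float | None = None,
               axis: int = 0) -> DoHResponse:
    """Per-slice DoH response at a single scale, stacked into 3D."""
    if not v.isotropic:
        raise ValueError("DoH blob detection requires isotropic voxels; resample first")
    s = v.spacing[0]
    t = scale_for_radius(radius_mm / s) if scale_index is None else float(scale_index)
    resp = np.zeros(v.shape, dtype=float)
    for k in range(v.shape[axis]):
        sl = np.take(v.data, k, axis=axis)
        r2 = doh_response(scale_space_slice(sl, t), t)
        if axis == 0:
            resp[k, :, :] = r2
        elif axis == 1:
            resp[:, k, :] = r2
        else:
            resp[:, :, k] = r2
    return DoHResponse(Volume(resp, v.spacing, v.origin), t)


def blob_candidates(
    v: Volume,
    radius_mm: float,
    scale_index: float | None = None,
    axis: int = 0,
    min_distance_mm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """All positive local DoH maxima in a marker-radius-sized
    neighbourhood (positions mm, response values). Deliberately permissive;
    filtering happens downstream. ``min_distance_mm`` defaults to the
    sphere radius."""
    doh = doh_volume(v, radius_mm, scale_index, axis)
    md = radius_mm if min_distance_mm is None else min_distance_mm
    return find_local_maxima(doh.response, min_distance=md, threshold=0.0)


def moment_descriptor(v: Volume, center, radius_mm: float) -> MomentDescriptor:
    """Normalized second-order central moments of the intensity in the
    cubic neighbourhood of half-size ``radius_mm`` around ``center`` (mm).

    Negative intensities are clipped to zero so the moment matrix stays
    positive semi-definite. A zero-total-intensity window yields a
    descriptor flagged degenerate.
    """
    center = np.asarray(center, dtype=float)
    ci = np.round(v.physical_to_voxel(center)).astype(int)
    half = [max(1, int(round(radius_mm / s))) for s in v.spacing]
    lo = np.maximum(ci - half, 0)
    hi = np.minimum(ci + half, np.asarray(v.shape) - 1)
    region = tuple(np.s_[a:b + 1] for a, b in zip(lo, hi))
    w = np.clip(np.asarray(v.data[region], dtype=float), 0.0, None)
    total = w.sum()
    if total <= 0:
        return MomentDescriptor(np.zeros((3, 3)), degenerate=True)
    axes = [(np.arange(a, b + 1) * s) for (a, b), s in zip(zip(lo, hi), v.spacing)]
    grids = np.meshgrid(*axes, indexing="ij")
    mean = np.asarray([float((g * w).sum() / total) for g in grids])
    d = [g - m for g, m in zip(grids, mean)]
    m = np.empty((3, 3))
    for a in range(3):
        for b in range(a, 3):
            m[a, b] = m[b, a] = float((w * d[a] * d[b]).sum() / total)
    return MomentDescriptor(m)


def sphere_moment_trace(radius_mm: float) -> float:
    """Trace of the normalized second-moment matrix of a uniform solid
    sphere: 3 R^2 / 5 (each diagonal entry is R^2/5)."""
    return 3.0 * radius_mm * radius_mm / 5.0


def _knee_index(inertias: np.ndarray) -> int:
    """Knee of a decreasing curve: point of maximum distance to the chord
    between its endpoints.

    The curve is taken on a log scale (inertia drops are multiplicative)
    and both axes are normalized to [0, 1], so early huge drops do not
    mask a later elbow.
    """
    n = len(inertias)
    if n <= 2:
        return n
    x = np.linspace(0.0, 1.0, n)
    y = np.log(np.maximum(inertias, np.max(inertias) * 1e-12))
    if y[0] == y[-1]:
        return 1
    y = (y - y[-1]) / (y[0] - y[-1])
    # distance from (x_i, y_i) to the chord from (0, 1) to (1, 0)
    dist = np.abs(1.0 - x - y) / np.sqrt(2.0)
    return int(np.argmax(dist)) + 1  # back to 1-based k


def cluster_select(
    descriptors: list[MomentDescriptor],
    characteristic_size: float,
    k_max: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Select the descriptor cluster matching the marker's characteristic
    moment signature.

    k-means is run for k = 1..k_max. The cluster count is the smallest k
    whose within-cluster inertia drops below 5% of the single-cluster
    inertia (clusters are then essentially resolved); if no k achieves
    that, the knee of the inertia curve decides. The cluster whose mean
    descriptor lies closest to the analytic solid-sphere signature
    (isotropic diagonal ``characteristic_size / 3``, zero off-diagonals)
    is returned, as indices into ``descriptors``.
    """
    X = np.stack([d.vector for d in descriptors])
    n = len(X)
    if n < 2 or np.allclose(X, X[0]):
        return np.arange(n)
    # a spread that is negligible against the descriptor magnitudes is one
    # tight group: clustering would only carve up noise
    scatter = float(((X - X.mean(axis=0)) ** 2).sum())
    scale = float((X**2).sum()) + 1e-30
    if scatter <= 1e-4 * scale:
        return np.arange(n)
    k_hi = min(k_max, len(np.unique(X, axis=0)))
    inertias = []
    fits = {}
    for k in range(1, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        inertias.append(km.inertia_)
        fits[k] = km
    inert = np.asarray(inertias)
    resolved = np.nonzero(inert <= 0.05 * inert[0])[0]
    if resolved.size:
        k_sel = int(resolved[0]) + 1
    else:
        k_sel = _knee_index(inert)
        # a knee is only meaningful if splitting actually explains
        # structure; a single tight group shows no substantial drop
        if inert[0] > 0 and inert[k_sel - 1] > 0.5 * inert[0]:
            k_sel = 1
    km = fits[k_sel]
    signature = np.asarray([characteristic_size / 3.0] * 3 + [0.0] * 3)
    best, best_dev = 0, np.inf
    for c in range(k_sel):
        members = km.labels_ == c
        if not members.any():
            continue
        dev = float(np.linalg.norm(X[members].mean(axis=0) - signature))
        if dev < best_dev:
            best, best_dev = c, dev
    return np.nonzero(km.labels_ == best)[0]


def detect_spheres_blob(
    v: Volume,
    radius_mm: float = 3.5,
    scale_index: float | None = None,
    axis: int = 0,
    k_max: int = 8,
    seed: int = 0,
) -> list[SphereCandidate]:
    """DoH candidates -> moment descriptors -> knee/k-means cluster
    selection; the marker-model pairing happens downstream as for all
    detectors. Score is the DoH response.

    Candidate maxima are merged within one sphere diameter (two true
    centres can never lie closer than that), matching the other detectors'
    suppression distance.
    """
    pos, vals = blob_candidates(
        v, radius_mm, scale_index, axis, min_distance_mm=2.0 * radius_mm
    )
    if len(pos) == 0:
        return []
    descriptors = [moment_descriptor(v, p, radius_mm) for p in pos]
    valid = np.asarray([not d.degenerate for d in descriptors])
    pos, vals = pos[valid], vals[valid]
    descriptors = [d for d, ok in zip(descriptors, valid) if ok]
    if len(descriptors) == 0:
        return []
    if len(descriptors) < 2:
        sel = np.arange(len(descriptors))
    else:
        sel = cluster_select(descriptors, sphere_moment_trace(radius_mm),
                             k_max=k_max, seed=seed)
    return [SphereCandidate(pos[i], vals[i], "blob") for i in sel]
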