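"""Connected-component labeling and analysis (CCA) sphere detector.

Pipeline: Gaussian blur (noise cancellation) -> unsharp mask (suppresses
the spheres' immediate surroundings, separating them from the housing) ->
binarization at the first threshold of a four-class multi-Otsu -> 6-connected
component labeling -> per-component radius and roundness filtering ->
centroids of the surviving components as sphere candidates.

Roundness is the ratio of the surface area of the equal-volume sphere to
the surface area measured on the component (1 for a perfect sphere,
smaller for elongated or hollow shapes); the measured area comes from a
triangulated iso-surface of the component mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.measure import marching_cubes, mesh_surface_area

from .volume import DegenerateInputError, SphereCandidate, Volume

# 6-connectivity: faces only
STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class LabeledComponents:
    """Label map of maximal 6-connected foreground components
    (0 = background, components labeled 1..n_components)."""

    label_map: np.ndarray
    n_components: int


@dataclass
class ComponentFeatures:
    label: int
    voxel_count: int
    volume_mm3: float
    equivalent_radius: float
    roundness: float
    centroid: np.ndarray
    surface_area_mm2: float


def gaussian_blur(v: Volume, sigma_mm: float) -> Volume:
    """Gaussian smoothing with sigma given in mm (converted per axis)."""
    sig_vox = [sigma_mm / s for s in v.spacing]
    return Volume(
        ndimage.gaussian_filter(np.asarray(v.data, dtype=float), sig_vox, mode="nearest"),
        v.spacing,
        v.origin,
    )


def unsharp_mask(v: Volume, sigma_mm: float, amount: float) -> Volume:
    """out = v + amount * (v - blur(v, sigma)); sharpens edges and pushes
    the neighbourhood of bright objects below its original intensity."""
    if sigma_mm <= 0 or amount < 0:
        raise ValueError("sigma must be positive and amount non-negative")
    blurred = gaussian_blur(v, sigma_mm)
    return Volume(v.data + amount * (v.data - blurred.data), v.spacing, v.origin)


def multi_otsu_thresholds(counts, bin_centers, n_classes: int = 4) -> np.ndarray:
    """Multi-level Otsu thresholds from a histogram.

    Returns ``n_classes - 1`` thresholds maximizing the between-class
    variance. For binarization only the first is used (the first class is
    background).
    """
    counts = np.asarray(counts, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if np.count_nonzero(counts) < n_classes:
        raise DegenerateInputError(
            f"histogram has fewer than {n_classes} populated bins"
        )
    return threshold_multiotsu(classes=n_classes, hist=(counts, bin_centers))


def label_components(binary: np.ndarray) -> LabeledComponents:
    """6-connected component labeling of a binary volume."""
    arr = np.asarray(binary)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("input must be binary (0/1)")
    labels, n = ndimage.label(arr, structure=STRUCTURE_6)
    return LabeledComponents(labels, int(n))


def component_features(
    lc: LabeledComponents, v: Volume, labels=None
) -> list[ComponentFeatures]:
    """Geometric features per labeled component.

    Surface area is measured on a triangulated iso-surface (level 0.5) of
    the padded component mask; centroids are means of member voxel centres
    in mm.
    """
    if labels is None:
        labels = range(1, lc.n_components + 1)
    voxel_vol = float(np.prod(v.spacing))
    sphere_area_coeff = (36.0 * np.pi) ** (1.0 / 3.0)
    objects = ndimage.find_objects(lc.label_map)
    feats = []
    for lab in labels:
        sl = objects[lab - 1]
        if sl is None:
            continue
        mask = lc.label_map[sl] == lab
        count = int(mask.sum())
        vol_mm3 = count * voxel_vol
        r_eq = (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
        padded = np.pad(mask.astype(float), 1)
        try:
            verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=v.spacing)
            area = float(mesh_surface_area(verts, faces))
        except (ValueError, RuntimeError):
            area = np.inf  # degenerate/too-small surface
        roundness = sphere_area_coeff * vol_mm3 ** (2.0 / 3.0) / area if area > 0 else 0.0
        idx = np.argwhere(mask) + np.asarray([s.start for s in sl])
        centroid = v.voxel_to_physical(idx.mean(axis=0))
        feats.append(
            ComponentFeatures(int(lab), count, vol_mm3, float(r_eq), float(roundness),
                              centroid, area)
        )
    return feats


def detect_spheres_cca(
    v: Volume,
    radius_mm: float = 3.5,
    radius_tol: float = 0.35,
    roundness_min: float = 0.6,
    blur_sigma_factor: float = 0.5,
    unsharp_sigma_mm: float = 1.0,
    unsharp_amount: float = 1.0,
    nbins: int = 256,
) -> list[SphereCandidate]:
    """Full CCA detection pipeline; candidate score is the roundness."""
    if radius_mm <= 0 or radius_tol <= 0 or roundness_min <= 0:
        raise ValueError("parameters must be positive")
    blurred = gaussian_blur(v, blur_sigma_factor * min(v.spacing))
    # unsharp sigma is fixed in mm so the housing suppression does not
    # weaken at fine resolutions
    sharp = unsharp_mask(blurred, unsharp_sigma_mm, unsharp_amount)
    counts, edges = np.histogram(sharp.data, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    thresholds = multi_otsu_thresholds(counts, centers, n_classes=4)
    # binarize at the first cut above the histogram mode: the lowest class
    # is the background population, but when a heavily dominant background
    # peak is itself split by a cut, that sub-mode cut is not a
    # background/foreground boundary
    mode_center = centers[int(np.argmax(counts))]
    above = [t for t in thresholds if t > mode_center]
    t_bg = above[0] if above else thresholds[0]
    binary = (sharp.data > t_bg).astype(np.uint8)
    if not binary.any():
        return []
    lc = label_components(binary)
    if lc.n_components == 0:
        return []
    # cheap size prefilter before the (costly) surface measurement
    sizes = np.bincount(lc.label_map.ravel(), minlength=lc.n_components + 1)
    voxel_vol = float(np.prod(v.spacing))
    r_eq_all = (3.0 * sizes * voxel_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    lo, hi = (1 - radius_tol) * radius_mm, (1 + radius_tol) * radius_mm
    keep_labels = [
        lab for lab in range(1, lc.n_components + 1) if lo <= r_eq_all[lab] <= hi
    ]
    candidates = []
    for f in component_features(lc, v, labels=keep_labels):
        if abs(f.equivalent_radius - radius_mm) <= radius_tol * radius_mm and (
            f.roundness >= roundness_min
        ):
            candidates.append(SphereCandidate(f.centroid, f.roundness, "cca"))
    return candidates
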