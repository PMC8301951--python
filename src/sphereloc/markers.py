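"""Two-sphere marker model: pairing by the distance constraint and pose.

A physical marker holds two spheres a fixed 11 mm apart, so a valid
detection is a pair of sphere candidates whose distance falls within a
corridor (11.0 +- 1.0 mm by default). Pairing greedily consumes candidates
in descending score order; solitary candidates with no in-corridor partner
are returned unpaired and treated as discarded false positives. The marker
pose is the midpoint plus the unit axis direction between the centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import SphereCandidate

DEFAULT_SPACING_MM = 11.0
DEFAULT_SPACING_TOL_MM = 1.0


@dataclass
class Marker:
    """A paired two-sphere marker (positions in mm)."""

    sphere_a: np.ndarray
    sphere_b: np.ndarray

    def __post_init__(self) -> None:
        self.sphere_a = np.asarray(self.sphere_a, dtype=float)
        self.sphere_b = np.asarray(self.sphere_b, dtype=float)
        if np.allclose(self.sphere_a, self.sphere_b):
            raise ValueError("marker spheres must not coincide")

    @property
    def spacing_mm(self) -> float:
        return float(np.linalg.norm(self.sphere_b - self.sphere_a))

    @property
    def direction(self) -> np.ndarray:
        d = self.sphere_b - self.sphere_a
        return d / np.linalg.norm(d)

    @property
    def position(self) -> np.ndarray:
        return 0.5 * (self.sphere_a + self.sphere_b)


def pair_spheres(
    candidates: list[SphereCandidate],
    spacing: float = DEFAULT_SPACING_MM,
    tol: float = DEFAULT_SPACING_TOL_MM,
) -> tuple[list[Marker], list[SphereCandidate]]:
    """Greedily pair sphere candidates into markers.

    Candidates are visited in descending score order (ties by input
    order). Each still-unpaired candidate searches the remaining unpaired
    set for the partner whose distance is closest to ``spacing`` within
    ``|d - spacing| <= tol``; accepted pairs are removed from the set.
    Candidates never paired are returned as the second element.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    order = sorted(range(len(candidates)), key=lambda i: (-candidates[i].score, i))
    unpaired = set(order)
    markers: list[Marker] = []
    for i in order:
        if i not in unpaired:
            continue
        best_j, best_dev = None, np.inf
        for j in order:
            if j == i or j not in unpaired:
                continue
            d = float(np.linalg.norm(candidates[j].position - candidates[i].position))
            dev = abs(d - spacing)
            if dev <= tol and dev < best_dev:
                best_j, best_dev = j, dev
        if best_j is not None:
            unpaired.discard(i)
            unpaired.discard(best_j)
            markers.append(Marker(candidates[i].position, candidates[best_j].position))
    leftovers = [candidates[i] for i in sorted(unpaired)]
    return markers, leftovers


def canonical_direction(d: np.ndarray) -> np.ndarray:
    """Sign-canonical representative of an axis direction: the component
    of largest magnitude is made positive (the two marker spheres are
    constructively identical, so the axis has no intrinsic sign)."""
    d = np.asarray(d, dtype=float)
    k = int(np.argmax(np.abs(d)))
    return -d if d[k] < 0 else d.copy()


def marker_pose(m: Marker) -> tuple[np.ndarray, np.ndarray]:
    """(position, direction): midpoint of the two centroids and the
    sign-canonical unit axis."""
    return m.position, canonical_direction(m.direction)
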