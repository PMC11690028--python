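"""Y-view cut planes and per-section voxel masks.

The sectional measurement anchors everything to the scapular Y-view plane.
Medial offset planes (default 0, 25, 50 mm, i.e. the Y, Y+2.5 cm and Y+5 cm
sections) are parallel to the Y-view plane, offsets measured perpendicular to
it; sections are *cumulative* regions from the most lateral extent of a muscle
to the section's bounding plane.  A second, axial cut-off plane 30 mm inferior
to the lower end of the glenoid labrum removes the inferior muscle margin that
shoulder CT protocols do not reliably cover.

Voxel membership uses the voxel-center rule: a voxel belongs to a section iff
its world-mapped center lies on the kept (lateral resp. superior) side of the
bounding planes, with centers exactly on a plane kept.  This rule is
deterministic and converges to the continuum volume as spacing shrinks; an
optional sub-voxel supersampling refines partial-volume handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import LandmarkGeometryError, LandmarkSet, MuscleLabelMap

__all__ = [
    "OrientedPlane",
    "SectionPlaneSet",
    "SectionMask",
    "EmptySectionWarning",
    "build_plane_set",
    "signed_distance",
    "voxel_center_distances",
    "section_mask",
    "section_name",
]

INFERIOR = np.array([0.0, 0.0, -1.0])  # -z in RAS/LPS world frames


class EmptySectionWarning(UserWarning):
    """A sectional mask came out empty (plane configuration excludes the muscle)."""


@dataclass(frozen=True)
class OrientedPlane:
    """A plane through ``point`` with unit ``normal``.

    The normal fixes an orientation: positive signed distance is the medial
    side for the Y-plane family and the inferior side for the cut-off plane.
    """

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-9:
            raise ValueError(f"plane normal must be unit length (|n|={norm})")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance (mm) of world point(s); positive on the oriented side."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.point) @ self.normal


def signed_distance(plane: OrientedPlane, point) -> float | np.ndarray:
    """Functional form of :meth:`OrientedPlane.signed_distance`."""
    d = plane.signed_distance(point)
    return float(d) if np.ndim(d) == 0 else d


def section_name(offset_mm: float) -> str:
    """Canonical section label for a medial offset: 0 -> ``Y``, 25 -> ``Y+2.5``."""
    if offset_mm == 0:
        return "Y"
    return f"Y+{offset_mm / 10:g}"


@dataclass(frozen=True)
class SectionPlaneSet:
    """The Y-view plane family plus the inferior cut-off of one exam."""

    base: OrientedPlane
    offsets_mm: tuple
    inferior_cutoff: OrientedPlane

    def __post_init__(self) -> None:
        offs = tuple(float(o) for o in self.offsets_mm)
        if not offs or offs[0] != 0.0 or any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError(
                f"offsets_mm must start at 0 and strictly increase, got {offs}"
            )
        object.__setattr__(self, "offsets_mm", offs)
        if self.inferior_cutoff.normal[2] >= 0:
            raise ValueError("inferior cut-off normal must point inferior (-z)")

    @property
    def section_names(self) -> tuple:
        return tuple(section_name(o) for o in self.offsets_mm)

    def offset_for(self, section: str) -> float:
        for off in self.offsets_mm:
            if section_name(off) == section:
                return off
        raise KeyError(
            f"unknown section {section!r}; available: {self.section_names}"
        )

    def bounding_plane(self, section: str) -> OrientedPlane:
        """The medial bounding plane of a section (base displaced medially)."""
        off = self.offset_for(section)
        return OrientedPlane(self.base.point + off * self.base.normal, self.base.normal)


@dataclass
class SectionMask:
    """Boolean voxel mask of one muscle restricted to one cumulative section."""

    mask: np.ndarray
    muscle: str
    section: str


def build_plane_set(
    landmarks: LandmarkSet,
    offsets_mm: Sequence[float] = (0.0, 25.0, 50.0),
    inferior_offset_mm: float = 30.0,
) -> SectionPlaneSet:
    """Construct the Y-view plane family and the inferior cut-off plane.

    The base plane passes through the three ``y_plane_points``; its normal is
    oriented toward ``medial_reference`` so that positive signed distance is
    medial.  Offset planes share this normal, displaced by ``offsets_mm``
    along it.  The cut-off plane passes ``inferior_offset_mm`` inferior to
    ``labrum_inferior``, normal pointing inferior, so voxels with positive
    signed distance to it are below the kept region.
    """
    landmarks.validate()
    if inferior_offset_mm <= 0:
        raise ValueError("inferior_offset_mm must be positive")
    p1, p2, p3 = landmarks.y_plane_points
    cross = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(cross)
    if norm / 2.0 <= 1.0:
        raise LandmarkGeometryError("y_plane_points nearly collinear")
    normal = cross / norm
    if float(np.dot(normal, landmarks.medial_reference - p1)) < 0:
        normal = -normal
    base = OrientedPlane(p1, normal)
    cutoff_point = landmarks.labrum_inferior + inferior_offset_mm * INFERIOR
    cutoff = OrientedPlane(cutoff_point, INFERIOR)
    return SectionPlaneSet(base=base, offsets_mm=tuple(offsets_mm),
                           inferior_cutoff=cutoff)


def voxel_center_distances(affine: np.ndarray, shape, plane: OrientedPlane) -> np.ndarray:
    """Signed distance of every voxel center to ``plane``.

    The distance is affine in the voxel index, so it is assembled from three
    1-D per-axis ramps plus a constant — no voxel coordinate array is ever
    materialised.
    """
    affine = np.asarray(affine, dtype=float)
    m = affine[:3, :3]
    t = affine[:3, 3]
    coef = plane.normal @ m  # distance increment per index step, each axis
    const = float(plane.normal @ (t - plane.point))
    ni, nj, nk = shape
    di = coef[0] * np.arange(ni, dtype=float)
    dj = coef[1] * np.arange(nj, dtype=float)
    dk = coef[2] * np.arange(nk, dtype=float)
    return di[:, None, None] + dj[None, :, None] + dk[None, None, :] + const


def _kept(affine, shape, planes: SectionPlaneSet, offset_mm: float):
    """Voxel centers lateral of the bounding plane and superior to the cut-off."""
    d_base = voxel_center_distances(affine, shape, planes.base)
    keep = d_base <= offset_mm  # medial distance at most the offset: lateral side kept
    d_cut = voxel_center_distances(affine, shape, planes.inferior_cutoff)
    keep &= d_cut <= 0.0  # superior to (or exactly on) the cut-off
    return keep


def section_mask(
    labels: MuscleLabelMap,
    muscle: int,
    planes: SectionPlaneSet,
    section: str,
) -> SectionMask:
    """Binary mask of one muscle's cumulative section.

    A voxel is included iff its label equals ``muscle``, its center lies
    lateral of (or on) the section's bounding plane, and superior to (or on)
    the inferior cut-off.  An empty result is permitted but raises an
    :class:`EmptySectionWarning`.
    """
    if muscle not in labels.code_map or muscle == 0:
        raise ValueError(f"muscle code {muscle} not in code map {labels.code_map}")
    support = labels.support(muscle)
    if not support.any():
        raise ValueError(
            f"label {muscle} ({labels.code_map[muscle]}) is empty in this exam"
        )
    offset = planes.offset_for(section)
    mask = support & _kept(labels.affine, labels.shape, planes, offset)
    if not mask.any():
        warnings.warn(
            f"section {section} of {labels.code_map[muscle]} is empty",
            EmptySectionWarning,
            stacklevel=2,
        )
    return SectionMask(mask=mask, muscle=labels.code_map[muscle], section=section)


def section_fraction_map(
    labels: MuscleLabelMap,
    muscle: int,
    planes: SectionPlaneSet,
    section: str,
    supersample: int = 2,
) -> np.ndarray:
    """Partial-volume refinement of :func:`section_mask`.

    Each label voxel is subdivided into ``supersample**3`` sub-centers; the
    returned float array holds the fraction of sub-centers passing the plane
    predicates (label membership itself stays at voxel resolution — the label
    map is the finest segmentation available).
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    if supersample == 1:
        return section_mask(labels, muscle, planes, section).mask.astype(float)
    support = labels.support(muscle)
    offset = planes.offset_for(section)
    affine = np.asarray(labels.affine, dtype=float)
    m = affine[:3, :3]
    frac = np.zeros(labels.shape, dtype=float)
    steps = (np.arange(supersample) + 0.5) / supersample - 0.5
    for si in steps:
        for sj in steps:
            for sk in steps:
                shift = m @ np.array([si, sj, sk])
                sub_affine = affine.copy()
                sub_affine[:3, 3] = affine[:3, 3] + shift
                frac += _kept(sub_affine, labels.shape, planes, offset)
    frac /= supersample ** 3
    frac[~support] = 0.0
    return frac
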