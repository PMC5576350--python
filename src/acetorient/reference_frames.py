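"""Patient-specific reference planes and body axes from bony landmarks.

The coronal reference is the anterior pelvic plane (APP), the
total-least-squares plane through the two ASIS and the two pubic
tubercles (generically non-coplanar).  The sagittal plane is the
total-least-squares plane through the ASIS midpoint and the sacral-crest
points.  The transverse plane is constructed, not fitted: its normal is
the cross product of the coronal and sagittal normals, which makes it
exactly perpendicular to the sagittal plane and perpendicular to the
coronal plane to numerical precision.  (A "literal" alternative that
crosses the ASIS-to-ASIS vector with the sagittal normal is available;
it is near-degenerate because that vector is almost parallel to the
sagittal normal, which is why it is not the default.)

Normal orientations are fixed so signs downstream are meaningful:
coronal → anterior (away from the sacrum), sagittal → toward the
patient's right, transverse → cranial.  The longitudinal body axis is
the coronal–sagittal intersection (cranial); the transverse body axis is
the coronal–transverse intersection (patient left → right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_geometry import (
    DEGENERACY_TOL,
    DegenerateGeometryError,
    Plane,
    Point3,
    Vec3,
    angle_between_planes,
    plane_intersection_direction,
    unit,
)
from .landmarks import LandmarkSet

__all__ = [
    "ReferenceFrame",
    "PerpendicularityReport",
    "fit_plane_least_squares",
    "build_app",
    "build_sagittal",
    "build_transverse",
    "build_frame",
    "perpendicularity_report",
]


@dataclass(frozen=True)
class ReferenceFrame:
    """The three reference planes and derived body axes for one case.

    ``longitudinal_axis`` points cranially, ``transverse_axis`` from the
    patient's left toward the right; both are unit vectors.  ``origin``
    is the midpoint of the bilateral ASIS.
    """

    coronal: Plane
    sagittal: Plane
    transverse: Plane
    longitudinal_axis: Vec3
    transverse_axis: Vec3
    origin: Point3

    @property
    def anterior_axis(self) -> Vec3:
        """Unit anterior direction (the oriented coronal normal)."""
        return self.coronal.normal

    def lateral_axis(self, side: str) -> Vec3:
        """Unit lateral direction for a hip side (away from the midline)."""
        if side == "right":
            return self.transverse_axis
        if side == "left":
            return -self.transverse_axis
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")


@dataclass(frozen=True)
class PerpendicularityReport:
    """Pairwise oriented-normal angles between the three reference planes.

    The sagittal–transverse entry is 90° by construction; the two
    APP entries quantify how far the fitted anterior pelvic plane is
    from true coronal alignment.
    """

    angle_coronal_sagittal: float
    angle_coronal_transverse: float
    angle_sagittal_transverse: float

    def as_dict(self) -> dict[str, float]:
        return {
            "angle_coronal_sagittal": self.angle_coronal_sagittal,
            "angle_coronal_transverse": self.angle_coronal_transverse,
            "angle_sagittal_transverse": self.angle_sagittal_transverse,
        }


def fit_plane_least_squares(points) -> tuple[Plane, float]:
    """Total-least-squares plane through a point cloud.

    Minimizes the sum of squared *orthogonal* distances: the normal is
    the smallest-variance principal direction of the centered cloud
    (smallest right singular vector), and the plane passes through the
    centroid.  Returns the plane (normal sign arbitrary; callers orient)
    and the RMS orthogonal distance in mm.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or a (near-)collinear/coincident cloud,
        detected as a second singular value indistinguishable from noise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    n = len(pts)
    if n < 3:
        raise DegenerateGeometryError(f"plane fit needs ≥3 points, got {n}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(float(s[0]), 1.0)
    if s[1] < DEGENERACY_TOL * scale:
        raise DegenerateGeometryError("points are (near-)collinear; plane undefined")
    normal = vt[-1]
    rms = float(s[-1] / np.sqrt(n))
    return Plane.from_normal_point(normal, centroid), rms


def build_app(lset: LandmarkSet) -> Plane:
    """Anterior pelvic plane from the two ASIS and two pubic tubercles.

    Least-squares plane through the four points, its normal oriented
    anteriorly, i.e. away from the sacral-crest centroid.
    """
    pts = np.array([lset.asis_left, lset.asis_right, lset.pubic_left, lset.pubic_right])
    plane, _ = fit_plane_least_squares(pts)
    sacral_centroid = lset.sacral_crest.mean(axis=0)
    if plane.signed_distance(sacral_centroid) > 0:
        plane = plane.flipped()
    return plane


def build_sagittal(lset: LandmarkSet) -> Plane:
    """Sagittal plane through the ASIS midpoint and the sacral-crest points.

    Least-squares plane over {ASIS midpoint} ∪ sacral points, its normal
    oriented toward the patient's right (right ASIS on the positive side).

    Raises
    ------
    DegenerateGeometryError
        With fewer than 3 sacral points (validation minimum) or a
        collinear defining set.
    """
    if len(lset.sacral_crest) < 3:
        raise DegenerateGeometryError(
            f"sagittal plane needs ≥3 sacral points, got {len(lset.sacral_crest)}"
        )
    pts = np.vstack([lset.asis_midpoint[None, :], lset.sacral_crest])
    plane, _ = fit_plane_least_squares(pts)
    if plane.signed_distance(lset.asis_right) < 0:
        plane = plane.flipped()
    return plane


def build_transverse(
    coronal: Plane,
    sagittal: Plane,
    asis_vector: Vec3 | None = None,
    origin: Point3 | None = None,
    mode: str = "orthogonal",
    cranial_hint: Vec3 | None = None,
) -> Plane:
    """Transverse plane from the other two reference planes.

    mode="orthogonal" (default)
        Normal = n̂_coronal × n̂_sagittal — exactly perpendicular to the
        sagittal plane, and perpendicular to the coronal plane to
        numerical precision.
    mode="literal"
        Normal = (ASIS left→right vector) × n̂_sagittal.  Because the
        inter-ASIS vector is nearly parallel to the sagittal normal this
        cross product is near-degenerate and fails loudly on clean input;
        it is kept for comparison only.

    The plane passes through ``origin`` (the frame origin; the offset is
    inert — every downstream angle uses only the normal).  If
    ``cranial_hint`` is given the normal is flipped to point cranially.
    """
    if mode == "orthogonal":
        normal = np.cross(coronal.normal, sagittal.normal)
    elif mode == "literal":
        if asis_vector is None:
            raise ValueError("literal mode requires the ASIS left→right vector")
        normal = np.cross(np.asarray(asis_vector, dtype=float), sagittal.normal)
    else:
        raise ValueError(f"unknown transverse construction mode {mode!r}")
    norm = float(np.linalg.norm(normal))
    if norm < DEGENERACY_TOL:
        raise DegenerateGeometryError(
            "transverse normal (near-)zero: operand directions are (near-)parallel"
        )
    normal = normal / norm
    if cranial_hint is not None and float(np.dot(normal, cranial_hint)) < 0:
        normal = -normal
    if origin is None:
        origin = np.zeros(3)
    return Plane.from_normal_point(normal, origin)


def build_frame(lset: LandmarkSet, transverse_mode: str = "orthogonal") -> ReferenceFrame:
    """Compose the three reference planes and body axes for one case.

    Orientation conventions (all documented, all deterministic): the
    longitudinal axis points cranially — resolved with the ASIS-midpoint
    minus pubic-midpoint direction, since the pubic tubercles sit caudal
    to the ASIS — and the transverse axis points from the left ASIS
    toward the right.
    """
    origin = lset.asis_midpoint
    cranial_hint = lset.asis_midpoint - lset.pubic_midpoint
    coronal = build_app(lset)
    sagittal = build_sagittal(lset)
    transverse = build_transverse(
        coronal,
        sagittal,
        asis_vector=lset.asis_right - lset.asis_left,
        origin=origin,
        mode=transverse_mode,
        cranial_hint=cranial_hint,
    )
    longitudinal = plane_intersection_direction(coronal, sagittal)
    if float(np.dot(longitudinal, cranial_hint)) < 0:
        longitudinal = -longitudinal
    transverse_axis = plane_intersection_direction(coronal, transverse)
    if float(np.dot(transverse_axis, lset.asis_right - lset.asis_left)) < 0:
        transverse_axis = -transverse_axis
    return ReferenceFrame(
        coronal=coronal,
        sagittal=sagittal,
        transverse=transverse,
        longitudinal_axis=unit(longitudinal),
        transverse_axis=unit(transverse_axis),
        origin=origin,
    )


def perpendicularity_report(frame: ReferenceFrame) -> PerpendicularityReport:
    """Audit the mutual perpendicularity of the three reference planes.

    Oriented-normal angles in degrees; values near but not exactly 90°
    for the two APP pairs quantify how non-orthogonal the fitted
    landmark planes are for this case.
    """
    return PerpendicularityReport(
        angle_coronal_sagittal=angle_between_planes(frame.coronal, frame.sagittal),
        angle_coronal_transverse=angle_between_planes(frame.coronal, frame.transverse),
        angle_sagittal_transverse=angle_between_planes(frame.sagittal, frame.transverse),
    )
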