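"""Acetabular rim-plane fit and the oriented acetabular axis.

The acetabular face is approximated by the total-least-squares plane
through the labelled rim points; the plane's normal is the acetabular
axis.  The unoriented fit is side-agnostic; orientation fixes the sign
so the axis points *out* of the socket — laterally for that hip — which
is what makes anteversion vs. retroversion meaningful downstream.
No sphere or ellipsoid fit is attempted: the rim-plane normal is the
axis definition used throughout.
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
    project_point_to_plane,
)
from .reference_frames import ReferenceFrame, fit_plane_least_squares

__all__ = ["AcetabulumFit", "fit_acetabular_plane", "orient_axis"]


class AxisOrientationError(DegenerateGeometryError):
    """The fitted rim normal has no lateral component: sign is ambiguous."""


@dataclass(frozen=True)
class AcetabulumFit:
    """Fitted acetabular face for one hip.

    ``center`` is the rim centroid projected onto the fitted plane (the
    pivot of the angle constructions); ``axis`` is the unit face normal
    oriented out of the socket; ``rms_residual`` is the orthogonal-fit
    RMS in mm; ``arc_coverage_deg`` is the angular span of rim points
    around the center (360° minus the largest gap, e.g. the unlabelled
    transverse-acetabular-ligament arc).
    """

    side: str
    center: Point3
    axis: Vec3
    rms_residual: float
    n_points: int
    arc_coverage_deg: float


def _arc_coverage(rim: np.ndarray, plane: Plane, center: np.ndarray) -> float:
    """Angular coverage of the rim points around the center, in-plane."""
    n = plane.normal
    # in-plane orthonormal basis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(seed, n))) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - float(np.dot(seed, n)) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    rel = rim - center
    ang = np.sort(np.arctan2(rel @ e2, rel @ e1))
    if len(ang) < 2:
        return 0.0
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
    return float(np.degrees(2 * np.pi - gaps.max()))


def fit_acetabular_plane(rim) -> tuple[Plane, Point3, float]:
    """Fit the acetabular face plane to rim points (unoriented).

    Returns the total-least-squares plane, the rim centroid projected
    onto it, and the RMS orthogonal residual in mm.  Any ≥3 non-collinear
    points define the plane, so a ligament-gap arc does not bias a
    noise-free fit.

    Raises
    ------
    DegenerateGeometryError
        For <3 or (near-)collinear rim points.
    """
    rim = np.asarray(rim, dtype=float)
    plane, rms = fit_plane_least_squares(rim)
    center = project_point_to_plane(rim.mean(axis=0), plane)
    return plane, center, rms


def orient_axis(
    plane: Plane,
    center: Point3,
    rms_residual: float,
    n_points: int,
    frame: ReferenceFrame,
    side: str,
    arc_coverage_deg: float = float("nan"),
) -> AcetabulumFit:
    """Fix the rim-normal sign so the axis points out of the socket.

    The sign is chosen to give a positive component along the frame's
    lateral direction for ``side``.  If the normal is orthogonal to the
    lateral direction within tolerance the orientation is genuinely
    ambiguous and an error is raised rather than silently resolved.
    """
    lateral = frame.lateral_axis(side)
    component = float(np.dot(plane.normal, lateral))
    if abs(component) < DEGENERACY_TOL:
        raise AxisOrientationError(
            f"{side} rim normal has no lateral component; axis sign ambiguous"
        )
    axis = plane.normal if component > 0 else -plane.normal
    return AcetabulumFit(
        side=side,
        center=np.asarray(center, dtype=float),
        axis=axis,
        rms_residual=float(rms_residual),
        n_points=int(n_points),
        arc_coverage_deg=float(arc_coverage_deg),
    )


def fit_hip(rim, frame: ReferenceFrame, side: str) -> AcetabulumFit:
    """Fit and orient one hip's acetabular axis in one call."""
    rim = np.asarray(rim, dtype=float)
    plane, center, rms = fit_acetabular_plane(rim)
    coverage = _arc_coverage(rim, plane, center)
    return orient_axis(plane, center, rms, len(rim), frame, side, coverage)
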