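"""Elementary 3-D vector and plane geometry.

Everything downstream — reference-plane construction, acetabular-axis
fitting, and the six inclination/anteversion angles — reduces to the
handful of operations in this module: angles between direction vectors
(via the normalized inverse cosine), orthogonal projection of points and
vectors onto planes, and plane–plane intersection directions.

Conventions
-----------
* Points (``Point3``) and direction vectors (``Vec3``) are numpy float
  arrays of shape ``(3,)``.  Points are coordinates in millimetres in a
  shared right-handed scanner frame; vectors are dimensionless directions.
* Planes carry an *oriented* unit normal: ``Plane(a, b, c, d)`` encodes
  ``a*x + b*y + c*z + d = 0`` with ``(a, b, c)`` of unit length.  Angles
  between planes are angles between oriented normals in ``[0°, 180°]``;
  callers that need an acute angle fold explicitly.
* All angles cross module boundaries in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

__all__ = [
    "DEGENERACY_TOL",
    "DegenerateGeometryError",
    "Point3",
    "Vec3",
    "Plane",
    "angle_between_vectors",
    "angle_between_planes",
    "project_point_to_plane",
    "project_vector_to_plane",
    "plane_intersection_direction",
    "unit",
    "fold_to_acute",
]

#: Relative norm below which a direction is treated as degenerate.
#: Inputs are mm-scale landmarks with ~0.1 mm precision, so 1e-8 is far
#: below any physically meaningful direction.
DEGENERACY_TOL = 1e-8

#: A 3-D point in millimetres (numpy array of shape (3,)).
Point3 = npt.NDArray[np.float64]

#: A 3-D direction vector (numpy array of shape (3,)).
Vec3 = npt.NDArray[np.float64]


class DegenerateGeometryError(ValueError):
    """Raised when an operation's geometric precondition fails.

    Examples: a zero-length direction, projecting a vector parallel to a
    plane normal, or intersecting (near-)parallel planes.
    """


def _as_xyz(value, name: str = "value") -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must have shape (3,), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr}")
    return arr


def unit(v: Vec3) -> Vec3:
    """Return ``v`` scaled to unit length.

    Raises
    ------
    DegenerateGeometryError
        If ``|v|`` is below :data:`DEGENERACY_TOL`.
    """
    v = _as_xyz(v, "vector")
    n = float(np.linalg.norm(v))
    if n < DEGENERACY_TOL:
        raise DegenerateGeometryError("cannot normalize a (near-)zero vector")
    return v / n


def fold_to_acute(angle_deg: float) -> float:
    """Fold an oriented angle in [0°, 180°] to [0°, 90°] via min(θ, 180−θ)."""
    return float(min(angle_deg, 180.0 - angle_deg))


@dataclass(frozen=True)
class Plane:
    """Oriented plane ``a*x + b*y + c*z + d = 0`` with unit normal (a, b, c).

    The orientation (sign of the normal) is meaningful: anteversion and
    retroversion are distinguished by which side of a reference plane the
    acetabular axis points to.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        coeffs = np.array([self.a, self.b, self.c, self.d], dtype=float)
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("plane coefficients must be finite")
        norm = float(np.linalg.norm(coeffs[:3]))
        if abs(norm - 1.0) > 1e-12:
            raise ValueError(
                "plane normal must be unit length; use Plane.from_coefficients"
            )

    @classmethod
    def from_coefficients(cls, a: float, b: float, c: float, d: float) -> "Plane":
        """Build a plane from unnormalized coefficients, rescaling to unit normal."""
        n = float(np.linalg.norm([a, b, c]))
        if n < DEGENERACY_TOL:
            raise DegenerateGeometryError("plane normal is (near-)zero")
        return cls(a / n, b / n, c / n, d / n)

    @classmethod
    def from_normal_point(cls, normal: Vec3, point: Point3) -> "Plane":
        """Plane through ``point`` with the given (auto-normalized) normal."""
        n = unit(normal)
        p = _as_xyz(point, "point")
        return cls(float(n[0]), float(n[1]), float(n[2]), float(-np.dot(n, p)))

    @property
    def normal(self) -> Vec3:
        """Oriented unit normal (a, b, c)."""
        return np.array([self.a, self.b, self.c], dtype=float)

    def signed_distance(self, point: Point3) -> float:
        """Signed distance of ``point`` from the plane (positive on the normal side)."""
        p = _as_xyz(point, "point")
        return float(np.dot(self.normal, p) + self.d)

    def flipped(self) -> "Plane":
        """Same plane with the normal (and d) negated."""
        return Plane(-self.a, -self.b, -self.c, -self.d)


def angle_between_vectors(u: Vec3, v: Vec3) -> float:
    """Angle between two non-zero vectors, in degrees.

    θ = cos⁻¹( u·v / (|u||v|) ), the cosine argument clamped to [−1, 1]
    so rounding near parallel/anti-parallel input cannot produce NaN.

    Returns
    -------
    float
        θ in [0°, 180°].

    Raises
    ------
    DegenerateGeometryError
        If either vector has (near-)zero length.
    """
    u = _as_xyz(u, "u")
    v = _as_xyz(v, "v")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu < DEGENERACY_TOL or nv < DEGENERACY_TOL:
        raise DegenerateGeometryError("angle undefined for (near-)zero vector")
    cosine = float(np.dot(u, v) / (nu * nv))
    cosine = max(-1.0, min(1.0, cosine))
    return float(np.degrees(np.arccos(cosine)))


def angle_between_planes(p: Plane, q: Plane) -> float:
    """Angle between the *oriented* normals of two planes, in degrees.

    Deliberately not folded to [0°, 90°]: perpendicularity audits compare
    oriented-normal angles with 90°, which distinguishes 88° from 92°.
    """
    return angle_between_vectors(p.normal, q.normal)


def project_point_to_plane(point: Point3, plane: Plane) -> Point3:
    """Foot of the perpendicular from ``point`` onto ``plane``.

    With unit normal n̂ and offset d, the signed offset of the point is
    t = n̂·p + d and the projection is p − t·n̂.  (For a general normal
    this is t = (Ax+By+Cz+D)/(A²+B²+C²); the origin's offset D/(A²+B²+C²)
    is its special case.)
    """
    p = _as_xyz(point, "point")
    t = plane.signed_distance(p)
    return p - t * plane.normal


def project_vector_to_plane(v: Vec3, plane: Plane) -> Vec3:
    """Orthogonal projection of a direction vector into a plane.

    Equivalent to projecting both endpoints of a segment carrying ``v``
    and re-differencing: returns v − (v·n̂)n̂.

    Raises
    ------
    DegenerateGeometryError
        If ``v`` is (near-)parallel to the plane normal, i.e. the
        projection is (near-)zero and its direction undefined.
    """
    v = _as_xyz(v, "v")
    nv = float(np.linalg.norm(v))
    if nv < DEGENERACY_TOL:
        raise DegenerateGeometryError("cannot project a (near-)zero vector")
    n = plane.normal
    proj = v - float(np.dot(v, n)) * n
    if float(np.linalg.norm(proj)) < DEGENERACY_TOL * nv:
        raise DegenerateGeometryError(
            "vector is (near-)parallel to the plane normal; projection degenerate"
        )
    return proj


def plane_intersection_direction(p: Plane, q: Plane) -> Vec3:
    """Unit direction of the line where two non-parallel planes intersect.

    Computed as the cross product of the two unit normals, so the result
    lies in both planes.  The sign follows the right-hand rule on
    (n̂_p, n̂_q); callers orient it anatomically.

    Raises
    ------
    DegenerateGeometryError
        If the planes are (near-)parallel.
    """
    cross = np.cross(p.normal, q.normal)
    n = float(np.linalg.norm(cross))
    if n < DEGENERACY_TOL:
        raise DegenerateGeometryError("planes are (near-)parallel; no unique intersection")
    return cross / n
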