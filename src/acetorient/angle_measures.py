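"""The six acetabular orientation angles and conversion-formula residuals.

Murray's taxonomy distinguishes three measurement systems for cup
orientation, each an (inclination, anteversion) pair defined against the
patient's body planes.  Writing the oriented acetabular axis in frame
components (ℓ, a, c) = (lateral, anterior, cranial):

===============  =============================================  ==========
angle            geometric definition                            closed form
===============  =============================================  ==========
anatomical AI    axis vs. longitudinal axis                      cos AI = −c (folded)
anatomical AA    axis projected to transverse plane vs.          tan AA = a/ℓ
                 transverse axis, signed anterior
operative  OI    axis vs. sagittal plane (line–plane angle,      sin OI = ℓ
                 signed lateral)
operative  OA    axis projected to sagittal plane vs.            tan OA = a/(−c)
                 longitudinal axis, folded, signed anterior
radiographic RI  axis projected to coronal plane vs.             tan RI = ℓ/(−c)
                 longitudinal axis, folded
radiographic RA  axis vs. coronal plane (line–plane angle,       sin RA = a
                 signed anterior)
===============  =============================================  ==========

The pipeline computes each angle *geometrically* (projections and the
inverse-cosine angle formula), never through the closed forms — those
serve as an independent oracle in the tests.

Folding: the raw angle between an infero-laterally pointing axis and the
cranial longitudinal axis is ~140° for a clinically ~40° inclination; by
default inclinations (and OA) are folded to the acute value
min(θ, 180°−θ) so canonical anatomy lands on the clinical scale, with
the raw oriented angles kept in diagnostic fields.

Anteversion sign: positive = anterior; negative values are reported as
retroversion, never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .acetabular_axis import AcetabulumFit, fit_hip
from .core_geometry import (
    DegenerateGeometryError,
    Vec3,
    angle_between_vectors,
    fold_to_acute,
    project_vector_to_plane,
    unit,
)
from .landmarks import LandmarkSet, validate_landmarks
from .reference_frames import (
    PerpendicularityReport,
    ReferenceFrame,
    build_frame,
    perpendicularity_report,
)

__all__ = [
    "OrientationAngles",
    "MurrayResiduals",
    "HipResult",
    "CaseReport",
    "orientation_angles",
    "anatomical_angles",
    "operative_angles",
    "radiographic_angles",
    "murray_residuals",
    "measure_all",
]


@dataclass(frozen=True)
class OrientationAngles:
    """The six orientation angles (degrees) for one hip.

    ``flags`` names angles whose defining projection was degenerate
    (axis within tolerance of a reference-plane normal); those angles
    are NaN, never silently zero.  ``ai_raw``/``oa_raw``/``ri_raw`` keep
    the unfolded oriented angles.
    """

    case_id: str
    side: str
    ai: float
    aa: float
    oi: float
    oa: float
    ri: float
    ra: float
    ai_raw: float
    oa_raw: float
    ri_raw: float
    flags: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {
            "AI": self.ai,
            "AA": self.aa,
            "OI": self.oi,
            "OA": self.oa,
            "RI": self.ri,
            "RA": self.ra,
        }

    @property
    def degenerate(self) -> bool:
        return bool(self.flags)


def _signed_by(value: float, reference: float) -> float:
    return value if reference >= 0 else -value


def orientation_angles(
    axis: Vec3,
    frame: ReferenceFrame,
    side: str,
    case_id: str = "",
    fold: bool = True,
) -> OrientationAngles:
    """Compute all six angles for an oriented acetabular axis.

    ``axis`` must already be oriented out of the socket (lateral for
    ``side``); see :func:`acetorient.acetabular_axis.orient_axis`.
    """
    axis = unit(axis)
    longitudinal = frame.longitudinal_axis
    anterior = frame.anterior_axis
    lateral = frame.lateral_axis(side)
    flags: set[str] = set()

    # anatomical inclination: axis vs. longitudinal (cranio-caudal) axis
    ai_raw = angle_between_vectors(axis, longitudinal)
    ai = fold_to_acute(ai_raw) if fold else ai_raw

    # anatomical anteversion: axis projected into the transverse plane,
    # measured from the transverse axis, signed anterior
    try:
        proj_t = project_vector_to_plane(axis, frame.transverse)
        aa = _signed_by(
            angle_between_vectors(proj_t, lateral), float(np.dot(proj_t, anterior))
        )
    except DegenerateGeometryError:
        flags.add("AA")
        aa = float("nan")

    # operative inclination: line-plane angle between axis and the
    # sagittal plane, signed positive toward this hip's lateral side
    sagittal_out = frame.sagittal.normal if side == "right" else -frame.sagittal.normal
    oi = 90.0 - angle_between_vectors(axis, sagittal_out)

    # operative anteversion: axis projected into the sagittal plane,
    # measured from the longitudinal axis, folded, signed anterior
    try:
        proj_s = project_vector_to_plane(axis, frame.sagittal)
        oa_raw = angle_between_vectors(proj_s, longitudinal)
        oa_mag = fold_to_acute(oa_raw) if fold else oa_raw
        oa = _signed_by(oa_mag, float(np.dot(proj_s, anterior)))
    except DegenerateGeometryError:
        flags.add("OA")
        oa_raw = float("nan")
        oa = float("nan")

    # radiographic inclination: axis projected into the coronal plane,
    # measured from the longitudinal axis, folded (unsigned)
    try:
        proj_c = project_vector_to_plane(axis, frame.coronal)
        ri_raw = angle_between_vectors(proj_c, longitudinal)
        ri = fold_to_acute(ri_raw) if fold else ri_raw
    except DegenerateGeometryError:
        flags.add("RI")
        ri_raw = float("nan")
        ri = float("nan")

    # radiographic anteversion: line-plane angle between axis and the
    # coronal plane, signed positive anterior
    ra = 90.0 - angle_between_vectors(axis, anterior)

    return OrientationAngles(
        case_id=case_id,
        side=side,
        ai=ai,
        aa=aa,
        oi=oi,
        oa=oa,
        ri=ri,
        ra=ra,
        ai_raw=ai_raw,
        oa_raw=oa_raw,
        ri_raw=ri_raw,
        flags=frozenset(flags),
    )


def anatomical_angles(
    axis: Vec3, frame: ReferenceFrame, side: str = "right", fold: bool = True
) -> tuple[float, float]:
    """(AI, AA): inclination vs. the longitudinal axis, anteversion in the transverse plane."""
    a = orientation_angles(axis, frame, side, fold=fold)
    return a.ai, a.aa


def operative_angles(
    axis: Vec3, frame: ReferenceFrame, side: str = "right", fold: bool = True
) -> tuple[float, float]:
    """(OI, OA): inclination vs. the sagittal plane, anteversion in the sagittal plane."""
    a = orientation_angles(axis, frame, side, fold=fold)
    return a.oi, a.oa


def radiographic_angles(
    axis: Vec3, frame: ReferenceFrame, side: str = "right", fold: bool = True
) -> tuple[float, float]:
    """(RI, RA): inclination in the coronal projection, anteversion vs. the coronal plane."""
    a = orientation_angles(axis, frame, side, fold=fold)
    return a.ri, a.ra


# ---------------------------------------------------------------------------
# Conversion residuals


@dataclass(frozen=True)
class MurrayResiduals:
    """Residuals of published conversion formulas between the three systems.

    ``r1``–``r3`` evaluate the conversions exactly as commonly printed::

        r1 = OA − tan⁻¹(sin RI · cos RA)
        r2 = AA − tan⁻¹(cos OI · cos OA)
        r3 = RA − sin⁻¹(tan OI · cos OA)

    These do *not* vanish on geometrically exact angle sets — the printed
    expressions are not self-consistent identities — which is the point
    of computing them.  ``r3`` is flagged undefined when the arcsine
    argument leaves [−1, 1].  With ``textbook=True`` in
    :func:`murray_residuals`, ``r1_identity``–``r3_identity`` also report
    residuals against the self-consistent geometric identities
    OA = tan⁻¹(tan RA / cos RI), AA = tan⁻¹(tan RA / sin RI),
    RA = tan⁻¹(tan OA · cos RI), which are zero for exact sets.
    """

    r1: float
    r2: float
    r3: float
    r3_defined: bool = True
    r1_identity: float | None = None
    r2_identity: float | None = None
    r3_identity: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {"r1": self.r1, "r2": self.r2, "r3": self.r3}


def _sind(x: float) -> float:
    return math.sin(math.radians(x))


def _cosd(x: float) -> float:
    return math.cos(math.radians(x))


def _tand(x: float) -> float:
    return math.tan(math.radians(x))


def murray_residuals(angles: OrientationAngles, textbook: bool = False) -> MurrayResiduals:
    """Evaluate the conversion-formula residuals for one hip's angles.

    Raises
    ------
    ValueError
        If any required angle is degenerate (NaN).
    """
    needed = (angles.oa, angles.ri, angles.ra, angles.aa, angles.oi)
    if any(map(math.isnan, needed)):
        raise ValueError(
            f"cannot evaluate conversion residuals with degenerate angles {sorted(angles.flags)}"
        )
    oi, oa, ri, ra, aa = angles.oi, angles.oa, angles.ri, angles.ra, angles.aa
    r1 = oa - math.degrees(math.atan(_sind(ri) * _cosd(ra)))
    r2 = aa - math.degrees(math.atan(_cosd(oi) * _cosd(oa)))
    arg = _tand(oi) * _cosd(oa)
    if abs(arg) <= 1.0:
        r3 = ra - math.degrees(math.asin(arg))
        r3_defined = True
    else:
        r3 = float("nan")
        r3_defined = False
    out = MurrayResiduals(r1=r1, r2=r2, r3=r3, r3_defined=r3_defined)
    if textbook:
        out = MurrayResiduals(
            r1=r1,
            r2=r2,
            r3=r3,
            r3_defined=r3_defined,
            r1_identity=oa - math.degrees(math.atan(_tand(ra) / _cosd(ri))),
            r2_identity=aa - math.degrees(math.atan(_tand(ra) / _sind(ri)))
            if abs(_sind(ri)) > 1e-12
            else float("nan"),
            r3_identity=ra - math.degrees(math.atan(_tand(oa) * _cosd(ri))),
        )
    return out


# ---------------------------------------------------------------------------
# Whole-case pipeline


@dataclass
class HipResult:
    """One hip's full measurement: fit, angles, conversion residuals."""

    fit: AcetabulumFit
    angles: OrientationAngles
    residuals: MurrayResiduals | None


@dataclass
class CaseReport:
    """Per-case output of :func:`measure_all`.

    ``failures`` lists (side, message) for hips whose geometry was
    degenerate; one bad hip does not abort the case.
    """

    case_id: str
    frame: ReferenceFrame
    frame_audit: PerpendicularityReport
    hips: list[HipResult]
    failures: list[tuple[str, str]]

    def rows(self) -> list[dict]:
        """Flatten to one report row per measured hip (CSV/JSON-ready)."""
        out = []
        for hip in self.hips:
            row: dict = {"case_id": self.case_id, "side": hip.angles.side}
            row.update(hip.angles.as_dict())
            res = hip.residuals
            row.update(
                res.as_dict()
                if res is not None
                else {"r1": float("nan"), "r2": float("nan"), "r3": float("nan")}
            )
            row["fit_rms_mm"] = hip.fit.rms_residual
            row["n_rim_points"] = hip.fit.n_points
            row["arc_coverage_deg"] = hip.fit.arc_coverage_deg
            row.update(self.frame_audit.as_dict())
            row["flags"] = ";".join(sorted(hip.angles.flags))
            out.append(row)
        return out


def measure_all(
    lset: LandmarkSet,
    transverse_mode: str = "orthogonal",
    fold: bool = True,
    strict: bool = False,
) -> CaseReport:
    """Full pipeline for one case: frame, per-hip axis, six angles, residuals.

    Composition: validate → build reference frame → fit each labelled
    hip's rim plane → orient its axis → compute the six angles and the
    conversion residuals.  Per-hip degeneracies are recorded in
    ``failures`` rather than aborting the case.
    """
    validate_landmarks(lset, strict=strict)
    frame = build_frame(lset, transverse_mode=transverse_mode)
    audit = perpendicularity_report(frame)
    hips: list[HipResult] = []
    failures: list[tuple[str, str]] = []
    for side in lset.sides():
        try:
            fit = fit_hip(lset.hips[side], frame, side)
            angles = orientation_angles(
                fit.axis, frame, side, case_id=lset.case_id, fold=fold
            )
            try:
                residuals = murray_residuals(angles)
            except ValueError:
                residuals = None
            hips.append(HipResult(fit=fit, angles=angles, residuals=residuals))
        except DegenerateGeometryError as exc:
            failures.append((side, str(exc)))
    return CaseReport(
        case_id=lset.case_id,
        frame=frame,
        frame_audit=audit,
        hips=hips,
        failures=failures,
    )
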