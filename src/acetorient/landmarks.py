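"""Landmark data model, file I/O, protocol validation and rater agreement.

A case is described by the bony landmarks picked on a reconstructed
pelvis: the two anterior superior iliac spines (ASIS), the two pubic
tubercles, at least three points along the sacral crest, and — per hip —
at least thirty points around the acetabular rim (the arc over the
transverse acetabular ligament is simply left unlabelled).  Coordinates
are millimetres in one arbitrary, shared scanner frame per case; every
downstream angle is invariant to that frame.

Two serialization dialects are supported:

* JSON — roles as keys, human-editable::

      {"case_id": "...", "landmarks": {"asis_left": [x,y,z], ...,
       "sacral_crest": [[x,y,z], ...]},
       "hips": {"left": [[x,y,z], ...], "right": [...]},
       "age": 34, "sex": "F"}

* CSV — long format, pipeline-friendly, columns
  ``case_id,role,side,index,x_mm,y_mm,z_mm`` with roles
  ``asis``/``pubic`` (side left/right), ``sacral_crest`` and ``rim``.
  Age and sex are JSON-only metadata.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .core_geometry import Point3

__all__ = [
    "LandmarkSet",
    "LandmarkFormatError",
    "ValidationReport",
    "RaterAgreementReport",
    "read_landmarks",
    "write_landmarks",
    "validate_landmarks",
    "rater_agreement",
]

MIN_RIM_POINTS = 30
MIN_SACRAL_POINTS = 3
MIN_ASIS_SEPARATION_MM = 1.0

_PELVIC_ROLES = ("asis_left", "asis_right", "pubic_left", "pubic_right")


class LandmarkFormatError(ValueError):
    """A landmark file is missing roles, malformed, or duplicates a role."""


class LandmarkValidationError(ValueError):
    """Strict validation failed; message lists the violated protocol rules."""


def _point(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,) or not np.all(np.isfinite(arr)):
        raise LandmarkFormatError(f"{name}: expected three finite coordinates, got {value!r}")
    return arr


def _points(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or not np.all(np.isfinite(arr)):
        raise LandmarkFormatError(f"{name}: expected an (n, 3) array of finite coordinates")
    return arr


@dataclass
class LandmarkSet:
    """All labelled bony points for one case, in millimetres, one shared frame.

    ``hips`` maps side (``"left"``/``"right"``) to an ``(n, 3)`` array of
    acetabular-rim points; a side may be absent.  ``sacral_crest`` is an
    ``(n, 3)`` array of midline sacral points.
    """

    case_id: str
    asis_left: Point3
    asis_right: Point3
    pubic_left: Point3
    pubic_right: Point3
    sacral_crest: np.ndarray
    hips: dict[str, np.ndarray] = field(default_factory=dict)
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        for role in _PELVIC_ROLES:
            setattr(self, role, _point(getattr(self, role), role))
        self.sacral_crest = _points(self.sacral_crest, "sacral_crest")
        clean: dict[str, np.ndarray] = {}
        for side, pts in self.hips.items():
            if side not in ("left", "right"):
                raise LandmarkFormatError(f"unknown hip side {side!r}")
            clean[side] = _points(pts, f"hips[{side}]")
        self.hips = clean

    @property
    def asis_midpoint(self) -> Point3:
        return (self.asis_left + self.asis_right) / 2.0

    @property
    def pubic_midpoint(self) -> Point3:
        return (self.pubic_left + self.pubic_right) / 2.0

    def sides(self) -> tuple[str, ...]:
        return tuple(s for s in ("left", "right") if s in self.hips)

    def transformed(self, rotation: np.ndarray, translation) -> "LandmarkSet":
        """Apply the rigid map ``p ↦ R p + t`` to every coordinate."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return replace(
            self,
            asis_left=R @ self.asis_left + t,
            asis_right=R @ self.asis_right + t,
            pubic_left=R @ self.pubic_left + t,
            pubic_right=R @ self.pubic_right + t,
            sacral_crest=self.sacral_crest @ R.T + t,
            hips={s: pts @ R.T + t for s, pts in self.hips.items()},
        )

    def allclose(self, other: "LandmarkSet", atol: float = 1e-9) -> bool:
        """Geometric equality of all landmarks within ``atol`` millimetres."""
        if self.sides() != other.sides():
            return False
        if self.sacral_crest.shape != other.sacral_crest.shape:
            return False
        same = all(
            np.allclose(getattr(self, r), getattr(other, r), atol=atol)
            for r in _PELVIC_ROLES
        )
        same = same and np.allclose(self.sacral_crest, other.sacral_crest, atol=atol)
        for side in self.sides():
            if self.hips[side].shape != other.hips[side].shape:
                return False
            same = same and np.allclose(self.hips[side], other.hips[side], atol=atol)
        return bool(same)


# ---------------------------------------------------------------------------
# I/O


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise LandmarkFormatError(f"cannot infer landmark format from {path.name!r}")


def read_landmarks(path, format: str | None = None) -> LandmarkSet:
    """Read one case's landmarks from a JSON or CSV file (see module docs).

    Raises :class:`LandmarkFormatError` naming the offending record when a
    required role is missing, duplicated, or malformed.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        return _read_json(path)
    if fmt == "csv":
        return _read_csv(path)
    raise LandmarkFormatError(f"unsupported landmark format {fmt!r}")


def _read_json(path: Path) -> LandmarkSet:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise LandmarkFormatError(f"{path.name}: invalid JSON ({exc})") from exc
    lm = doc.get("landmarks", {})
    missing = [r for r in (*_PELVIC_ROLES, "sacral_crest") if r not in lm]
    if missing:
        raise LandmarkFormatError(f"{path.name}: missing landmark role(s) {missing}")
    return LandmarkSet(
        case_id=str(doc.get("case_id", path.stem)),
        asis_left=_point(lm["asis_left"], "asis_left"),
        asis_right=_point(lm["asis_right"], "asis_right"),
        pubic_left=_point(lm["pubic_left"], "pubic_left"),
        pubic_right=_point(lm["pubic_right"], "pubic_right"),
        sacral_crest=_points(lm["sacral_crest"], "sacral_crest"),
        hips={s: _points(p, f"hips[{s}]") for s, p in doc.get("hips", {}).items()},
        age=doc.get("age"),
        sex=doc.get("sex"),
    )


def _read_csv(path: Path) -> LandmarkSet:
    singles: dict[str, np.ndarray] = {}
    sacral: list[tuple[int, np.ndarray]] = []
    rims: dict[str, list[tuple[int, np.ndarray]]] = {}
    case_id: str | None = None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        needed = {"case_id", "role", "side", "index", "x_mm", "y_mm", "z_mm"}
        if reader.fieldnames is None or not needed.issubset(reader.fieldnames):
            raise LandmarkFormatError(
                f"{path.name}: CSV must have columns {sorted(needed)}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                xyz = np.array(
                    [float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])]
                )
            except (TypeError, ValueError) as exc:
                raise LandmarkFormatError(
                    f"{path.name} line {i}: malformed coordinates"
                ) from exc
            if case_id is None:
                case_id = row["case_id"]
            role, side = row["role"], (row["side"] or "")
            idx = int(row["index"] or 0)
            if role in ("asis", "pubic"):
                key = f"{role}_{side}"
                if key not in dict.fromkeys(_PELVIC_ROLES):
                    raise LandmarkFormatError(f"{path.name} line {i}: bad role/side {role}/{side}")
                if key in singles:
                    raise LandmarkFormatError(f"{path.name} line {i}: duplicate role {key}")
                singles[key] = xyz
            elif role == "sacral_crest":
                sacral.append((idx, xyz))
            elif role == "rim":
                if side not in ("left", "right"):
                    raise LandmarkFormatError(f"{path.name} line {i}: rim needs a side")
                rims.setdefault(side, []).append((idx, xyz))
            else:
                raise LandmarkFormatError(f"{path.name} line {i}: unknown role {role!r}")
    missing = [r for r in _PELVIC_ROLES if r not in singles]
    if missing:
        raise LandmarkFormatError(f"{path.name}: missing landmark role(s) {missing}")
    if not sacral:
        raise LandmarkFormatError(f"{path.name}: missing landmark role(s) ['sacral_crest']")
    sacral.sort(key=lambda kv: kv[0])
    return LandmarkSet(
        case_id=case_id or path.stem,
        sacral_crest=np.array([p for _, p in sacral]),
        hips={
            s: np.array([p for _, p in sorted(pts, key=lambda kv: kv[0])])
            for s, pts in rims.items()
        },
        **singles,
    )


def write_landmarks(lset: LandmarkSet, path, format: str | None = None) -> None:
    """Write a landmark set so that :func:`read_landmarks` round-trips it.

    JSON keeps age/sex metadata; the CSV dialect stores coordinates only.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = {
            "case_id": lset.case_id,
            "landmarks": {
                **{r: list(map(float, getattr(lset, r))) for r in _PELVIC_ROLES},
                "sacral_crest": lset.sacral_crest.tolist(),
            },
            "hips": {s: lset.hips[s].tolist() for s in lset.sides()},
        }
        if lset.age is not None:
            doc["age"] = lset.age
        if lset.sex is not None:
            doc["sex"] = lset.sex
        path.write_text(json.dumps(doc, indent=1))
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["case_id", "role", "side", "index", "x_mm", "y_mm", "z_mm"])
            for role in _PELVIC_ROLES:
                base, side = role.rsplit("_", 1)
                writer.writerow([lset.case_id, base, side, 0, *map(repr, map(float, getattr(lset, role)))])
            for i, p in enumerate(lset.sacral_crest):
                writer.writerow([lset.case_id, "sacral_crest", "", i, *map(repr, map(float, p))])
            for side in lset.sides():
                for i, p in enumerate(lset.hips[side]):
                    writer.writerow([lset.case_id, "rim", side, i, *map(repr, map(float, p))])
    else:
        raise LandmarkFormatError(f"unsupported landmark format {fmt!r}")


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    """Outcome of checking one case against the labelling protocol."""

    case_id: str
    violations: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _rim_spacing_cv(rim: np.ndarray) -> float:
    """Coefficient of variation of nearest-neighbour spacing along the rim.

    Rim points should be roughly evenly spaced; gross non-uniformity
    (e.g. many near-duplicates) inflates this well above ~1.
    """
    if len(rim) < 3:
        return 0.0
    d = np.linalg.norm(rim[:, None, :] - rim[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nearest = d.min(axis=1)
    mean = nearest.mean()
    if mean <= 0:
        return np.inf
    return float(nearest.std() / mean)


#: Spacing coefficient-of-variation above which a rim is flagged as
#: grossly non-uniform.  An evenly spaced circle has CV 0 and stays
#: below ~0.5 even under 2 mm labelling jitter; clusters of
#: near-duplicate points push it well past 0.6.
RIM_SPACING_CV_WARN = 0.6


def validate_landmarks(
    lset: LandmarkSet,
    strict: bool = False,
    min_rim: int = MIN_RIM_POINTS,
    min_sacral: int = MIN_SACRAL_POINTS,
) -> ValidationReport:
    """Check the labelling protocol: point counts, separations, rim spacing.

    Rules: ≥``min_rim`` rim points per labelled hip, ≥``min_sacral``
    sacral-crest points, ASIS separation > 1 mm, pubic tubercles not
    coincident, and a warning when rim spacing is grossly non-uniform.
    In strict mode violations raise :class:`LandmarkValidationError`.
    """
    report = ValidationReport(case_id=lset.case_id)
    if np.linalg.norm(lset.asis_left - lset.asis_right) <= MIN_ASIS_SEPARATION_MM:
        report.violations.append(
            ("asis_separation", "left and right ASIS are (near-)coincident")
        )
    if np.linalg.norm(lset.pubic_left - lset.pubic_right) <= 1e-6:
        report.violations.append(("pubic_separation", "pubic tubercles coincide"))
    if len(lset.sacral_crest) < min_sacral:
        report.violations.append(
            ("sacral_count", f"{len(lset.sacral_crest)} sacral points; need ≥{min_sacral}")
        )
    for side in lset.sides():
        rim = lset.hips[side]
        if len(rim) < min_rim:
            report.violations.append(
                ("rim_count", f"{side} rim has {len(rim)} points; need ≥{min_rim}")
            )
        cv = _rim_spacing_cv(rim)
        if cv > RIM_SPACING_CV_WARN:
            report.warnings.append(
                ("rim_spacing", f"{side} rim spacing grossly non-uniform (CV={cv:.2f})")
            )
    if strict and report.violations:
        raise LandmarkValidationError(
            "; ".join(f"{rule}: {msg}" for rule, msg in report.violations)
        )
    return report


# ---------------------------------------------------------------------------
# Two-rater agreement


@dataclass
class RaterAgreementReport:
    """Per-landmark distances (mm) between two raters' labels of one case.

    Named pelvic landmarks are compared role-by-role.  Rim points carry no
    stable identity between raters, so each hip's rim distance is the
    symmetric Hausdorff distance (worst nearest-neighbour mismatch in
    either direction).  ``passed`` is true iff every distance is below
    ``tolerance_mm``.
    """

    case_id: str
    distances_mm: dict[str, float]
    tolerance_mm: float

    @property
    def max_distance_mm(self) -> float:
        return max(self.distances_mm.values())

    @property
    def passed(self) -> bool:
        return self.max_distance_mm < self.tolerance_mm

    @property
    def failed_roles(self) -> list[str]:
        return [r for r, d in self.distances_mm.items() if d >= self.tolerance_mm]


def _hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def rater_agreement(
    a: LandmarkSet, b: LandmarkSet, tolerance_mm: float = 2.0
) -> RaterAgreementReport:
    """Compare two independent labellings of the same case.

    The labelling protocol accepts a case when every landmark diverges by
    less than ``tolerance_mm`` (default 2 mm) between raters.

    Raises
    ------
    ValueError
        If the two sets label different roles or hips.
    """
    if a.sides() != b.sides():
        raise ValueError(f"raters labelled different hips: {a.sides()} vs {b.sides()}")
    if len(a.sacral_crest) != len(b.sacral_crest):
        raise ValueError("raters labelled different numbers of sacral points")
    distances: dict[str, float] = {}
    for role in _PELVIC_ROLES:
        distances[role] = float(np.linalg.norm(getattr(a, role) - getattr(b, role)))
    distances["sacral_crest"] = _hausdorff(a.sacral_crest, b.sacral_crest)
    for side in a.sides():
        distances[f"rim_{side}"] = _hausdorff(a.hips[side], b.hips[side])
    return RaterAgreementReport(
        case_id=a.case_id, distances_mm=distances, tolerance_mm=tolerance_mm
    )
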