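"""Seeded synthetic pelvis landmark generator with known ground truth.

Generates the landmark sets a rater would export from a reconstructed
pelvis — ASIS pair, pubic tubercles, sacral-crest points, and per-hip
acetabular-rim circles — in a canonical body frame, then applies noise
and an arbitrary rigid pose.  Because the true acetabular axis and the
true reference planes are known by construction, every pipeline stage
can be tested for exact recovery, noise response, and rigid-motion
invariance without any imaging data.

Canonical frame (before the pose is applied): x = patient left → right,
y = posterior → anterior, z = caudal → cranial.  In this frame the
ideal coronal, sagittal and transverse planes are y = 0, x = 0, z = 0.

The rim is a circle of configurable radius whose plane normal realizes
the requested anatomical (inclination, anteversion) truth; an arc of
configurable width is left empty, mimicking the unlabelled
transverse-acetabular-ligament gap.  Out-of-plane rim noise and global
landmark jitter are independent isotropic Gaussians.  All randomness is
drawn from an explicit, seed-threaded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core_geometry import Plane
from .landmarks import LandmarkSet

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "axis_from_angles",
    "angles_from_axis_truth",
    "generate_pelvis",
    "generate_cohort",
    "perturb_rater",
]

#: Cohort-level sampling defaults: anatomical-system angle distributions
#: (mean, sd in degrees) and demographic mix matching a typical adult
#: pelvic-CT cohort (57% male; age bins <30, 30s, 40s, ≥50 with ages
#: spanning 18–56 years).
DEFAULT_ANGLE_DISTRIBUTIONS: Mapping[str, tuple[float, float]] = {
    "AI": (37.48, 11.07),
    "AA": (18.12, 7.59),
}
DEFAULT_DEMOGRAPHICS: Mapping[str, object] = {
    "male_fraction": 0.5714,
    "age_bin_probs": (0.3673, 0.1633, 0.3878, 0.0816),
    "age_bins": ((18, 30), (30, 40), (40, 50), (50, 57)),
}
#: Truncation bounds keeping sampled truths geometrically non-degenerate.
AI_BOUNDS = (10.0, 80.0)
AA_BOUNDS = (-20.0, 50.0)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic pelvis.

    ``true_ai``/``true_aa`` are the anatomical-system truth in degrees
    (defaults at the lower end of the accepted clinical target ranges,
    40° inclination / 15° anteversion); ``pose_rotation_deg`` is an
    x-y-z Euler rotation emulating pelvic tilt/rotation on the table.
    Dimensions are millimetres.
    """

    true_ai: float = 40.0
    true_aa: float = 15.0
    rim_radius: float = 25.0
    n_rim: int = 30
    rim_gap_degrees: float = 60.0
    rim_out_of_plane_sd: float = 0.0
    landmark_jitter_sd: float = 0.0
    pose_rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pose_translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    asis_width: float = 240.0
    pelvis_depth: float = 90.0
    sacrum_offsets: tuple[tuple[float, float, float], ...] = (
        (0.0, -90.0, -20.0),
        (0.0, -96.0, -55.0),
        (0.0, -102.0, -90.0),
    )
    hip_center: tuple[float, float, float] = (80.0, -10.0, -70.0)
    per_side_angles: dict[str, tuple[float, float]] | None = None
    seed: int = 0
    case_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_rim < 3:
            raise ValueError("n_rim must be ≥ 3")
        if min(self.rim_radius, self.rim_out_of_plane_sd, self.landmark_jitter_sd) < 0:
            raise ValueError("radius and noise SDs must be ≥ 0")
        if not 0 <= self.rim_gap_degrees < 360:
            raise ValueError("rim_gap_degrees must be in [0, 360)")
        for side, (ai, aa) in (self.per_side_angles or {"both": (self.true_ai, self.true_aa)}).items():
            if not 0 < ai < 90 or not -90 < aa < 90:
                raise ValueError(
                    f"true angles out of range for {side}: AI={ai}, AA={aa}"
                )

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SyntheticSpec":
        return cls(**dict(doc))


@dataclass
class GroundTruth:
    """Noise-free truth for one generated pelvis, in posed coordinates.

    ``angles[side]`` holds the six true angles implied by the per-side
    (AI, AA) under exact reference frames; ``axes[side]`` the true unit
    acetabular axis; ``planes`` the true reference planes.
    """

    case_id: str
    true_ai: float
    true_aa: float
    angles: dict[str, dict[str, float]]
    axes: dict[str, np.ndarray]
    planes: dict[str, Plane]
    rotation: np.ndarray
    translation: np.ndarray


def axis_from_angles(ai_deg: float, aa_deg: float, side: str) -> np.ndarray:
    """Unit acetabular axis realizing an anatomical (AI, AA) truth.

    In canonical (left→right, post→ant, caudal→cranial) coordinates the
    axis components are (lateral, anterior, cranial) =
    (cos AA sin AI, sin AA sin AI, −cos AI), with lateral = +x on the
    right and −x on the left.
    """
    ai = math.radians(ai_deg)
    aa = math.radians(aa_deg)
    lateral = math.cos(aa) * math.sin(ai)
    anterior = math.sin(aa) * math.sin(ai)
    cranial = -math.cos(ai)
    sign = 1.0 if side == "right" else -1.0
    return np.array([sign * lateral, anterior, cranial])


def angles_from_axis_truth(ai_deg: float, aa_deg: float) -> dict[str, float]:
    """The six true angles implied by an anatomical (AI, AA) pair.

    Closed forms under exact frames, with the default folded/signed
    reporting conventions: sin OI = cos AA sin AI, tan OA = tan AA /
    cos AI · ... — expressed directly from the axis components.
    """
    ai = math.radians(ai_deg)
    aa = math.radians(aa_deg)
    lateral = math.cos(aa) * math.sin(ai)
    anterior = math.sin(aa) * math.sin(ai)
    caudal = math.cos(ai)  # −cranial; positive for AI < 90°
    return {
        "AI": ai_deg,
        "AA": aa_deg,
        "OI": math.degrees(math.asin(lateral)),
        "OA": math.degrees(math.atan2(anterior, caudal)),
        "RI": math.degrees(math.atan2(lateral, caudal)),
        "RA": math.degrees(math.asin(anterior)),
    }


def _pose(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    R = Rotation.from_euler("xyz", spec.pose_rotation_deg, degrees=True).as_matrix()
    t = np.asarray(spec.pose_translation_mm, dtype=float)
    return R, t


def _rim_points(center: np.ndarray, axis: np.ndarray, spec: SyntheticSpec, rng) -> np.ndarray:
    seed = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(seed, axis))) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - float(np.dot(seed, axis)) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    gap = math.radians(spec.rim_gap_degrees)
    if gap == 0.0:
        theta = np.arange(spec.n_rim) * 2 * np.pi / spec.n_rim
    else:
        theta = gap / 2 + np.arange(spec.n_rim) * (2 * np.pi - gap) / (spec.n_rim - 1)
    pts = (
        center
        + spec.rim_radius * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
    )
    if spec.rim_out_of_plane_sd > 0:
        pts = pts + rng.normal(0, spec.rim_out_of_plane_sd, size=len(pts))[:, None] * axis
    return pts


def generate_pelvis(spec: SyntheticSpec) -> tuple[LandmarkSet, GroundTruth]:
    """Generate one pelvis's landmark set and its ground truth.

    Deterministic for a given spec (seed included): noise draws come
    from ``default_rng(spec.seed)`` and the rigid pose is applied after
    all noise, so the ground truth records pre-jitter geometry in posed
    coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.asis_width
    asis_left = np.array([-w / 2, 0.0, 0.0])
    asis_right = np.array([w / 2, 0.0, 0.0])
    pubic_left = np.array([-0.15 * w, 0.0, -spec.pelvis_depth])
    pubic_right = np.array([0.15 * w, 0.0, -spec.pelvis_depth])
    sacral = np.asarray(spec.sacrum_offsets, dtype=float)

    side_angles = spec.per_side_angles or {
        "left": (spec.true_ai, spec.true_aa),
        "right": (spec.true_ai, spec.true_aa),
    }
    hips: dict[str, np.ndarray] = {}
    axes: dict[str, np.ndarray] = {}
    truth_angles: dict[str, dict[str, float]] = {}
    cx, cy, cz = spec.hip_center
    for side, (ai, aa) in side_angles.items():
        center = np.array([cx if side == "right" else -cx, cy, cz])
        axis = axis_from_angles(ai, aa, side)
        hips[side] = _rim_points(center, axis, spec, rng)
        axes[side] = axis
        truth_angles[side] = angles_from_axis_truth(ai, aa)

    lset = LandmarkSet(
        case_id=spec.case_id,
        asis_left=asis_left,
        asis_right=asis_right,
        pubic_left=pubic_left,
        pubic_right=pubic_right,
        sacral_crest=sacral,
        hips=hips,
    )
    if spec.landmark_jitter_sd > 0:
        lset = perturb_rater(lset, spec.landmark_jitter_sd, seed=rng.integers(2**31))

    R, t = _pose(spec)
    lset = lset.transformed(R, t)
    origin = t  # canonical origin (ASIS midpoint) maps to t
    truth = GroundTruth(
        case_id=spec.case_id,
        true_ai=spec.true_ai,
        true_aa=spec.true_aa,
        angles=truth_angles,
        axes={s: R @ a for s, a in axes.items()},
        planes={
            "coronal": Plane.from_normal_point(R @ np.array([0.0, 1.0, 0.0]), origin),
            "sagittal": Plane.from_normal_point(R @ np.array([1.0, 0.0, 0.0]), origin),
            "transverse": Plane.from_normal_point(R @ np.array([0.0, 0.0, 1.0]), origin),
        },
        rotation=R,
        translation=t,
    )
    return lset, truth


def perturb_rater(lset: LandmarkSet, sd_mm: float, seed: int = 0) -> LandmarkSet:
    """Simulate an independent rater: isotropic jitter on every landmark.

    ``sd_mm = 0`` returns an identical copy.  Used to drive the 2-mm
    two-rater agreement check.
    """
    if sd_mm < 0:
        raise ValueError("sd_mm must be ≥ 0")
    rng = np.random.default_rng(seed)

    def jit(p: np.ndarray) -> np.ndarray:
        return p + rng.normal(0, sd_mm, size=p.shape) if sd_mm > 0 else p.copy()

    return LandmarkSet(
        case_id=lset.case_id,
        asis_left=jit(lset.asis_left),
        asis_right=jit(lset.asis_right),
        pubic_left=jit(lset.pubic_left),
        pubic_right=jit(lset.pubic_right),
        sacral_crest=jit(lset.sacral_crest),
        hips={s: jit(p) for s, p in lset.hips.items()},
        age=lset.age,
        sex=lset.sex,
    )


def _truncated_normal(rng, mean: float, sd: float, bounds: tuple[float, float]) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if bounds[0] <= x <= bounds[1]:
            return float(x)
    return float(np.clip(mean, *bounds))


def generate_cohort(
    n_cases: int = 49,
    angle_distributions: Mapping[str, tuple[float, float]] = DEFAULT_ANGLE_DISTRIBUTIONS,
    demographics: Mapping[str, object] = DEFAULT_DEMOGRAPHICS,
    seed: int = 0,
    **spec_overrides,
) -> list[tuple[LandmarkSet, GroundTruth]]:
    """Generate a cohort of cases, two hips each, with demographics.

    Per case, per side, the true anatomical (AI, AA) are drawn from the
    configured normal distributions (truncated to geometric validity);
    age and sex follow the configured mix.  ``spec_overrides`` pass
    through to each case's :class:`SyntheticSpec` (noise levels, pose,
    rim protocol).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be ≥ 1")
    rng = np.random.default_rng(seed)
    ai_mean, ai_sd = angle_distributions["AI"]
    aa_mean, aa_sd = angle_distributions["AA"]
    male_fraction = float(demographics["male_fraction"])
    bin_probs = np.asarray(demographics["age_bin_probs"], dtype=float)
    bin_probs = bin_probs / bin_probs.sum()
    age_bins = demographics["age_bins"]
    out = []
    for i in range(n_cases):
        per_side = {
            side: (
                _truncated_normal(rng, ai_mean, ai_sd, AI_BOUNDS),
                _truncated_normal(rng, aa_mean, aa_sd, AA_BOUNDS),
            )
            for side in ("left", "right")
        }
        spec = SyntheticSpec(
            case_id=f"case{i:03d}",
            per_side_angles=per_side,
            seed=int(rng.integers(2**31)),
            **spec_overrides,
        )
        lset, truth = generate_pelvis(spec)
        k = int(rng.choice(len(age_bins), p=bin_probs))
        lo, hi = age_bins[k]
        lset.age = float(rng.uniform(lo, hi))
        lset.sex = "M" if rng.random() < male_fraction else "F"
        out.append((lset, truth))
    return out
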