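import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from acetorient import (
    Plane,
    SyntheticSpec,
    angle_between_planes,
    build_app,
    build_frame,
    build_sagittal,
    build_transverse,
    fit_plane_least_squares,
    generate_pelvis,
    perpendicularity_report,
)
from acetorient.core_geometry import DegenerateGeometryError


def brute_force_plane_rms(points: np.ndarray, n_grid: int = 4000) -> float:
    """Independent oracle: minimize RMS orthogonal distance by scanning
    normal directions on a Fibonacci hemisphere and polishing the best
    with a local optimizer.  Shares no code with the SVD fit."""

    def rms_for(normal: np.ndarray) -> float:
        normal = normal / np.linalg.norm(normal)
        d = points @ normal
        d = d - d.mean()  # optimal offset for fixed normal
        return float(np.sqrt(np.mean(d**2)))

    i = np.arange(n_grid)
    phi = np.arccos(1 - (i + 0.5) / n_grid)  # hemisphere
    theta = np.pi * (1 + 5**0.5) * i
    dirs = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    best = dirs[int(np.argmin([rms_for(d) for d in dirs]))]
    res = minimize(
        lambda ang: rms_for(
            np.array(
                [
                    np.sin(ang[0]) * np.cos(ang[1]),
                    np.sin(ang[0]) * np.sin(ang[1]),
                    np.cos(ang[0]),
                ]
            )
        ),
        x0=[np.arccos(np.clip(best[2], -1, 1)), np.arctan2(best[1], best[0])],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12},
    )
    return float(res.fun)


class TestPlaneFit:
    def test_exact_coplanar_square(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        plane, rms = fit_plane_least_squares(pts)
        assert abs(abs(plane.normal[2]) - 1.0) < 1e-12
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_three_exact_points(self):
        pts = np.array([[0, 0, 1], [5, 0, 1], [0, 5, 1]], float)
        plane, rms = fit_plane_least_squares(pts)
        assert rms == pytest.approx(0.0, abs=1e-12)
        for p in pts:
            assert abs(plane.signed_distance(p)) < 1e-9

    def test_alternating_offsets_keep_normal_and_set_rms(self):
        # points on z=0 shifted alternately by ±h: by symmetry the best
        # plane stays z=0 and the rms equals h
        h = 0.5
        theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = np.stack(
            [10 * np.cos(theta), 10 * np.sin(theta), h * (-1.0) ** np.arange(8)], axis=1
        )
        plane, rms = fit_plane_least_squares(pts)
        assert abs(abs(plane.normal[2]) - 1.0) < 1e-9
        assert rms == pytest.approx(h, abs=1e-9)
        assert rms == pytest.approx(brute_force_plane_rms(pts), abs=1e-6)

    def test_plane_passes_through_centroid(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 3)) * 20
        plane, _ = fit_plane_least_squares(pts)
        assert abs(plane.signed_distance(pts.mean(axis=0))) < 1e-9

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5, dtype=float), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            fit_plane_least_squares(pts)

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            pts = rng.normal(size=(10, 3)) * np.array([20, 20, 2])
            _, rms = fit_plane_least_squares(pts)
            assert rms == pytest.approx(brute_force_plane_rms(pts), abs=1e-3)


class TestAppAndSagittal:
    def test_app_exact_for_coplanar_landmarks(self):
        lset, _ = generate_pelvis(SyntheticSpec(seed=1))
        plane = build_app(lset)
        for p in (lset.asis_left, lset.asis_right, lset.pubic_left, lset.pubic_right):
            assert abs(plane.signed_distance(p)) < 1e-9

    def test_app_normal_recovers_anterior_truth(self):
        lset, truth = generate_pelvis(
            SyntheticSpec(seed=1, pose_rotation_deg=(12, -7, 30))
        )
        assert build_app(lset).normal == pytest.approx(
            truth.planes["coronal"].normal, abs=1e-6
        )

    def test_app_coincident_asis_rejected(self):
        lset, _ = generate_pelvis(SyntheticSpec(seed=1))
        lset.asis_right = lset.asis_left.copy()
        lset.pubic_right = lset.pubic_left.copy()
        with pytest.raises(DegenerateGeometryError):
            build_app(lset)

    def test_sagittal_axis_aligned_case(self):
        lset, _ = generate_pelvis(SyntheticSpec(seed=1))
        plane = build_sagittal(lset)
        assert plane.normal == pytest.approx(np.array([1.0, 0, 0]), abs=1e-9)
        assert plane.signed_distance(lset.asis_right) > 0  # oriented to the right

    def test_sagittal_recovers_truth_under_pose(self):
        lset, truth = generate_pelvis(SyntheticSpec(seed=2, pose_rotation_deg=(5, 20, -40)))
        assert build_sagittal(lset).normal == pytest.approx(
            truth.planes["sagittal"].normal, abs=1e-6
        )

    def test_two_sacral_points_rejected(self):
        lset, _ = generate_pelvis(SyntheticSpec(seed=1))
        lset.sacral_crest = lset.sacral_crest[:2]
        with pytest.raises(DegenerateGeometryError):
            build_sagittal(lset)


class TestTransverse:
    def test_axis_aligned_construction(self):
        coronal = Plane(0.0, 1.0, 0.0, 0.0)
        sagittal = Plane(1.0, 0.0, 0.0, 0.0)
        t = build_transverse(coronal, sagittal, origin=np.zeros(3))
        assert abs(abs(t.normal[2]) - 1.0) < 1e-12

    def test_sagittal_always_exactly_perpendicular(self):
        lset, _ = generate_pelvis(
            SyntheticSpec(seed=5, landmark_jitter_sd=1.5, pose_rotation_deg=(8, 3, -12))
        )
        frame = build_frame(lset)
        assert angle_between_planes(frame.transverse, frame.sagittal) == pytest.approx(
            90.0, abs=1e-12
        )

    def test_literal_mode_degenerate_when_asis_parallel_to_sagittal_normal(self):
        coronal = Plane(0.0, 1.0, 0.0, 0.0)
        sagittal = Plane(1.0, 0.0, 0.0, 0.0)
        with pytest.raises(DegenerateGeometryError):
            build_transverse(
                coronal, sagittal, asis_vector=np.array([1.0, 0, 0]),
                origin=np.zeros(3), mode="literal",
            )


class TestFrame:
    def test_canonical_pose_axes(self, clean_pelvis):
        lset, _ = clean_pelvis
        frame = build_frame(lset)
        assert frame.longitudinal_axis == pytest.approx(np.array([0.0, 0, 1]), abs=1e-9)
        assert frame.transverse_axis == pytest.approx(np.array([1.0, 0, 0]), abs=1e-9)
        assert frame.origin == pytest.approx(np.zeros(3), abs=1e-9)

    def test_axes_mutually_orthogonal(self, clean_pelvis):
        lset, _ = clean_pelvis
        frame = build_frame(lset)
        for u, v in [
            (frame.longitudinal_axis, frame.transverse_axis),
            (frame.longitudinal_axis, frame.anterior_axis),
            (frame.transverse_axis, frame.anterior_axis),
        ]:
            assert abs(np.dot(u, v)) < 1e-6

    def test_equivariance_under_rigid_transform(self, clean_pelvis):
        lset, _ = clean_pelvis
        rng = np.random.default_rng(17)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3) * 100
        base = build_frame(lset)
        moved = build_frame(lset.transformed(R, t))
        assert moved.longitudinal_axis == pytest.approx(R @ base.longitudinal_axis, abs=1e-9)
        assert moved.transverse_axis == pytest.approx(R @ base.transverse_axis, abs=1e-9)
        assert moved.coronal.normal == pytest.approx(R @ base.coronal.normal, abs=1e-9)
        assert moved.origin == pytest.approx(R @ base.origin + t, abs=1e-9)


class TestPerpendicularityReport:
    def test_noise_free_all_90(self, clean_pelvis):
        lset, _ = clean_pelvis
        report = perpendicularity_report(build_frame(lset))
        for angle in report.as_dict().values():
            assert angle == pytest.approx(90.0, abs=1e-9)

    def test_sagittal_transverse_exact_under_noise(self):
        for seed in range(5):
            lset, _ = generate_pelvis(SyntheticSpec(seed=seed, landmark_jitter_sd=2.0))
            report = perpendicularity_report(build_frame(lset))
            assert report.angle_sagittal_transverse == pytest.approx(90.0, abs=1e-12)

    def test_app_sagittal_spread_grows_with_noise(self):
        def spread(sd: float) -> float:
            vals = [
                perpendicularity_report(
                    build_frame(generate_pelvis(SyntheticSpec(seed=s, landmark_jitter_sd=sd))[0])
                ).angle_coronal_sagittal
                for s in range(40)
            ]
            return float(np.std(vals))

        s_low, s_high = spread(0.3), spread(3.0)
        assert s_low < s_high
        assert spread(0.0) == pytest.approx(0.0, abs=1e-9)
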