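import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from acetorient import (
    SyntheticSpec,
    anatomical_angles,
    generate_pelvis,
    measure_all,
    murray_residuals,
    operative_angles,
    orientation_angles,
    radiographic_angles,
)
from acetorient.angle_measures import OrientationAngles

from conftest import closed_form_angles, random_unit_axes


def make_angles(ai=0.0, aa=0.0, oi=0.0, oa=0.0, ri=0.0, ra=0.0) -> OrientationAngles:
    return OrientationAngles(
        case_id="t", side="right", ai=ai, aa=aa, oi=oi, oa=oa, ri=ri, ra=ra,
        ai_raw=ai, oa_raw=oa, ri_raw=ri,
    )


class TestSingleSystems:
    def test_axis_along_longitudinal(self, canonical_frame):
        a = orientation_angles(np.array([0.0, 0, 1]), canonical_frame, "right")
        assert a.ai == pytest.approx(0.0, abs=1e-12)
        assert "AA" in a.flags and math.isnan(a.aa)

    def test_axis_along_transverse_axis(self, canonical_frame):
        ai, aa = anatomical_angles(np.array([1.0, 0, 0]), canonical_frame)
        assert ai == pytest.approx(90.0, abs=1e-12)
        assert aa == pytest.approx(0.0, abs=1e-12)
        oi, _ = operative_angles(np.array([1.0, 0, 0]), canonical_frame)
        assert oi == pytest.approx(90.0, abs=1e-12)
        a = orientation_angles(np.array([1.0, 0, 0]), canonical_frame, "right")
        assert "OA" in a.flags

    def test_axis_in_sagittal_plane(self, canonical_frame):
        axis = np.array([0.0, math.sin(0.3), -math.cos(0.3)])
        oi, _ = operative_angles(axis, canonical_frame)
        assert oi == pytest.approx(0.0, abs=1e-12)

    def test_axis_in_coronal_plane_and_coronal_normal(self, canonical_frame):
        axis = np.array([math.sin(0.5), 0.0, -math.cos(0.5)])
        _, ra = radiographic_angles(axis, canonical_frame)
        assert ra == pytest.approx(0.0, abs=1e-12)
        a = orientation_angles(np.array([0.0, 1.0, 0]), canonical_frame, "right")
        assert a.ra == pytest.approx(90.0, abs=1e-12)
        assert "RI" in a.flags

    def test_hand_trigonometry_40_15(self, canonical_frame):
        # axis components (lateral, anterior, cranial) for AI=40°, AA=15°
        ai_t, aa_t = math.radians(40), math.radians(15)
        axis = np.array(
            [math.cos(aa_t) * math.sin(ai_t), math.sin(aa_t) * math.sin(ai_t), -math.cos(ai_t)]
        )
        a = orientation_angles(axis, canonical_frame, "right")
        assert a.ai == pytest.approx(40.0, abs=1e-9)
        assert a.ai_raw == pytest.approx(140.0, abs=1e-9)
        assert a.aa == pytest.approx(15.0, abs=1e-9)
        assert math.sin(math.radians(a.oi)) == pytest.approx(
            math.cos(aa_t) * math.sin(ai_t), abs=1e-12
        )
        assert math.tan(math.radians(a.oa)) == pytest.approx(
            math.sin(aa_t) * math.sin(ai_t) / math.cos(ai_t), abs=1e-12
        )
        assert a.ra == pytest.approx(
            math.degrees(math.asin(math.sin(aa_t) * math.sin(ai_t))), abs=1e-9
        )

    def test_retroversion_reported_negative(self, canonical_frame):
        axis = np.array([math.sin(math.radians(40)), 0.0, 0.0])
        axis[1] = -0.2  # posteriorly tipped socket
        axis /= np.linalg.norm(axis)
        a = orientation_angles(axis, canonical_frame, "right")
        assert a.aa < 0 and a.ra < 0 and a.oa < 0


class TestClosedFormOracle:
    def test_random_axes_match_closed_forms(self, canonical_frame):
        rng = np.random.default_rng(2024)
        for axis in random_unit_axes(rng, 200):
            got = orientation_angles(axis, canonical_frame, "right").as_dict()
            want = closed_form_angles(axis, canonical_frame, "right")
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-9), key

    def test_left_side_uses_mirrored_lateral(self, canonical_frame):
        rng = np.random.default_rng(5)
        for axis in random_unit_axes(rng, 50):
            got = orientation_angles(axis, canonical_frame, "left").as_dict()
            want = closed_form_angles(axis, canonical_frame, "left")
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-9), key


class TestMeasureAll:
    def test_noise_free_recovery(self, clean_pelvis):
        lset, truth = clean_pelvis
        report = measure_all(lset)
        assert not report.failures
        for hip in report.hips:
            want = truth.angles[hip.angles.side]
            for key, value in hip.angles.as_dict().items():
                assert value == pytest.approx(want[key], abs=1e-6), key

    def test_rigid_rotation_leaves_angles_unchanged(self, clean_pelvis):
        lset, _ = clean_pelvis
        base = {h.angles.side: h.angles.as_dict() for h in measure_all(lset).hips}
        R = Rotation.from_rotvec(np.radians(30) * np.array([0.6, 0.64, 0.48])).as_matrix()
        moved = measure_all(lset.transformed(R, np.array([40.0, -10.0, 25.0])))
        for hip in moved.hips:
            for key, value in hip.angles.as_dict().items():
                assert value == pytest.approx(base[hip.angles.side][key], abs=1e-9), key

    def test_mirror_symmetry_of_sides(self, clean_pelvis):
        lset, _ = clean_pelvis  # both hips share the same truth, mirrored
        report = measure_all(lset)
        left = next(h.angles for h in report.hips if h.angles.side == "left")
        right = next(h.angles for h in report.hips if h.angles.side == "right")
        for key in ("AI", "AA", "OI", "OA", "RI", "RA"):
            assert left.as_dict()[key] == pytest.approx(right.as_dict()[key], abs=1e-9)

    def test_bad_hip_does_not_kill_case(self, clean_pelvis):
        lset, _ = clean_pelvis
        lset.hips["left"] = np.outer(np.linspace(0, 1, 30), [1.0, 0.0, 0.0])
        report = measure_all(lset)
        assert [side for side, _ in report.failures] == ["left"]
        assert [h.angles.side for h in report.hips] == ["right"]

    def test_rows_carry_audit_and_flags(self, clean_pelvis):
        lset, _ = clean_pelvis
        rows = measure_all(lset).rows()
        assert len(rows) == 2
        for row in rows:
            assert row["angle_sagittal_transverse"] == pytest.approx(90.0, abs=1e-12)
            assert row["flags"] == ""
            assert row["n_rim_points"] == 30


class TestMurrayResiduals:
    def test_all_zero_angles(self):
        res = murray_residuals(make_angles())
        assert res.r1 == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(-45.0, abs=1e-12)
        assert res.r3 == pytest.approx(0.0, abs=1e-12)

    def test_ri90_ra0_oa45_gives_zero_r1(self):
        res = murray_residuals(make_angles(ri=90.0, ra=0.0, oa=45.0))
        assert res.r1 == pytest.approx(0.0, abs=1e-12)

    def test_r3_undefined_outside_arcsin_domain(self):
        res = murray_residuals(make_angles(oi=80.0, oa=0.0))
        assert not res.r3_defined
        assert math.isnan(res.r3)

    def test_degenerate_angles_rejected(self, canonical_frame):
        a = orientation_angles(np.array([0.0, 0, 1]), canonical_frame, "right")
        with pytest.raises(ValueError, match="degenerate"):
            murray_residuals(a)

    def test_printed_formulas_nonzero_on_exact_sets(self, canonical_frame):
        # geometrically consistent angle sets do not satisfy the printed
        # conversions: the residuals are generically far from zero
        rng = np.random.default_rng(77)
        nonzero = 0
        for axis in random_unit_axes(rng, 50):
            a = orientation_angles(axis, canonical_frame, "right")
            res = murray_residuals(a)
            if abs(res.r1) > 1.0 or abs(res.r2) > 1.0:
                nonzero += 1
        assert nonzero > 45

    def test_identity_residuals_vanish_on_exact_sets(self, canonical_frame):
        # the self-consistent geometric identities, by contrast, hold
        rng = np.random.default_rng(78)
        for axis in random_unit_axes(rng, 50, margin=0.05):
            if axis[0] < 0.05:  # keep RI well-defined and lateral
                continue
            a = orientation_angles(axis, canonical_frame, "right")
            res = murray_residuals(a, textbook=True)
            assert res.r1_identity == pytest.approx(0.0, abs=1e-9)
            assert res.r3_identity == pytest.approx(0.0, abs=1e-9)
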