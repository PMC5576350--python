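import math

import numpy as np
import pytest

from acetorient import LandmarkSet, Plane, ReferenceFrame, SyntheticSpec, generate_pelvis


@pytest.fixture
def canonical_frame() -> ReferenceFrame:
    """Exact reference frame: coronal y=0, sagittal x=0, transverse z=0.

    Constructed directly (not via the landmark pipeline) so it can serve
    as an independent fixture for angle oracles.
    """
    return ReferenceFrame(
        coronal=Plane(0.0, 1.0, 0.0, 0.0),
        sagittal=Plane(1.0, 0.0, 0.0, 0.0),
        transverse=Plane(0.0, 0.0, 1.0, 0.0),
        longitudinal_axis=np.array([0.0, 0.0, 1.0]),
        transverse_axis=np.array([1.0, 0.0, 0.0]),
        origin=np.zeros(3),
    )


@pytest.fixture
def clean_pelvis() -> tuple[LandmarkSet, object]:
    """Noise-free synthetic pelvis in canonical pose, truth AI=40°, AA=15°."""
    return generate_pelvis(SyntheticSpec(seed=7))


def closed_form_angles(axis: np.ndarray, frame: ReferenceFrame, side: str) -> dict:
    """Independent trigonometric oracle for the six angles.

    Derived once by hand from the axis decomposition (lateral, anterior,
    cranial) = (l, a, c) under the package's folded/signed reporting
    conventions; shares no code path with the geometric pipeline.
    """
    lat = float(np.dot(axis, frame.lateral_axis(side)))
    ant = float(np.dot(axis, frame.anterior_axis))
    cra = float(np.dot(axis, frame.longitudinal_axis))
    sign_a = 1.0 if ant >= 0 else -1.0
    return {
        "AI": math.degrees(math.acos(abs(cra))),
        "AA": sign_a * math.degrees(math.acos(lat / math.hypot(lat, ant))),
        "OI": math.degrees(math.asin(max(-1.0, min(1.0, lat)))),
        "OA": sign_a * math.degrees(math.acos(abs(cra) / math.hypot(ant, cra))),
        "RI": math.degrees(math.acos(abs(cra) / math.hypot(lat, cra))),
        "RA": math.degrees(math.asin(max(-1.0, min(1.0, ant)))),
    }


def random_unit_axes(rng: np.random.Generator, n: int, margin: float = 1e-3) -> np.ndarray:
    """Uniform random unit vectors staying ``margin`` away from every
    degenerate configuration (axis parallel to a frame plane normal)."""
    out = []
    while len(out) < n:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if min(np.hypot(v[0], v[1]), np.hypot(v[1], v[2]), np.hypot(v[0], v[2])) > margin:
            out.append(v)
    return np.array(out)
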