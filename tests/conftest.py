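import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cochleomap.geometry import angular_depth, fit_modiolar_axis
from cochleomap.synthetic import generate, paper_preset
from cochleomap.tonotopy import attach_dendrites, map_oc_frequencies, transfer_to_sg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def rotation_matrix(angles):
    """Rotation from three Euler-like angles (radians), for rigid-motion tests."""
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@pytest.fixture(scope="session")
def preset_bundle():
    """The noise-free specimen-calibrated synthetic cochlea."""
    return generate(paper_preset())


@pytest.fixture(scope="session")
def preset_pipeline(preset_bundle):
    """Full pipeline products on the preset: frame, angle profiles, OC/SG maps."""
    b = preset_bundle
    frame = fit_modiolar_axis(b.bm, b.rw_center)
    bm_angles = angular_depth(b.bm, frame)
    sg_angles = angular_depth(b.sg, frame)
    oc_map = map_oc_frequencies(b.bm, bm_angles)
    dendrites = attach_dendrites(b.dendrites, b.bm, b.sg)
    sg_map = transfer_to_sg(oc_map, dendrites, b.sg, sg_angles)
    return {
        "bundle": b,
        "frame": frame,
        "bm_angles": bm_angles,
        "sg_angles": sg_angles,
        "oc_map": oc_map,
        "sg_map": sg_map,
    }
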