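import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import footmech as fm
from footmech.anatomy import AttachmentRecord, Bone, Skeleton
from footmech.geometry import Pose, rotvec_to_matrix
from footmech.ligaments import (
    InSituStrainTable,
    LigamentBand,
    band_energy,
    band_strain,
    band_tension,
    calibrate_rest_lengths,
    path_length,
)


def _two_bone_skeleton(origin_pt, insertion_pt, beads=()):
    """Minimal fixture skeleton: two bones at identity poses."""
    lms_a = {"o": np.asarray(origin_pt, dtype=float)}
    lms_b = {"i": np.asarray(insertion_pt, dtype=float)}
    bead_recs = []
    for k, (bone, pt) in enumerate(beads):
        name = f"b{k}"
        (lms_a if bone == "a" else lms_b)[name] = np.asarray(pt, dtype=float)
        bead_recs.append((bone, name, 5.0))
    bones = {
        "a": Bone("a", Pose(), lms_a),
        "b": Bone("b", Pose(), lms_b),
    }
    sk = Skeleton(bones=bones, joint_pairs=[], attachments=[])
    band = LigamentBand(
        name="t", group="g", structure="generic",
        origin=("a", "o"), insertion=("b", "i"), via_beads=tuple(bead_recs),
        stiffness_k=1.0, rest_length_L0=1.0,
    )
    return sk, band


def test_path_length_three_four_five():
    sk, band = _two_bone_skeleton((0, 0, 0), (3, 4, 0))
    assert np.isclose(path_length(band, sk), 5.0)


def test_collinear_bead_does_not_change_length():
    sk, band = _two_bone_skeleton((0, 0, 0), (10, 0, 0), beads=[("a", (4, 0, 0))])
    assert np.isclose(path_length(band, sk), 10.0)


def test_right_angle_bead_path():
    sk, band = _two_bone_skeleton((0, 0, 0), (10, 10, 0), beads=[("a", (10, 0, 0))])
    assert np.isclose(path_length(band, sk), 20.0)


def test_path_never_shorter_than_chord():
    sk, band = _two_bone_skeleton((0, 0, 0), (8, 0, 0), beads=[("a", (4, 3, 1))])
    assert path_length(band, sk) >= 8.0


@given(st.lists(st.floats(-0.5, 0.5), min_size=3, max_size=3),
       st.lists(st.floats(-20, 20), min_size=3, max_size=3))
@settings(max_examples=25, deadline=None)
def test_path_length_rigid_invariance(rv, t):
    sk, band = _two_bone_skeleton((1, 2, 3), (20, 5, -4), beads=[("b", (12, 9, 0))])
    L0 = path_length(band, sk)
    R = rotvec_to_matrix(np.array(rv))
    poses = {n: Pose(np.array(t), R) for n in ("a", "b")}
    assert np.isclose(path_length(band, sk, poses), L0, atol=1e-9)


def test_tension_is_tension_only():
    sk, band = _two_bone_skeleton((0, 0, 0), (21, 0, 0))
    taut = LigamentBand(**{**band.__dict__, "stiffness_k": 39.0, "rest_length_L0": 20.0})
    assert np.isclose(band_tension(taut, sk), 39.0)  # 39 N/mm, 1 mm elongation
    slack = LigamentBand(**{**band.__dict__, "stiffness_k": 240.0, "rest_length_L0": 50.0})
    assert band_tension(slack, sk) == 0.0
    boundary = LigamentBand(**{**band.__dict__, "stiffness_k": 100.0, "rest_length_L0": 21.0})
    assert band_tension(boundary, sk) == 0.0


def test_energy_nonnegative_and_zero_iff_slack():
    sk, band = _two_bone_skeleton((0, 0, 0), (10, 0, 0))
    taut = LigamentBand(**{**band.__dict__, "rest_length_L0": 9.0})
    slack = LigamentBand(**{**band.__dict__, "rest_length_L0": 11.0})
    assert band_energy(taut, sk) > 0.0
    assert band_energy(slack, sk) == 0.0


def test_force_length_law_matches_energy_gradient():
    """Numerical d(energy)/dL equals the analytic tension across the kink."""
    sk, band = _two_bone_skeleton((0, 0, 0), (10, 0, 0))
    b = LigamentBand(**{**band.__dict__, "stiffness_k": 200.0, "rest_length_L0": 10.0})
    h = 1e-6
    for L in (9.5, 10.5, 12.0):
        poses_p = {"a": Pose(), "b": Pose(position=[L + h - 10, 0, 0])}
        poses_m = {"a": Pose(), "b": Pose(position=[L - h - 10, 0, 0])}
        dE = (band_energy(b, sk, poses_p) - band_energy(b, sk, poses_m)) / (2 * h)
        T = band_tension(b, sk, {"a": Pose(), "b": Pose(position=[L - 10, 0, 0])})
        assert np.isclose(dE, T, atol=1e-3 * max(1.0, T))


def test_calibration_algebra_and_round_trip(skeleton0, bands0):
    # L_neutral = 51, eps = 0.02 -> L0 = 50
    sk, band = _two_bone_skeleton((0, 0, 0), (51, 0, 0))
    out, = calibrate_rest_lengths([band], sk, InSituStrainTable(default=0.02, groups={}))
    assert np.isclose(out.rest_length_L0, 50.0)
    # eps = 0 -> L0 = L_neutral
    out0, = calibrate_rest_lengths([band], sk, InSituStrainTable(default=0.0, groups={}))
    assert np.isclose(out0.rest_length_L0, 51.0)
    # full skeleton: neutral strain reproduces the configured in-situ strain
    table = InSituStrainTable()
    neutral_lengths = {b.name: path_length(b, skeleton0) for b in bands0}
    for b in bands0:
        eps = table.strain_for(b)
        got = band_strain(b, skeleton0, skeleton0.reference_poses(),
                          {b.name: b.rest_length_L0 * 1.0})
        # strain vs rest length equals the calibrated pre-strain
        assert np.isclose((neutral_lengths[b.name] - b.rest_length_L0) / b.rest_length_L0,
                          eps, atol=1e-9), b.name
        del got


def test_strain_table_resolution_order():
    table = InSituStrainTable(default=0.02, groups={"g": 0.01}, bands={"special": 0.05})
    base = dict(name="x", group="g", structure="generic", origin=("a", "o"),
                insertion=("b", "i"), via_beads=(), stiffness_k=1.0, rest_length_L0=1.0)
    assert table.strain_for(LigamentBand(**base)) == 0.01
    assert table.strain_for(LigamentBand(**{**base, "group": "other"})) == 0.02
    assert table.strain_for(LigamentBand(**{**base, "name": "special"})) == 0.05


def test_strain_table_rejects_out_of_range():
    with pytest.raises(ValueError):
        InSituStrainTable(default=0.2, groups={})


def test_negative_strain_representable():
    sk, band = _two_bone_skeleton((0, 0, 0), (10, 0, 0))
    ref = {"t": 10.0}
    poses = {"a": Pose(), "b": Pose(position=[-0.1, 0, 0])}
    assert band_strain(band, sk, poses, ref) < 0.0
    with pytest.raises(KeyError):
        band_strain(band, sk, poses, {})
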