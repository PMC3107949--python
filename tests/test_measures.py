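import numpy as np
import pytest

from footmech.anatomy import Bone, Skeleton
from footmech.geometry import Pose, rotvec_to_matrix
from footmech.measures import (
    AP_VIEW_ELEVATION_DEG,
    MeasureReport,
    ReferenceFrame,
    all_angles,
    ap_angles,
    hindfoot_angle,
    lateral_angles,
)


def _measure_skeleton(
    talar=((0, 0, 0), (50, 0, 0)),
    mt1=((60, 0, 0), (110, 0, 0)),
    border=((0, 0, 0), (60, 0, 0)),
    bisect=((0, 0, 0), (0, 40, 0)),
    chord=((0, 0, -10), (0, 0, 10)),
):
    bones = {
        "talus": Bone("talus", Pose(), {"talus_axis_post": np.array(talar[0], float),
                                        "talus_axis_head": np.array(talar[1], float)}),
        "ray1": Bone("ray1", Pose(), {"mt1_axis_base": np.array(mt1[0], float),
                                      "mt1_axis_head": np.array(mt1[1], float)}),
        "calcaneus": Bone("calcaneus", Pose(), {
            "calc_inf_post": np.array(border[0], float),
            "calc_inf_ant": np.array(border[1], float),
            "calc_bisect_inf": np.array(bisect[0], float),
            "calc_bisect_sup": np.array(bisect[1], float),
        }),
        "navicular": Bone("navicular", Pose(), {"nav_chord_med": np.array(chord[0], float),
                                                "nav_chord_lat": np.array(chord[1], float)}),
    }
    return Skeleton(bones=bones, joint_pairs=[], attachments=[])


def _poses(sk):
    return sk.reference_poses()


def test_collinear_axes_give_zero_meary_angle():
    sk = _measure_skeleton()
    t1, _, _ = lateral_angles(_poses(sk), sk)
    assert np.isclose(t1, 0.0, atol=1e-9)


def test_calcaneal_pitch_twenty_degrees():
    c, s = np.cos(np.radians(20)), np.sin(np.radians(20))
    sk = _measure_skeleton(border=((0, 0, 0), (60 * c, 60 * s, 0)))
    _, _, cp = lateral_angles(_poses(sk), sk)
    assert np.isclose(cp, 20.0, atol=1e-9)


def test_talocalcaneal_angle_forty_degrees():
    c, s = np.cos(np.radians(40)), np.sin(np.radians(40))
    sk = _measure_skeleton(talar=((0, 0, 0), (50 * c, 50 * s, 0)))
    _, tc, _ = lateral_angles(_poses(sk), sk)
    assert np.isclose(tc, 40.0, atol=1e-9)


def test_plantar_apex_reads_negative_meary():
    # talar axis declines 10 deg more than the metatarsal axis: arch droop
    c, s = np.cos(np.radians(10)), np.sin(np.radians(10))
    sk = _measure_skeleton(talar=((0, 0, 0), (50 * c, -50 * s, 0)))
    t1, _, _ = lateral_angles(_poses(sk), sk)
    assert np.isclose(t1, -10.0, atol=1e-9)


def _ap_basis():
    el = np.radians(AP_VIEW_ELEVATION_DEG)
    n = np.array([np.cos(el), np.sin(el), 0.0])
    e1 = np.array([1.0, 0.0, 0.0]) - np.cos(el) * n
    e1 /= np.linalg.norm(e1)
    medial = np.array([0.0, 0.0, -1.0])
    return n, e1, medial


def test_ap_t1mt_in_projection_rotation_reads_exactly():
    """An axis pair differing by 7.2 deg toward medial in the raised-AP
    projection reads AP-T1MT = +7.2 (adduction positive)."""
    n, e1, m = _ap_basis()
    talar = 50 * e1
    phi = np.radians(7.2)
    mt1 = 50 * (np.cos(phi) * e1 + np.sin(phi) * m)
    sk = _measure_skeleton(talar=((0, 0, 0), tuple(talar)), mt1=((0, 0, 0), tuple(mt1)))
    t4, _ = ap_angles(_poses(sk), sk)
    assert np.isclose(t4, 7.2, atol=1e-9)
    # abduction (lateral deviation) reads negative
    mt1_abd = 50 * (np.cos(phi) * e1 - np.sin(phi) * m)
    sk2 = _measure_skeleton(talar=((0, 0, 0), tuple(talar)), mt1=((0, 0, 0), tuple(mt1_abd)))
    t4b, _ = ap_angles(_poses(sk2), sk2)
    assert np.isclose(t4b, -7.2, atol=1e-9)


def test_navicular_chord_perpendicular_reads_zero_coverage():
    n, e1, m = _ap_basis()
    talar = 50 * e1
    chord_dir = np.cross(n, e1)  # in-plane perpendicular of the talar axis
    sk = _measure_skeleton(
        talar=((0, 0, 0), tuple(talar)),
        chord=(tuple(-10 * chord_dir), tuple(10 * chord_dir)),
    )
    _, t5 = ap_angles(_poses(sk), sk)
    assert np.isclose(t5, 0.0, atol=1e-9)


def test_hindfoot_vertical_reads_ninety():
    sk = _measure_skeleton()
    assert np.isclose(hindfoot_angle(_poses(sk), sk), 90.0, atol=1e-12)


def test_hindfoot_valgus_and_varus_directions():
    # valgus heel: the distal segment deviates laterally, i.e. the bisection
    # top tips medially: reads above 90 (96.4-style flatfoot values)
    zoff = -40 * np.tan(np.radians(3.4))  # medial = -Z, right foot
    sk = _measure_skeleton(bisect=((0, 0, 0), (0, 40, zoff)))
    assert np.isclose(hindfoot_angle(_poses(sk), sk), 93.4, atol=1e-6)
    # varus: top tips laterally, reads below 90 (87.7-style MCO values)
    zoff = +40 * np.tan(np.radians(2.3))
    sk = _measure_skeleton(bisect=((0, 0, 0), (0, 40, zoff)))
    assert np.isclose(hindfoot_angle(_poses(sk), sk), 87.7, atol=1e-6)


def test_angles_invariant_under_global_rigid_transform():
    sk = _measure_skeleton(
        talar=((0, 2, 1), (50, -8, -4)),
        mt1=((60, 1, -3), (110, -9, -6)),
        border=((0, 0, 1), (58, 17, 3)),
        bisect=((1, 0, 0), (0.5, 40, -2)),
        chord=((0, 1, -10), (-2, 3, 9)),
    )
    base = all_angles(_poses(sk), sk)
    R = rotvec_to_matrix(np.array([0.3, -0.2, 0.4]))
    t = np.array([12.0, -5.0, 30.0])
    poses = {name: Pose(R @ p.position + t, R @ p.rotation) for name, p in _poses(sk).items()}
    frame = ReferenceFrame(anterior=R @ [1, 0, 0], superior=R @ [0, 1, 0])
    moved = all_angles(poses, sk, frame)
    for k in ("l_t1mt", "l_tc", "l_cp", "ap_t1mt", "ap_tn", "hindfoot"):
        assert np.isclose(getattr(base, k), getattr(moved, k), atol=1e-6), k


def test_missing_landmark_rejected_by_name():
    sk = _measure_skeleton()
    del sk.bones["talus"].landmarks["talus_axis_head"]
    with pytest.raises(KeyError, match="talus_axis_head"):
        lateral_angles(_poses(sk), sk)


def test_strain_tables_order_and_length(solved_normal):
    rep = solved_normal.report
    assert len(rep.long_plantar_strains_pct) == 8
    assert len(rep.plantar_fascia_strains_pct) == 5
    # medial band is index 0: matches band name long_plantar_1
    from footmech.ligaments import path_length

    b1 = next(b for b in solved_normal.bands if b.name == "long_plantar_1")
    L = path_length(b1, solved_normal.skeleton, solved_normal.loaded.poses)
    L_ref = path_length(b1, solved_normal.skeleton, solved_normal.unloaded.poses)
    assert np.isclose(rep.long_plantar_strains_pct[0], 100 * (L - L_ref) / L_ref, atol=1e-9)


def test_zero_strain_when_loaded_equals_unloaded(solved_normal):
    from footmech.measures import strain_tables

    lp, pf = strain_tables(
        solved_normal.unloaded,
        solved_normal.skeleton,
        solved_normal.bands,
        {b.name: __import__("footmech").ligaments.path_length(
            b, solved_normal.skeleton, solved_normal.unloaded.poses)
         for b in solved_normal.bands},
    )
    assert np.allclose(lp, 0.0, atol=1e-9) and np.allclose(pf, 0.0, atol=1e-9)


def test_report_round_trip_and_rounding(solved_normal):
    rep = solved_normal.report
    back = MeasureReport.from_dict(rep.to_dict())
    assert back.scenario == rep.scenario
    assert np.allclose(back.long_plantar_strains_pct, rep.long_plantar_strains_pct)
    assert back.calcaneocuboid_force_N == rep.calcaneocuboid_force_N
    r = rep.rounded()
    assert isinstance(r["plantar_loads_N"]["ray1"], int)
    assert abs(r["angles_deg"]["l_t1mt"] - rep.angles.l_t1mt) <= 0.05 + 1e-12


def test_measure_report_validates_array_lengths(solved_normal):
    import dataclasses

    with pytest.raises(ValueError):
        MeasureReport(
            scenario="x",
            angles=solved_normal.report.angles,
            long_plantar_strains_pct=[0.0] * 7,
            plantar_fascia_strains_pct=[0.0] * 5,
            calcaneocuboid_force_N=None,
            plantar_loads_N={},
        )
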