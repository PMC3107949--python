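import numpy as np
import pytest

import footmech as fm
from footmech.mechanics import degrees_of_freedom
from footmech.surgery import (
    OsteotomyParams,
    apply_ccda,
    apply_evans,
    apply_mco,
    apply_procedures,
)


def _world_points(skeleton, bone):
    b = skeleton.bones[bone]
    pts = {f"lm:{k}": b.world_landmark(k) for k in b.landmarks}
    for c in b.contact_points:
        pts[f"c:{c.name}"] = b.reference_pose.transform(c.local)
    return pts


def _moved_keys(before, after, tol=1e-9):
    return {k for k in before if np.linalg.norm(after[k] - before[k]) > tol}


def test_params_validation():
    with pytest.raises(ValueError):
        OsteotomyParams(wedge_width_mm=30.0)  # wider than deep
    with pytest.raises(ValueError):
        OsteotomyParams(wedge_depth_mm=0.0)
    assert np.isclose(OsteotomyParams().hinge_angle_deg, np.degrees(np.arctan2(10, 25)))


def test_hinge_angle_equals_wedge_trigonometry():
    assert np.isclose(OsteotomyParams().hinge_angle_deg, 21.801409, atol=1e-6)


def test_mco_zero_offset_is_identity(skeleton0):
    out = apply_mco(skeleton0, OsteotomyParams(mco_offset_mm=0.0))
    before, after = _world_points(skeleton0, "calcaneus"), _world_points(out, "calcaneus")
    assert not _moved_keys(before, after)


def test_mco_translates_tuberosity_fragment_medially(skeleton0):
    out = apply_mco(skeleton0)
    before, after = _world_points(skeleton0, "calcaneus"), _world_points(out, "calcaneus")
    moved = _moved_keys(before, after)
    assert "lm:achilles_insertion" in moved
    assert "c:heel_med" in moved and "c:heel_lat" in moved
    assert "lm:calc_cc_center" not in moved
    d = after["lm:achilles_insertion"] - before["lm:achilles_insertion"]
    assert np.allclose(d, [0.0, 0.0, -10.0], atol=1e-12)  # medial = -Z, right foot
    # rigid fragment: intra-fragment distances preserved
    keys = sorted(moved)
    for a in keys[:5]:
        for b in keys[:5]:
            d0 = np.linalg.norm(before[a] - before[b])
            d1 = np.linalg.norm(after[a] - after[b])
            assert np.isclose(d0, d1, atol=1e-9)
    # nothing outside the fragment moves, on any bone
    for bone in skeleton0.bones:
        if bone == "calcaneus":
            continue
        assert not _moved_keys(_world_points(skeleton0, bone), _world_points(out, bone))


def test_mco_translation_composes(skeleton0):
    twice = apply_mco(apply_mco(skeleton0, OsteotomyParams(mco_offset_mm=5.0)),
                      OsteotomyParams(mco_offset_mm=5.0))
    once = apply_mco(skeleton0, OsteotomyParams(mco_offset_mm=10.0))
    a, b = _world_points(twice, "calcaneus"), _world_points(once, "calcaneus")
    for k in a:
        assert np.allclose(a[k], b[k], atol=1e-9), k


def test_evans_rotates_anterior_fragment_rigidly(skeleton0):
    out = apply_evans(skeleton0)
    before, after = _world_points(skeleton0, "calcaneus"), _world_points(out, "calcaneus")
    moved = _moved_keys(before, after)
    assert "lm:calc_cc_center" in moved
    assert "lm:achilles_insertion" not in moved
    keys = sorted(moved)
    for a in keys:
        for b in keys:
            assert np.isclose(
                np.linalg.norm(before[a] - before[b]),
                np.linalg.norm(after[a] - after[b]),
                atol=1e-9,
            )
    # the lateral edge opens anteriorly: the articular center advances
    assert after["lm:calc_cc_center"][0] > before["lm:calc_cc_center"][0]


def test_evans_attachments_ride_the_fragment(skeleton0):
    """Ligament attachments on the moved fragment move with it."""
    out = apply_evans(skeleton0)
    calc_b, calc_a = _world_points(skeleton0, "calcaneus"), _world_points(out, "calcaneus")
    moved = _moved_keys(calc_b, calc_a)
    cage_on_fragment = [k for k in moved if "cage" in k]
    assert cage_on_fragment, "capsule fibers at the CC joint should ride the fragment"


def test_ccda_fuses_and_removes_contacts(skeleton0):
    out = apply_ccda(skeleton0)
    assert out.bones["cuboid"].fusion_group == out.bones["calcaneus"].fusion_group
    assert degrees_of_freedom(out).n_coords == degrees_of_freedom(skeleton0).n_coords - 6
    from footmech.mechanics import build_contact_set

    cs = build_contact_set(out)
    assert not any(p.joint == "calcaneocuboid" for p in cs.joints)
    with pytest.raises(ValueError, match="already fused"):
        apply_ccda(out)


def test_ccda_zero_geometry_still_fuses(skeleton0):
    p = OsteotomyParams(wedge_width_mm=0.0, ccda_resection_mm=0.0)
    out = apply_ccda(skeleton0, p)
    before, after = _world_points(skeleton0, "cuboid"), _world_points(out, "cuboid")
    assert not _moved_keys(before, after)
    assert out.bones["cuboid"].fusion_group == out.bones["calcaneus"].fusion_group


def test_ccda_rotates_whole_cuboid(skeleton0):
    out = apply_ccda(skeleton0)
    before, after = _world_points(skeleton0, "cuboid"), _world_points(out, "cuboid")
    moved = _moved_keys(before, after)
    assert set(before) == moved  # every cuboid point moves (rotation + shave)
    keys = [k for k in sorted(before) if "jc_calcaneocuboid" not in k and "cc_center" not in k]
    for a in keys[:6]:
        for b in keys[:6]:
            assert np.isclose(
                np.linalg.norm(before[a] - before[b]),
                np.linalg.norm(after[a] - after[b]),
                atol=1e-9,
            )


def test_procedure_set_rules(skeleton0):
    assert apply_procedures(skeleton0, []) is skeleton0  # empty set = identity
    with pytest.raises(ValueError, match="mutually exclusive"):
        apply_procedures(skeleton0, ["Evans", "CCDA"])
    with pytest.raises(ValueError, match="unknown"):
        apply_procedures(skeleton0, ["Hoke"])


def test_combined_evans_mco_has_both_effects(skeleton0):
    out = apply_procedures(skeleton0, ["Evans", "MCO"])
    before, after = _world_points(skeleton0, "calcaneus"), _world_points(out, "calcaneus")
    d_ach = after["lm:achilles_insertion"] - before["lm:achilles_insertion"]
    assert np.allclose(d_ach, [0, 0, -10.0], atol=1e-12)
    assert after["lm:calc_cc_center"][0] > before["lm:calc_cc_center"][0]


def test_left_foot_mirror_surgery():
    left = fm.build_skeleton(fm.AnatomyParams(handedness="left"), seed=0)
    out = apply_mco(left)
    d = (out.bones["calcaneus"].world_landmark("achilles_insertion")
         - left.bones["calcaneus"].world_landmark("achilles_insertion"))
    assert np.allclose(d, [0, 0, +10.0], atol=1e-12)  # medial = +Z on the left
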