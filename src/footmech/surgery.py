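"""Virtual corrective osteotomies as geometric skeleton operations.

Three procedures are modeled, each as a rigid transform of a landmark
subset (fragments re-fuse into their parent body, so no new degrees of
freedom appear):

* **MCO** (medializing calcaneal osteotomy): the posterior tuberosity
  fragment — including the Achilles insertion and the heel ground
  contacts — is translated medially and re-fixed.
* **Evans** (lateral column lengthening): the anterior calcaneal facet is
  cut a fixed distance behind the calcaneocuboid articular surface and
  rotated about a vertical hinge on the medial border of the cut until a
  triangular wedge of the requested width fits at the lateral edge; the
  hinge angle is ``arctan(wedge_width / wedge_depth)``.
* **CCDA** (calcaneocuboid distraction arthrodesis): the shared articular
  surfaces are shaved back, the whole cuboid is rotated about the medial
  border of the joint by the same wedge angle, and the joint is fused
  (the cuboid joins the calcaneal fusion group; its contact pairs
  deactivate automatically).

Ligament attachments are landmarks, so attachments riding on a moved
fragment move with it — this is how the procedures re-tension the plantar
structures. Contact rest gaps stay frozen at their intact values, so an
Evans fragment pressing into the cuboid registers as joint load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import Skeleton

__all__ = ["OsteotomyParams", "apply_mco", "apply_evans", "apply_ccda", "apply_procedures", "PROCEDURES"]

PROCEDURES = ("MCO", "Evans", "CCDA")

# fraction of the tuberosity-to-articular-surface span at which the MCO cut
# plane sits (isolates the posterior tuberosity)
_MCO_CUT_FRACTION = 0.35


@dataclass(frozen=True)
class OsteotomyParams:
    mco_offset_mm: float = 10.0
    evans_cut_offset_mm: float = 10.0  # behind the articular surface
    wedge_width_mm: float = 10.0
    wedge_depth_mm: float = 25.0
    ccda_resection_mm: float = 3.0  # per articular surface
    ccda_trim_mm: float = 4.0  # visual wedge trim only (mesh export)

    def __post_init__(self):
        for name in ("mco_offset_mm", "wedge_width_mm", "ccda_resection_mm", "ccda_trim_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("evans_cut_offset_mm", "wedge_depth_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.wedge_width_mm >= self.wedge_depth_mm:
            raise ValueError("wedge_width_mm must be smaller than wedge_depth_mm")

    @property
    def hinge_angle_deg(self) -> float:
        """Opening angle of the inserted wedge, arctan(width / depth)."""
        return float(np.degrees(np.arctan2(self.wedge_width_mm, self.wedge_depth_mm)))


def _bone_points(bone):
    """Yield mutable references to every local point on a bone."""
    for name in bone.landmarks:
        yield ("landmark", name)
    for i, _c in enumerate(bone.contact_points):
        yield ("contact", i)


def _get_world(bone, kind, key):
    pose = bone.reference_pose
    if kind == "landmark":
        return pose.transform(bone.landmarks[key])
    return pose.transform(bone.contact_points[key].local)


def _set_world(bone, kind, key, world):
    pose = bone.reference_pose
    local = pose.rotation.T @ (np.asarray(world, dtype=float) - pose.position)
    if kind == "landmark":
        bone.landmarks[key] = local
    else:
        bone.contact_points[key].local = local


def _lateral_sign(skeleton: Skeleton) -> float:
    return 1.0 if skeleton.handedness == "right" else -1.0


def apply_mco(skeleton: Skeleton, params: OsteotomyParams | None = None) -> Skeleton:
    """Medialize the posterior calcaneal tuberosity fragment."""
    params = params if params is not None else OsteotomyParams()
    out = skeleton.copy()
    calc = out.bones["calcaneus"]

    x_post = calc.world_landmark("calc_tuber_post")[0]
    x_art = calc.world_landmark("calc_cc_center")[0]
    x_cut = x_post + _MCO_CUT_FRACTION * (x_art - x_post)

    fragment = [(k, key) for (k, key) in _bone_points(calc) if _get_world(calc, k, key)[0] < x_cut]
    frag_names = {key for kind, key in fragment if kind == "landmark"}
    if not fragment:
        raise ValueError("MCO cut plane isolates no landmarks")
    if "achilles_insertion" not in frag_names:
        raise ValueError("MCO fragment does not contain the Achilles insertion")
    if "calc_cc_center" in frag_names or any(n.startswith("jc_calcaneocuboid") for n in frag_names):
        raise ValueError("MCO cut plane isolates the calcaneocuboid articular landmarks")

    shift = skeleton.medial_direction * params.mco_offset_mm
    for kind, key in fragment:
        _set_world(calc, kind, key, _get_world(calc, kind, key) + shift)
    return out


def _hinge_rotation(skeleton: Skeleton, angle_deg: float) -> np.ndarray:
    """Rotation matrix about the vertical hinge, opening the wedge laterally."""
    a = np.radians(angle_deg) * _lateral_sign(skeleton)
    c, s = np.cos(a), np.sin(a)
    # about +Y: for a right foot (+Z lateral), +angle moves lateral points anterior
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def apply_evans(skeleton: Skeleton, params: OsteotomyParams | None = None) -> Skeleton:
    """Opening-wedge osteotomy of the anterior calcaneus."""
    params = params if params is not None else OsteotomyParams()
    out = skeleton.copy()
    calc = out.bones["calcaneus"]

    cc = calc.world_landmark("calc_cc_center")
    x_cut = cc[0] - params.evans_cut_offset_mm
    fragment = [(k, key) for (k, key) in _bone_points(calc) if _get_world(calc, k, key)[0] > x_cut]
    frag_names = {key for kind, key in fragment if kind == "landmark"}
    if not fragment or "calc_cc_center" not in frag_names:
        raise ValueError("Evans cut plane misses the anterior calcaneus")

    lat = _lateral_sign(skeleton)
    hinge = np.array([x_cut, 0.0, cc[2] - lat * params.wedge_depth_mm / 2.0])
    R = _hinge_rotation(skeleton, params.hinge_angle_deg)
    for kind, key in fragment:
        w = _get_world(calc, kind, key)
        _set_world(calc, kind, key, hinge + R @ (w - hinge))
    return out


def apply_ccda(skeleton: Skeleton, params: OsteotomyParams | None = None) -> Skeleton:
    """Calcaneocuboid distraction arthrodesis: shave, rotate, fuse."""
    params = params if params is not None else OsteotomyParams()
    if skeleton.bones["cuboid"].fusion_group == skeleton.bones["calcaneus"].fusion_group:
        raise ValueError("calcaneocuboid joint is already fused")
    out = skeleton.copy()
    calc, cub = out.bones["calcaneus"], out.bones["cuboid"]

    # shave the shared articular surfaces along the joint normal (anterior axis)
    shave = np.array([params.ccda_resection_mm, 0.0, 0.0])
    for kind, key in _bone_points(calc):
        name = key if kind == "landmark" else ""
        if name == "calc_cc_center" or str(name).startswith("jc_calcaneocuboid"):
            _set_world(calc, kind, key, _get_world(calc, kind, key) - shave)
    for kind, key in _bone_points(cub):
        name = key if kind == "landmark" else ""
        if name == "cub_cc_center" or str(name).startswith("jc_calcaneocuboid"):
            _set_world(cub, kind, key, _get_world(cub, kind, key) + shave)

    # rotate the entire cuboid about the medial border of the joint
    cc = calc.world_landmark("calc_cc_center")
    lat = _lateral_sign(skeleton)
    hinge = np.array([cc[0], 0.0, cc[2] - lat * params.wedge_depth_mm / 2.0])
    R = _hinge_rotation(skeleton, params.hinge_angle_deg)
    for kind, key in _bone_points(cub):
        w = _get_world(cub, kind, key)
        _set_world(cub, kind, key, hinge + R @ (w - hinge))

    # arthrodesis: one rigid construct; CC contact pairs deactivate on build
    cub.fusion_group = calc.fusion_group
    return out


def apply_procedures(
    skeleton: Skeleton, procedures, params: OsteotomyParams | None = None
) -> Skeleton:
    """Apply a procedure set (lateral column procedure first, then MCO)."""
    params = params if params is not None else OsteotomyParams()
    procs = {p.upper() for p in procedures}
    unknown = procs - {"MCO", "EVANS", "CCDA"}
    if unknown:
        raise ValueError(f"unknown procedures: {sorted(unknown)}")
    if "EVANS" in procs and "CCDA" in procs:
        raise ValueError("Evans and CCDA are mutually exclusive lateral column procedures")
    out = skeleton
    if "EVANS" in procs:
        out = apply_evans(out, params)
    if "CCDA" in procs:
        out = apply_ccda(out, params)
    if "MCO" in procs:
        out = apply_mco(out, params)
    return out
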