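"""Visualization mesh export (STL/PLY) for skeletons and osteotomy wedges.

Bones are represented mechanically as landmark frames plus contact
spheres, not surface meshes; for visualization each bone is exported as
the convex hull of its landmark/contact point cloud in the world frame
(units mm). Osteotomy wedges are exported as triangular prisms built
from the cut geometry. Requires :mod:`trimesh`.
"""

from __future__ import annotations

import numpy as np

from .anatomy import Skeleton
from .geometry import Pose
from .surgery import OsteotomyParams, _lateral_sign

__all__ = ["bone_point_cloud", "export_meshes", "wedge_mesh"]


def bone_point_cloud(skeleton: Skeleton, bone: str, poses: dict[str, Pose] | None = None) -> np.ndarray:
    """World-frame points (landmarks + contact centers) of one bone."""
    b = skeleton.bones[bone]
    pose = (poses or {}).get(bone, b.reference_pose)
    pts = [pose.transform(p) for p in b.landmarks.values()]
    pts += [pose.transform(c.local) for c in b.contact_points]
    return np.array(pts)


def export_meshes(
    skeleton: Skeleton,
    out_dir,
    poses: dict[str, Pose] | None = None,
    fmt: str = "stl",
) -> list:
    """Write one convex-hull mesh per bone; returns the file paths."""
    import trimesh
    from pathlib import Path

    if fmt not in ("stl", "ply"):
        raise ValueError("mesh format must be 'stl' or 'ply'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in skeleton.bones:
        pts = bone_point_cloud(skeleton, name, poses)
        if len(pts) < 4:
            continue
        hull = trimesh.PointCloud(pts).convex_hull
        path = out_dir / f"{name}.{fmt}"
        hull.export(path)
        written.append(path)
    return written


def wedge_mesh(skeleton: Skeleton, params: OsteotomyParams | None = None, procedure: str = "Evans"):
    """Triangular-prism wedge of an Evans/CCDA lateral column lengthening.

    The prism opens from the medial hinge to ``wedge_width_mm`` at the
    lateral edge over ``wedge_depth_mm``; its vertical extent is trimmed
    by ``ccda_trim_mm`` (display only — the mechanics never sees the
    wedge as material).
    """
    import trimesh

    params = params if params is not None else OsteotomyParams()
    if procedure.upper() not in ("EVANS", "CCDA"):
        raise ValueError("wedge procedures are Evans or CCDA")
    cc = skeleton.bones["calcaneus"].world_landmark("calc_cc_center")
    lat = _lateral_sign(skeleton)
    x0 = cc[0] - (params.evans_cut_offset_mm if procedure.upper() == "EVANS" else 0.0)
    z_hinge = cc[2] - lat * params.wedge_depth_mm / 2.0
    height = max(2.0, 20.0 - params.ccda_trim_mm)
    y0, y1 = cc[1] - height / 2.0, cc[1] + height / 2.0
    w, d = params.wedge_width_mm, params.wedge_depth_mm
    tri = [
        (x0, z_hinge),
        (x0, z_hinge + lat * d),
        (x0 + w, z_hinge + lat * d),
    ]
    verts = [(x, y0, z) for (x, z) in tri] + [(x, y1, z) for (x, z) in tri]
    return trimesh.PointCloud(np.array(verts, dtype=float)).convex_hull
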