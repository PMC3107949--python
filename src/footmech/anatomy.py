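"""Parametric synthetic right-foot skeleton.

The generator replaces subject-specific (CT-derived) anatomy with a
deterministic landmark template of a neutrally aligned right foot with a
medial arch, plus small seeded jitter. Bones are rigid bodies described by

* named landmarks (measurement axes, ligament attachment sites, joint
  contact sites), stored in bone-local coordinates (mm);
* ground-contact spheres under the five rays and the calcaneus;
* a fusion group (bones sharing a group move as one rigid body).

Bone units (phalanges are merged into their metatarsal ray; tibia and
fibula are one unit): ``tibfib``, ``talus``, ``calcaneus``, ``navicular``,
``cuboid``, ``cuneiforms``, ``ray1`` .. ``ray5``.

Frame convention: +X anterior, +Y superior, +Z lateral (right foot,
medial = -Z); ground plane at Y = 0. A left foot is the exact mirror
(Z negated); the ``handedness`` flag tells the measurement code which
direction is medial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .geometry import Pose

__all__ = [
    "AnatomyParams",
    "GroundContact",
    "JointContactPair",
    "AttachmentRecord",
    "Bone",
    "Skeleton",
    "build_skeleton",
    "attachment_map",
    "BONE_UNITS",
    "REQUIRED_LANDMARKS",
]

BONE_UNITS = (
    "tibfib",
    "talus",
    "calcaneus",
    "navicular",
    "cuboid",
    "cuneiforms",
    "ray1",
    "ray2",
    "ray3",
    "ray4",
    "ray5",
)

#: measurement / load-application landmarks every skeleton must provide
REQUIRED_LANDMARKS = {
    "tibfib": ("tibia_proximal", "gastroc_proximal"),
    "talus": ("talus_axis_post", "talus_axis_head"),
    "calcaneus": (
        "calc_inf_post",
        "calc_inf_ant",
        "calc_bisect_inf",
        "calc_bisect_sup",
        "achilles_insertion",
        "calc_tuber_post",
        "calc_cc_center",
    ),
    "navicular": ("nav_chord_med", "nav_chord_lat"),
    "cuboid": ("cub_cc_center",),
    "ray1": ("mt1_axis_base", "mt1_axis_head"),
}

GROUND_PENETRATION_TOL = 0.1  # mm, allowed in the reference pose

#: normative windows (degrees) for the neutral-pose radiographic angles a
#: generated skeleton is expected to satisfy
NORMATIVE_WINDOWS = {
    "l_t1mt": (-5.0, 5.0),
    "l_tc": (20.0, 45.0),
    "l_cp": (10.0, 25.0),
    "ap_t1mt": (-5.0, 15.0),
    "ap_tn": (-20.0, 5.0),
    "hindfoot": (88.0, 96.0),
}


@dataclass(frozen=True)
class AnatomyParams:
    """Generator parameters with documented valid ranges."""

    foot_length_mm: float = 250.0  # heel to toe, 200-300
    arch_height_fraction: float = 0.24  # arch apex height / foot length, 0.15-0.35
    foot_width_mm: float = 90.0  # across metatarsal heads, 70-110
    hindfoot_lean_deg: float = 3.0  # neutral lateral lean of calc bisection, 0-6
    jitter_mm: float = 0.6  # uniform landmark jitter half-width, 0-2
    handedness: str = "right"

    _RANGES = {
        "foot_length_mm": (200.0, 300.0),
        "arch_height_fraction": (0.15, 0.35),
        "foot_width_mm": (70.0, 110.0),
        "hindfoot_lean_deg": (0.0, 6.0),
        "jitter_mm": (0.0, 2.0),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"anatomy parameter {name}={v!r} outside documented range [{lo}, {hi}]"
                )
        if self.handedness not in ("right", "left"):
            raise ValueError(f"handedness must be 'right' or 'left', got {self.handedness!r}")


@dataclass
class GroundContact:
    """Contact sphere (bone-local center, mm) that may bear on the ground."""

    name: str
    local: np.ndarray
    radius: float
    region: str  # ray1..ray5 | calcaneus | other

    def __post_init__(self) -> None:
        self.local = np.asarray(self.local, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError(f"ground contact {self.name}: radius must be > 0")


@dataclass(frozen=True)
class JointContactPair:
    """Unilateral articular facet contact between two bones.

    The facet normal is fixed in bone ``a`` and encoded as a third landmark
    (``landmark_n``) sitting exactly 1 mm along the normal from the a-side
    site, so osteotomy fragment transforms carry the facet orientation
    automatically. Penetration is the shortfall of the b-site's advance
    along the normal relative to ``rest_gap_mm`` (the normal gap in the
    intact neutral pose, frozen at generation time so surgical
    re-positioning registers as joint load); tangential sliding is free and
    is restrained by the capsular bands.
    """

    joint: str
    bone_a: str
    landmark_a: str
    bone_b: str
    landmark_b: str
    landmark_n: str
    rest_gap_mm: float
    kind: str = "facet"  # facet | ball


@dataclass(frozen=True)
class AttachmentRecord:
    """One ligament band: named origin/insertion (+ optional via beads)."""

    band: str
    group: str
    structure: str  # stiffness-table key (pathology module)
    origin_bone: str
    origin_landmark: str
    insertion_bone: str
    insertion_landmark: str
    beads: tuple = ()  # ((bone, landmark, radius_mm), ...)


@dataclass
class Bone:
    """Rigid bone unit: local landmarks + contact spheres + fusion group."""

    name: str
    reference_pose: Pose
    landmarks: dict[str, np.ndarray]
    contact_points: list[GroundContact] = field(default_factory=list)
    fusion_group: str = ""

    def __post_init__(self) -> None:
        if not self.fusion_group:
            self.fusion_group = self.name
        self.landmarks = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.landmarks.items()}

    def world_landmark(self, name: str, pose: Pose | None = None) -> np.ndarray:
        if name not in self.landmarks:
            raise KeyError(f"bone {self.name!r} has no landmark {name!r}")
        pose = pose if pose is not None else self.reference_pose
        return pose.transform(self.landmarks[name])


@dataclass
class Skeleton:
    """Ordered bone collection plus ground plane and generation metadata."""

    bones: dict[str, Bone]
    joint_pairs: list[JointContactPair]
    attachments: list[AttachmentRecord]
    ground_height: float = 0.0
    handedness: str = "right"
    generation_seed: int = 0
    params: AnatomyParams = field(default_factory=AnatomyParams)

    # -- queries -----------------------------------------------------------

    def fusion_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for b in self.bones.values():
            groups.setdefault(b.fusion_group, []).append(b.name)
        return groups

    def world_landmark(self, bone: str, name: str, poses: dict[str, Pose] | None = None) -> np.ndarray:
        pose = None if poses is None else poses[bone]
        return self.bones[bone].world_landmark(name, pose)

    @property
    def medial_direction(self) -> np.ndarray:
        """Unit vector pointing medially (-Z for a right foot)."""
        return np.array([0.0, 0.0, -1.0 if self.handedness == "right" else 1.0])

    def reference_poses(self) -> dict[str, Pose]:
        return {name: b.reference_pose.copy() for name, b in self.bones.items()}

    def copy(self) -> "Skeleton":
        bones = {
            n: Bone(
                name=b.name,
                reference_pose=b.reference_pose.copy(),
                landmarks={k: v.copy() for k, v in b.landmarks.items()},
                contact_points=[
                    GroundContact(c.name, c.local.copy(), c.radius, c.region)
                    for c in b.contact_points
                ],
                fusion_group=b.fusion_group,
            )
            for n, b in self.bones.items()
        }
        return Skeleton(
            bones=bones,
            joint_pairs=list(self.joint_pairs),
            attachments=list(self.attachments),
            ground_height=self.ground_height,
            handedness=self.handedness,
            generation_seed=self.generation_seed,
            params=self.params,
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        names = set(self.bones)
        missing = set(BONE_UNITS) - names
        if missing:
            raise ValueError(f"skeleton missing bone units: {sorted(missing)}")
        extra = names - set(BONE_UNITS)
        if extra:
            raise ValueError(f"skeleton has unexpected bone units: {sorted(extra)}")
        for bone, lms in REQUIRED_LANDMARKS.items():
            for lm in lms:
                if lm not in self.bones[bone].landmarks:
                    raise ValueError(f"bone {bone!r} missing required landmark {lm!r}")
        for b in self.bones.values():
            b.reference_pose.validate()
            for c in b.contact_points:
                if c.radius <= 0:
                    raise ValueError(f"contact {c.name} on {b.name}: radius must be > 0")
                center = b.reference_pose.transform(c.local)
                pen = (self.ground_height + c.radius) - center[1]
                if pen > GROUND_PENETRATION_TOL:
                    raise ValueError(
                        f"contact {c.name} on {b.name} penetrates ground by {pen:.3f} mm "
                        f"in the reference pose"
                    )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": "footmech-skeleton-v1",
            "ground_height_mm": self.ground_height,
            "handedness": self.handedness,
            "generation_seed": int(self.generation_seed),
            "params": asdict(self.params),
            "bones": {
                n: {
                    "fusion_group": b.fusion_group,
                    "reference_pose": b.reference_pose.to_dict(),
                    "landmarks": {k: [float(x) for x in v] for k, v in b.landmarks.items()},
                    "contact_points": [
                        {
                            "name": c.name,
                            "local_mm": [float(x) for x in c.local],
                            "radius_mm": c.radius,
                            "region": c.region,
                        }
                        for c in b.contact_points
                    ],
                }
                for n, b in self.bones.items()
            },
            "joint_pairs": [asdict(p) for p in self.joint_pairs],
            "attachments": [
                {**asdict(a), "beads": [list(bd) for bd in a.beads]} for a in self.attachments
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "Skeleton":
        bones = {
            n: Bone(
                name=n,
                reference_pose=Pose.from_dict(bd["reference_pose"]),
                landmarks={k: np.array(v) for k, v in bd["landmarks"].items()},
                contact_points=[
                    GroundContact(c["name"], np.array(c["local_mm"]), c["radius_mm"], c["region"])
                    for c in bd["contact_points"]
                ],
                fusion_group=bd["fusion_group"],
            )
            for n, bd in d["bones"].items()
        }
        return cls(
            bones=bones,
            joint_pairs=[JointContactPair(**p) for p in d["joint_pairs"]],
            attachments=[
                AttachmentRecord(**{**a, "beads": tuple(tuple(bd) for bd in a["beads"])})
                for a in d["attachments"]
            ],
            ground_height=d["ground_height_mm"],
            handedness=d["handedness"],
            generation_seed=d["generation_seed"],
            params=AnatomyParams(**d["params"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "Skeleton":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# template (world coordinates, mm, at default parameters)
# ---------------------------------------------------------------------------

# bone -> body-frame origin in the world (template scale)
_ORIGINS = {
    "tibfib": (60.0, 120.0, 2.0),
    "talus": (60.0, 46.0, 0.0),
    "calcaneus": (40.0, 25.0, 5.0),
    "navicular": (105.0, 42.0, -10.0),
    "cuboid": (98.0, 26.0, 12.0),
    "cuneiforms": (122.0, 36.0, -10.0),
    "ray1": (180.0, 22.0, -26.0),
    "ray2": (185.0, 20.0, -10.0),
    "ray3": (182.0, 19.0, 1.0),
    "ray4": (170.0, 17.0, 10.0),
    "ray5": (160.0, 16.0, 20.0),
}

# measurement / load landmarks: bone -> {name: world point}
_MEASURE_LANDMARKS = {
    "tibfib": {
        "tibia_proximal": (60.0, 300.0, 2.0),
        "gastroc_proximal": (30.0, 280.0, 6.0),
    },
    "talus": {
        "talus_axis_post": (42.0, 52.0, 2.0),
        "talus_axis_head": (95.0, 39.0, 0.0),
    },
    "calcaneus": {
        "calc_inf_post": (12.0, 8.0, 3.0),
        "calc_inf_ant": (72.0, 26.0, 8.0),
        "calc_bisect_inf": (10.0, 8.0, 3.0),
        # the lateral lean of the bisection line is a parameter; the Z offset
        # is filled in by the generator from hindfoot_lean_deg
        "calc_bisect_sup": (10.0, 48.0, None),
        "achilles_insertion": (8.0, 38.0, 4.0),
        "calc_tuber_post": (4.0, 30.0, 3.0),
        "calc_cc_center": (79.0, 28.0, 12.0),
    },
    "navicular": {
        "nav_chord_med": (104.0, 40.0, -20.0),
        "nav_chord_lat": (102.0, 43.0, 1.0),
    },
    "cuboid": {
        "cub_cc_center": (83.0, 28.0, 12.0),
    },
    "ray1": {
        "mt1_axis_base": (132.0, 34.0, -24.0),
        "mt1_axis_head": (225.0, 12.0, -30.0),
    },
}

# ground contact spheres: bone -> [(name, world center, radius, region)]
# centers sit exactly at y = radius (touching the ground in neutral)
_GROUND_CONTACTS = {
    "calcaneus": [
        ("heel_med", (18.0, 10.0, -3.0), 10.0, "calcaneus"),
        ("heel_lat", (20.0, 10.0, 9.0), 10.0, "calcaneus"),
    ],
    "ray1": [("pad1", (222.0, 7.0, -28.0), 7.0, "ray1")],
    "ray2": [("pad2", (232.0, 6.0, -12.0), 6.0, "ray2")],
    "ray3": [("pad3", (227.0, 6.0, 0.0), 6.0, "ray3")],
    "ray4": [("pad4", (217.0, 5.5, 10.0), 5.5, "ray4")],
    "ray5": [("pad5", (207.0, 5.5, 21.0), 5.5, "ray5")],
}

# articular joints. Two articulation kinds are modeled:
#
# * "socket": four contact pads at +/- two tangent offsets around the joint
#   center, facet normals splayed toward the center — a congruent, concave
#   proximal surface that resists shear and tilt while compressed (ankle
#   mortise, subtalar facets);
# * "ball": a single central compression-only contact — rotation-free, so
#   the spanning ligaments alone govern joint angulation (the column
#   joints; this is what lets ligament attenuation express as deformity).
#
# Fields:
# (name, bone_a, bone_b, center, normal a->b, tangent1, r1, tangent2, r2,
#  splay_deg, kind)
_JOINTS = [
    # ankle mortise: a hinge — the fore-aft pad splay matches the talar dome
    # curvature (free plantar/dorsiflexion about the dome axis), while the
    # side pads' vertical normals resist inversion/eversion roll
    ("ankle", "tibfib", "talus",
     (58.0, 50.0, 1.0), (0.0, -1.0, 0.0), (1.0, 0.0, 0.0), 8.0, (0.0, 0.0, 1.0), 9.0, (25.0, 0.0), "socket"),
    # the subtalar load path runs medially (posterior facet + sustentaculum),
    # placing the joint's effective inversion/eversion pivot medial of the
    # intact heel contact
    ("subtalar_posterior", "talus", "calcaneus",
     (48.0, 40.0, -2.0), (0.0, -1.0, 0.0), (1.0, 0.0, 0.0), 6.0, (0.0, 0.0, 1.0), 4.0, 20.0, "socket"),
    # sustentaculum tali: a horizontal medial shelf; the talar head pressing
    # it down rolls the calcaneus into eversion (the valgus coupling the
    # failing spring ligament unmasks)
    ("subtalar_anterior", "talus", "calcaneus",
     (62.0, 29.0, -10.0), (0.0, -1.0, 0.0), (1.0, 0.0, 0.0), 5.0, (0.0, 0.0, 1.0), 4.0, 15.0, "socket"),
    # talonavicular joint: the acetabulum pedis — a spherical cup whose pad
    # normals converge at the talar head center (8 mm behind the articular
    # ring), so the head rotates freely in the socket (angulation is owned
    # by the spring complex and capsule) while subluxation is blocked
    ("talonavicular", "talus", "navicular",
     (98.0, 38.5, -4.5), (1.0, -0.45, -0.3), (0.0, 1.0, 0.0), 5.0, (0.0, 0.0, 1.0), 5.5,
     (32.0, 34.5), "socket"),
    ("calcaneocuboid", "calcaneus", "cuboid",
     (80.0, 29.0, 11.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), 4.5, (0.0, 0.0, 1.0), 4.5, 30.0, "socket"),
    ("naviculocuneiform", "navicular", "cuneiforms",
     (114.0, 39.0, -10.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), 4.0, (0.0, 0.0, 1.0), 5.0, 30.0, "socket"),
    ("cuneocuboid", "cuneiforms", "cuboid",
     (124.0, 29.0, 3.0), (0.0, 0.0, 1.0), (1.0, 0.0, 0.0), 3.0, (0.0, 1.0, 0.0), 3.0, 20.0, "socket"),
    ("cubonavicular", "navicular", "cuboid",
     (105.0, 31.0, 2.0), (0.0, 0.0, 1.0), (1.0, 0.0, 0.0), 3.0, (0.0, 1.0, 0.0), 3.0, 20.0, "socket"),
    ("tarsometatarsal1", "cuneiforms", "ray1",
     (130.0, 34.0, -22.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), 4.0, (0.0, 0.0, 1.0), 4.0, 30.0, "socket"),
    ("tarsometatarsal2", "cuneiforms", "ray2",
     (133.0, 32.0, -8.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), 3.5, (0.0, 0.0, 1.0), 3.5, 30.0, "socket"),
    ("tarsometatarsal3", "cuneiforms", "ray3",
     (131.0, 30.0, 2.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), 3.5, (0.0, 0.0, 1.0), 3.5, 30.0, "socket"),
    ("tarsometatarsal4", "cuboid", "ray4",
     (118.0, 25.0, 9.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), 4.0, (0.0, 0.0, 1.0), 4.0, 30.0, "socket"),
    ("tarsometatarsal5", "cuboid", "ray5",
     (110.0, 23.0, 19.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), 4.0, (0.0, 0.0, 1.0), 4.0, 30.0, "socket"),
]

#: separation between paired pad sites across each joint (mm)
_JOINT_GAP = 4.0

#: azimuthal pad-normal twist (deg) per socket: alternating helical tilt
#: that lets the articular congruence resist torsion about the joint
#: normal (the saddle shape of the calcaneocuboid joint, the screw-like
#: subtalar facets). Joints not listed have torsion-free pads.
_SOCKET_TWIST = {
    "calcaneocuboid": 25.0,
}

#: articular clearance (mm): how far a joint can settle before its bony
#: contacts engage. Within the clearance envelope, joint position is
#: governed purely by ligaments — at the talonavicular joint the spring
#: hammock is functionally part of the socket, so the talar head rides on
#: it before bottoming out on bone. Joints not listed engage immediately.
_JOINT_CLEARANCE: dict[str, float] = {}


def _joint_axes(entry):
    name, ba, bb, center, n, t1, r1, t2, r2, splay, kind = entry
    c = np.asarray(center, dtype=float)
    n = np.asarray(n, dtype=float)
    n = n / np.linalg.norm(n)
    u1 = np.asarray(t1, dtype=float)
    u1 = u1 - np.dot(u1, n) * n
    u1 = u1 / np.linalg.norm(u1)
    u2 = np.cross(n, u1) if t2 is None else np.asarray(t2, dtype=float)
    u2 = u2 - np.dot(u2, n) * n
    u2 = u2 / np.linalg.norm(u2)
    return name, ba, bb, c, n, u1, r1, u2, r2, splay, kind


def _joint_pad_specs():
    """Expand the joint table into per-contact records.

    Returns (joint, bone_a, pt_a, bone_b, pt_b, kind): four splayed pads
    for a socket, one central compression element for a ball.
    """
    pads = []
    for entry in _JOINTS:
        name, ba, bb, c, n, u1, r1, u2, r2, splay, kind = _joint_axes(entry)
        if kind == "ball":
            pads.append((name, ba, c, bb, c + n * _JOINT_GAP, "ball"))
            continue
        s1, s2 = (splay, splay) if np.isscalar(splay) else splay
        tw = np.radians(_SOCKET_TWIST.get(name, 0.0))
        for i, (u, r, s_deg) in enumerate(((u1, r1, s1), (-u1, r1, s1), (u2, r2, s2), (-u2, r2, s2))):
            s = np.radians(s_deg)
            pa = c + u * r
            # concave socket: pad normal tilts back toward the joint center,
            # plus an alternating helical twist that engages torsion
            w = np.cross(n, u / np.linalg.norm(u))
            sign = 1.0 if i % 2 == 0 else -1.0
            pn = np.cos(s) * n - np.sin(s) * u + sign * np.sin(tw) * w
            pn = pn / np.linalg.norm(pn)
            pb = pa + pn * _JOINT_GAP
            pads.append((name, ba, pa, bb, pb, "facet"))
    return pads


#: capsule cage geometry: fiber ring radius margin, proximal/distal reach
#: (mm) and fiber crossing angle (deg) about the joint normal
_CAGE_MARGIN = 1.0
_CAGE_REACH = 2.0
_CAGE_CROSS_DEG = 35.0

#: the mobile transverse tarsal (Chopart) joints: their plantar capsule
#: portion IS a named plantar ligament (spring complex medially, long and
#: short plantar laterally), so their generated cage keeps only the dorsal
#: fibers and the arch-fold (plantar gapping) mode is owned by the named
#: structures the disease model attenuates. The naviculocuneiform,
#: tarsometatarsal and cuboid-side joints are bone-locked in a real foot
#: and keep their full circumferential cage.
_DORSAL_ONLY_CAGES = {
    "talonavicular",
}

#: bone-locked joints (the naviculocuneiform and tarsometatarsal rows and
#: the cuboid-side junctions are clinically near-immobile): their capsule
#: cage carries eight fibers instead of four
_DENSE_CAGES = {
    "naviculocuneiform",
    "cuneocuboid",
    "cubonavicular",
    "tarsometatarsal1",
    "tarsometatarsal2",
    "tarsometatarsal3",
    "tarsometatarsal4",
    "tarsometatarsal5",
}


def _joint_cage_specs():
    """Oblique circumferential capsule fibers around every articular joint.

    Fibers sit on a ring around the joint center at azimuths between the
    contact pads and cross the joint plane at alternating +/- azimuthal
    offsets, so the cage resists joint distraction, shear and torsion —
    the moment-bearing role real joint capsules play. Azimuth 0 is the
    first tangent direction (dorsal for the column joints).
    """
    specs = []
    for entry in _JOINTS:
        name, ba, bb, c, n, u1, r1, u2, r2, splay, kind = _joint_axes(entry)
        r_f = max(r1, r2) + _CAGE_MARGIN

        def ring(azim_deg):
            a = np.radians(azim_deg)
            return r_f * (np.cos(a) * u1 + np.sin(a) * u2)

        if name in _DORSAL_ONLY_CAGES:
            azimuths = (45.0, 315.0)
        elif name in _DENSE_CAGES:
            azimuths = (22.5, 67.5, 112.5, 157.5, 202.5, 247.5, 292.5, 337.5)
        else:
            azimuths = (45.0, 135.0, 225.0, 315.0)
        for k, az in enumerate(azimuths):
            cross = _CAGE_CROSS_DEG if k % 2 == 0 else -_CAGE_CROSS_DEG
            pa = c - _CAGE_REACH * n + ring(az + cross / 2.0)
            pb = c + _CAGE_REACH * n + ring(az - cross / 2.0)
            specs.append(
                (f"{name}_cage_{k + 1}", f"capsule_{name}", "generic",
                 ba, tuple(pa), bb, tuple(pb), ())
            )
    return specs

_BEAD_RADIUS = 5.0

# ligament band specs:
# (band, group, structure, origin bone, world pt, insertion bone, world pt, beads)
# beads: ((bone, world pt), ...)
_BAND_SPECS = [
    # --- named structures (stiffness table of the disease model) ----------
    # the spring (calcaneonavicular) complex is the hammock under the talar
    # head: each band runs from the sustentaculum to the dorsomedial
    # navicular over a bead on the plantar-medial head surface that sits
    # below the attachment chord, so head subsidence and medial drift
    # lengthen the wrapped path (pulley wrapping)
    ("spring_superomedial", "spring_superomedial", "spring_superomedial",
     "calcaneus", (60.0, 31.0, -9.0), "navicular", (100.0, 38.0, -9.0),
     (("talus", (92.0, 32.0, -8.0)),)),
    ("spring_inferomedial", "spring_inferomedial", "spring_inferomedial",
     "calcaneus", (62.0, 29.0, -8.0), "navicular", (100.0, 36.0, -11.0),
     (("talus", (88.0, 31.0, -6.0)),)),
    ("talocalcaneal_interosseous", "talocalcaneal_interosseous", "talocalcaneal_interosseous",
     "talus", (55.0, 40.0, -2.0), "calcaneus", (55.0, 35.0, -2.0), ()),
    # plantar fascia: 5 bands, medial -> lateral, wrapping under the MT heads
    ("plantar_fascia_1", "plantar_fascia", "plantar_fascia",
     "calcaneus", (24.0, 7.0, -5.0), "ray1", (238.0, 5.0, -28.0),
     (("ray1", (224.0, 4.0, -28.0)),)),
    ("plantar_fascia_2", "plantar_fascia", "plantar_fascia",
     "calcaneus", (24.0, 7.0, -2.0), "ray2", (244.0, 4.0, -12.0),
     (("ray2", (234.0, 3.5, -12.0)),)),
    ("plantar_fascia_3", "plantar_fascia", "plantar_fascia",
     "calcaneus", (24.0, 7.0, 0.0), "ray3", (240.0, 4.0, 0.0),
     (("ray3", (229.0, 3.5, 0.0)),)),
    ("plantar_fascia_4", "plantar_fascia", "plantar_fascia",
     "calcaneus", (24.0, 7.0, 3.0), "ray4", (232.0, 4.0, 10.0),
     (("ray4", (219.0, 3.0, 10.0)),)),
    ("plantar_fascia_5", "plantar_fascia", "plantar_fascia",
     "calcaneus", (24.0, 7.0, 6.0), "ray5", (222.0, 4.0, 20.0),
     (("ray5", (209.0, 3.0, 21.0)),)),
    # long plantar: 8 bands, medial -> lateral, wrapping over the cuboid ridge
    ("long_plantar_1", "long_plantar", "long_and_short_plantar",
     "calcaneus", (34.0, 9.0, -2.0), "ray2", (139.0, 24.0, -8.0),
     (("cuboid", (94.0, 14.0, 6.0)),)),
    ("long_plantar_2", "long_plantar", "long_and_short_plantar",
     "calcaneus", (36.0, 9.0, 0.0), "ray2", (141.0, 24.0, -4.0),
     (("cuboid", (94.0, 14.0, 8.0)),)),
    ("long_plantar_3", "long_plantar", "long_and_short_plantar",
     "calcaneus", (38.0, 9.0, 2.0), "ray3", (137.0, 23.0, 0.0),
     (("cuboid", (94.0, 14.0, 10.0)),)),
    ("long_plantar_4", "long_plantar", "long_and_short_plantar",
     "calcaneus", (40.0, 10.0, 4.0), "ray3", (139.0, 23.0, 3.0),
     (("cuboid", (94.0, 14.0, 12.0)),)),
    ("long_plantar_5", "long_plantar", "long_and_short_plantar",
     "calcaneus", (42.0, 10.0, 6.0), "ray4", (126.0, 21.0, 8.0),
     (("cuboid", (94.0, 14.5, 14.0)),)),
    ("long_plantar_6", "long_plantar", "long_and_short_plantar",
     "calcaneus", (44.0, 10.0, 8.0), "ray4", (128.0, 21.0, 11.0),
     (("cuboid", (94.0, 14.5, 16.0)),)),
    ("long_plantar_7", "long_plantar", "long_and_short_plantar",
     "calcaneus", (45.0, 11.0, 9.0), "ray5", (118.0, 19.0, 17.0),
     (("cuboid", (94.0, 15.0, 17.5)),)),
    ("long_plantar_8", "long_plantar", "long_and_short_plantar",
     "calcaneus", (46.0, 11.0, 10.0), "ray5", (118.0, 19.0, 21.0),
     (("cuboid", (94.0, 15.0, 19.0)),)),
    ("short_plantar", "short_plantar", "long_and_short_plantar",
     "calcaneus", (56.0, 13.0, 9.0), "cuboid", (88.0, 16.0, 12.0), ()),
    ("plantar_metatarsocuneiform_1", "plantar_metatarsocuneiform", "plantar_metatarsocuneiform",
     "cuneiforms", (120.0, 27.0, -16.0), "ray1", (138.0, 26.0, -23.0), ()),
    ("plantar_metatarsocuneiform_2", "plantar_metatarsocuneiform", "plantar_metatarsocuneiform",
     "cuneiforms", (122.0, 26.0, -8.0), "ray2", (141.0, 25.0, -9.0), ()),
    ("plantar_metatarsocuneiform_3", "plantar_metatarsocuneiform", "plantar_metatarsocuneiform",
     "cuneiforms", (121.0, 25.0, 0.0), "ray3", (139.0, 24.0, 1.0), ()),
    ("plantar_naviculocuneiform_1", "plantar_naviculocuneiform", "plantar_naviculocuneiform",
     "navicular", (106.0, 32.0, -14.0), "cuneiforms", (120.0, 30.0, -16.0), ()),
    ("plantar_naviculocuneiform_2", "plantar_naviculocuneiform", "plantar_naviculocuneiform",
     "navicular", (107.0, 32.0, -6.0), "cuneiforms", (121.0, 30.0, -8.0), ()),
    ("deltoid_deep_1", "deltoid_deep", "deltoid_deep",
     "tibfib", (53.0, 57.0, -13.0), "talus", (55.0, 47.0, -9.0), ()),
    ("deltoid_deep_2", "deltoid_deep", "deltoid_deep",
     "tibfib", (57.0, 56.0, -13.0), "talus", (59.0, 46.0, -9.0), ()),
    ("deltoid_superficial_anterior", "deltoid_superficial_anterior", "deltoid_superficial_anterior",
     "tibfib", (56.0, 58.0, -14.0), "navicular", (101.0, 44.0, -17.0), ()),
    ("deltoid_superficial_posterior", "deltoid_superficial_posterior", "deltoid_superficial_posterior",
     "tibfib", (50.0, 56.0, -13.0), "calcaneus", (58.0, 32.0, -9.0), ()),
    # --- generic capsular stabilizers (mean stiffness of named baselines) --
    ("ankle_capsule_anterior", "ankle_ligaments", "generic",
     "tibfib", (64.0, 58.0, 0.0), "talus", (68.0, 50.0, 0.0), ()),
    ("ankle_capsule_posterior", "ankle_ligaments", "generic",
     "tibfib", (44.0, 58.0, 2.0), "talus", (44.0, 50.0, 4.0), ()),
    ("ankle_lateral_talar", "ankle_ligaments", "generic",
     "tibfib", (62.0, 54.0, 14.0), "talus", (70.0, 46.0, 10.0), ()),
    ("ankle_lateral_calcaneal", "ankle_ligaments", "generic",
     "tibfib", (60.0, 54.0, 15.0), "calcaneus", (56.0, 32.0, 12.0), ()),
    ("intermetatarsal_12", "intermetatarsal", "generic",
     "ray1", (150.0, 28.0, -20.0), "ray2", (152.0, 27.0, -10.0), ()),
    ("intermetatarsal_23", "intermetatarsal", "generic",
     "ray2", (150.0, 26.0, -9.0), "ray3", (148.0, 25.0, 0.0), ()),
    ("intermetatarsal_34", "intermetatarsal", "generic",
     "ray3", (146.0, 24.0, 1.0), "ray4", (138.0, 23.0, 9.0), ()),
    ("intermetatarsal_45", "intermetatarsal", "generic",
     "ray4", (136.0, 22.0, 10.0), "ray5", (130.0, 21.0, 19.0), ()),
    # Lisfranc ligament: ties the medial cuneiform to the 2nd ray base and
    # locks the tarsometatarsal complex in the transverse plane
    ("lisfranc", "lisfranc", "generic",
     "cuneiforms", (127.0, 31.0, -18.0), "ray2", (136.0, 29.0, -9.0), ()),
    # deep transverse metatarsal ligaments: couple the ray heads so the
    # forefoot fan swings as one transverse arch
    ("transverse_metatarsal_12", "transverse_metatarsal", "generic",
     "ray1", (218.0, 10.0, -27.0), "ray2", (226.0, 9.0, -13.0), ()),
    ("transverse_metatarsal_23", "transverse_metatarsal", "generic",
     "ray2", (228.0, 9.0, -11.0), "ray3", (223.0, 9.0, -1.0), ()),
    ("transverse_metatarsal_34", "transverse_metatarsal", "generic",
     "ray3", (225.0, 9.0, 1.0), "ray4", (213.0, 8.0, 9.0), ()),
    ("transverse_metatarsal_45", "transverse_metatarsal", "generic",
     "ray4", (215.0, 8.0, 11.0), "ray5", (203.0, 8.0, 20.0), ()),
]

# template values the scaling is defined against
_TEMPLATE_LENGTH = 250.0
_TEMPLATE_ARCH_FRACTION = 0.24
_TEMPLATE_WIDTH = 90.0


def build_skeleton(params: AnatomyParams | None = None, seed: int = 0) -> Skeleton:
    """Generate a synthetic right (or mirrored left) foot skeleton.

    Deterministic: the same ``(params, seed)`` yields bit-identical
    coordinates. Randomness is confined to small uniform jitter applied to
    every landmark (ground-contact centers are jittered only in the
    horizontal plane so the neutral pose keeps resting on the ground).
    """
    params = params if params is not None else AnatomyParams()
    params.validate()
    rng = np.random.default_rng(seed)

    sx = params.foot_length_mm / _TEMPLATE_LENGTH
    sy = (params.arch_height_fraction * params.foot_length_mm) / (
        _TEMPLATE_ARCH_FRACTION * _TEMPLATE_LENGTH
    )
    sz = params.foot_width_mm / _TEMPLATE_WIDTH
    scale = np.array([sx, sy, sz])
    mirror = -1.0 if params.handedness == "left" else 1.0
    j = params.jitter_mm

    def _world(pt) -> np.ndarray:
        return np.asarray(pt, dtype=float) * scale

    def _jitter3() -> np.ndarray:
        return rng.uniform(-j, j, size=3)

    # landmark world coordinates are assembled first (template order), then
    # converted to bone-local frames
    world_landmarks: dict[str, dict[str, np.ndarray]] = {n: {} for n in BONE_UNITS}

    for bone, lms in _MEASURE_LANDMARKS.items():
        for name, pt in lms.items():
            if name == "calc_bisect_sup":
                # neutral hindfoot lean: bisection top tips medially by the
                # configured valgus angle (right foot: medial = -Z)
                inf = np.asarray(_MEASURE_LANDMARKS["calcaneus"]["calc_bisect_inf"], dtype=float)
                height = (pt[1] - inf[1]) * sy
                zoff = -height * np.tan(np.radians(params.hindfoot_lean_deg))
                base = np.array([pt[0] * sx, pt[1] * sy, inf[2] * sz + zoff])
                world_landmarks[bone][name] = base + _jitter3()
            else:
                world_landmarks[bone][name] = _world(pt) + _jitter3()

    ground: dict[str, list[tuple[str, np.ndarray, float, str]]] = {n: [] for n in BONE_UNITS}
    for bone, contacts in _GROUND_CONTACTS.items():
        for name, pt, radius, region in contacts:
            r = radius * sy
            center = _world(pt)
            center[1] = r  # rest exactly on the ground plane
            dj = rng.uniform(-j, j, size=2)
            center[0] += dj[0]
            center[2] += dj[1]
            ground[bone].append((name, center, r, region))

    joint_pairs_world = []
    for i, (joint, ba, pa, bb, pb, kind) in enumerate(_joint_pad_specs()):
        # one shared jitter per pad keeps the facet normal and gap exact
        dj = _jitter3()
        wa = _world(pa) + dj
        wb = _world(pb) + dj
        gap = float(np.linalg.norm(wb - wa)) - _JOINT_CLEARANCE.get(joint, 0.0)
        la = f"jc_{joint}_{i}_a"
        lb = f"jc_{joint}_{i}_b"
        ln = f"jc_{joint}_{i}_n"
        world_landmarks[ba][la] = wa
        world_landmarks[bb][lb] = wb
        world_landmarks[ba][ln] = wa + (wb - wa) / gap  # unit normal tip
        joint_pairs_world.append((joint, ba, la, bb, lb, ln, gap, kind))

    attachments: list[AttachmentRecord] = []
    for band, group, structure, ob, op, ib, ip, beads in _BAND_SPECS + _joint_cage_specs():
        lo, li = f"att_{band}_org", f"att_{band}_ins"
        world_landmarks[ob][lo] = _world(op) + _jitter3()
        world_landmarks[ib][li] = _world(ip) + _jitter3()
        bead_records = []
        for k, (bead_bone, bead_pt) in enumerate(beads):
            lbk = f"att_{band}_bead{k}"
            world_landmarks[bead_bone][lbk] = _world(bead_pt) + _jitter3()
            bead_records.append((bead_bone, lbk, _BEAD_RADIUS))
        attachments.append(
            AttachmentRecord(
                band=band,
                group=group,
                structure=structure,
                origin_bone=ob,
                origin_landmark=lo,
                insertion_bone=ib,
                insertion_landmark=li,
                beads=tuple(bead_records),
            )
        )

    # mirror for a left foot (jitter included, so the left foot is the exact
    # mirror image of the right foot generated from the same seed)
    if mirror < 0:
        for bone in world_landmarks:
            for name in world_landmarks[bone]:
                world_landmarks[bone][name] = world_landmarks[bone][name] * np.array([1, 1, -1.0])
        for bone in ground:
            ground[bone] = [
                (n, c * np.array([1, 1, -1.0]), r, reg) for (n, c, r, reg) in ground[bone]
            ]

    bones: dict[str, Bone] = {}
    for name in BONE_UNITS:
        origin = _world(_ORIGINS[name])
        if mirror < 0:
            origin = origin * np.array([1, 1, -1.0])
        pose = Pose(position=origin)
        bones[name] = Bone(
            name=name,
            reference_pose=pose,
            landmarks={k: v - origin for k, v in world_landmarks[name].items()},
            contact_points=[
                GroundContact(n, c - origin, r, reg) for (n, c, r, reg) in ground[name]
            ],
        )

    skeleton = Skeleton(
        bones=bones,
        joint_pairs=[
            JointContactPair(joint, ba, la, bb, lb, ln, gap, kind)
            for (joint, ba, la, bb, lb, ln, gap, kind) in joint_pairs_world
        ],
        attachments=attachments,
        ground_height=0.0,
        handedness=params.handedness,
        generation_seed=int(seed),
        params=params,
    )
    skeleton.validate()
    return skeleton


def attachment_map(skeleton: Skeleton) -> list[AttachmentRecord]:
    """Return the named ligament-attachment table of a skeleton.

    Every record is checked against the skeleton's landmark tables; a band
    whose origin, insertion or bead landmark is missing is rejected by name.
    """
    for rec in skeleton.attachments:
        refs = [(rec.origin_bone, rec.origin_landmark), (rec.insertion_bone, rec.insertion_landmark)]
        refs += [(b, lm) for (b, lm, _r) in rec.beads]
        for bone, lm in refs:
            if bone not in skeleton.bones or lm not in skeleton.bones[bone].landmarks:
                raise ValueError(f"band {rec.band!r}: attachment landmark {bone}:{lm} missing")
    return list(skeleton.attachments)
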