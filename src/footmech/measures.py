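"""Radiographic measurement suite computed from a solved equilibrium.

Six joint angles are measured the way they are read off clinical
radiographs, from projections of landmark-defined axes:

* lateral view (sagittal projection): talo-first-metatarsal angle
  ``L-T1MT`` (signed; negative = drooping medial arch), talocalcaneal
  angle ``L-TC`` (unsigned), calcaneal pitch ``L-CP`` (unsigned
  inclination of the calcaneal inferior border vs the ground);
* raised AP view (viewing direction elevated 70 degrees from the
  horizontal within the sagittal plane): AP talo-first-metatarsal angle
  ``AP-T1MT`` and talonavicular coverage angle ``AP-TN`` (both signed,
  positive = adduction, negative = abduction);
* posterior view (coronal projection): hindfoot varus/valgus angle,
  reported on a +90-degree-shifted scale so that a vertical calcaneal
  bisection line reads 90 (values above 90 = valgus, below = varus).

All operations are invariant under a global rigid transform applied to
every pose together with the ground frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import Skeleton
from .geometry import Pose
from .ligaments import LigamentBand, path_length
from .mechanics import EquilibriumResult, ground_region_loads, joint_contact_force, GROUND_REGIONS

__all__ = [
    "ReferenceFrame",
    "AngleSet",
    "MeasureReport",
    "lateral_angles",
    "ap_angles",
    "hindfoot_angle",
    "strain_tables",
    "measure_all",
    "AP_VIEW_ELEVATION_DEG",
]

AP_VIEW_ELEVATION_DEG = 70.0


@dataclass(frozen=True)
class ReferenceFrame:
    """Ground/radiographic frame: anterior and superior unit directions.

    The lateral direction completes the right-handed triad for the given
    handedness; passing a rotated frame together with rigidly transformed
    poses leaves every angle unchanged.
    """

    anterior: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    superior: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    handedness: str = "right"

    def __post_init__(self):
        a = np.asarray(self.anterior, dtype=float)
        s = np.asarray(self.superior, dtype=float)
        object.__setattr__(self, "anterior", a / np.linalg.norm(a))
        object.__setattr__(self, "superior", s / np.linalg.norm(s))
        if abs(np.dot(self.anterior, self.superior)) > 1e-9:
            raise ValueError("frame axes must be orthogonal")

    @property
    def lateral(self) -> np.ndarray:
        v = np.cross(self.anterior, self.superior)
        return v if self.handedness == "right" else -v

    @property
    def medial(self) -> np.ndarray:
        return -self.lateral

    @classmethod
    def for_skeleton(cls, skeleton: Skeleton) -> "ReferenceFrame":
        return cls(handedness=skeleton.handedness)


@dataclass(frozen=True)
class AngleSet:
    """The six radiographic angles, degrees (raw precision)."""

    l_t1mt: float
    l_tc: float
    l_cp: float
    ap_t1mt: float
    ap_tn: float
    hindfoot: float

    def rounded(self) -> dict[str, float]:
        """One-decimal reporting, matching radiographic reading precision."""
        return {k: round(v, 1) for k, v in self.__dict__.items()}


def _axis(skeleton, poses, bone, lm_from, lm_to) -> np.ndarray:
    return skeleton.world_landmark(bone, lm_to, poses) - skeleton.world_landmark(
        bone, lm_from, poses
    )


def _sagittal_angle(v: np.ndarray, frame: ReferenceFrame) -> float:
    """Inclination (deg) of ``v`` in the sagittal plane; + = pointing up."""
    return float(np.degrees(np.arctan2(np.dot(v, frame.superior), np.dot(v, frame.anterior))))


def lateral_angles(
    poses: dict[str, Pose], skeleton: Skeleton, frame: ReferenceFrame | None = None
) -> tuple[float, float, float]:
    """(L-T1MT, L-TC, L-CP) from the lateral (sagittal) projection."""
    frame = frame if frame is not None else ReferenceFrame.for_skeleton(skeleton)
    talar = _axis(skeleton, poses, "talus", "talus_axis_post", "talus_axis_head")
    mt1 = _axis(skeleton, poses, "ray1", "mt1_axis_base", "mt1_axis_head")
    calc = _axis(skeleton, poses, "calcaneus", "calc_inf_post", "calc_inf_ant")
    a_tal = _sagittal_angle(talar, frame)
    a_mt1 = _sagittal_angle(mt1, frame)
    a_cal = _sagittal_angle(calc, frame)
    l_t1mt = _wrap(a_tal - a_mt1)  # negative when the construct apex is plantar
    l_tc = abs(_wrap(a_tal - a_cal))
    l_cp = abs(a_cal)
    return l_t1mt, l_tc, l_cp


def _ap_projection(frame: ReferenceFrame):
    """In-plane axes of the raised AP view: (view normal, in-plane anterior)."""
    el = np.radians(AP_VIEW_ELEVATION_DEG)
    n = np.cos(el) * frame.anterior + np.sin(el) * frame.superior
    e1 = frame.anterior - np.dot(frame.anterior, n) * n
    return n, e1 / np.linalg.norm(e1)


def _medial_deviation(v: np.ndarray, n: np.ndarray, e1: np.ndarray, medial: np.ndarray) -> float:
    vp = v - np.dot(v, n) * n
    x = np.dot(vp, e1)
    if abs(x) < 1e-12 and abs(np.dot(vp, medial)) < 1e-12:
        raise ValueError("axis is parallel to the AP viewing direction")
    return float(np.degrees(np.arctan2(np.dot(vp, medial), x)))


def ap_angles(
    poses: dict[str, Pose], skeleton: Skeleton, frame: ReferenceFrame | None = None
) -> tuple[float, float]:
    """(AP-T1MT, AP-TN) from the 70-degree raised AP projection.

    AP-T1MT is the medial deviation of the first-metatarsal axis relative
    to the talar axis; AP-TN is the medial deviation of the navicular
    articular chord's anterior normal relative to the talar axis
    (coverage). Positive = adduction, negative = abduction.
    """
    frame = frame if frame is not None else ReferenceFrame.for_skeleton(skeleton)
    n, e1 = _ap_projection(frame)
    medial = frame.medial
    talar = _axis(skeleton, poses, "talus", "talus_axis_post", "talus_axis_head")
    mt1 = _axis(skeleton, poses, "ray1", "mt1_axis_base", "mt1_axis_head")
    chord = _axis(skeleton, poses, "navicular", "nav_chord_med", "nav_chord_lat")

    dev_tal = _medial_deviation(talar, n, e1, medial)
    dev_mt1 = _medial_deviation(mt1, n, e1, medial)
    ap_t1mt = _wrap(dev_mt1 - dev_tal)

    # anterior normal of the navicular chord within the projection plane
    cp = chord - np.dot(chord, n) * n
    perp = np.cross(n, cp)
    if np.dot(perp, e1) < 0:
        perp = -perp
    dev_nav = _medial_deviation(perp, n, e1, medial)
    ap_tn = _wrap(dev_nav - dev_tal)
    return ap_t1mt, ap_tn


def hindfoot_angle(
    poses: dict[str, Pose], skeleton: Skeleton, frame: ReferenceFrame | None = None
) -> float:
    """Hindfoot varus/valgus on the +90-shifted scale (90 = vertical)."""
    frame = frame if frame is not None else ReferenceFrame.for_skeleton(skeleton)
    u = _axis(skeleton, poses, "calcaneus", "calc_bisect_inf", "calc_bisect_sup")
    # coronal projection (normal = anterior axis). Valgus (eversion) tips
    # the bisection top medially: the heel, the distal segment, deviates
    # laterally — so a medial lean of the top reads above 90.
    lean = np.degrees(np.arctan2(np.dot(u, frame.medial), np.dot(u, frame.superior)))
    return 90.0 + float(lean)


def _wrap(angle_deg: float) -> float:
    return float((angle_deg + 180.0) % 360.0 - 180.0)


def all_angles(
    poses: dict[str, Pose], skeleton: Skeleton, frame: ReferenceFrame | None = None
) -> AngleSet:
    l_t1mt, l_tc, l_cp = lateral_angles(poses, skeleton, frame)
    ap_t1mt, ap_tn = ap_angles(poses, skeleton, frame)
    return AngleSet(l_t1mt, l_tc, l_cp, ap_t1mt, ap_tn, hindfoot_angle(poses, skeleton, frame))


def strain_tables(
    result: EquilibriumResult,
    skeleton: Skeleton,
    bands: list[LigamentBand],
    reference_lengths: dict[str, float],
) -> tuple[list[float], list[float]]:
    """(long plantar strains [8], plantar fascia strains [5]), in % strain.

    Ordered medial to lateral; reference lengths come from the unloaded
    equilibrium of the same scenario.
    """
    by_name = {b.name: b for b in bands}

    def collect(prefix: str, count: int) -> list[float]:
        names = [f"{prefix}_{i}" for i in range(1, count + 1)]
        missing = [n for n in names if n not in by_name]
        if missing:
            raise ValueError(f"band-count mismatch: missing {missing}")
        out = []
        for n in names:
            L = path_length(by_name[n], skeleton, result.poses)
            L_ref = reference_lengths[n]
            out.append(100.0 * (L - L_ref) / L_ref)
        return out

    return collect("long_plantar", 8), collect("plantar_fascia", 5)


@dataclass
class MeasureReport:
    """The full output block of one scenario."""

    scenario: str
    angles: AngleSet
    long_plantar_strains_pct: list[float]  # 8 values, medial -> lateral
    plantar_fascia_strains_pct: list[float]  # 5 values, medial -> lateral
    calcaneocuboid_force_N: float | None  # None = not applicable (fused)
    plantar_loads_N: dict[str, float]  # keyed by region
    converged: bool = True

    def __post_init__(self):
        if len(self.long_plantar_strains_pct) != 8:
            raise ValueError("long plantar strain array must have exactly 8 entries")
        if len(self.plantar_fascia_strains_pct) != 5:
            raise ValueError("plantar fascia strain array must have exactly 5 entries")

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "converged": bool(self.converged),
            "angles_deg": {k: float(v) for k, v in self.angles.__dict__.items()},
            "long_plantar_strains_pct": [float(v) for v in self.long_plantar_strains_pct],
            "plantar_fascia_strains_pct": [float(v) for v in self.plantar_fascia_strains_pct],
            "calcaneocuboid_force_N": (
                None if self.calcaneocuboid_force_N is None else float(self.calcaneocuboid_force_N)
            ),
            "plantar_loads_N": {k: float(v) for k, v in self.plantar_loads_N.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeasureReport":
        return cls(
            scenario=d["scenario"],
            angles=AngleSet(**d["angles_deg"]),
            long_plantar_strains_pct=list(d["long_plantar_strains_pct"]),
            plantar_fascia_strains_pct=list(d["plantar_fascia_strains_pct"]),
            calcaneocuboid_force_N=d["calcaneocuboid_force_N"],
            plantar_loads_N=dict(d["plantar_loads_N"]),
            converged=d.get("converged", True),
        )

    def rounded(self) -> dict:
        """Display precision: angles 0.1 deg, strains 0.1 %, loads 1 N."""
        return {
            "scenario": self.scenario,
            "angles_deg": self.angles.rounded(),
            "long_plantar_strains_pct": [round(v, 1) for v in self.long_plantar_strains_pct],
            "plantar_fascia_strains_pct": [round(v, 1) for v in self.plantar_fascia_strains_pct],
            "calcaneocuboid_force_N": (
                None
                if self.calcaneocuboid_force_N is None
                else round(self.calcaneocuboid_force_N)
            ),
            "plantar_loads_N": {k: round(v) for k, v in self.plantar_loads_N.items()},
        }


def measure_all(
    result: EquilibriumResult,
    skeleton: Skeleton,
    bands: list[LigamentBand],
    reference_lengths: dict[str, float],
    scenario: str = "",
) -> MeasureReport:
    """Aggregate all measurement families from a converged equilibrium."""
    if not result.converged:
        raise ValueError("measure_all requires a converged equilibrium")
    lp, pf = strain_tables(result, skeleton, bands, reference_lengths)
    fused = (
        skeleton.bones["calcaneus"].fusion_group == skeleton.bones["cuboid"].fusion_group
    )
    cc = None if fused else joint_contact_force(result, "calcaneus", "cuboid")
    loads = ground_region_loads(result)
    return MeasureReport(
        scenario=scenario,
        angles=all_angles(result.poses, skeleton),
        long_plantar_strains_pct=lp,
        plantar_fascia_strains_pct=pf,
        calcaneocuboid_force_N=cc,
        plantar_loads_N={r: loads.get(r, 0.0) for r in GROUND_REGIONS},
        converged=result.converged,
    )
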