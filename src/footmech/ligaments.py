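"""Tension-only ligament band mechanics.

Every band is a linear spring that can only pull: tension
``T = k * max(0, L - L0)`` where ``L`` is the current path length through
any via beads and ``L0`` the slack (rest) length. Beads act as
frictionless via points redirecting the path around bone; their radius is
kept for mesh export only and does not enter the length computation.

Rest lengths are calibrated from the neutral reference pose and an
in-situ (pre-)strain table: ``L0 = L_neutral / (1 + eps)``, so that the
neutral pose reproduces the prescribed pre-strain exactly.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import numpy as np

from .anatomy import AttachmentRecord, Skeleton
from .geometry import Pose
from . import pathology

__all__ = [
    "LigamentBand",
    "InSituStrainTable",
    "build_bands",
    "band_path_points",
    "path_length",
    "band_tension",
    "band_energy",
    "band_strain",
    "calibrate_rest_lengths",
    "bands_to_csv",
]

DEFAULT_IN_SITU_STRAIN = 0.02

#: encoded per-group reference-pose strains for the long plantar-arch
#: structures. A linear spring at 2% pre-strain over a 150-250 mm path
#: would carry several hundred newtons at rest and visibly distort the
#: unloaded pose; real long ligaments sit in their compliant toe region at
#: rest, which a linear model emulates with a smaller effective pre-strain.
DEFAULT_GROUP_STRAINS = {
    "plantar_fascia": 0.002,
    "long_plantar": 0.002,
    "short_plantar": 0.005,
    "intermetatarsal": 0.005,
    "spring_superomedial": 0.03,
    "spring_inferomedial": 0.03,
    "deltoid_superficial_anterior": 0.01,
    "deltoid_superficial_posterior": 0.01,
}


@dataclass(frozen=True)
class LigamentBand:
    """One tension-only band referencing skeleton attachment landmarks."""

    name: str
    group: str
    structure: str
    origin: tuple[str, str]  # (bone, landmark)
    insertion: tuple[str, str]
    via_beads: tuple = ()  # ((bone, landmark, radius_mm), ...)
    stiffness_k: float = 1.0  # N/mm
    rest_length_L0: float = 1.0  # mm
    damage_stage: str = "0"

    def __post_init__(self):
        if self.stiffness_k <= 0:
            raise ValueError(f"band {self.name!r}: stiffness must be > 0")
        if self.rest_length_L0 <= 0:
            raise ValueError(f"band {self.name!r}: rest length must be > 0")


@dataclass(frozen=True)
class InSituStrainTable:
    """Reference-pose engineering strain: band override > group > default."""

    default: float = DEFAULT_IN_SITU_STRAIN
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_STRAINS))
    bands: dict = field(default_factory=dict)

    def __post_init__(self):
        for label, eps in [("default", self.default), *self.groups.items(), *self.bands.items()]:
            if not (0.0 <= eps <= 0.10):
                raise ValueError(f"in-situ strain {label}={eps!r} outside [0, 0.10]")

    def strain_for(self, band: LigamentBand) -> float:
        if band.name in self.bands:
            return self.bands[band.name]
        if band.group in self.groups:
            return self.groups[band.group]
        return self.default


def band_path_points(
    band: LigamentBand, skeleton: Skeleton, poses: dict[str, Pose] | None = None
) -> np.ndarray:
    """World-frame polyline origin -> beads -> insertion, shape (n, 3)."""
    pts = [skeleton.world_landmark(*band.origin, poses=poses)]
    for bone, lm, _r in band.via_beads:
        pts.append(skeleton.world_landmark(bone, lm, poses=poses))
    pts.append(skeleton.world_landmark(*band.insertion, poses=poses))
    return np.array(pts)


def path_length(
    band: LigamentBand, skeleton: Skeleton, poses: dict[str, Pose] | None = None
) -> float:
    """Sum of straight-segment lengths along the band path, mm."""
    pts = band_path_points(band, skeleton, poses)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def band_tension(
    band: LigamentBand, skeleton: Skeleton, poses: dict[str, Pose] | None = None
) -> float:
    """Tension k*max(0, L - L0), N; identically zero when slack."""
    L = path_length(band, skeleton, poses)
    return band.stiffness_k * max(0.0, L - band.rest_length_L0)


def band_energy(
    band: LigamentBand, skeleton: Skeleton, poses: dict[str, Pose] | None = None
) -> float:
    """Spring energy 0.5*k*max(0, L - L0)^2, N*mm."""
    L = path_length(band, skeleton, poses)
    return 0.5 * band.stiffness_k * max(0.0, L - band.rest_length_L0) ** 2


def band_strain(
    band: LigamentBand,
    skeleton: Skeleton,
    poses: dict[str, Pose],
    reference_lengths: dict[str, float],
) -> float:
    """Engineering strain (L - L_ref)/L_ref; negative when slackened.

    ``reference_lengths`` come from the unloaded equilibrium of the same
    scenario (no axial load), keyed by band name.
    """
    if band.name not in reference_lengths:
        raise KeyError(f"no reference length for band {band.name!r}")
    L_ref = reference_lengths[band.name]
    L = path_length(band, skeleton, poses)
    return (L - L_ref) / L_ref


def build_bands(
    skeleton: Skeleton, attachments: list[AttachmentRecord] | None = None
) -> list[LigamentBand]:
    """Instantiate uncalibrated bands with healthy baseline stiffnesses."""
    from .anatomy import attachment_map

    attachments = attachments if attachments is not None else attachment_map(skeleton)
    bands = []
    for rec in attachments:
        k = pathology.baseline_stiffness(rec.structure)
        bands.append(
            LigamentBand(
                name=rec.band,
                group=rec.group,
                structure=rec.structure,
                origin=(rec.origin_bone, rec.origin_landmark),
                insertion=(rec.insertion_bone, rec.insertion_landmark),
                via_beads=rec.beads,
                stiffness_k=k,
                rest_length_L0=1.0,  # placeholder until calibration
            )
        )
    return bands


def calibrate_rest_lengths(
    bands: list[LigamentBand],
    skeleton: Skeleton,
    in_situ: InSituStrainTable | None = None,
) -> list[LigamentBand]:
    """Set every band's rest length from its neutral length and pre-strain.

    ``L0 = L_neutral / (1 + eps)``; measuring the strain of a calibrated
    band at the neutral pose returns ``eps`` to numerical precision.
    """
    in_situ = in_situ if in_situ is not None else InSituStrainTable()
    out = []
    for band in bands:
        eps = in_situ.strain_for(band)
        if eps <= -1.0:
            raise ValueError(f"band {band.name!r}: in-situ strain {eps} <= -1")
        L_neutral = path_length(band, skeleton)
        out.append(replace(band, rest_length_L0=L_neutral / (1.0 + eps)))
    return out


def bands_to_csv(bands: list[LigamentBand], skeleton: Skeleton) -> str:
    """Band table as CSV text (name, group, bones, local coords, k, L0, stage)."""
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(
        [
            "name", "group", "structure", "origin_bone", "origin_x", "origin_y", "origin_z",
            "insertion_bone", "insertion_x", "insertion_y", "insertion_z",
            "n_beads", "stiffness_N_per_mm", "rest_length_mm", "damage_stage",
        ]
    )
    for b in bands:
        o = skeleton.bones[b.origin[0]].landmarks[b.origin[1]]
        i = skeleton.bones[b.insertion[0]].landmarks[b.insertion[1]]
        w.writerow(
            [
                b.name, b.group, b.structure, b.origin[0], *[f"{v:.6f}" for v in o],
                b.insertion[0], *[f"{v:.6f}" for v in i],
                len(b.via_beads), f"{b.stiffness_k:.6f}", f"{b.rest_length_L0:.6f}",
                b.damage_stage,
            ]
        )
    return buf.getvalue()
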