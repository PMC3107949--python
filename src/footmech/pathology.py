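"""Stage II flatfoot ligament attenuation.

The disease model reduces the stiffness of the medial soft-tissue
restraints according to an MR-derived damage staging: each affected
structure loses a fixed fraction of its stiffness (stage 0 none, stage I
one eighth, stage II three eighths, stage IV seven eighths). The table
below carries the attenuated ("flatfoot") stiffness per structure;
healthy baselines are back-computed as ``flatfoot / (1 - fraction)``.

Structures not in the table (the generic capsular stabilizers of the
synthetic anatomy) take the mean of the named healthy baselines and are
never attenuated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

__all__ = [
    "STAGE_FRACTIONS",
    "FLATFOOT_TABLE",
    "DamageMap",
    "default_damage_map",
    "baseline_stiffness",
    "generic_baseline_stiffness",
    "apply_flatfoot",
]

#: stiffness fraction removed per damage stage (stage III is not defined
#: by the staging template and is deliberately absent)
STAGE_FRACTIONS = {
    "0": Fraction(0),
    "I": Fraction(1, 8),
    "II": Fraction(3, 8),
    "IV": Fraction(7, 8),
}

#: structure -> (damage stage, attenuated stiffness N/mm)
FLATFOOT_TABLE = {
    "spring_superomedial": ("IV", 39.0),
    "spring_inferomedial": ("II", 94.0),
    "talocalcaneal_interosseous": ("I", 236.0),
    "plantar_fascia": ("I", 175.0),
    "plantar_metatarsocuneiform": ("0", 90.0),
    "plantar_naviculocuneiform": ("0", 180.0),
    "long_and_short_plantar": ("0", 240.0),
    "deltoid_deep": ("0", 200.0),
    "deltoid_superficial_anterior": ("I", 70.0),
    "deltoid_superficial_posterior": ("0", 117.0),
}


@dataclass(frozen=True)
class DamageMap:
    """Structure name -> damage stage; defaults to the full staging table."""

    stages: dict

    def __post_init__(self):
        for structure, stage in self.stages.items():
            if stage not in STAGE_FRACTIONS:
                raise ValueError(
                    f"structure {structure!r}: unknown damage stage {stage!r} "
                    f"(valid: {sorted(STAGE_FRACTIONS)})"
                )

    def validate_complete(self) -> None:
        missing = set(FLATFOOT_TABLE) - set(self.stages)
        if missing:
            raise ValueError(f"damage map missing structures: {sorted(missing)}")

    def fraction_removed(self, structure: str) -> Fraction:
        return STAGE_FRACTIONS[self.stages.get(structure, "0")]


def default_damage_map() -> DamageMap:
    return DamageMap({s: stage for s, (stage, _k) in FLATFOOT_TABLE.items()})


def baseline_stiffness(structure: str) -> float:
    """Healthy (pre-attenuation) stiffness of a named structure, N/mm.

    Back-computed from the attenuated value and the removed fraction:
    ``baseline = flatfoot / (1 - fraction)``; stage-0 structures return the
    tabulated value unchanged. Unnamed structures resolve through
    :func:`generic_baseline_stiffness`.
    """
    if structure == "generic":
        return generic_baseline_stiffness()
    if structure not in FLATFOOT_TABLE:
        raise KeyError(f"unknown soft-tissue structure {structure!r}")
    stage, attenuated = FLATFOOT_TABLE[structure]
    frac = STAGE_FRACTIONS[stage]
    return attenuated / float(1 - frac)


def generic_baseline_stiffness() -> float:
    """Mean of the named healthy baselines (used for capsular stabilizers)."""
    return sum(baseline_stiffness(s) for s in FLATFOOT_TABLE) / len(FLATFOOT_TABLE)


def apply_flatfoot(bands, damage_map: DamageMap | None = None):
    """Attenuate a calibrated band set according to the damage map.

    Each band whose ``structure`` appears in the map has its stiffness
    multiplied by ``(1 - fraction_removed)``. Geometry, rest lengths and
    unaffected bands are untouched. Re-application is rejected: the
    returned bands carry ``damage_stage`` provenance.
    """
    damage_map = damage_map if damage_map is not None else default_damage_map()
    damage_map.validate_complete()
    out = []
    for band in bands:
        if band.damage_stage != "0":
            raise ValueError(
                f"band {band.name!r} already attenuated (stage {band.damage_stage}); "
                "flatfoot attenuation is single-shot"
            )
        stage = damage_map.stages.get(band.structure, "0")
        frac = STAGE_FRACTIONS[stage]
        if frac == 0:
            out.append(band)
        else:
            out.append(
                replace(band, stiffness_k=band.stiffness_k * float(1 - frac), damage_stage=stage)
            )
    return out
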