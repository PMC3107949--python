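"""Scenario orchestration, comparison tables, and derived arithmetic.

The default study runs seven configurations of one synthetic foot —
``normal``, ``flatfoot``, and flatfoot treated with ``MCO``, ``Evans``,
``CCDA``, ``Evans_MCO``, ``CCDA_MCO`` — and assembles the full
measurement block (six radiographic angles, plantar-band strain arrays,
calcaneocuboid contact force, plantar region loads) per scenario,
together with derived rows: angle deltas and percent changes between
named scenario pairs.

The module also ships the published reference tables of the
cadaver-derived simulation study this package emulates (attenuation
scheme, joint angles, band strains, plantar loads) as packaged CSV
fixtures, so that the derived-arithmetic operations can be validated
against printed values independently of the simulator.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field, replace

import pandas as pd

from .anatomy import AnatomyParams, Skeleton, build_skeleton
from .ligaments import InSituStrainTable, LigamentBand, build_bands, calibrate_rest_lengths, path_length
from .mechanics import (
    EquilibriumResult,
    LoadCase,
    SolverOptions,
    solve_scenario_pair,
)
from .measures import MeasureReport, measure_all
from .pathology import DamageMap, apply_flatfoot, default_damage_map
from .surgery import OsteotomyParams, apply_procedures

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "ComparisonTable",
    "DEFAULT_SUITE",
    "default_suite",
    "run_scenario",
    "run_suite",
    "angle_delta",
    "percent_change",
    "percent_of_reference",
    "reference_tables",
    "scale_band_stiffness",
]

#: canonical scenario order, matching the published table layout
DEFAULT_SUITE = ("normal", "flatfoot", "MCO", "Evans", "CCDA", "Evans_MCO", "CCDA_MCO")

_SCENARIO_PROCEDURES = {
    "normal": (),
    "flatfoot": (),
    "MCO": ("MCO",),
    "Evans": ("Evans",),
    "CCDA": ("CCDA",),
    "Evans_MCO": ("Evans", "MCO"),
    "CCDA_MCO": ("CCDA", "MCO"),
}

_FIXTURE_SHA256 = {
    "reference_attenuation.csv": "bdd2c3353531bfd49e09924af33491a3f0380b7d72bb648a581cf247ac16bdd0",
    "reference_joint_angles.csv": "c85a762037ddf584e4312496917758bb4796cc4ee294221a60c535fedefe400a",
    "reference_plantar_loads.csv": "f63e03e48746e8dc978390634db6eacadac0fbbab6964b33a7f0eb73afa988e1",
    "reference_strains.csv": "4e3d7bef2d230685732eeffc93cb422e3473ae973002a089f7cb9d33d777d9aa",
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One fully-specified simulation scenario."""

    name: str
    condition: str = "normal"  # normal | flatfoot
    procedures: tuple = ()
    anatomy: AnatomyParams = field(default_factory=AnatomyParams)
    seed: int = 0
    load_case: LoadCase = field(default_factory=LoadCase)
    osteotomy: OsteotomyParams = field(default_factory=OsteotomyParams)
    solver: SolverOptions = field(default_factory=SolverOptions)
    damage_map: DamageMap | None = None
    in_situ: InSituStrainTable | None = None
    stiffness_scale: float = 1.0

    def __post_init__(self):
        if self.condition not in ("normal", "flatfoot"):
            raise ValueError(f"condition must be 'normal' or 'flatfoot', got {self.condition!r}")
        procs = {p.upper() for p in self.procedures}
        if procs and self.condition != "flatfoot":
            raise ValueError("bony procedures are applied to the flatfoot model only")
        if {"EVANS", "CCDA"} <= procs:
            raise ValueError("Evans and CCDA are mutually exclusive")
        if self.stiffness_scale <= 0:
            raise ValueError("stiffness_scale must be > 0")


def default_suite(
    seed: int = 0,
    anatomy: AnatomyParams | None = None,
    solver: SolverOptions | None = None,
    stiffness_scale: float = 1.0,
    names=DEFAULT_SUITE,
) -> list[ScenarioConfig]:
    """The canonical seven-configuration study for one anatomy seed."""
    anatomy = anatomy if anatomy is not None else AnatomyParams()
    solver = solver if solver is not None else SolverOptions()
    configs = []
    for name in names:
        if name not in _SCENARIO_PROCEDURES:
            raise ValueError(f"unknown scenario {name!r}; valid: {sorted(_SCENARIO_PROCEDURES)}")
        configs.append(
            ScenarioConfig(
                name=name,
                condition="normal" if name == "normal" else "flatfoot",
                procedures=_SCENARIO_PROCEDURES[name],
                anatomy=anatomy,
                seed=seed,
                solver=solver,
                stiffness_scale=stiffness_scale,
            )
        )
    return configs


def scale_band_stiffness(bands: list[LigamentBand], factor: float) -> list[LigamentBand]:
    """Uniformly scale every band stiffness (robustness studies)."""
    if factor <= 0:
        raise ValueError("stiffness scale factor must be > 0")
    return [replace(b, stiffness_k=b.stiffness_k * factor) for b in bands]


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    skeleton: Skeleton
    bands: list[LigamentBand]
    unloaded: EquilibriumResult
    loaded: EquilibriumResult
    report: MeasureReport


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Build, calibrate, modify, solve and measure one scenario.

    Pipeline: intact skeleton -> bands with healthy baselines -> rest-length
    calibration at the intact neutral pose -> disease attenuation (stiffness
    only) -> virtual surgery (geometry only; calibrated rest lengths are
    kept, which is how the osteotomies re-tension the plantar structures) ->
    unloaded reference equilibrium -> ramped mid-stance load.
    """
    skeleton = build_skeleton(config.anatomy, config.seed)
    bands = calibrate_rest_lengths(build_bands(skeleton), skeleton, config.in_situ)
    if config.condition == "flatfoot":
        bands = apply_flatfoot(bands, config.damage_map or default_damage_map())
    if config.stiffness_scale != 1.0:
        bands = scale_band_stiffness(bands, config.stiffness_scale)
    if config.procedures:
        skeleton = apply_procedures(skeleton, config.procedures, config.osteotomy)

    unloaded, loaded = solve_scenario_pair(skeleton, bands, config.load_case, config.solver)
    reference_lengths = {b.name: path_length(b, skeleton, unloaded.poses) for b in bands}
    report = measure_all(loaded, skeleton, bands, reference_lengths, scenario=config.name)
    return ScenarioResult(config, skeleton, bands, unloaded, loaded, report)


# --------------------------------------------------------------------- #
# derived arithmetic
# --------------------------------------------------------------------- #


def angle_delta(a: float, b: float) -> float:
    """Angle difference ``a - b`` in degrees, reported to 0.1."""
    return round(a - b, 1)


def percent_change(reference: float, new: float) -> int:
    """Signed percent change from ``reference`` to ``new``, nearest integer."""
    if reference <= 0:
        raise ValueError("percent_change requires a positive reference value")
    return round((new - reference) / reference * 100.0)


def percent_of_reference(reference: float, new: float) -> int:
    """``new`` as a percentage of ``reference``, nearest integer."""
    if reference <= 0:
        raise ValueError("percent_of_reference requires a positive reference value")
    return round(new / reference * 100.0)


# --------------------------------------------------------------------- #
# comparison table
# --------------------------------------------------------------------- #

_ANGLE_FIELDS = ("l_t1mt", "l_tc", "l_cp", "ap_t1mt", "ap_tn", "hindfoot")


@dataclass
class ComparisonTable:
    """Per-scenario measurement columns plus derived delta rows."""

    reports: dict[str, MeasureReport]
    seed: int = 0

    def angles_frame(self) -> pd.DataFrame:
        data = {
            name: {f: getattr(r.angles, f) for f in _ANGLE_FIELDS}
            for name, r in self.reports.items()
        }
        return pd.DataFrame(data).round(1)

    def loads_frame(self) -> pd.DataFrame:
        data = {name: r.plantar_loads_N for name, r in self.reports.items()}
        return pd.DataFrame(data).round(0)

    def strains_frame(self) -> pd.DataFrame:
        data = {}
        for name, r in self.reports.items():
            col = {f"long_plantar_{i+1}": v for i, v in enumerate(r.long_plantar_strains_pct)}
            col.update(
                {f"plantar_fascia_{i+1}": v for i, v in enumerate(r.plantar_fascia_strains_pct)}
            )
            data[name] = col
        return pd.DataFrame(data).round(1)

    def derived_rows(self) -> dict[str, float]:
        """Angle deltas vs normal/flatfoot recomputed from the columns."""
        out: dict[str, float] = {}
        if len(self.reports) < 2:
            return out
        for base in ("normal", "flatfoot"):
            if base not in self.reports:
                continue
            for name, r in self.reports.items():
                if name == base:
                    continue
                for f in _ANGLE_FIELDS:
                    out[f"{f}:{name}-{base}"] = angle_delta(
                        getattr(r.angles, f), getattr(self.reports[base].angles, f)
                    )
        return out

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "reports": {k: r.to_dict() for k, r in self.reports.items()},
            "derived": self.derived_rows(),
            "unconverged": [k for k, r in self.reports.items() if not r.converged],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_csv(self) -> str:
        frames = [self.angles_frame(), self.strains_frame(), self.loads_frame()]
        cc = pd.DataFrame(
            {
                name: {"calcaneocuboid_force": r.calcaneocuboid_force_N}
                for name, r in self.reports.items()
            }
        ).round(0)
        return pd.concat(frames + [cc]).to_csv()


def run_suite(configs: list[ScenarioConfig]) -> tuple[ComparisonTable, dict[str, ScenarioResult]]:
    """Run a scenario list sharing one anatomy seed; flag non-convergence."""
    seeds = {c.seed for c in configs}
    if len(seeds) != 1:
        raise ValueError(f"suite scenarios must share one anatomy seed, got {sorted(seeds)}")
    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError("scenario names must be unique within a suite")
    results: dict[str, ScenarioResult] = {}
    for cfg in configs:
        results[cfg.name] = run_scenario(cfg)
    table = ComparisonTable(
        reports={name: res.report for name, res in results.items()}, seed=seeds.pop()
    )
    return table, results


# --------------------------------------------------------------------- #
# published reference tables (packaged fixtures)
# --------------------------------------------------------------------- #


def _load_fixture(name: str) -> pd.DataFrame:
    res = importlib.resources.files("footmech").joinpath("data", name)
    raw = res.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(f"reference table {name} is corrupted (checksum mismatch)")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), index_col=0)


def reference_tables() -> dict[str, pd.DataFrame]:
    """The published reference tables, exactly as printed.

    Keys: ``attenuation`` (damage stages and attenuated stiffnesses),
    ``angles`` (joint angles, degrees), ``strains`` (plantar band strains,
    %), ``loads`` (plantar contact loads, N). Columns follow the scenario
    order of :data:`DEFAULT_SUITE` (lower-cased).
    """
    return {
        "attenuation": _load_fixture("reference_attenuation.csv"),
        "angles": _load_fixture("reference_joint_angles.csv"),
        "strains": _load_fixture("reference_strains.csv"),
        "loads": _load_fixture("reference_plantar_loads.csv"),
    }
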