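"""Configuration files, run manifests, and result I/O.

Scenario suites are described in YAML:

.. code-block:: yaml

    suite:
      seed: 0
      scenarios: [normal, flatfoot, MCO, Evans, CCDA, Evans_MCO, CCDA_MCO]
    anatomy:
      foot_length_mm: 250.0
      arch_height_fraction: 0.24
    load:
      axial_load_N: 690.0
      achilles_load_N: 345.0
    surgery:
      mco_offset_mm: 10.0
    solver:
      tolerance_N: 0.5
    damage:
      spring_superomedial: IV
    stiffness_scale: 1.0

Every block is optional; omitted values take the package defaults.
Results are written as JSON (floats at full precision) plus CSV tables
(display-rounded), and every run emits a manifest with configuration and
output checksums sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .anatomy import AnatomyParams
from .analysis import (
    ComparisonTable,
    ScenarioConfig,
    default_suite,
    _SCENARIO_PROCEDURES,
)
from .ligaments import InSituStrainTable
from .measures import MeasureReport
from .mechanics import LoadCase, SolverOptions
from .pathology import DamageMap, default_damage_map
from .surgery import OsteotomyParams

__all__ = [
    "load_config",
    "sha256_file",
    "write_manifest",
    "write_suite_outputs",
    "read_reports",
]

_ALLOWED_BLOCKS = {
    "suite", "anatomy", "load", "surgery", "solver", "damage", "in_situ", "stiffness_scale",
}


def _build(cls, block: dict, label: str):
    try:
        return cls(**block)
    except TypeError as e:
        raise ValueError(f"invalid {label} block: {e}") from None


def load_config(path) -> list[ScenarioConfig]:
    """Parse and validate a scenario-suite YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _ALLOWED_BLOCKS
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")

    suite = raw.get("suite", {}) or {}
    seed = int(suite.get("seed", 0))
    names = suite.get("scenarios", list(_SCENARIO_PROCEDURES))
    for n in names:
        if n not in _SCENARIO_PROCEDURES:
            raise ValueError(f"unknown scenario {n!r}; valid: {sorted(_SCENARIO_PROCEDURES)}")

    anatomy = _build(AnatomyParams, raw.get("anatomy", {}) or {}, "anatomy")
    load = _build(LoadCase, raw.get("load", {}) or {}, "load")
    osteo = _build(OsteotomyParams, raw.get("surgery", {}) or {}, "surgery")
    solver = _build(SolverOptions, raw.get("solver", {}) or {}, "solver")
    damage = DamageMap(raw["damage"]) if "damage" in raw else default_damage_map()
    in_situ = _build(InSituStrainTable, raw.get("in_situ", {}) or {}, "in_situ") if "in_situ" in raw else None
    scale = float(raw.get("stiffness_scale", 1.0))

    configs = []
    for name in names:
        configs.append(
            ScenarioConfig(
                name=name,
                condition="normal" if name == "normal" else "flatfoot",
                procedures=_SCENARIO_PROCEDURES[name],
                anatomy=anatomy,
                seed=seed,
                load_case=load,
                osteotomy=osteo,
                solver=solver,
                damage_map=damage,
                in_situ=in_situ,
                stiffness_scale=scale,
            )
        )
    return configs


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, *, seed: int, config_digest: str, diagnostics: dict, files: list) -> Path:
    """Write the run manifest (seed, version, diagnostics, file checksums)."""
    out_dir = Path(out_dir)
    manifest = {
        "software": {"name": "footmech", "version": __version__},
        "seed": int(seed),
        "config_sha256": config_digest,
        "convergence": diagnostics,
        "outputs": [{"file": str(Path(f).name), "sha256": sha256_file(f)} for f in files],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def write_suite_outputs(out_dir, table: ComparisonTable, results: dict) -> list:
    """Per-scenario report + equilibrium JSON, comparison CSV/JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for name, res in results.items():
        rp = out_dir / f"report_{name}.json"
        rp.write_text(json.dumps(res.report.to_dict(), indent=2))
        files.append(rp)
        ep = out_dir / f"equilibrium_{name}.json"
        ep.write_text(json.dumps(res.loaded.to_dict(), indent=2))
        files.append(ep)
    cj = out_dir / "comparison.json"
    cj.write_text(table.to_json(indent=2))
    files.append(cj)
    cc = out_dir / "comparison.csv"
    cc.write_text(table.to_csv())
    files.append(cc)
    return files


def read_reports(results_dir) -> tuple[dict[str, MeasureReport], int | None]:
    """Load ``report_*.json`` files from a results directory.

    Returns the reports keyed by scenario plus the suite seed recorded in
    the manifest (None if no manifest is present). Corrupted report files
    are rejected by name.
    """
    results_dir = Path(results_dir)
    reports: dict[str, MeasureReport] = {}
    for path in sorted(results_dir.glob("report_*.json")):
        try:
            d = json.loads(path.read_text())
            rep = MeasureReport.from_dict(d)
        except Exception as e:
            raise ValueError(f"corrupted report file {path.name}: {e}") from None
        reports[rep.scenario] = rep
    seed = None
    man = results_dir / "manifest.json"
    if man.exists():
        seed = json.loads(man.read_text()).get("seed")
    return reports, seed
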