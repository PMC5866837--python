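"""Run configuration: schema-validated YAML in, validated parameter objects out.

All public interfaces use uM for concentrations and mg/kg bw for doses;
internal unit conversions live in :mod:`qivive.units`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .chem_params import ChemicalParams, PartitionCoefficients
from .errors import ConfigurationError
from .pbk_core import ExposureScenario, PhysiologyParams, SolverSettings

__all__ = ["RunConfig", "load_config", "default_config", "config_hash"]

_CHEMICAL_KEYS = {
    "mw",
    "log_pow",
    "papp_caco2",
    "clint_invitro",
    "fub_serum",
    "fub_medium",
    "partition_coefficients",
    "papp_unit_convention",
}
_PHYSIOLOGY_KEYS = {
    "body_weight",
    "vlc",
    "vfc",
    "vbc",
    "vrc",
    "perfused_fraction",
    "cardiac_output_coeff",
    "qlc",
    "qfc",
    "qrc",
    "vin_ml",
    "sain_cm2",
    "kin_per_h",
    "gastric_emptying_per_h",
    "s9_protein_g_per_kg",
}
_SCENARIO_KEYS = {"chemical", "route", "dose_mg_per_kg", "duration_h", "n_output"}
_SOLVER_KEYS = {"method", "rtol", "atol"}
_TOP_KEYS = {"seed", "output_dir", "solver", "physiology", "chemicals", "scenarios", "fixtures"}
_FIXTURE_KEYS = {"hill", "uterotrophic"}
_HILL_FIXTURE_KEYS = {"assay", "ec50_m", "slope", "bottom", "top", "noise_sd_pct"}
_UTERO_FIXTURE_KEYS = {"a", "b", "d", "doses", "noise_cv", "n_per_group"}


@dataclass
class RunConfig:
    """A fully validated run configuration."""

    chemicals: dict[str, ChemicalParams]
    physiology: PhysiologyParams
    scenarios: list[tuple[str, ExposureScenario]]
    solver: SolverSettings = SolverSettings()
    seed: int = 0
    output_dir: Path = Path("results")
    fixtures: dict[str, dict[str, dict]] = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)


def _reject_unknown(section: str, mapping: Mapping[str, Any], allowed: set[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {section}: {sorted(unknown)}")


def _build_chemical(name: str, spec: Mapping[str, Any]) -> ChemicalParams:
    if not isinstance(spec, Mapping):
        raise ConfigurationError(f"chemical {name!r} must be a mapping")
    _reject_unknown(f"chemicals.{name}", spec, _CHEMICAL_KEYS)
    pc = None
    if "partition_coefficients" in spec:
        pc_spec = dict(spec["partition_coefficients"])
        _reject_unknown(
            f"chemicals.{name}.partition_coefficients",
            pc_spec,
            {"liver", "fat", "richly_perfused", "slowly_perfused"},
        )
        pc = PartitionCoefficients(**pc_spec)
    kwargs: dict[str, Any] = {k: spec[k] for k in spec if k not in ("partition_coefficients",)}
    try:
        return ChemicalParams(name=name, partition_coefficients=pc, **kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"chemical {name!r}: {exc}") from exc


def _parse(raw: Mapping[str, Any], base: Optional[Path] = None) -> RunConfig:
    if not isinstance(raw, Mapping):
        raise ConfigurationError("configuration root must be a mapping")
    _reject_unknown("top level", raw, _TOP_KEYS)

    chemicals_raw = raw.get("chemicals", {})
    if not chemicals_raw:
        raise ConfigurationError("configuration must define at least one chemical")
    chemicals = {name: _build_chemical(name, spec) for name, spec in chemicals_raw.items()}

    phys_raw = dict(raw.get("physiology") or {})
    _reject_unknown("physiology", phys_raw, _PHYSIOLOGY_KEYS)
    physiology = PhysiologyParams(**phys_raw)

    solver_raw = dict(raw.get("solver") or {})
    _reject_unknown("solver", solver_raw, _SOLVER_KEYS)
    solver = SolverSettings(**solver_raw)

    scenarios: list[tuple[str, ExposureScenario]] = []
    for i, item in enumerate(raw.get("scenarios", [])):
        item = dict(item)
        _reject_unknown(f"scenarios[{i}]", item, _SCENARIO_KEYS)
        chem_name = item.pop("chemical", None)
        if chem_name not in chemicals:
            raise ConfigurationError(
                f"scenarios[{i}] refers to unknown chemical {chem_name!r}"
            )
        scenarios.append((chem_name, ExposureScenario(**item)))

    fixtures_raw = dict(raw.get("fixtures") or {})
    _reject_unknown("fixtures", fixtures_raw, _FIXTURE_KEYS)
    for kind, allowed in (("hill", _HILL_FIXTURE_KEYS), ("uterotrophic", _UTERO_FIXTURE_KEYS)):
        for chem_name, spec in dict(fixtures_raw.get(kind) or {}).items():
            if chem_name not in chemicals:
                raise ConfigurationError(
                    f"fixtures.{kind} refers to unknown chemical {chem_name!r}"
                )
            _reject_unknown(f"fixtures.{kind}.{chem_name}", spec, allowed)

    output_dir = Path(raw.get("output_dir", "results"))
    if base is not None and not output_dir.is_absolute():
        output_dir = base / output_dir
    return RunConfig(
        chemicals=chemicals,
        physiology=physiology,
        scenarios=scenarios,
        solver=solver,
        seed=int(raw.get("seed", 0)),
        output_dir=output_dir,
        fixtures={k: dict(v or {}) for k, v in fixtures_raw.items()},
        raw=dict(raw),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration. Unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    return _parse(raw, base=path.parent)


def default_config() -> RunConfig:
    """The packaged default configuration (model estrogens, rat physiology)."""
    text = resources.files("qivive.data").joinpath("defaults.yaml").read_text()
    return _parse(yaml.safe_load(text))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the raw configuration, for provenance logging."""
    canonical = yaml.safe_dump(config.raw, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
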