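"""YAML-backed configuration with schema validation and unit normalization.

Defaults are the tabulated parameter values of the underlying model (local
geometry/material/kinetic constants and the three-segment network).  Keys
are validated strictly: unknown keys raise, with a close-match suggestion.
"""

from __future__ import annotations

import difflib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .chemistry import KineticsParams, ToneParams
from .geometry import CrossSectionGeometry
from .hemodynamics import NetworkParams
from .mechanics import CalcifiedParams, ECMParams, SMCParams, WallMaterials


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SolverSettings:
    n_radial_media: int = 10
    n_radial_adventitia: int = 5
    n_circ: int = 96
    seed: int = 0
    newton_tol: float = 1e-8
    p_max: float = 250.0          # surrogate sweep range (mmHg)
    n_p: int = 10
    coupling_tol: float = 1e-3
    slow_dt_ramp: float = 10.0    # s
    slow_dt_plateau: float = 60.0  # s
    rd_dt_max: float = 30.0       # s


@dataclass(frozen=True)
class ScenarioSettings:
    name: str = "basal_equilibrium"
    alpha_dys: float = 0.0
    calcified: bool = False
    calc_angular_fraction: float = 1.0 / 3.0
    calc_radial_extent: float = 1.0
    regulation: bool = True
    duration: float = 3600.0      # s


@dataclass(frozen=True)
class Config:
    geometry: CrossSectionGeometry = field(default_factory=CrossSectionGeometry)
    ecm: ECMParams = field(default_factory=ECMParams)
    smc: SMCParams = field(default_factory=SMCParams)
    calcified: CalcifiedParams = field(default_factory=CalcifiedParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    tone: ToneParams = field(default_factory=ToneParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    solver: SolverSettings = field(default_factory=SolverSettings)
    scenario: ScenarioSettings = field(default_factory=ScenarioSettings)
    output_dir: str = "output"
    output_stride: int = 1

    def materials(self) -> WallMaterials:
        return WallMaterials(ecm=self.ecm, smc=self.smc, calcified=self.calcified)

    def to_dict(self) -> dict:
        return asdict(self)


# unit-normalizing hooks: config files may give a few quantities in
# alternative units; everything is stored in the internal unit system
_UNIT_KEYS = {
    ("ecm", "kappa_MPa"): ("kappa", 1.0e3),
    ("calcified", "kappa_MPa"): ("kappa", 1.0e3),
    ("kinetics", "D_NO_um2_s"): ("D_NO", 1.0e-6),
    ("kinetics", "D_ROS_um2_s"): ("D_ROS", 1.0e-6),
    ("geometry", "ell_S_cm"): ("ell_S", 10.0),
    ("network", "ell_S_cm"): ("ell_S", 10.0),
    ("network", "cardiac_output_L_min"): ("V_h", 1000.0 / 60.0),
}


def _apply_section(obj, name: str, overrides: dict):
    valid = {f.name for f in fields(obj)}
    clean = {}
    for key, value in overrides.items():
        if (name, key) in _UNIT_KEYS:
            target, factor = _UNIT_KEYS[(name, key)]
            clean[target] = float(value) * factor
            continue
        if key not in valid:
            hint = difflib.get_close_matches(key, sorted(valid), n=1)
            extra = f"; did you mean '{hint[0]}'?" if hint else ""
            raise ConfigError(f"unknown key '{name}.{key}'{extra}")
        clean[key] = value
    return replace(obj, **clean)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> Config:
    """Load a config from YAML (missing file entries fall back to defaults)."""
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("config root must be a mapping")
            data = loaded
    if overrides:
        for k, v in overrides.items():
            data.setdefault(k, {})
            if isinstance(v, dict):
                data[k].update(v)
            else:
                data[k] = v
    cfg = Config()
    sections = {f.name for f in fields(Config)}
    out = {}
    for key, value in data.items():
        if key not in sections:
            hint = difflib.get_close_matches(key, sorted(sections), n=1)
            extra = f"; did you mean '{hint[0]}'?" if hint else ""
            raise ConfigError(f"unknown section '{key}'{extra}")
        if isinstance(value, dict):
            out[key] = _apply_section(getattr(cfg, key), key, value)
        else:
            out[key] = value
    return replace(cfg, **out)


def dump_config(cfg: Config, path: str | Path):
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
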