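"""Run configuration: TOML parsing, validation, canonical form, hashing.

The config file is flat-sectioned TOML with a ``schema`` version key and
sections ``electrolyte``, ``device``, ``mesh``, ``solver``, ``experiment``.
Unknown keys are rejected with the offending key path; every omitted key
falls back to a documented default, so the minimal valid config is an
empty file (or just an experiment name).
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .device import DEFAULTS, DeviceSpec, default_isfet_device, set_receptor_states
from .electrolyte import ElectrolyteSpec, InvalidParameterError
from .mesh import MeshSpec
from .solver import SolverOptions

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid configuration; message carries the offending key path."""


_ELECTROLYTE_KEYS = {
    # config key -> ElectrolyteSpec field
    "pH": "pH", "temperature_K": "T", "eps_r": "eps_r", "pKw": "pKw",
    "mu_cation": "mu_cation_max", "mu_anion": "mu_anion_max",
    "Eg0": "Eg0", "alpha": "alpha", "beta": "beta",
    "tau_n": "tau_n", "tau_p": "tau_p",
}

_DEVICE_KEYS = {
    "n_receptors": None,          # handled separately
    "pattern": None,
    "channel_length_um": "channel_length",
    "sd_window_um": "sd_window",
    "substrate_depth_um": "substrate_depth",
    "oxide_thickness_um": "oxide_thickness",
    "electrolyte_height_um": "electrolyte_height",
    "junction_depth_um": "junction_depth",
    "lateral_straggle_um": "lateral_straggle",
    "nd_peak_cm3": "nd_peak",
    "na_substrate_cm3": "na_substrate",
    "receptor_length_um": "receptor_length",
    "receptor_thickness_um": "receptor_thickness",
    "receptor_eps": "receptor_eps_r",
    "Q_T_coulomb": "Q_T",
    "charge_sign": "charge_sign",
    "width_um": "width_normalization",
}

_SOLVER_FIELDS = {f.name for f in fields(SolverOptions)}
_MESH_FIELDS = {f.name for f in fields(MeshSpec)}

_EXPERIMENT_KEYS = {
    "name", "seed", "v_ds", "v_ref", "sweep_start", "sweep_stop",
    "sweep_step", "ph_values", "i_crit_A_per_um", "n_on", "n_samples",
    "cut_x_um", "profile_depth_um",
}

_EXPERIMENT_DEFAULTS = {
    "name": "sweep", "seed": 1, "v_ds": 0.1, "v_ref": 0.0,
    "sweep_start": 0.0, "sweep_stop": 1.0, "sweep_step": 0.05,
    "ph_values": [4.0, 7.0, 10.0], "i_crit_A_per_um": 2.0e-8,
    "n_on": 3, "n_samples": 5, "cut_x_um": 3.5, "profile_depth_um": 0.002,
}


@dataclass(frozen=True)
class RunConfig:
    electrolyte: ElectrolyteSpec
    n_receptors: int
    pattern: tuple[int, ...]
    device_overrides: dict
    mesh: MeshSpec
    solver: SolverOptions
    experiment: dict
    output_dir: str = "out"

    def build_device(self) -> DeviceSpec:
        dev = default_isfet_device(self.n_receptors, self.electrolyte.pH,
                                   **self.device_overrides)
        dev = DeviceSpec(regions=dev.regions, receptors=dev.receptors,
                         contacts=dev.contacts, electrolyte=self.electrolyte,
                         oxide_thickness=dev.oxide_thickness,
                         width_normalization=dev.width_normalization,
                         receptor_eps_r=dev.receptor_eps_r)
        if self.pattern:
            q = (self.device_overrides.get("charge_sign",
                                           DEFAULTS["charge_sign"])
                 * self.device_overrides.get("Q_T", DEFAULTS["Q_T"]))
            dev = set_receptor_states(dev, list(self.pattern), q)
        return dev


def _section(raw: dict, name: str) -> dict:
    sec = raw.pop(name, {})
    if not isinstance(sec, dict):
        raise ConfigError(f"{name}: expected a table")
    return dict(sec)


def _build(cls, kwargs, path):
    try:
        return cls(**kwargs)
    except (InvalidParameterError, ValueError) as err:
        raise ConfigError(f"{path}: {err}") from err


def parse_config(raw: dict) -> RunConfig:
    """Validate a parsed TOML mapping into a :class:`RunConfig`."""
    raw = dict(raw)
    schema = raw.pop("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise ConfigError(f"schema: unsupported version {schema!r}")
    output_dir = raw.pop("output_dir", "out")

    esec = _section(raw, "electrolyte")
    ekw = {}
    for key, val in esec.items():
        if key not in _ELECTROLYTE_KEYS:
            raise ConfigError(f"electrolyte.{key}: unknown key")
        ekw[_ELECTROLYTE_KEYS[key]] = val
    try:
        electrolyte = ElectrolyteSpec(**ekw)
    except InvalidParameterError as err:
        bad = next((k for k, f in _ELECTROLYTE_KEYS.items()
                    if f in str(err) or k in str(err)), "")
        raise ConfigError(f"electrolyte.{bad or '?'}: {err}") from err

    dsec = _section(raw, "device")
    n_receptors = dsec.pop("n_receptors", 10)
    pattern = tuple(dsec.pop("pattern", ()))
    overrides = {}
    for key, val in dsec.items():
        if key not in _DEVICE_KEYS or _DEVICE_KEYS[key] is None:
            raise ConfigError(f"device.{key}: unknown key")
        overrides[_DEVICE_KEYS[key]] = val
    if not isinstance(n_receptors, int) or n_receptors < 0:
        raise ConfigError("device.n_receptors: must be a non-negative int")

    msec = _section(raw, "mesh")
    for key in msec:
        if key not in _MESH_FIELDS:
            raise ConfigError(f"mesh.{key}: unknown key")
    mesh = _build(MeshSpec, msec, "mesh")

    ssec = _section(raw, "solver")
    for key in ssec:
        if key not in _SOLVER_FIELDS:
            raise ConfigError(f"solver.{key}: unknown key")
    solver = _build(SolverOptions, ssec, "solver")

    xsec = _section(raw, "experiment")
    for key in xsec:
        if key not in _EXPERIMENT_KEYS:
            raise ConfigError(f"experiment.{key}: unknown key")
    experiment = dict(_EXPERIMENT_DEFAULTS)
    experiment.update(xsec)

    if raw:
        raise ConfigError(f"{sorted(raw)[0]}: unknown top-level key")

    cfg = RunConfig(electrolyte=electrolyte, n_receptors=n_receptors,
                    pattern=pattern, device_overrides=overrides,
                    mesh=mesh, solver=solver, experiment=experiment,
                    output_dir=str(output_dir))
    try:
        cfg.build_device()
    except Exception as err:
        raise ConfigError(f"device: {err}") from err
    return cfg


def load_config(path) -> RunConfig:
    """Parse and validate a TOML config file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    with open(p, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as err:
            raise ConfigError(f"TOML parse error: {err}") from err
    return parse_config(raw)


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise ConfigError(f"cannot serialize {type(v).__name__}")


def serialize_config(cfg: RunConfig) -> str:
    """Canonical TOML form: fixed section order, sorted keys.  Two equal
    configs serialize identically, so the form is stable for hashing."""
    inv_e = {v: k for k, v in _ELECTROLYTE_KEYS.items()}
    inv_d = {v: k for k, v in _DEVICE_KEYS.items() if v}
    lines = [f"schema = {SCHEMA_VERSION}",
             f"output_dir = {_toml_scalar(cfg.output_dir)}", ""]
    lines.append("[electrolyte]")
    for f, v in sorted(asdict(cfg.electrolyte).items(),
                       key=lambda kv: inv_e[kv[0]]):
        lines.append(f"{inv_e[f]} = {_toml_scalar(v)}")
    lines.append("")
    lines.append("[device]")
    lines.append(f"n_receptors = {cfg.n_receptors}")
    if cfg.pattern:
        lines.append(f"pattern = {_toml_scalar(list(cfg.pattern))}")
    for f, v in sorted(cfg.device_overrides.items(),
                       key=lambda kv: inv_d[kv[0]]):
        lines.append(f"{inv_d[f]} = {_toml_scalar(v)}")
    lines.append("")
    lines.append("[mesh]")
    for k, v in sorted(asdict(cfg.mesh).items()):
        lines.append(f"{k} = {_toml_scalar(v)}")
    lines.append("")
    lines.append("[solver]")
    for k, v in sorted(asdict(cfg.solver).items()):
        lines.append(f"{k} = {_toml_scalar(v)}")
    lines.append("")
    lines.append("[experiment]")
    for k, v in sorted(cfg.experiment.items()):
        lines.append(f"{k} = {_toml_scalar(v)}")
    return "\n".join(lines) + "\n"


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 of the canonical serialized form (first 16 hex chars)."""
    return hashlib.sha256(serialize_config(cfg).encode()).hexdigest()[:16]
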