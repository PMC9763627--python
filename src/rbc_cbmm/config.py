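"""Configuration loading with explicit units, presets, and validation.

Every physical quantity in a config file is a string ``"<value> <unit>"``
(e.g. ``"6.54 uN/m"``, ``"100 nm"``, ``"3.6 cP"``); unit-less counts and
flags are plain scalars.  Unknown keys and missing/unknown units are
rejected with the offending key path.  Named presets shipped with the
package transcribe the published parameter sets for the doublet-formation
groups, the disaggregation comparisons and the pathophysiology cases.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .adhesion import AdhesionParams, PathophysParams
from .errors import ConfigurationError
from .mechanics import MembraneParams
from .protocols import ProtocolConfig
from .transport import TransportParams

# multiplicative SI factors for accepted unit spellings
_UNITS = {
    # length
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    # time
    "s": 1.0, "ms": 1e-3,
    # speed
    "m/s": 1.0, "um/s": 1e-6, "µm/s": 1e-6, "nm/s": 1e-9,
    # force
    "N": 1.0, "uN": 1e-6, "nN": 1e-9, "pN": 1e-12,
    # mass
    "kg": 1.0, "g": 1e-3, "mg": 1e-6, "ug": 1e-9,
    # energy / bending modulus
    "J": 1.0,
    # surface energy density (affinity)
    "J/m^2": 1.0, "uJ/m^2": 1e-6, "mJ/m^2": 1e-3,
    # elastic moduli per length
    "N/m": 1.0, "uN/m": 1e-6, "mN/m": 1e-3,
    # volume penalty
    "J/m^3": 1.0, "N/m^2": 1.0, "Pa": 1.0,
    # viscosity
    "Pa.s": 1.0, "Pa*s": 1.0, "mPa.s": 1e-3, "cP": 1e-3, "P": 0.1,
    # membrane (surface) viscosity
    "N.s/m": 1.0, "uN.s/m": 1e-6, "Pa.s.m": 1.0,
    # diffusivity
    "m^2/s": 1.0, "um^2/s": 1e-12, "cm^2/s": 1e-4,
    # inverse length
    "1/m": 1.0, "m^-1": 1.0, "1/nm": 1e9, "nm^-1": 1e9, "1/um": 1e6,
    # dimensionless
    "-": 1.0, "1": 1.0,
}


def parse_quantity(value, key: str = "") -> float:
    """Parse ``"<number> <unit>"`` into an SI float."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        raise ConfigurationError(
            f"{key}: physical quantity {value!r} is missing a unit string")
    if not isinstance(value, str):
        raise ConfigurationError(f"{key}: cannot parse quantity {value!r}")
    parts = value.split()
    if len(parts) != 2:
        raise ConfigurationError(
            f"{key}: expected '<value> <unit>', got {value!r}")
    num, unit = parts
    if unit not in _UNITS:
        raise ConfigurationError(f"{key}: unknown unit {unit!r}")
    try:
        return float(num) * _UNITS[unit]
    except ValueError as exc:
        raise ConfigurationError(f"{key}: bad number {num!r}") from exc


@dataclass
class RunConfig:
    """Fully resolved configuration of one simulation run (SI units)."""

    membrane: MembraneParams = field(default_factory=MembraneParams)
    adhesion: AdhesionParams = field(default_factory=AdhesionParams)
    transport: TransportParams = field(default_factory=TransportParams)
    pathophys: PathophysParams | None = None
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    output_dir: str = "."
    log_level: str = "info"
    name: str = "run"

    def manifest(self) -> dict:
        """Every resolved parameter in SI units (echoed into run manifests)."""
        from dataclasses import asdict
        out = {
            "name": self.name,
            "membrane": asdict(self.membrane),
            "adhesion": asdict(self.adhesion),
            "transport": asdict(self.transport),
            "pathophys": asdict(self.pathophys) if self.pathophys else None,
            "protocol": asdict(self.protocol),
            "output_dir": self.output_dir,
        }
        return out


_QUANTITY_KEYS = {
    "membrane": {"es0", "eb", "ka", "kd", "k0", "k_omega", "eta_m",
                 "mass_total"},
    "adhesion": {"gamma_ifgr", "gamma_ifg", "gamma_mfg", "beta", "r0",
                 "r_cutoff", "r_glyco", "mu_gap", "eps_gap"},
    "transport": {"d_mfg", "delta_fg"},
    "pathophys": {"gamma_mfg_b"},
    "protocol": {"duration", "dt", "pulling_rate", "escape_threshold",
                 "initial_gap", "snapshot_interval", "equilibration",
                 "cell_diameter", "perturbation"},
}
_PLAIN_KEYS = {
    "membrane": {"eta_relation"},
    "adhesion": {"scheme"},
    "transport": {"adsorption_on", "phi0", "n0", "nb_fg"},
    "pathophys": {"n_star", "gamma_star", "n_b_rbc1", "n_b_rbc2"},
    "protocol": {"protocol", "trap_patch_fraction",
                 "initial_offset_fraction", "n_vertices", "transport_stride",
                 "contact_reassign_every", "nave0", "rng_seed"},
}
_SECTION_TYPES = {
    "membrane": MembraneParams,
    "adhesion": AdhesionParams,
    "transport": TransportParams,
    "pathophys": PathophysParams,
    "protocol": ProtocolConfig,
}


def _build_section(section: str, raw: dict):
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"section {section!r} must be a mapping")
    kwargs = {}
    for key, value in raw.items():
        path = f"{section}.{key}"
        if key in _QUANTITY_KEYS[section]:
            kwargs[key] = None if value is None else parse_quantity(value, path)
        elif key in _PLAIN_KEYS[section]:
            kwargs[key] = value
        else:
            raise ConfigurationError(f"unknown key {path!r}")
    return _SECTION_TYPES[section](**kwargs)


def config_from_dict(raw: dict, name: str = "run") -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    known = set(_SECTION_TYPES) | {"output_dir", "log_level", "name"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown section(s): {sorted(unknown)}")
    cfg = RunConfig(
        membrane=_build_section("membrane", raw.get("membrane")),
        adhesion=_build_section("adhesion", raw.get("adhesion")),
        transport=_build_section("transport", raw.get("transport")),
        pathophys=(_build_section("pathophys", raw["pathophys"])
                   if raw.get("pathophys") else None),
        protocol=_build_section("protocol", raw.get("protocol")),
        output_dir=raw.get("output_dir", "."),
        log_level=raw.get("log_level", "info"),
        name=raw.get("name", name),
    )
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw, name=str(path))


def list_presets() -> list[str]:
    """Names of the shipped parameter presets (``<group>/<name>``)."""
    root = importlib.resources.files("rbc_cbmm") / "presets"
    out = []
    for sub in sorted(root.iterdir()):
        if sub.is_dir():
            for f in sorted(sub.iterdir()):
                if f.name.endswith(".yaml"):
                    out.append(f"{sub.name}/{f.name[:-5]}")
    return out


def load_preset(name: str) -> RunConfig:
    """Load a shipped preset by ``<group>/<name>``."""
    root = importlib.resources.files("rbc_cbmm") / "presets"
    path = root / f"{name}.yaml"
    try:
        text = path.read_text()
    except (FileNotFoundError, NotADirectoryError):
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {list_presets()}")
    return config_from_dict(yaml.safe_load(text), name=name)
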