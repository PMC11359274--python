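"""Run configuration: TOML schema, validation and packaged sample presets.

The schema mirrors the simulation-box conditions of the five reported
amorphous samples: ``[system]`` (density, molecule count, bond expansion,
rotation count), ``[mc]`` (temperature, move amplitudes, seed), ``[ep]``
(empirical-potential cap/rate/period) and ``[collect]`` (ensemble counts).
Unknown keys are rejected.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

__all__ = ["RefinementConfig", "read_config", "write_config", "preset", "PRESETS"]

_SCHEMA = {
    "system": {"density", "n_molecules", "bond_expansion", "rotations",
               "rotation_amplitude"},
    "mc": {"temperature", "translation", "rotation", "group_rotation", "seed"},
    "ep": {"cap", "rate", "period"},
    "collect": {"n_equil_sweeps", "n_collect", "collect_stride"},
}


@dataclass(frozen=True)
class RefinementConfig:
    density: float = 0.0925
    n_molecules: int = 64
    bond_expansion: float = 0.0
    rotations: int = 5          # number of enabled group rotations (0 or 5)
    rotation_amplitude: float = 180.0  # deg; "a few degrees" for rigid models
    temperature: float = 300.0
    translation: float = 0.3
    rotation: float = 10.0
    group_rotation: float = 10.0
    seed: int = 0
    ep_cap: float = 2.0
    ep_rate: float = 0.1
    ep_period: int = 50
    n_equil_sweeps: int = 2000
    n_collect: int = 500
    collect_stride: int = 2

    def __post_init__(self):
        if not 0.01 <= self.density <= 0.2:
            raise ValueError(f"density {self.density} atoms/A^3 out of range")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.rotations not in (0, 5):
            # the rotation count is a free integer in principle; the packaged
            # models are either fully rigid (0) or fully semi-rigid (5)
            raise ValueError("rotations must be 0 or 5 in packaged presets")
        for name in ("temperature", "translation", "rotation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.group_rotation < 0:
            raise ValueError("group_rotation must be non-negative")


# Per-sample presets: densities and rotation settings of the five reported
# amorphous samples (I, II: low density, semi-rigid; III: intermediate;
# IV, V: high density, rigid with slight variation), with the reported
# mean C-X bond expansions.
PRESETS = {
    "sample_I": RefinementConfig(density=0.0900, rotations=5, bond_expansion=0.015),
    "sample_II": RefinementConfig(density=0.0900, rotations=5, bond_expansion=0.015),
    "sample_III": RefinementConfig(density=0.0925, rotations=5, bond_expansion=0.036),
    "sample_IV": RefinementConfig(density=0.0950, rotations=0, bond_expansion=0.041,
                                  rotation_amplitude=5.0, group_rotation=2.0),
    "sample_V": RefinementConfig(density=0.0950, rotations=0, bond_expansion=0.036,
                                 rotation_amplitude=5.0, group_rotation=2.0),
}


def preset(name: str) -> RefinementConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None


_FIELD_SECTION = {
    "density": ("system", "density"),
    "n_molecules": ("system", "n_molecules"),
    "bond_expansion": ("system", "bond_expansion"),
    "rotations": ("system", "rotations"),
    "rotation_amplitude": ("system", "rotation_amplitude"),
    "temperature": ("mc", "temperature"),
    "translation": ("mc", "translation"),
    "rotation": ("mc", "rotation"),
    "group_rotation": ("mc", "group_rotation"),
    "seed": ("mc", "seed"),
    "ep_cap": ("ep", "cap"),
    "ep_rate": ("ep", "rate"),
    "ep_period": ("ep", "period"),
    "n_equil_sweeps": ("collect", "n_equil_sweeps"),
    "n_collect": ("collect", "n_collect"),
    "collect_stride": ("collect", "collect_stride"),
}


def read_config(path) -> RefinementConfig:
    """Read and validate a TOML run configuration; unknown keys rejected."""
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    kwargs = {}
    for section, table in doc.items():
        if section not in _SCHEMA:
            raise KeyError(f"unknown config section [{section}]")
        if not isinstance(table, dict):
            raise TypeError(f"[{section}] must be a table")
        for key, value in table.items():
            if key not in _SCHEMA[section]:
                raise KeyError(f"unknown key {key!r} in [{section}]")
            fname = next(f for f, (s, k) in _FIELD_SECTION.items()
                         if s == section and k == key)
            kwargs[fname] = value
    return RefinementConfig(**kwargs)


def write_config(path, config: RefinementConfig) -> None:
    sections: dict[str, list[str]] = {}
    for fname, value in asdict(config).items():
        section, key = _FIELD_SECTION[fname]
        sections.setdefault(section, []).append(f"{key} = {value!r}")
    with open(path, "w") as fh:
        for section in _SCHEMA:
            fh.write(f"[{section}]\n")
            for line in sections.get(section, []):
                fh.write(line + "\n")
            fh.write("\n")
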