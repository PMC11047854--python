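"""Run configuration: YAML-backed, validated, fruit-fly defaults.

An empty config file yields the full default model: the fruit-fly wing of
the reference morphology (Re about 134), the standard stroke amplitudes and
phases with elevation initial phase 10 deg, 32 cells per chord, lattice tip
speed 0.04, a 40-chord four-tier domain and seven flapping cycles.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .kinematics import PhysicalWing, WingKinematics

__all__ = ["SolverConfig", "ExperimentConfig", "OutputConfig", "RunConfig",
           "load_config", "save_config"]


@dataclass(frozen=True)
class SolverConfig:
    resolution: int = 32          # cells per mean chord on the finest tier
    u_lattice: float = 0.04       # cycle-mean tip speed in lattice units
    cycles: int = 7
    reporting_cycle: int = 6
    domain_chords: float = 40.0
    n_tiers: int = 4

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be a positive integer")
        if not 0 < self.u_lattice < 0.3:
            raise ValueError("lattice tip speed must be in (0, 0.3)")
        if self.cycles < 1 or self.reporting_cycle > self.cycles:
            raise ValueError("need at least one cycle and a valid reporting cycle")
        if self.domain_chords <= 0 or self.n_tiers < 1:
            raise ValueError("bad domain size or tier count")


@dataclass(frozen=True)
class ExperimentConfig:
    phi_e0_list: tuple = tuple(float(p) for p in range(0, 360, 45))
    reynolds_list: tuple = (33.5, 67.0, 134.0, 268.0, 536.0)


@dataclass(frozen=True)
class OutputConfig:
    outdir: str = "runs"
    csv_stride: int = 1
    field_stride: int = 0         # 0 disables VTK export
    checkpoint_stride: int = 0


@dataclass(frozen=True)
class RunConfig:
    wing: PhysicalWing = field(default_factory=PhysicalWing)
    kinematics: WingKinematics = field(default_factory=WingKinematics)
    solver: SolverConfig = field(default_factory=SolverConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(asdict(self))


_SECTIONS = {
    "wing": PhysicalWing,
    "kinematics": WingKinematics,
    "solver": SolverConfig,
    "experiment": ExperimentConfig,
    "output": OutputConfig,
}


def _build_section(cls, data: dict, errors: list, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        errors.append(f"{path}.{key}: unknown key")
    kwargs = {k: v for k, v in data.items() if k in known}
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as err:
        errors.append(f"{path}: {err}")
        return cls()


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are itemized."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    errors: list[str] = []
    sections = {}
    for name, cls in _SECTIONS.items():
        block = data.pop(name, {}) or {}
        if not isinstance(block, dict):
            errors.append(f"{name}: must be a mapping")
            block = {}
        sections[name] = _build_section(cls, block, errors, name)
    for key in sorted(data):
        errors.append(f"{key}: unknown section")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return RunConfig(**sections)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
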