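"""Run configuration: every pipeline parameter in one serializable object.

The YAML schema is strict: unknown keys are rejected so typos cannot
silently fall back to defaults. Defaults mirror the screening and tracer
methods (min count 100 in vitro / 25 in vivo, pseudocount 10, top-7
phenotype score, untreated-arm exclusion at -0.12 / 1.5, per-amino-acid
regression windows, 0.64e6 effective cells).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigError
from .kinetics import DEFAULT_IMPORT_WINDOWS, DEFAULT_N_CELLS


@dataclass
class ScoringConfig:
    min_count: float = 100.0
    min_count_invivo: float = 25.0
    pseudocount: float = 10.0
    top_k: int = 7
    min_sgrnas: int = 5
    p_floor: float = 1e-16
    threshold_source: str = "per_replicate"
    untreated_threshold: float = -0.12
    resistant_cutoff: float = 1.5
    hypersensitive_cutoff: float = -1.5


@dataclass
class TracerConfig:
    windows_s: dict = field(default_factory=lambda: dict(DEFAULT_IMPORT_WINDOWS))
    n_cells: float = DEFAULT_N_CELLS
    initial_volume_ul: float = 300.0
    per_sample_volume_ul: float = 15.0
    tic_variant_import: str = "ratio_to_mean"
    tic_variant_consumption: str = "regression"


@dataclass
class SimulationConfig:
    n_replicates: int = 2
    reads_per_sgrna: float = 500.0
    doublings: float = 8.0
    sigma_abundance: float = 0.5


@dataclass
class RunConfig:
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    tracer: TracerConfig = field(default_factory=TracerConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable content hash of the configuration."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _build(cls, data: dict, path: str):
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under {path or 'top level'}")
    kwargs = {}
    for name, val in data.items():
        ftype = allowed[name].type
        if isinstance(val, dict) and ftype in ("ScoringConfig", "TracerConfig", "SimulationConfig"):
            sub = {"ScoringConfig": ScoringConfig, "TracerConfig": TracerConfig,
                   "SimulationConfig": SimulationConfig}[ftype]
            kwargs[name] = _build(sub, val, f"{path}.{name}" if path else name)
        else:
            kwargs[name] = val
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    sections = {"scoring": ScoringConfig, "tracer": TracerConfig, "simulation": SimulationConfig}
    unknown = set(data) - set(sections) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in sections.items():
        if name in data:
            kwargs[name] = _build(cls, data[name] or {}, name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration file must contain a mapping")
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
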