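"""Run configuration: one plain-text (YAML) file drives the whole pipeline.

The defaults reproduce the method's published constants: bandpass
gradient g = 0.02, fiducial selection fraction 0.5%, neighbour offset
10 px, 128 histogram bins, search schedules +-20/4 then +-2/1 (global)
and +-10/2 then +-1/1 (subregions), singular-value cutoff ratios 1.2
(inter-fraction) and 7.0 (intra-fraction), 5 fractions and 10 stochastic
repeats on a 2 mm dose grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "GeometryConfig",
    "CohortConfig",
    "PreprocessConfig",
    "ModelConfig",
    "DoseConfig",
    "RunConfig",
    "load_config",
    "save_config",
]


@dataclass
class GeometryConfig:
    image_size: int = 128
    pixel_spacing_mm: float = 2.5


@dataclass
class CohortConfig:
    n_patients: int = 4
    n_fractions: int = 3
    n_images: int = 6
    noise_level: float = 0.05
    intensity_perturbation: float = 0.10
    baseline_sigma_mm: float = 5.0
    include_fiducials: bool = True


@dataclass
class PreprocessConfig:
    g: float = 0.02
    top_fraction: float = 0.005
    neighbour_offset: int = 10
    equalization_grid: int = 5  # fixed 5x5 partition


@dataclass
class ModelConfig:
    r_inter: float = 1.2
    r_intra: float = 7.0


@dataclass
class DoseConfig:
    n_fractions: int = 5
    n_repeats: int = 10
    n_beams: int = 60
    prescription_gy: float = 35.0
    grid_spacing_mm: float = 2.0
    grid_half_extent_mm: float = 60.0


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    dose: DoseConfig = field(default_factory=DoseConfig)
    #: optional overrides applied to the phantom configuration
    phantom: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config block {path!r}")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML file; unknown keys are rejected."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    kwargs = {}
    for f in dataclasses.fields(RunConfig):
        if f.name not in data:
            continue
        block = data.pop(f.name)
        if f.name in ("phantom",):
            kwargs[f.name] = dict(block or {})
        elif f.name == "seed":
            kwargs[f.name] = int(block)
        else:
            kwargs[f.name] = _build(f.type if isinstance(f.type, type) else
                                    {"geometry": GeometryConfig,
                                     "cohort": CohortConfig,
                                     "preprocess": PreprocessConfig,
                                     "model": ModelConfig,
                                     "dose": DoseConfig}[f.name],
                                    block or {}, f.name)
    if data:
        raise ValueError(f"unknown top-level config key(s) {sorted(data)} in {path}")
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
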