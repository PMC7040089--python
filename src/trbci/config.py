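"""Pipeline configuration: YAML schema, strict validation, hashing.

The configuration mirrors the pipeline stages — protocol, acquisition,
optics, hemodynamics, noise, cohort, processing, decoding — and every
stochastic entry point carries an explicit seed.  Unknown keys are rejected
and the canonical hash of the validated configuration is stamped into all
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .protocol import ProtocolDesign, build_protocol
from .simulate import AcquisitionConfig, CohortConfig, NoiseConfig


@dataclass
class OpticsConfig:
    n_photons: int = 1_000_000
    mc_seed: int = 20260921
    mu_a: float = 0.017
    mu_s_prime: float = 1.0
    n_layers: int = 10
    layer_thickness_mm: float = 2.0
    brain_layers: tuple[int, ...] = tuple(range(5, 11))
    separation_mm: float = 30.0
    detector_radius_mm: float = 2.0
    external_n: float = 1.0
    delta_mua: float = 0.001


@dataclass
class ProcessingConfig:
    rise_frac: float = 0.10
    fall_frac: float = 0.01
    window_mode: str = "baseline"  # or "per_frame"
    baseline_frames: int | None = None  # default: the whole 30-s baseline
    motion_correction: bool = True
    motion_window_s: float = 1.0
    motion_k: float = 3.0
    spline_smoothing: float = 0.001
    cutoff_period_s: float = 128.0
    smooth_fwhm_s: float = 4.0
    smooth_shape: str = "gaussian"
    slope_window_s: float = 16.0


@dataclass
class DecodingConfig:
    methods: tuple[str, ...] = ("LDA", "SVM")
    primary_method: str = "SVM"
    cycles_curve: bool = True
    nested: bool = False


@dataclass
class PipelineConfig:
    protocol: ProtocolDesign = field(default_factory=ProtocolDesign)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    master_seed: int = 1

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SECTIONS = {
    "protocol": ProtocolDesign,
    "acquisition": AcquisitionConfig,
    "optics": OpticsConfig,
    "noise": NoiseConfig,
    "cohort": CohortConfig,
    "processing": ProcessingConfig,
    "decoding": DecodingConfig,
}


def _build_section(cls, data: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in section '{name}': {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name in data:
            value = data[f.name]
            if isinstance(value, list):
                value = tuple(value)
            coerced[f.name] = value
    if cls is ProtocolDesign:
        return build_protocol(**coerced)
    return cls(**coerced)


def load_config(path_or_dict: str | Path | dict) -> PipelineConfig:
    """Load and strictly validate a YAML (or dict) pipeline configuration."""
    if isinstance(path_or_dict, (str, Path)):
        data = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        data = dict(path_or_dict)
    unknown = set(data) - set(_SECTIONS) - {"master_seed"}
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {
        name: _build_section(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    cfg = PipelineConfig(master_seed=int(data.get("master_seed", 1)), **kwargs)
    if cfg.decoding.primary_method not in ("LDA", "SVM"):
        raise ValueError("primary_method must be 'LDA' or 'SVM'")
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
    return path
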