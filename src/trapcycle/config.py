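"""Structured pipeline configuration (YAML) with strict key validation.

Unknown keys anywhere in the file are rejected before any computation, so a
typo in a threshold name cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .preprocess import FilterThresholds
from .synthetic_data import SimSpec

__all__ = ["QCConfig", "RankConfig", "HarmonicConfig", "PathsConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class QCConfig:
    period: float = 24.0
    phase_step: float = 0.5
    min_best_r: float = 0.8
    min_replicate_r: float = 0.9
    controls: tuple[str, ...] = ()


@dataclass(frozen=True)
class RankConfig:
    period: float = 24.0
    phase_step: float = 4.0


@dataclass(frozen=True)
class HarmonicConfig:
    order: int = 6
    period_range: tuple[float, float] = (20.0, 28.0)
    methods: tuple[str, ...] = ("yule_walker", "burg")


@dataclass(frozen=True)
class PathsConfig:
    counts: str = ""
    sample_sheet: str = ""
    categories: str = ""
    outdir: str = "trapcycle_out"


@dataclass(frozen=True)
class PipelineConfig:
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    qc: QCConfig = field(default_factory=QCConfig)
    rank: RankConfig = field(default_factory=RankConfig)
    harmonic: HarmonicConfig = field(default_factory=HarmonicConfig)
    simulate: SimSpec = field(default_factory=SimSpec)
    paths: PathsConfig = field(default_factory=PathsConfig)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_SECTIONS = {
    "filters": FilterThresholds,
    "qc": QCConfig,
    "detect": None,  # nested: rank / harmonic
    "simulate": SimSpec,
    "paths": PathsConfig,
}

_TUPLE_FIELDS = {
    "cts",
    "amplitude_range",
    "phase_modes",
    "period_range",
    "methods",
    "controls",
}


def _build(cls, data: dict, where: str):
    valid = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - valid
    if unknown:
        raise ValidationError(f"unknown config key(s) under {where}: {sorted(unknown)}")
    kwargs = {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v for k, v in data.items()}
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config; absent file or sections mean package defaults."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = {**data, **overrides}
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValidationError(f"unknown top-level config key(s): {sorted(unknown)}")
    detect = data.get("detect", {}) or {}
    if not isinstance(detect, dict):
        raise ValidationError("config key 'detect' must be a mapping")
    unknown = set(detect) - {"rank", "harmonic"}
    if unknown:
        raise ValidationError(f"unknown config key(s) under detect: {sorted(unknown)}")
    return PipelineConfig(
        filters=_build(FilterThresholds, data.get("filters", {}) or {}, "filters"),
        qc=_build(QCConfig, data.get("qc", {}) or {}, "qc"),
        rank=_build(RankConfig, detect.get("rank", {}) or {}, "detect.rank"),
        harmonic=_build(HarmonicConfig, detect.get("harmonic", {}) or {}, "detect.harmonic"),
        simulate=_build(SimSpec, data.get("simulate", {}) or {}, "simulate"),
        paths=_build(PathsConfig, data.get("paths", {}) or {}, "paths"),
    )
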