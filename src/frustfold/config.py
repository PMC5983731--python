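"""Run configuration: a single YAML file, validated up front.

Unknown keys are rejected so typos never silently fall back to defaults.
CLI flags override file values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .params import ModelParams
from .vtf import VTFConfig

__all__ = ["RunConfig", "load_config", "provenance_header"]


@dataclass
class AnalysisSettings:
    fe_bins: int = 50          # free-energy profile binning
    burn_in_fraction: float = 0.25
    r_c: float = 10.0          # generic contact-map cutoff, A
    hold_ratio: float = 1.2    # contact-hold criterion r <= hold_ratio * r0


@dataclass
class RunConfig:
    structure: str | None = None      # input PDB path
    topology: str | None = None       # topology JSON path
    output_dir: str = "."
    chain: str | None = None
    mutations: list = field(default_factory=list)
    params: ModelParams = field(default_factory=ModelParams)
    vtf: VTFConfig = field(default_factory=lambda: VTFConfig(
        n_t=50_000, n_epochs=60, save_stride=50))
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        def enc(obj):
            if isinstance(obj, ModelParams):
                return obj.to_dict()
            if hasattr(obj, "__dataclass_fields__"):
                return {f.name: enc(getattr(obj, f.name))
                        for f in fields(obj)}
            return obj
        return enc(self)


def _build(cls, data: dict, path: str = ""):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)}"
                         + (f" under '{path}'" if path else ""))
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "params":
            kwargs[f.name] = ModelParams.from_dict(v)
        elif f.name == "vtf":
            kwargs[f.name] = _build(VTFConfig, v, "vtf")
        elif f.name == "analysis":
            kwargs[f.name] = _build(AnalysisSettings, v, "analysis")
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path_or_text: str, is_text: bool = False) -> RunConfig:
    """Load and validate a YAML run configuration."""
    text = path_or_text if is_text else open(path_or_text).read()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    return _build(RunConfig, data)


def provenance_header(config: RunConfig, comment: str = "#") -> str:
    """Reproducibility header written on top of every output table."""
    from . import __version__
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return (f"{comment} frustfold {__version__}  seed={config.seed}  "
            f"config_sha256={digest}\n")
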