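"""Pipeline configuration.

Defaults pin the analysis constants of the protocol: the 1.5 s apnea
threshold, the FDR < 0.05 and ±1.2 fold-change deregulation cut, 20 µl
calibration injections at 3 Hz, the 10 s / 60 s / 300 s ventilation
window rule and the 600 s pattern rule, P ≤ 0.05 significance, and
GREAT-default regulatory-domain sizes (5 kb / 1 kb basal, 1 Mb
extension). Configs load from YAML; every field is validated on
construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

from .pleth import InputError


@dataclass
class PipelineConfig:
    apnea_threshold_s: float = 1.5
    fdr_threshold: float = 0.05
    fc_threshold: float = 1.2
    significance_p: float = 0.05
    min_segment_s: float = 10.0
    min_total_s: float = 60.0
    tail_s: float = 300.0
    pattern_total_s: float = 600.0
    calibration_volume_ul: float = 20.0
    calibration_rate_hz: float = 3.0
    basal_up_bp: int = 5000
    basal_down_bp: int = 1000
    max_extension_bp: int = 1_000_000
    cv_definition: str = "se"  # "se" (SE/mean) or "sd" (SD/mean)
    require_reciprocal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "apnea_threshold_s",
            "fdr_threshold",
            "fc_threshold",
            "significance_p",
            "min_segment_s",
            "min_total_s",
            "tail_s",
            "pattern_total_s",
            "calibration_volume_ul",
            "calibration_rate_hz",
            "basal_up_bp",
            "basal_down_bp",
            "max_extension_bp",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.cv_definition not in ("se", "sd"):
            raise InputError("cv_definition must be 'se' or 'sd'")
        if not isinstance(self.seed, int):
            raise InputError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputError("config YAML must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
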