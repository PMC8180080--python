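"""Pipeline configuration: one structured object, YAML-loadable, with the
screening defaults of the study design (alpha 0.05 over all compounds,
detection cutoff 60%, discovery cohort of 100, one orthogonal OPLS-DA
component, 7 CV folds)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .datamodel import DEFAULT_CONTAMINANT_PATTERNS


@dataclass(frozen=True)
class PipelineConfig:
    alpha: float = 0.05
    detection_cutoff: float = 0.6
    discovery_size: int = 100
    seed: int = 0
    oplsda_n_orthogonal: int = 1
    oplsda_cv_folds: int = 7
    pca_components: int = 2
    ridge: float | None = None  # None -> 1e-6 * n at fit time
    log_transform_panel: bool = False
    contaminant_patterns: tuple[str, ...] = DEFAULT_CONTAMINANT_PATTERNS
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def digest(self) -> str:
        payload = asdict(self)
        payload["contaminant_patterns"] = list(self.contaminant_patterns)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "contaminant_patterns" in data:
            data["contaminant_patterns"] = tuple(data["contaminant_patterns"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["contaminant_patterns"] = list(self.contaminant_patterns)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
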