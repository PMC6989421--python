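"""Run configuration: a YAML-serialisable record of every pipeline choice.

Every run writes its resolved configuration (plus a content hash) beside
its outputs, so any result can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InputError


@dataclass
class RunConfig:
    cohort_dir: str = ""
    output_dir: str = "out"
    basis_id: str = "biharmonic_r"
    smoothing_alpha: float = 1.0
    variance_estimator: str = "mean"
    exclusions: list = field(default_factory=list)
    seed: int = 0
    flip_z: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @staticmethod
    def load(path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        known = RunConfig().to_dict().keys()
        unknown = sorted(set(data) - set(known))
        if unknown:
            raise InputError(f"unknown config key(s): {unknown}")
        return RunConfig(**data)
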