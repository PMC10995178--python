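"""Pipeline configuration: a YAML-serializable record of every knob.

The configuration round-trips losslessly through YAML, and its SHA-256 hash
is stamped into every numeric output file so a run can be reproduced
byte-for-byte from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

__all__ = ["PipelineConfig", "config_hash"]


@dataclass
class PipelineConfig:
    """All parameters of one end-to-end pipeline run.

    Either ``scenario`` (a synthetic preset name, with optional parameter
    ``overrides``) or explicit ``snapshot_paths`` + ``lineage_paths`` must
    be given.
    """

    scenario: Optional[str] = "gynoecium"
    overrides: Dict = field(default_factory=dict)
    snapshot_paths: List[str] = field(default_factory=list)
    lineage_paths: List[str] = field(default_factory=list)

    # axis grid control points (µm); default: straight axes from the bounding
    # box of each snapshot (medial midline for v=0)
    longitudinal_control_points: Optional[List[List[float]]] = None
    mediolateral_control_points: Optional[List[List[float]]] = None

    # distance / profile settings
    n_bins: int = 8
    # normalization domain for mediolateral fields: "region" or "organ"
    normalization_domain: str = "region"

    # gradient statistic parameters
    alpha: float = 0.05
    delta: float = 0.1
    min_consecutive: int = 2
    n_permutations: int = 999

    seed: int = 0
    out_dir: str = "organgrowth_out"
    heatmaps: bool = False

    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(d: Dict) -> str:
    """SHA-256 of the canonical JSON serialization of a config dict."""
    blob = json.dumps(d, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
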