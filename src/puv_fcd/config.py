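"""Pipeline configuration with the published parameter choices as defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the detection pipeline.

    Defaults reproduce the published parameter choices: a 3x3x3 normative
    window (N=27 neighbors), feature group FG6, all four base classifiers,
    opening window Lw=3, and a region-size threshold of 112.5 mm^3
    (900 voxels at 0.5 mm isotropic spacing). The threshold is configured as
    a physical volume and converted to voxels via the working spacing.
    """

    working_spacing_mm: Optional[tuple[float, float, float]] = None
    window_edge: int = 3
    feature_group: str = "FG6"
    classifier_kinds: tuple[str, ...] = ("NB", "LDA", "QDA", "MDA")
    lw: int = 3
    ts_mm3: float = 112.5
    connectivity: int = 26
    qda_variant: str = "full"
    ridge: float = 1e-6
    neg_per_pos: int = 10
    scale_features: bool = True
    standardize_lo: float = 1.0
    standardize_hi: float = 99.0
    zone_lo: float = 0.1
    zone_hi: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.window_edge < 1 or self.window_edge % 2 == 0:
            raise ValueError("window_edge must be odd and >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.qda_variant not in ("full", "printed"):
            raise ValueError("qda_variant must be 'full' or 'printed'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["working_spacing_mm"] is not None:
            d["working_spacing_mm"] = list(d["working_spacing_mm"])
        d["classifier_kinds"] = list(d["classifier_kinds"])
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "working_spacing_mm" in raw and raw["working_spacing_mm"] is not None:
            raw["working_spacing_mm"] = tuple(raw["working_spacing_mm"])
        if "classifier_kinds" in raw:
            raw["classifier_kinds"] = tuple(raw["classifier_kinds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
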