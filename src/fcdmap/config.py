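"""Pipeline configuration: one dataclass, YAML round-trip, stable hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .segmentation import SegmentationConfig


@dataclass
class PipelineConfig:
    """All tunable parameters of the end-to-end pipeline.

    Scales: ``pixel_size_slide`` is the whole-section scan resolution,
    ``pixel_size_cell`` the high-resolution crop scale (um/px). The fence
    variant, minimum flagged-region length and thickness sampling step
    drive the detection stage; granulometry sizes and the segmentation
    block drive the cellular stage.
    """

    pixel_size_slide: float = 25.0  # um/px
    pixel_size_cell: float = 0.74  # um/px
    solver_tol: float = 1e-6
    sample_step_um: float = 200.0
    curvature_window_um: float = 2000.0
    trim_um: float = 1000.0
    fence_variant: str = "adjusted"  # or "tukey"
    min_region_len_um: float = 1000.0
    max_dy_mm: float = 1.2
    granulometry_step_um: float = 0.74
    granulometry_max_um: float = 30.0
    seed: int = 0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    def __post_init__(self):
        if isinstance(self.segmentation, dict):
            self.segmentation = SegmentationConfig(**self.segmentation)
        for name in ("pixel_size_slide", "pixel_size_cell", "solver_tol",
                     "sample_step_um", "min_region_len_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fence_variant not in ("adjusted", "tukey"):
            raise ValueError("fence_variant must be 'adjusted' or 'tukey'")
        if not 1.0 < self.segmentation.p <= 2.0:
            raise ValueError("segmentation.p must be in (1, 2]")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
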