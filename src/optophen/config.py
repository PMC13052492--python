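"""Pipeline configuration: one YAML document drives every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .synthgen import SynthConfig


@dataclass
class PipelineConfig:
    """Resolved configuration for a full synthetic run.

    Geometry, thresholds, ROI size and k live here so a run directory
    can be reproduced from the config snapshot plus seeds alone.
    """

    seed: int = 0
    synth: dict = field(default_factory=dict)      # SynthConfig overrides
    roi_size: int = 70
    valid_lo: int = 2000
    valid_hi: int = 65535
    glcm_levels: int = 64
    abundance_mode: str = "ratio"
    k: int | None = None           # phenotype count; None -> true cluster count
    scan_k: tuple[int, int] | None = None
    svm_folds: int = 5
    cnn_folds: int = 10
    cnn_epochs: int = 50
    tile_px: int = 32
    tile_mode: str = "native"
    alpha: float = 1e-3

    def synth_config(self) -> SynthConfig:
        kw = dict(self.synth)
        for key in ("channel_means", "texture_corr_lengths"):
            if key in kw and kw[key] is not None:
                kw[key] = np.asarray(kw[key], float)
        if "grid_shape" in kw:
            kw["grid_shape"] = tuple(kw["grid_shape"])
        kw.setdefault("seed", self.seed)
        return SynthConfig(**kw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scan_k" in raw and raw["scan_k"] is not None:
            raw["scan_k"] = tuple(raw["scan_k"])
        return cls(**raw)
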