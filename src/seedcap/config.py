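"""Pipeline configuration: one JSON-serialisable object holding every fixed
constant of the analysis (thresholds, seed definition, consensus parameters,
RNG seed)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from ._errors import ConfigurationError

#: Seed presets: right / left temporo-parietal junction, MNI mm.
SEED_PRESETS = {
    "rtpj": (62.0, -34.0, 30.0),
    "ltpj": (-62.0, -34.0, 30.0),
}


@dataclass
class PipelineConfig:
    """All tunables of the CAP pipeline.

    Defaults reproduce the canonical analysis: FD scrubbing at 0.5 mm with 30%
    subject exclusion, seed-frame selection at z > 0.84 (80th percentile), map
    thresholding at |z| >= 1.04 (15% tails), matching gate at the 5th
    percentile, PCA to 90% variance and consensus clustering over K = 2..8
    with 100 subsamples of 80% of frames.
    """

    seed_preset: str = "rtpj"
    seed_center_mm: tuple[float, float, float] | None = None
    seed_radius_mm: float = 10.0
    fd_threshold_mm: float = 0.5
    exclusion_fraction: float = 0.30
    frame_z: float = 0.84
    map_z: float = 1.04
    gate_percentile: float = 5.0
    variance_target: float = 0.90
    k: int | None = None
    k_range: tuple[int, int] = (2, 8)
    n_iter: int = 100
    subsample_fraction: float = 0.8
    tr_seconds: float | None = None
    rng_seed: int = 0
    #: optional synthetic-cohort parameters (kwargs of SyntheticConfig);
    #: when set, the pipeline simulates its own cohort instead of reading one.
    synthetic: dict | None = None
    #: optional path to a cohort manifest JSON (see seedcap.io).
    manifest: str | None = None

    def __post_init__(self) -> None:
        if self.seed_preset not in (*SEED_PRESETS, "custom"):
            raise ConfigurationError(f"unknown seed preset {self.seed_preset!r}")
        if self.seed_preset == "custom" and self.seed_center_mm is None:
            raise ConfigurationError("custom seed preset needs seed_center_mm")
        for name, lo, hi in (
            ("exclusion_fraction", 0.0, 1.0),
            ("subsample_fraction", 0.0, 1.0),
            ("gate_percentile", 0.0, 100.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigurationError(f"{name}={v} outside [{lo}, {hi}]")
        if not 0 < self.variance_target <= 1:
            raise ConfigurationError("variance_target must be in (0, 1]")
        if self.fd_threshold_mm <= 0 or self.seed_radius_mm <= 0:
            raise ConfigurationError("thresholds must be positive")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ConfigurationError("invalid k_range")

    @property
    def seed_center(self) -> tuple[float, float, float]:
        if self.seed_preset == "custom":
            return tuple(self.seed_center_mm)  # type: ignore[arg-type]
        return SEED_PRESETS[self.seed_preset]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        for key in ("seed_center_mm", "k_range"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def config_hash(self) -> str:
        """Short stable hash embedded in every output for provenance."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
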