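"""Pipeline configuration: one validated object carrying every tunable.

Defaults mirror standard resting-state practice for this analysis:
0.5-30 Hz band-pass, resampling to 500 Hz, eight eye channels excluded,
2-s epochs with 72 kept per subject/condition, four classical bands,
5% Hilbert edge trim, 5,000 permutations at alpha = 0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .containers import DEFAULT_BANDS, DEFAULT_EYE_CHANNELS, BandDefinition
from .connectivity import DEFAULT_ROIS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    filter_low: float = 0.5
    filter_high: float = 30.0
    filter_order: int = 4
    resample_rate: float = 500.0
    epoch_length: float = 2.0
    n_epochs: int | None = 72
    reject_threshold: float | None = None
    eye_channels: tuple[str, ...] = DEFAULT_EYE_CHANNELS
    rois: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ROIS)
    )
    edge_fraction: float = 0.05
    eps: float = 1e-12
    n_perm: int = 5000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.bands = tuple(
            b if isinstance(b, BandDefinition) else BandDefinition(**b)
            for b in self.bands
        )
        if not 0 < self.filter_low < self.filter_high:
            raise ValueError("need 0 < filter_low < filter_high")
        if self.filter_high > self.resample_rate / 2:
            raise ValueError("filter_high above Nyquist of resample_rate")
        for b in self.bands:
            if b.high > self.resample_rate / 2:
                raise ValueError(f"band {b.name!r} above Nyquist")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.n_epochs is not None and self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not 0 <= self.edge_fraction < 0.5:
            raise ValueError("edge_fraction must be in [0, 0.5)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [asdict(b) for b in self.bands]
        d["eye_channels"] = list(self.eye_channels)
        d["rois"] = {k: list(v) for k, v in self.rois.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(BandDefinition(**b) for b in d["bands"])
        if "eye_channels" in d:
            d["eye_channels"] = tuple(d["eye_channels"])
        if "rois" in d:
            d["rois"] = {k: tuple(v) for k, v in d["rois"].items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
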