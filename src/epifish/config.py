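"""Pipeline configuration: every analysis parameter in one object.

Defaults follow the published protocol where stated: 30-95 Hz band,
250 ms window stepped 50 ms, 2-SD threshold, 3-frame persistence,
2-neighbor support, 2x2 binning, 10 principal components, 25 s event
window, 300-voxel domain threshold, 3-px ROI radius, donut templates of
size 10 and 7 px.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    # acquisition
    sampling_rate: float = 5000.0      # Hz, LFP
    frame_rate: float = 4.0            # Hz, imaging
    pixel_size: float = 1.2            # um / raw pixel
    dark_level: float = 0.0            # counts
    # LFP power
    band_low: float = 30.0             # Hz
    band_high: float = 95.0            # Hz
    window: float = 0.25               # s, sliding RMS window
    step: float = 0.05                 # s, window step
    k_sd: float = 2.0                  # SM / binarization threshold, SDs
    trim_tol: float = 0.05             # trim-fit convergence tolerance
    trim_max_iter: int = 100
    robust_fit: bool = False
    # imaging
    bin_factor: int = 2
    min_frames: int = 3                # temporal persistence
    min_neighbors: int = 2             # spatial support (8-neighborhood)
    connectivity: int = 26             # cluster connectivity (6 or 26)
    min_cluster_volume: int = 300      # voxels, region classification
    # coupling
    lag_half_width: int | None = None  # L in frames; None = estimate
    default_L: int = 4
    # neurons
    n_pc: int = 10
    roi_radius: int = 3                # px
    template_sizes: tuple[int, int] = (10, 7)
    min_distance: int = 5              # px, detection exclusion
    score_threshold: float = 0.3
    both_threshold: float = 0.2        # class-exclusivity cutoff
    min_peak_r: float = 0.2            # pre-Ep peak significance
    event_window: float = 25.0         # s, event correlogram window
    # misc
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.band_high >= self.sampling_rate / 2:
            raise ValueError("band_high must be below Nyquist")
        if self.step > self.window or self.step <= 0:
            raise ValueError("need 0 < step <= window")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.bin_factor < 1 or self.min_frames < 1:
            raise ValueError("bin_factor and min_frames must be >= 1")

    @property
    def band(self) -> tuple[float, float]:
        return (self.band_low, self.band_high)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable hash of all parameters, recorded in every output."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must hold a key/value mapping")
        data.update(loaded)
    data.update(overrides)
    if "template_sizes" in data:
        data["template_sizes"] = tuple(data["template_sizes"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
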