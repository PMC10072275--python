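"""Pipeline configuration: one plain-text (YAML) file drives every stage.

Defaults follow the acquisition and analysis settings the pipeline is
built around: rolling-ball radius 50 px, 5-frame rolling average, 10
frames/s for ER/mitochondrial and 50 frames/s for cytosolic/postsynaptic
recordings, alpha = 0.05 for the normality gate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # simulation
    simulate: bool = True
    compartment: str = "cytosol"
    n_larvae_per_genotype: int = 10
    frequencies_hz: list = field(default_factory=lambda: [5.0, 20.0, 40.0, 80.0])
    mutant_scale: float = 0.5
    noise_sd_fraction: float = 0.02
    duration_s: float = 20.0
    stim_onset_s: float = 5.0
    stim_duration_s: float = 2.0
    # preprocessing
    rolling_ball_radius_px: int = 50
    registration_residual_threshold: float = 0.2
    min_rois: int = 3
    # trace analysis
    smoothing_window_frames: int = 5
    noise_band_k: float = 1.0
    # mini detection
    mini_threshold_sigma: float = 3.0
    mini_min_separation_s: float = 0.2
    mini_frequency_window_s: float = 5.0
    mini_counting_window_s: float = 20.0
    # statistics
    alpha: float = 0.05
    control_label: str = "WT"
    # orchestration
    input_dir: str = ""
    output_dir: str = "nmjcal_out"
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> "PipelineConfig":
        if self.rolling_ball_radius_px < 1:
            raise ValueError("rolling_ball_radius_px must be >= 1")
        if self.smoothing_window_frames % 2 == 0:
            raise ValueError("smoothing_window_frames must be odd")
        if not self.simulate and not self.input_dir:
            raise ValueError("input_dir is required when simulate is false")
        return self
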