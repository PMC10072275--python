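"""Core data containers shared across the pipeline.

The central currency is the :class:`Trace` — a single-ROI fluorescence time
series in arbitrary camera units, annotated with its frame rate, an optional
stimulation window, and experiment metadata (genotype, compartment, larva).
Movies, ROIs and the various result records are thin dataclasses around
numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

COMPARTMENTS = ("cytosol", "er", "mito", "postsynaptic")
ROI_KINDS = ("nmj", "bouton", "mitochondrion", "puncta", "background")


@dataclass(frozen=True)
class StimWindow:
    """A stimulation train: onset (s), duration (s) and pulse frequency (Hz)."""

    onset_s: float
    duration_s: float
    frequency_hz: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def validate(self, recording_duration_s: float) -> None:
        if self.onset_s < 0 or self.end_s > recording_duration_s + 1e-9:
            raise ValueError(
                f"stimulation window [{self.onset_s}, {self.end_s}] s lies "
                f"outside the recording [0, {recording_duration_s}] s"
            )
        if self.frequency_hz < 0:
            raise ValueError("stimulation frequency must be >= 0")


@dataclass
class Trace:
    """A per-ROI fluorescence time series.

    Parameters
    ----------
    values :
        Fluorescence per frame, arbitrary units (or ΔF/F units downstream).
    frame_rate_hz :
        Acquisition rate; ER/mitochondrial recordings are typically 10
        frames/s and cytosolic/postsynaptic recordings 50 frames/s.
    stim :
        Optional stimulation window metadata.
    meta :
        Free-form annotations (genotype, compartment, larva_id, nmj_id,
        batch_id, roi_id ...).
    """

    values: np.ndarray
    frame_rate_hz: float
    stim: Optional[StimWindow] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a trace needs at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.stim is not None:
            self.stim.validate(self.duration_s)

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def replace_values(self, values: np.ndarray) -> "Trace":
        """Copy of this trace with new values but identical annotations."""
        return Trace(np.asarray(values, dtype=float), self.frame_rate_hz,
                     self.stim, dict(self.meta))

    def stim_onset_frame(self) -> int:
        if self.stim is None:
            raise ValueError("trace carries no stimulation metadata")
        return int(np.floor(self.stim.onset_s * self.frame_rate_hz + 1e-9))


@dataclass
class Movie:
    """A T x H x W single-channel recording."""

    data: np.ndarray
    frame_rate_hz: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("movie data must be a T x H x W array, T >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie values must be finite")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.data.shape[1:]


@dataclass
class Roi:
    """A named pixel set on the imaging plane, stored as a boolean mask."""

    id: str
    kind: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}; expected one of {ROI_KINDS}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError(f"ROI {self.id!r} is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def pixels(self) -> np.ndarray:
        """(n, 2) array of (row, col) coordinates."""
        return np.argwhere(self.mask)

    @classmethod
    def from_pixels(cls, id: str, kind: str, pixels: Sequence, shape: tuple) -> "Roi":
        mask = np.zeros(shape, dtype=bool)
        px = np.asarray(pixels, dtype=int)
        if px.size and (px.min() < 0 or (px[:, 0] >= shape[0]).any() or (px[:, 1] >= shape[1]).any()):
            raise ValueError("ROI pixels outside image bounds")
        if px.size:
            mask[px[:, 0], px[:, 1]] = True
        return cls(id, kind, mask)


@dataclass
class BleachModel:
    """Fitted power-law photobleach curve PC(x) = a * x**b.

    The domain variable is ``x = frame_index + x_offset`` (offset 1 by
    default, so the curve is defined at the first frame).
    """

    a: float
    b: float
    fit_window: tuple
    x_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("bleach amplitude a must be > 0")
        lo, hi = self.fit_window
        if hi - lo < 3:
            raise ValueError("bleach fit window must span at least 3 frames")

    def predict(self, frame_index) -> np.ndarray:
        x = np.asarray(frame_index, dtype=float) + self.x_offset
        return self.a * np.power(x, self.b)


@dataclass
class EvokedFeatures:
    """Scalar readouts of one evoked response.

    ``resting_F`` is the fitted bleach curve evaluated at the last
    pre-stimulation frame; ``max_F`` is the maximum raw fluorescence;
    time features are in seconds relative to stimulation onset (time to
    peak) or to the peak (recovery times). Recovery times are ``None``
    when the trace never crosses the respective level.
    """

    resting_F: float
    max_F: float
    delta_F: float
    max_dff: float
    min_dff_post_stim: float
    time_to_peak_s: float
    t50_recovery_s: Optional[float]
    t100_recovery_s: Optional[float]

    def __post_init__(self) -> None:
        if self.time_to_peak_s < -1e-12:
            raise ValueError("time_to_peak_s must be >= 0")


@dataclass(frozen=True)
class MiniEvent:
    """One detected spontaneous (miniature) transient."""

    time_s: float
    amplitude_dff: float
    roi_id: str = ""

    def __post_init__(self) -> None:
        if self.amplitude_dff <= 0:
            raise ValueError("mini amplitude must be > 0")


@dataclass
class QcReport:
    """Outcome of quality-control filtering: kept vs discarded trace ids."""

    kept: list
    discarded: list  # (trace_id, reason)

    def __post_init__(self) -> None:
        bad = set(self.kept) & {tid for tid, _ in self.discarded}
        if bad:
            raise ValueError(f"traces both kept and discarded: {sorted(bad)}")

    @property
    def discard_reasons(self) -> dict:
        return dict(self.discarded)


@dataclass
class QuantResult:
    """Static-image intensity measurement over one ROI."""

    roi_id: str
    mean_intensity: float
    area_px: int
    relative_intensity: Optional[float] = None
    normalized_value: Optional[float] = None

    @property
    def sum_intensity(self) -> float:
        return self.mean_intensity * self.area_px


@dataclass
class GroupSummary:
    """Per-group descriptive statistics; n counts larvae, not NMJs."""

    label: str
    n: int
    mean: float
    sem: float
    median: float
    iqr: float


@dataclass
class StatResult:
    test_name: str
    statistic: float
    df: tuple
    p_value: float
    groups: list = field(default_factory=list)
    posthoc: Optional[list] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")
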