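"""Trace-level analysis: photobleach correction, smoothing, ΔF/F, evoked
features, and the normalizations used for group comparisons.

Photobleaching of the resting fluorescence is modeled as a power curve
``PC(x) = a * x**b`` fitted to the pre-stimulation frames (``x`` is the
1-based frame index by default) and divided out of the entire time course,
so the corrected baseline sits at 1 and ``ΔF/F = corrected - 1``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datatypes import BleachModel, EvokedFeatures, Trace


def fit_bleach(trace: Trace, prestim_end_frame: Optional[int] = None,
               x_offset: float = 1.0) -> BleachModel:
    """Fit ``PC(x) = a * x**b`` to the pre-stimulation frames.

    Ordinary least squares on ``log F`` versus ``log x`` over frames
    ``[0, prestim_end_frame)``; closed-form and exact on noiseless
    power-law data. When ``prestim_end_frame`` is omitted it is taken from
    the trace's stimulation onset.
    """
    if prestim_end_frame is None:
        prestim_end_frame = trace.stim_onset_frame()
    if prestim_end_frame < 3:
        raise ValueError("bleach fit needs at least 3 pre-stimulation frames")
    f = trace.values[:prestim_end_frame]
    if np.any(f <= 0):
        raise ValueError("pre-stimulation values must be > 0 for a log-log fit")
    x = np.arange(prestim_end_frame, dtype=float) + x_offset
    b, log_a = np.polyfit(np.log(x), np.log(f), 1)
    return BleachModel(a=float(np.exp(log_a)), b=float(b),
                       fit_window=(0, prestim_end_frame), x_offset=x_offset)


def correct_bleach(trace: Trace, model: BleachModel) -> Trace:
    """Divide the entire time course by the fitted bleach curve.

    The result is dimensionless with baseline ≈ 1.
    """
    pc = model.predict(np.arange(trace.n_frames))
    if np.any(pc <= 0):
        raise ValueError("bleach curve is non-positive over the trace domain")
    return trace.replace_values(trace.values / pc)


def rolling_average(trace: Trace, window_frames: int = 5) -> Trace:
    """Centered moving mean; the window shrinks symmetrically at the edges.

    At index ``i`` the half-width is ``min(w // 2, i, n - 1 - i)``, so no
    padding values are invented. The window must be odd.
    """
    w = int(window_frames)
    if w < 1:
        raise ValueError("window must be >= 1")
    if w % 2 == 0:
        raise ValueError("window must be odd (centered average)")
    v = trace.values
    n = v.size
    h = w // 2
    out = np.empty(n)
    for i in range(n):
        k = min(h, i, n - 1 - i)
        out[i] = v[i - k:i + k + 1].mean()
    return trace.replace_values(out)


def dff(corrected: Trace) -> Trace:
    """ΔF/F of a bleach-corrected trace: ``corrected - 1``."""
    return corrected.replace_values(corrected.values - 1.0)


def evoked_features(raw: Trace, model: BleachModel, dff_trace: Trace,
                    noise_band_k: float = 1.0,
                    min_dff_window_s: float = 2.0) -> EvokedFeatures:
    """Extract the scalar evoked-response readouts.

    * ``resting_F`` — the fitted power curve at the last pre-stimulation
      frame (the immediate pre-stimulation value of the curve).
    * ``max_F`` — maximum raw fluorescence; ``delta_F = max_F - resting_F``.
    * ``max_dff`` — maximum ΔF/F at/after stimulation onset.
    * ``min_dff_post_stim`` — minimum ΔF/F from onset to onset +
      ``min_dff_window_s`` (captures the ER release dip).
    * ``time_to_peak_s`` — onset to the ΔF/F peak.
    * ``t50_recovery_s`` — peak to the first sample at or below half peak.
    * ``t100_recovery_s`` — peak to the first sample back inside
      ``noise_band_k`` pre-stimulation SDs of baseline; ``None`` if never
      reached within the recording.
    """
    if raw.stim is None:
        raise ValueError("evoked features need stimulation metadata")
    fr = dff_trace.frame_rate_hz
    onset_frame = raw.stim_onset_frame()
    d = dff_trace.values

    resting_F = float(model.predict(max(onset_frame - 1, 0)))
    max_F = float(raw.values.max())
    delta_F = max_F - resting_F

    post = d[onset_frame:]
    peak_rel = int(np.argmax(post))
    peak_idx = onset_frame + peak_rel
    max_dff = float(d[peak_idx])
    time_to_peak_s = peak_idx / fr - raw.stim.onset_s

    win_end = min(d.size, onset_frame + int(round(min_dff_window_s * fr)))
    min_dff_post_stim = float(d[onset_frame:win_end].min())

    def _first_at_or_below(level: float) -> Optional[float]:
        below = np.nonzero(d[peak_idx:] <= level)[0]
        if below.size == 0:
            return None
        return float(below[0] / fr)

    t50 = _first_at_or_below(max_dff / 2.0)
    sigma_pre = float(d[:onset_frame].std()) if onset_frame > 1 else 0.0
    t100 = _first_at_or_below(noise_band_k * sigma_pre)

    return EvokedFeatures(resting_F=resting_F, max_F=max_F, delta_F=delta_F,
                          max_dff=max_dff, min_dff_post_stim=min_dff_post_stim,
                          time_to_peak_s=max(time_to_peak_s, 0.0),
                          t50_recovery_s=t50, t100_recovery_s=t100)


def analyze_trace(raw: Trace, smoothing_window: int = 5,
                  noise_band_k: float = 1.0,
                  prestim_end_frame: Optional[int] = None) -> tuple:
    """Full single-trace pipeline: fit, correct, smooth, ΔF/F, features.

    Returns ``(features, dff_trace, model)``. Smoothing (default 5 frames)
    is applied to the bleach-corrected trace before feature extraction.
    """
    model = fit_bleach(raw, prestim_end_frame)
    corrected = correct_bleach(raw, model)
    smoothed = rolling_average(corrected, smoothing_window)
    d = dff(smoothed)
    feats = evoked_features(raw, model, d, noise_band_k=noise_band_k)
    return feats, d, model


# -- normalizations used for cross-group figures ------------------------------


def normalize_group_to_control(values: Sequence[float], genotypes: Sequence,
                               control_label="WT") -> np.ndarray:
    """Divide every value by the control-group mean (control mean maps to 1)."""
    values = np.asarray(values, dtype=float)
    genotypes = np.asarray(genotypes)
    ctrl = values[genotypes == control_label]
    if ctrl.size == 0:
        raise ValueError(f"no datapoints with control label {control_label!r}")
    mean = ctrl.mean()
    if mean <= 0:
        raise ValueError("control-group mean must be > 0 for normalization")
    return values / mean


def normalize_timecourse_pair(wt_mean: Trace, other_mean: Trace) -> tuple:
    """Scale both mean time courses by 100 / (max - min) of the WT trace.

    After scaling, the WT max-minus-min span equals exactly 100; the other
    trace is scaled by the same single factor so shapes remain comparable.
    """
    span = float(wt_mean.values.max() - wt_mean.values.min())
    if span <= 0:
        raise ValueError("WT trace is flat; cannot normalize its span to 100")
    factor = 100.0 / span
    return (wt_mean.replace_values(wt_mean.values * factor),
            other_mean.replace_values(other_mean.values * factor))


def batch_normalize(values: Sequence[float], genotypes: Sequence,
                    batches: Sequence, control_label="WT") -> np.ndarray:
    """Divide each batch's values by that batch's control mean.

    Removes multiplicative gain differences between acquisition setups so
    batches can be pooled. Every batch must contain control datapoints.
    """
    values = np.asarray(values, dtype=float)
    genotypes = np.asarray(genotypes)
    batches = np.asarray(batches)
    out = np.empty_like(values)
    for batch in np.unique(batches):
        sel = batches == batch
        ctrl = values[sel & (genotypes == control_label)]
        if ctrl.size == 0:
            raise ValueError(f"batch {batch!r} has no {control_label!r} datapoints")
        mean = ctrl.mean()
        if mean <= 0:
            raise ValueError(f"batch {batch!r} control mean must be > 0")
        out[sel] = values[sel] / mean
    return out


def channel_ratio(numerator: Trace, denominator: Trace) -> Trace:
    """Per-frame ratio of two traces (ratiometric-sensor convenience)."""
    if numerator.n_frames != denominator.n_frames:
        raise ValueError("traces must have equal length")
    if np.any(denominator.values == 0):
        raise ValueError("denominator trace contains zeros")
    return numerator.replace_values(numerator.values / denominator.values)
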