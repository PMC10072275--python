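"""Detection and scoring of spontaneous miniature ("mini") transients.

Minis are single-vesicle neurotransmission events visible as small, sharp
ΔF/F transients in resting (unstimulated) recordings. Detection is local
maxima above a robust noise threshold: the baseline SD is estimated by the
median absolute deviation (x 1.4826), which resists contamination by the
events themselves. Amplitudes are measured relative to the trace median so
the detector is invariant to a constant offset and equivariant to gain.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .datatypes import MiniEvent, Trace

MAD_TO_SD = 1.4826


def robust_sigma(values: np.ndarray) -> float:
    """Median-absolute-deviation estimate of the noise SD."""
    v = np.asarray(values, dtype=float)
    return MAD_TO_SD * float(np.median(np.abs(v - np.median(v))))


def robust_sigma_diff(values: np.ndarray) -> float:
    """Noise SD estimated from first differences (MAD / sqrt(2)).

    Sparse transients occupy many frames but contribute only one large
    increment each, so the difference-based MAD stays calibrated even when
    events cover a sizable fraction of the recording, where the plain MAD
    of the trace is inflated by the event tails.
    """
    d = np.diff(np.asarray(values, dtype=float))
    return MAD_TO_SD * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def detect_minis(dff_trace: Trace, threshold_sigma: float = 3.0,
                 min_separation_s: float = 0.2, roi_id: str = "") -> list:
    """Detect miniature events in a resting ΔF/F trace.

    Candidate events are local maxima of the median-subtracted trace
    exceeding ``threshold_sigma`` robust SDs (difference-based MAD
    estimate), separated by at least ``min_separation_s``. Because a mini
    has a one-frame rise and a multi-frame decay while noise does not,
    three shape gates reject spurious maxima:

    * persistence — the sample after the peak stays above half threshold
      (a single-frame spike is not a transient);
    * sharp rise — the largest single-frame increment just before the peak
      is at least the threshold and a fixed fraction of the peak height
      (a ripple riding an earlier event's decay tail rises gradually);
    * elevation — the peak stands a full threshold above the median of the
      frames preceding its rise (a bounce after a noise dip does not).

    The reported event time is the rising edge, which marks the onset at
    the sampling resolution; the amplitude is the peak's median-subtracted
    ΔF/F. The recording must be at least 1 s long and must not contain a
    stimulation train.
    """
    if dff_trace.duration_s < 1.0:
        raise ValueError("mini detection needs a window of at least 1 s")
    x = dff_trace.values - np.median(dff_trace.values)
    sigma = robust_sigma_diff(dff_trace.values)
    if sigma == 0.0:
        sigma = np.finfo(float).tiny  # noiseless trace: any bump is an event
    fr = dff_trace.frame_rate_hz
    distance = max(1, int(round(min_separation_s * fr)))
    thr = threshold_sigma * sigma
    peaks, _ = find_peaks(x, height=thr, prominence=thr / 3.0, distance=distance)

    n = x.size
    increments = np.diff(x, prepend=x[0])
    lookback = max(distance, int(round(0.1 * fr)), 1)
    events = []
    prev_peak = 0
    for p in peaks:
        if p + 1 < n and x[p + 1] < 0.5 * thr:
            continue  # single-frame spike
        lo = max(1, p - lookback, prev_peak + 1)
        rise = lo + int(np.argmax(increments[lo:p + 1])) if p >= lo else p
        if increments[rise] < max(thr, 0.4 * x[p]):
            continue  # no sharp onset: decay-tail ripple
        base = float(np.median(x[max(0, rise - 4):rise])) if rise > 0 else 0.0
        if x[p] - base < thr:
            continue  # bounce after a noise dip, not a new event
        events.append(MiniEvent(time_s=float(rise / fr),
                                amplitude_dff=float(x[p]), roi_id=roi_id))
        prev_peak = p
    return events


def mini_frequency(events: Sequence[MiniEvent], window_s: float) -> float:
    """Event rate in events per second over the counting window."""
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    return len(events) / window_s


def max_mini_amplitude(dff_trace: Trace, window_s: float = 20.0,
                       start_s: float = 0.0) -> float:
    """Maximum ΔF/F reached within the counting window (default 20 s)."""
    fr = dff_trace.frame_rate_hz
    i0 = int(round(start_s * fr))
    i1 = min(dff_trace.n_frames, i0 + int(round(window_s * fr)))
    if i1 <= i0:
        raise ValueError("window lies outside the recording")
    return float(dff_trace.values[i0:i1].max())


def match_events(detected: Sequence[MiniEvent], truth_times_s: Sequence[float],
                 frame_rate_hz: float, tolerance_frames: int = 1) -> tuple:
    """Greedy one-to-one matching of detected events to ground-truth times.

    Returns ``(n_matched, n_detected, n_truth)``; recall and precision
    follow directly. Matching tolerance is ±``tolerance_frames`` at the
    sampling resolution.
    """
    tol = tolerance_frames / frame_rate_hz + 1e-9
    truth = sorted(truth_times_s)
    used = [False] * len(truth)
    matched = 0
    for ev in sorted(detected, key=lambda e: e.time_s):
        for j, t in enumerate(truth):
            if not used[j] and abs(ev.time_s - t) <= tol:
                used[j] = True
                matched += 1
                break
    return matched, len(detected), len(truth)
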