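"""File-format plumbing: multilayer TIFF movies, label-image masks, CSV
traces with plain-text metadata sidecars, and tidy result tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .datatypes import MiniEvent, Movie, QcReport, Roi, StimWindow, Trace


def write_movie(path, movie: Movie) -> None:
    """Write a movie as a multilayer grayscale TIFF (float32)."""
    tifffile.imwrite(str(path), movie.data.astype(np.float32))
    _write_sidecar(Path(path).with_suffix(".meta.txt"), {
        "frame_rate_hz": movie.frame_rate_hz,
        "channel_label": movie.channel_label,
    })


def read_movie(path, frame_rate_hz: Optional[float] = None,
               channel_label: str = "") -> Movie:
    data = tifffile.imread(str(path)).astype(float)
    if data.ndim == 2:
        data = data[None]
    sidecar = Path(path).with_suffix(".meta.txt")
    meta = _read_sidecar(sidecar) if sidecar.exists() else {}
    fr = frame_rate_hz or float(meta.get("frame_rate_hz", 0) or 0)
    if fr <= 0:
        raise ValueError("frame rate missing: pass frame_rate_hz or provide a sidecar")
    return Movie(data, fr, channel_label or str(meta.get("channel_label", "")))


def write_label_mask(path, rois: Sequence[Roi], shape: tuple) -> None:
    """Write ROIs as a 16-bit label TIFF (label i+1 = rois[i])."""
    labels = np.zeros(shape, dtype=np.uint16)
    for i, roi in enumerate(rois, start=1):
        labels[roi.mask] = i
    tifffile.imwrite(str(path), labels)
    _write_sidecar(Path(path).with_suffix(".meta.txt"), {
        f"label_{i}": f"{roi.id}:{roi.kind}" for i, roi in enumerate(rois, start=1)
    })


def read_label_mask(path) -> list:
    labels = tifffile.imread(str(path))
    sidecar = Path(path).with_suffix(".meta.txt")
    meta = _read_sidecar(sidecar) if sidecar.exists() else {}
    rois = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        name = str(meta.get(f"label_{lab}", f"roi_{lab}:nmj"))
        roi_id, _, kind = name.partition(":")
        rois.append(Roi(roi_id, kind or "nmj", labels == lab))
    return rois


def write_trace(path, trace: Trace) -> None:
    """Trace as CSV (frame, time_s, value) + key/value metadata sidecar."""
    df = pd.DataFrame({"frame": np.arange(trace.n_frames),
                       "time_s": trace.times_s, "value": trace.values})
    df.to_csv(path, index=False)
    meta = {"frame_rate_hz": trace.frame_rate_hz, **trace.meta}
    if trace.stim is not None:
        meta.update(stim_onset_s=trace.stim.onset_s,
                    stim_duration_s=trace.stim.duration_s,
                    stim_frequency_hz=trace.stim.frequency_hz)
    _write_sidecar(Path(path).with_suffix(".meta.txt"), meta)


def read_trace(path) -> Trace:
    df = pd.read_csv(path)
    meta = _read_sidecar(Path(path).with_suffix(".meta.txt"))
    fr = float(meta.pop("frame_rate_hz"))
    stim = None
    if "stim_onset_s" in meta:
        stim = StimWindow(float(meta.pop("stim_onset_s")),
                          float(meta.pop("stim_duration_s")),
                          float(meta.pop("stim_frequency_hz")))
    return Trace(df["value"].to_numpy(), fr, stim, meta)


def write_events(path, events: Sequence[MiniEvent]) -> None:
    pd.DataFrame([{"time_s": e.time_s, "amplitude_dff": e.amplitude_dff,
                   "roi_id": e.roi_id} for e in events]).to_csv(path, index=False)


def write_qc_report(path, report: QcReport) -> None:
    rows = [{"trace_id": t, "status": "kept", "reason": ""} for t in report.kept]
    rows += [{"trace_id": t, "status": "discarded", "reason": r}
             for t, r in report.discarded]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_truth(path, truth_dict: dict) -> None:
    """Ground-truth sidecar as JSON (lists for arrays)."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)
    Path(path).write_text(json.dumps(truth_dict, indent=1, default=default))


def _write_sidecar(path, mapping: dict) -> None:
    lines = [f"{k}={v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _read_sidecar(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, _, v = line.partition("=")
            out[k.strip()] = v.strip()
    return out
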