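"""Quantification of static confocal images: NMJ masking on a reference
channel, Intermodes histogram thresholding, marker/reference ratiometry,
puncta-vs-tubule partitioning, and connected-component object sizes.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from skimage import measure

from .datatypes import QuantResult, Roi


class NotBimodalError(ValueError):
    """Raised when a histogram cannot be reduced to exactly two modes."""


def nmj_mask_from_reference(reference_image: np.ndarray,
                            manual_threshold: float,
                            roi_id: str = "nmj") -> Roi:
    """Threshold the reference (plasma-membrane marker) channel at a
    manually chosen level; the resulting ROI is applied unchanged to the
    marker channel."""
    ref = np.asarray(reference_image, dtype=float)
    mask = ref >= manual_threshold
    if not mask.any():
        raise ValueError(
            f"threshold {manual_threshold} leaves an empty mask "
            f"(image range [{ref.min()}, {ref.max()}])")
    return Roi(roi_id, "nmj", mask)


def _smooth3(h: np.ndarray) -> np.ndarray:
    """Iterative 3-bin mean with replicated ends (classic Intermodes step)."""
    padded = np.concatenate(([h[0]], h, [h[-1]]))
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _count_modes(h: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (ends padded with zero)."""
    p = np.concatenate(([-np.inf], h, [-np.inf]))
    return np.nonzero((p[1:-1] > p[:-2]) & (p[1:-1] > p[2:]))[0]


def intermodes_threshold(image_or_histogram: np.ndarray, nbins: int = 256,
                         max_iter: int = 10000) -> float:
    """Classic Intermodes threshold.

    Smooth the intensity histogram with an iterative 3-bin mean until
    exactly two local maxima remain, at bins ``j`` and ``k``; the threshold
    is ``(j + k) / 2``. Given a 1-D array it is treated as a histogram and
    the threshold is returned in bin units; given a 2-D image, a ``nbins``-bin
    histogram over the min–max range is used and the threshold is returned
    in intensity units (the corresponding bin center).
    """
    arr = np.asarray(image_or_histogram, dtype=float)
    if arr.ndim == 1:
        hist = arr.copy()
        to_intensity = lambda t: float(t)
    elif arr.ndim == 2:
        lo, hi = float(arr.min()), float(arr.max())
        if hi <= lo:
            raise NotBimodalError("image is constant; histogram has one mode")
        hist, edges = np.histogram(arr, bins=nbins, range=(lo, hi))
        hist = hist.astype(float)
        width = (hi - lo) / nbins
        to_intensity = lambda t: lo + (t + 0.5) * width
    else:
        raise ValueError("expected a 1-D histogram or a 2-D image")

    h = hist
    for _ in range(max_iter):
        modes = _count_modes(h)
        if len(modes) == 2:
            j, k = modes
            return to_intensity((j + k) / 2.0)
        if len(modes) < 2:
            raise NotBimodalError(
                "histogram is unimodal; Intermodes needs two modes")
        h = _smooth3(h)
    raise NotBimodalError(
        f"histogram not reducible to two modes within {max_iter} smoothings")


def measure_intensity(marker_image: np.ndarray, roi: Roi,
                      reference_image: Optional[np.ndarray] = None) -> QuantResult:
    """Mean marker intensity and area over the ROI; if a reference channel
    is given, also the marker/reference mean ratio over the same ROI."""
    marker = np.asarray(marker_image, dtype=float)
    vals = marker[roi.mask]
    rel = None
    if reference_image is not None:
        ref_mean = float(np.asarray(reference_image, dtype=float)[roi.mask].mean())
        if ref_mean == 0:
            raise ValueError("reference mean over the ROI is zero")
        rel = float(vals.mean()) / ref_mean
    return QuantResult(roi_id=roi.id, mean_intensity=float(vals.mean()),
                       area_px=roi.n_pixels, relative_intensity=rel)


def puncta_partition(marker_image: np.ndarray, nmj_roi: Roi,
                     nbins: int = 256, max_iter: int = 10000) -> tuple:
    """Partition the NMJ into bright puncta and the remaining tubule signal.

    The puncta ROI is defined by Intermodes thresholding of the marker
    intensities inside the NMJ mask. Returns three :class:`QuantResult`:
    the whole NMJ, the puncta, and the NMJ excluding puncta. When the
    intensity histogram has no second mode (no puncta) a degenerate result
    is returned: puncta area 0 and complement equal to the whole NMJ.
    """
    marker = np.asarray(marker_image, dtype=float)
    inside = marker[nmj_roi.mask]
    whole = QuantResult(roi_id=f"{nmj_roi.id}_whole",
                        mean_intensity=float(inside.mean()),
                        area_px=nmj_roi.n_pixels)
    try:
        thr = intermodes_threshold(inside.reshape(1, -1) if inside.ndim == 1
                                   else inside, nbins=nbins, max_iter=max_iter)
    except NotBimodalError:
        empty = QuantResult(roi_id=f"{nmj_roi.id}_puncta",
                            mean_intensity=0.0, area_px=0)
        complement = QuantResult(roi_id=f"{nmj_roi.id}_nonpuncta",
                                 mean_intensity=whole.mean_intensity,
                                 area_px=whole.area_px)
        return whole, empty, complement

    puncta_mask = nmj_roi.mask & (marker >= thr)
    comp_mask = nmj_roi.mask & ~puncta_mask
    if puncta_mask.any():
        puncta = QuantResult(roi_id=f"{nmj_roi.id}_puncta",
                             mean_intensity=float(marker[puncta_mask].mean()),
                             area_px=int(puncta_mask.sum()))
    else:
        puncta = QuantResult(roi_id=f"{nmj_roi.id}_puncta",
                             mean_intensity=0.0, area_px=0)
    if comp_mask.any():
        complement = QuantResult(roi_id=f"{nmj_roi.id}_nonpuncta",
                                 mean_intensity=float(marker[comp_mask].mean()),
                                 area_px=int(comp_mask.sum()))
    else:
        complement = QuantResult(roi_id=f"{nmj_roi.id}_nonpuncta",
                                 mean_intensity=0.0, area_px=0)
    return whole, puncta, complement


def object_sizes(mask: np.ndarray) -> list:
    """Connected-component areas (8-connectivity), one per object."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        labels = measure.label(mask, connectivity=2)
    else:
        labels = measure.label(mask > 0, connectivity=2)
    if labels.max() == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]
    return [int(c) for c in counts]


def max_intensity_projection(stack: np.ndarray, axis: int = 0) -> np.ndarray:
    """Maximum-intensity projection of a confocal z-stack."""
    return np.asarray(stack).max(axis=axis)
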