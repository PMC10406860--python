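"""Spatial quantification of WFR phases: areal extent and peak amplitude.

For each intrinsic-signal phase the frame with the maximum thresholded areal
extent inside its search window is selected, Gaussian filtered (full width at
half maximum 5 px), and quantified: areal extent as the largest 8-connected
suprathreshold component containing (or nearest to) the extremal pixel, and
peak amplitude as the extremal FC value.  Default thresholds, away from zero:
1.75e-4 for the initial dip (shared by the undershoot) and 2.5e-4 for the
overshoot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .protocols import PHASES
from .ratio import FCSeries

#: the Gaussian filter's full width at half maximum, pixels
DEFAULT_FWHM_PX = 5.0

DEFAULT_THRESHOLDS = {
    "initial_dip": 1.75e-4,
    "overshoot": 2.5e-4,
    "undershoot": 1.75e-4,
}

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PhaseWindow:
    """Search window for one phase, seconds relative to stimulus onset."""

    phase: str
    polarity: int  # -1 dip/undershoot, +1 overshoot
    search_window_s: tuple[float, float]

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be -1 or +1")
        lo, hi = self.search_window_s
        if not lo < hi:
            raise ValueError("search window must have start < end")


DEFAULT_WINDOWS: dict[str, PhaseWindow] = {
    "initial_dip": PhaseWindow("initial_dip", -1, (0.0, 3.5)),
    "overshoot": PhaseWindow("overshoot", +1, (2.0, 7.0)),
    "undershoot": PhaseWindow("undershoot", -1, (6.0, 13.5)),
}


@dataclass
class ExtentResult:
    pixel_count: int
    area_mm2: float
    component_mask: np.ndarray | None
    threshold_fc: float
    polarity: int


@dataclass
class PhaseMetrics:
    """Spatial parameters of one detected (or absent) phase."""

    phase: str
    selected_frame: int
    selected_time_s: float
    pixel_count: int
    areal_extent_mm2: float
    peak_fc: float
    peak_px: tuple[int, int] | None
    threshold_fc: float
    detected: bool
    roi_id: str = "slit"


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth(
    frame: np.ndarray,
    fwhm: float = DEFAULT_FWHM_PX,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Isotropic Gaussian blur with the given FWHM, reflective boundaries.

    Invalid pixels (``valid`` False) are excluded via normalized convolution:
    the result at every pixel is the Gaussian-weighted mean of the valid
    neighbourhood, which also fills the invalid pixels with that estimate.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    sigma = fwhm_to_sigma(fwhm)
    radius = int(4.0 * sigma + 0.5)
    if min(frame.shape) < 2 * radius + 1:
        raise ValueError(
            f"frame smaller than the kernel support ({2 * radius + 1} px)"
        )
    if valid is None:
        if not np.all(np.isfinite(frame)):
            raise ValueError("frame must be finite (or pass a validity mask)")
        return ndimage.gaussian_filter(frame, sigma, mode="reflect")
    valid = np.asarray(valid, dtype=bool)
    data = np.where(valid, frame, 0.0)
    num = ndimage.gaussian_filter(data, sigma, mode="reflect")
    den = ndimage.gaussian_filter(valid.astype(float), sigma, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 1e-12, out, 0.0)


def _check_roi(frame: np.ndarray, roi: np.ndarray | None) -> np.ndarray:
    if roi is None:
        return np.ones(frame.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != frame.shape:
        raise ValueError("ROI shape must match the frame")
    if not roi.any():
        raise ValueError("ROI is disjoint from the frame (empty)")
    return roi


def peak_amplitude(
    frame: np.ndarray,
    polarity: int,
    roi: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> tuple[float, tuple[int, int]]:
    """Extremal FC value of the stated polarity within the ROI.

    Ties are broken by row-major first occurrence.  Returns the signed FC
    value and its (row, col) location.
    """
    frame = np.asarray(frame, dtype=float)
    roi = _check_roi(frame, roi)
    if valid is not None:
        roi = roi & np.asarray(valid, dtype=bool)
        if not roi.any():
            raise ValueError("all ROI pixels are masked")
    signal = np.where(roi, polarity * frame, -np.inf)
    flat = int(np.argmax(signal))
    px = np.unravel_index(flat, frame.shape)
    return float(frame[px]), (int(px[0]), int(px[1]))


def areal_extent(
    frame: np.ndarray,
    threshold_fc: float,
    polarity: int,
    roi: np.ndarray | None = None,
    pixel_area_mm2: float = 1.0,
    valid: np.ndarray | None = None,
) -> ExtentResult:
    """Thresholded areal extent of one phase on a (smoothed) FC frame.

    Counts the pixels of the largest 8-connected component beyond the
    threshold that contains the phase's extremal pixel, or, if the extremum
    is subthreshold, the suprathreshold component nearest to it.  This avoids
    counting disjoint noise islands.  A count of zero is a valid result.
    """
    if threshold_fc <= 0:
        raise ValueError("threshold_fc must be > 0 (applied away from zero)")
    frame = np.asarray(frame, dtype=float)
    roi = _check_roi(frame, roi)
    if valid is not None:
        roi = roi & np.asarray(valid, dtype=bool)
        if not roi.any():
            raise ValueError("all ROI pixels are masked")
    signal = polarity * frame
    active = (signal >= threshold_fc) & roi
    if not active.any():
        return ExtentResult(0, 0.0, None, threshold_fc, polarity)
    labels, n = ndimage.label(active, structure=_EIGHT_CONN)
    _, peak_px = peak_amplitude(frame, polarity, roi)
    lab = labels[peak_px]
    if lab == 0:
        # nearest suprathreshold component to the extremal pixel
        coords = np.argwhere(active)
        d2 = ((coords - np.asarray(peak_px)) ** 2).sum(axis=1)
        lab = labels[tuple(coords[int(np.argmin(d2))])]
    mask = labels == lab
    count = int(mask.sum())
    return ExtentResult(count, count * pixel_area_mm2, mask, threshold_fc, polarity)


def _frames_in_window(series: FCSeries, window: PhaseWindow) -> np.ndarray:
    if series.time_s is None:
        raise ValueError("FC series has no time axis")
    lo, hi = window.search_window_s
    idx = np.flatnonzero((series.time_s > lo) & (series.time_s <= hi))
    return idx


def select_phase_frame(
    series: FCSeries,
    window: PhaseWindow,
    threshold_fc: float,
    roi: np.ndarray | None = None,
    fwhm: float = DEFAULT_FWHM_PX,
    pixel_area_mm2: float = 1.0,
) -> tuple[int, ExtentResult]:
    """Frame inside the window with the maximum thresholded areal extent.

    Each candidate frame is Gaussian filtered before thresholding.  Ties
    (including the all-zero-extent case) resolve to the earliest frame; the
    returned ExtentResult then reports pixel_count 0.
    """
    idx = _frames_in_window(series, window)
    if idx.size == 0:
        raise ValueError(
            f"empty search window {window.search_window_s} for this series"
        )
    valid = ~series.invalid_mask
    best_i, best_ext = None, None
    for i in idx:
        sm = smooth(series.fc[i], fwhm=fwhm, valid=valid)
        ext = areal_extent(
            sm, threshold_fc, window.polarity, roi, pixel_area_mm2, valid=valid
        )
        if best_ext is None or ext.pixel_count > best_ext.pixel_count:
            best_i, best_ext = int(i), ext
    return best_i, best_ext


def measure_phase(
    series: FCSeries,
    phase: str,
    roi: np.ndarray | None = None,
    threshold_fc: float | None = None,
    window: PhaseWindow | None = None,
    fwhm: float = DEFAULT_FWHM_PX,
    pixel_area_mm2: float | None = None,
) -> PhaseMetrics:
    """Full spatial quantification of one phase on an aggregated FC series.

    The search window is clipped to the series duration; a window entirely
    outside the series yields an undetected phase with zero extent.  Peak
    amplitude is taken within the suprathreshold component when one exists
    (the pixel of peak activity within the areal extent), otherwise within
    the ROI.
    """
    if window is None:
        window = DEFAULT_WINDOWS[phase]
    if threshold_fc is None:
        threshold_fc = DEFAULT_THRESHOLDS[phase]
    if pixel_area_mm2 is None:
        pixel_area_mm2 = series.meta.get("pixel_size_mm", 1.0) ** 2
    lo, hi = window.search_window_s
    t_max = float(series.time_s.max()) if series.time_s is not None else hi
    if lo >= t_max:
        return PhaseMetrics(phase, -1, np.nan, 0, 0.0, np.nan, None, threshold_fc, False)
    window = PhaseWindow(window.phase, window.polarity, (lo, min(hi, t_max)))
    frame_i, ext = select_phase_frame(
        series, window, threshold_fc, roi, fwhm, pixel_area_mm2
    )
    valid = ~series.invalid_mask
    sm = smooth(series.fc[frame_i], fwhm=fwhm, valid=valid)
    peak_roi = ext.component_mask if ext.pixel_count > 0 else roi
    peak_fc, peak_px = peak_amplitude(sm, window.polarity, peak_roi, valid=valid)
    return PhaseMetrics(
        phase=phase,
        selected_frame=frame_i,
        selected_time_s=float(series.time_s[frame_i]),
        pixel_count=ext.pixel_count,
        areal_extent_mm2=ext.area_mm2,
        peak_fc=peak_fc,
        peak_px=peak_px,
        threshold_fc=threshold_fc,
        detected=ext.pixel_count > 0,
    )


def detect_phases(
    series: FCSeries,
    roi: np.ndarray | None = None,
    windows: dict[str, PhaseWindow] | None = None,
    thresholds: dict[str, float] | None = None,
    fwhm: float = DEFAULT_FWHM_PX,
    pixel_area_mm2: float | None = None,
) -> list[PhaseMetrics]:
    """Phases with nonzero areal extent at their default thresholds, in
    temporal order.  An empty list is a valid result (eliminated WFR)."""
    windows = windows or DEFAULT_WINDOWS
    thresholds = thresholds or DEFAULT_THRESHOLDS
    out = []
    for phase in PHASES:
        if phase not in windows:
            continue
        m = measure_phase(
            series,
            phase,
            roi=roi,
            threshold_fc=thresholds[phase],
            window=windows[phase],
            fwhm=fwhm,
            pixel_area_mm2=pixel_area_mm2,
        )
        if m.detected:
            out.append(m)
    return out
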