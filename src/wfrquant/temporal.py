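"""Temporal analysis: the peak pixel's FC time course and timing parameters.

The profile is the FC value of a single selected peak pixel in every 500 ms
frame, anchored at stimulus onset.  Per phase the half-maximum convention is
used: half-time is the linearly interpolated first crossing of half the peak
magnitude on the rising limb, duration the interpolated width at half
magnitude, rates the half-to-peak magnitude over the corresponding time, and
AUC the trapezoidal integral of FC over the above-half-magnitude span.
Absent phases are flagged undefined, never entered as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ratio import FCSeries
from .spatial import DEFAULT_THRESHOLDS, DEFAULT_WINDOWS, PhaseWindow

TIMING_PARAMS = (
    "onset_s",
    "half_time_s",
    "peak_time_s",
    "duration_s",
    "rise_rate",
    "fall_rate",
    "peak_magnitude",
    "auc",
)


@dataclass
class PhaseTimingMetrics:
    """Half-maximum timing parameters of one phase (undefined when absent)."""

    phase: str
    defined: bool = False
    onset_s: float = np.nan
    half_time_s: float = np.nan
    peak_time_s: float = np.nan
    duration_s: float = np.nan
    rise_rate: float = np.nan  # |dR/R| per s on the rising limb
    fall_rate: float = np.nan
    peak_magnitude: float = np.nan
    auc: float = np.nan  # signed dR/R * s over the above-half span
    truncated: bool = False  # falling limb did not return to half in-window

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in TIMING_PARAMS}


@dataclass
class TimingProfile:
    """One pixel's FC time course plus derived timing parameters."""

    time_s: np.ndarray
    fc: np.ndarray
    pixel: tuple[int, int]
    phases: dict[str, PhaseTimingMetrics] = field(default_factory=dict)
    min_to_max_ratio: float = np.nan  # |dip peak| / |overshoot peak|
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fc = np.asarray(self.fc, dtype=float)
        if self.time_s.shape != self.fc.shape or self.time_s.ndim != 1:
            raise ValueError("time_s and fc must be matching 1-D arrays")


def extract_time_course(series: FCSeries, pixel: tuple[int, int]) -> TimingProfile:
    """FC at one pixel in every frame, time axis anchored at stimulus onset."""
    if series.time_s is None:
        raise ValueError("FC series has no time axis")
    r, c = pixel
    if series.invalid_mask[r, c]:
        raise ValueError(f"pixel {pixel} is masked (invalid reference)")
    return TimingProfile(
        time_s=series.time_s.copy(),
        fc=series.fc[:, r, c].copy(),
        pixel=(int(r), int(c)),
        meta=dict(series.meta),
    )


def _interp_crossing(t0, y0, t1, y1, level):
    """Time where the segment (t0,y0)-(t1,y1) crosses ``level``."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _phase_timing(
    t: np.ndarray, s: np.ndarray, phase: str, window: PhaseWindow, min_peak: float
) -> PhaseTimingMetrics:
    """Timing parameters on the polarity-rectified series ``s`` (peak > 0)."""
    lo, hi = window.search_window_s
    idx = np.flatnonzero((t > lo) & (t <= hi))
    m = PhaseTimingMetrics(phase=phase)
    if idx.size == 0:
        return m
    pk_rel = int(np.argmax(s[idx]))
    pk = idx[pk_rel]
    peak = float(s[pk])
    if peak < min_peak:
        return m
    half = peak / 2.0
    t_pk = float(t[pk])

    # rising limb: last sample below half before the peak, interpolated
    j = pk
    while j > idx[0] and s[j - 1] >= half:
        j -= 1
    if j == idx[0] and s[j] >= half:
        t_half = float(t[idx[0]])
    else:
        t_half = _interp_crossing(t[j - 1], s[j - 1], t[j], s[j], half)

    # onset: last zero crossing before the peak
    j = pk
    while j > idx[0] and s[j - 1] > 0:
        j -= 1
    if j == idx[0] and s[j] > 0:
        t_on = float(lo)
    else:
        t_on = _interp_crossing(t[j - 1], s[j - 1], t[j], s[j], 0.0)

    # falling limb: first drop below half after the peak
    truncated = False
    j = pk
    while j < idx[-1] and s[j + 1] >= half:
        j += 1
    if j == idx[-1]:
        t_fall = float(t[idx[-1]])
        truncated = True
    else:
        t_fall = _interp_crossing(t[j], s[j], t[j + 1], s[j + 1], half)

    m.defined = True
    m.truncated = truncated
    m.onset_s = min(t_on, t_half)
    m.half_time_s = t_half
    m.peak_time_s = t_pk
    m.duration_s = max(t_fall - t_half, 0.0)
    m.peak_magnitude = peak
    m.rise_rate = (peak - half) / (t_pk - t_half) if t_pk > t_half else np.nan
    m.fall_rate = (peak - half) / (t_fall - t_pk) if t_fall > t_pk else np.nan

    # signed AUC over [t_half, t_fall] with interpolated endpoints
    sign = window.polarity
    seg_t = [t_half] + [float(tt) for tt in t if t_half < tt < t_fall] + [t_fall]
    seg_y = np.interp(seg_t, t, sign * s)
    m.auc = float(np.trapezoid(seg_y, seg_t))
    return m


def timing_metrics(
    profile: TimingProfile,
    windows: dict[str, PhaseWindow] | None = None,
    min_peaks: dict[str, float] | None = None,
) -> TimingProfile:
    """Fill a profile's per-phase timing parameters (in place; also returned).

    ``min_peaks`` sets the magnitude below which a phase is treated as absent
    (defaults to the spatial quantification thresholds).  The minimum-to-
    maximum ratio is |dip peak| / |overshoot peak| and stays undefined on
    dip-only profiles.
    """
    windows = windows or DEFAULT_WINDOWS
    min_peaks = min_peaks or DEFAULT_THRESHOLDS
    t = profile.time_s
    for phase, window in windows.items():
        lo, hi = window.search_window_s
        hi = min(hi, float(t.max()) + 1e-9)
        if lo >= hi:
            profile.phases[phase] = PhaseTimingMetrics(phase=phase)
            continue
        w = PhaseWindow(window.phase, window.polarity, (lo, hi))
        s = window.polarity * profile.fc
        profile.phases[phase] = _phase_timing(
            t, s, phase, w, float(min_peaks.get(phase, 0.0))
        )
    dip = profile.phases.get("initial_dip")
    over = profile.phases.get("overshoot")
    if dip and over and dip.defined and over.defined and over.peak_magnitude > 0:
        profile.min_to_max_ratio = dip.peak_magnitude / over.peak_magnitude
    else:
        profile.min_to_max_ratio = np.nan
    return profile


@dataclass
class SessionComparison:
    """Elementwise 24 h / baseline ratios of every defined timing parameter.

    ``half_time_ratio``/``peak_time_ratio`` are the between-session ratios of
    the initial dip's half-time and peak time; the alternative within-session
    half-time-over-peak-time reading is reported separately in
    ``within_session_half_over_peak`` as (baseline, follow-up) pairs.  Phases
    present at baseline but absent at follow-up are flagged eliminated;
    phases absent at baseline make the comparison invalid for that phase.
    """

    ratios: dict[str, dict[str, float]]
    eliminated: dict[str, bool]
    invalid: dict[str, bool]
    within_session_half_over_peak: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )

    @property
    def half_time_ratio(self) -> float:
        return self.ratios.get("initial_dip", {}).get("half_time_s", np.nan)

    @property
    def peak_time_ratio(self) -> float:
        return self.ratios.get("initial_dip", {}).get("peak_time_s", np.nan)


_RATIO_PARAMS = (
    "half_time_s",
    "peak_time_s",
    "duration_s",
    "rise_rate",
    "fall_rate",
    "peak_magnitude",
    "auc",
)


def compare_sessions(
    baseline: TimingProfile, followup: TimingProfile
) -> SessionComparison:
    """Per-parameter follow-up / baseline ratio table for every phase."""
    if not baseline.phases or not followup.phases:
        raise ValueError("run timing_metrics on both profiles first")
    ratios: dict[str, dict[str, float]] = {}
    eliminated: dict[str, bool] = {}
    invalid: dict[str, bool] = {}
    within: dict[str, tuple[float, float]] = {}
    for phase, base in baseline.phases.items():
        fup = followup.phases.get(phase, PhaseTimingMetrics(phase=phase))
        if not base.defined:
            invalid[phase] = True
            eliminated[phase] = False
            continue
        invalid[phase] = False
        if not fup.defined:
            eliminated[phase] = True
            continue
        eliminated[phase] = False
        r: dict[str, float] = {}
        for p in _RATIO_PARAMS:
            b, f = getattr(base, p), getattr(fup, p)
            if np.isfinite(b) and np.isfinite(f) and b != 0:
                r[p] = f / b
        if base.peak_time_s and fup.peak_time_s:
            within[phase] = (
                base.half_time_s / base.peak_time_s,
                fup.half_time_s / fup.peak_time_s,
            )
        ratios[phase] = r
    return SessionComparison(
        ratios=ratios,
        eliminated=eliminated,
        invalid=invalid,
        within_session_half_over_peak=within,
    )
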