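"""Ratio imaging: raw frame stacks to fractional-change (dR/R) series.

Raw intrinsic-signal frames (100 ms) are summed within trials to 500 ms
frames to improve signal-to-noise, then each 500 ms frame of a trial is
divided by the single 500 ms pre-stimulus reference frame collected
immediately before stimulus onset.  Fractional change is defined as
``frame / reference - 1`` so 0 means no change and the dip/overshoot
thresholds are symmetric about zero.  Trials are aggregated by the
framewise mean, so FC magnitudes are per-frame regardless of trial count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class FrameStack:
    """Time-ordered grayscale raster sequence with trial annotations.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``; counts (float or integer).
    frame_ms
        Duration of each frame in milliseconds.
    trial_index
        Per-frame trial id, non-decreasing, one contiguous run per trial.
    prestim_ref_index
        Per-trial, the in-trial index of the 500 ms pre-stimulus reference
        frame.  At a raw rate finer than 500 ms this is the index of the
        *first* frame of the reference window; ``sum_frames`` rescales it.
    trial_start_s
        Per-trial absolute acquisition start time (seconds); informational.
    meta
        Free-form session metadata (protocol name, prestim_s, pixel size...).
    """

    frames: np.ndarray
    frame_ms: float
    trial_index: np.ndarray
    prestim_ref_index: np.ndarray
    trial_start_s: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        self.prestim_ref_index = np.asarray(self.prestim_ref_index, dtype=int)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n_frames, rows, cols)")
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")
        if self.trial_index.shape != (self.frames.shape[0],):
            raise ValueError("trial_index must have one entry per frame")
        if np.any(np.diff(self.trial_index) < 0):
            raise ValueError("trial_index must be non-decreasing")
        if len(self.prestim_ref_index) != self.n_trials:
            raise ValueError("prestim_ref_index must have one entry per trial")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def trial_ids(self) -> np.ndarray:
        return np.unique(self.trial_index)

    @property
    def n_trials(self) -> int:
        return len(np.unique(self.trial_index))

    def trial_frames(self, trial_id: int) -> np.ndarray:
        sel = self.trial_index == trial_id
        if not sel.any():
            raise KeyError(f"no trial {trial_id}")
        return self.frames[sel]


@dataclass
class FCSeries:
    """Per-frame fractional-change rasters relative to a pre-stimulus reference.

    ``time_s`` holds frame-midpoint times anchored at stimulus onset
    (onset = 0).  ``invalid_mask`` flags pixels whose reference value was not
    strictly positive; their FC values are set to 0 and must be excluded
    downstream.
    """

    fc: np.ndarray
    frame_ms: float = 500.0
    time_s: np.ndarray | None = None
    n_trials_aggregated: int = 1
    invalid_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fc = np.asarray(self.fc, dtype=float)
        if self.fc.ndim != 3:
            raise ValueError("fc must have shape (n_frames, rows, cols)")
        if not np.all(np.isfinite(self.fc)):
            raise ValueError("FC values must be finite")
        if self.time_s is not None:
            self.time_s = np.asarray(self.time_s, dtype=float)
            if self.time_s.shape != (self.fc.shape[0],):
                raise ValueError("time_s must have one entry per frame")
        if self.invalid_mask is None:
            self.invalid_mask = np.zeros(self.fc.shape[1:], dtype=bool)
        else:
            self.invalid_mask = np.asarray(self.invalid_mask, dtype=bool)
            if self.invalid_mask.shape != self.fc.shape[1:]:
                raise ValueError("invalid_mask must match frame shape")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.fc.shape[1:]


def sum_frames(stack: FrameStack, factor: int = 5) -> FrameStack:
    """Sum ``factor`` consecutive frames within each trial.

    The default factor of 5 converts 100 ms raw frames to 500 ms frames.
    Frames are never summed across trial boundaries; a trailing remainder
    shorter than ``factor`` is dropped with a warning.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return stack

    out_dtype = (
        np.float64 if np.issubdtype(stack.frames.dtype, np.integer) else stack.frames.dtype
    )
    frames_out, trial_out = [], []
    dropped = 0
    for tid in stack.trial_ids:
        f = stack.trial_frames(tid)
        k, rem = divmod(len(f), factor)
        if rem:
            dropped += rem
        if k == 0:
            continue
        summed = (
            f[: k * factor]
            .astype(out_dtype, copy=False)
            .reshape(k, factor, *f.shape[1:])
            .sum(axis=1)
        )
        frames_out.append(summed)
        trial_out.append(np.full(k, tid, dtype=int))
    if dropped:
        warnings.warn(
            f"sum_frames dropped {dropped} trailing frame(s) not filling a "
            f"complete group of {factor}",
            stacklevel=2,
        )
    if not frames_out:
        raise ValueError("no complete frame groups to sum")
    return FrameStack(
        frames=np.concatenate(frames_out),
        frame_ms=stack.frame_ms * factor,
        trial_index=np.concatenate(trial_out),
        prestim_ref_index=stack.prestim_ref_index // factor,
        trial_start_s=stack.trial_start_s,
        meta=dict(stack.meta),
    )


def compute_fc(
    trial_frames: np.ndarray,
    ref_index: int,
    frame_ms: float = 500.0,
    time_s: np.ndarray | None = None,
) -> FCSeries:
    """Fractional change of every frame of one trial against its reference.

    ``FC_t(x, y) = frame_t(x, y) / frame_ref(x, y) - 1``; the reference frame
    itself maps to exactly 0.  Pixels whose reference value is not strictly
    positive are flagged invalid (FC forced to 0), never turned into
    infinities.
    """
    trial_frames = np.asarray(trial_frames, dtype=float)
    if trial_frames.ndim != 3:
        raise ValueError("trial_frames must have shape (n_frames, rows, cols)")
    if not 0 <= ref_index < len(trial_frames):
        raise ValueError("ref_index out of range")
    ref = trial_frames[ref_index]
    invalid = ~(ref > 0)
    safe_ref = np.where(invalid, 1.0, ref)
    fc = trial_frames / safe_ref - 1.0
    fc[:, invalid] = 0.0
    return FCSeries(
        fc=fc, frame_ms=frame_ms, time_s=time_s, n_trials_aggregated=1,
        invalid_mask=invalid,
    )


def session_fc(stack: FrameStack, prestim_s: float | None = None) -> list[FCSeries]:
    """Per-trial FC series for a whole session, with onset-anchored time axes.

    ``prestim_s`` (stimulus onset relative to trial start) is read from
    ``stack.meta`` when not given.
    """
    if prestim_s is None:
        prestim_s = stack.meta.get("prestim_s")
        if prestim_s is None:
            raise ValueError("prestim_s not given and absent from stack.meta")
    dt = stack.frame_ms / 1000.0
    out = []
    for k, tid in enumerate(stack.trial_ids):
        frames = stack.trial_frames(tid)
        t = (np.arange(len(frames)) + 0.5) * dt - prestim_s
        fcs = compute_fc(
            frames, int(stack.prestim_ref_index[k]), frame_ms=stack.frame_ms, time_s=t
        )
        fcs.meta.update(stack.meta)
        out.append(fcs)
    return out


def aggregate_trials(series: list[FCSeries]) -> FCSeries:
    """Framewise mean FC across trials.

    The mean (not the sum) keeps FC magnitudes per-frame, so areal-extent
    thresholds in FC units apply regardless of trial count.  Invalid-pixel
    masks are unioned.
    """
    if not series:
        raise ValueError("no FC series to aggregate")
    first = series[0]
    for s in series[1:]:
        if s.fc.shape != first.fc.shape:
            raise ValueError("all FC series must share the frame grid")
        if s.frame_ms != first.frame_ms:
            raise ValueError("all FC series must share frame timing")
        if (
            s.time_s is not None
            and first.time_s is not None
            and not np.allclose(s.time_s, first.time_s)
        ):
            raise ValueError("all FC series must share the time axis")
    mean_fc = np.mean([s.fc for s in series], axis=0)
    invalid = np.any([s.invalid_mask for s in series], axis=0)
    n_total = int(sum(s.n_trials_aggregated for s in series))
    return FCSeries(
        fc=mean_fc,
        frame_ms=first.frame_ms,
        time_s=first.time_s,
        n_trials_aggregated=n_total,
        invalid_mask=invalid,
        meta=dict(first.meta),
    )
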