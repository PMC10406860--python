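"""Stimulation protocols, study scenarios, and generator parameter types.

The study images the cortical representation of a single whisker (the WFR)
under two stimulation timings: a *sparse* protocol with a long post-stimulus
window that resolves the triphasic intrinsic signal (initial dip, overshoot,
undershoot), and a *condensed* protocol mimicking naturalistic whisking that
shows only a growing initial dip.  Four treatment groups are imaged at
baseline and 24 h; only the group with both arterial occlusion and blocked
lactate transport (group 4) loses its WFR and develops an infarct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SESSIONS = ("baseline", "during_drug", "24h")
GROUPS = (1, 2, 3, 4)
PHASES = ("initial_dip", "overshoot", "undershoot")

#: sign of the fractional-change excursion for each phase
PHASE_POLARITY = {"initial_dip": -1, "overshoot": +1, "undershoot": -1}

#: imaged field of view is ~7 mm x 7 mm regardless of raster size
FIELD_OF_VIEW_MM = 7.0


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing of one stimulation/acquisition protocol.

    ``prestim_s + stim_s + poststim_s`` is the acquired span per trial; frames
    are only collected inside trials, never during the inter-trial interval.
    ``nominal_trial_s`` records a protocol's advertised trial length when it
    differs from the sum of its segments (the sparse protocol is described
    both as a 15 s trial and as 1.5 + 1 + 13.5 = 16 s of data; the generator
    follows the segments and keeps the nominal value as metadata).
    """

    name: str
    prestim_s: float = 1.5
    stim_s: float = 1.0
    poststim_s: float = 13.5
    iti_base_s: float = 6.0
    iti_jitter_s: float = 5.0  # half-range of uniform jitter; 0 = constant ITI
    stim_rate_hz: float = 5.0
    deflection_deg: float = 9.0
    trials_per_block: int = 64
    raw_frame_ms: float = 100.0
    nominal_trial_s: float | None = None

    def __post_init__(self) -> None:
        for attr in ("prestim_s", "stim_s", "poststim_s"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if self.prestim_s + self.stim_s + self.poststim_s <= 0:
            raise ValueError("total acquired duration must be positive")
        if self.iti_base_s < 0 or self.iti_jitter_s < 0:
            raise ValueError("inter-trial interval parameters must be non-negative")
        if self.raw_frame_ms <= 0:
            raise ValueError("raw_frame_ms must be positive")
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be >= 1")

    @property
    def trial_s(self) -> float:
        """Acquired duration per trial (sum of the three segments)."""
        return self.prestim_s + self.stim_s + self.poststim_s

    @property
    def stim_onset_s(self) -> float:
        return self.prestim_s

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_s * 1000.0 / self.raw_frame_ms))


SPARSE = ProtocolSpec(name="sparse", nominal_trial_s=15.0)
CONDENSED = ProtocolSpec(
    name="condensed",
    poststim_s=2.0,
    iti_base_s=1.0,
    iti_jitter_s=0.0,
    trials_per_block=40,
)

PROTOCOLS = {"sparse": SPARSE, "condensed": CONDENSED}


def plus0h_trial_count(protocol: ProtocolSpec = SPARSE, n_blocks: int = 4) -> int:
    """Total immediate post-occlusion stimulation trials (4 sparse blocks)."""
    return n_blocks * protocol.trials_per_block


@dataclass(frozen=True)
class PhaseTiming:
    """Onset latency and peak time of one response phase, s after stimulus onset."""

    latency_s: float
    peak_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.latency_s < self.peak_s:
            raise ValueError("require 0 <= latency_s < peak_s")


DEFAULT_SPARSE_TIMING: dict[str, PhaseTiming] = {
    "initial_dip": PhaseTiming(0.25, 1.75),
    "overshoot": PhaseTiming(2.0, 4.0),
    "undershoot": PhaseTiming(6.0, 8.5),
}

#: condensed responses show a single dip still growing at trial end
DEFAULT_CONDENSED_TIMING: dict[str, PhaseTiming] = {
    "initial_dip": PhaseTiming(0.25, 2.5),
    "overshoot": PhaseTiming(2.6, 4.0),
    "undershoot": PhaseTiming(6.0, 8.5),
}


@dataclass(frozen=True)
class ResponseGroundTruth:
    """Ground-truth evoked response embedded by the generator.

    Amplitudes are magnitudes in fractional-change (dR/R) units; the temporal
    kernel applies the phase signs (dip -, overshoot +, undershoot -).
    """

    center_px: tuple[int, int]
    footprint_sigma_px: float
    amp_dip: float = 3.5e-4
    amp_overshoot: float = 4.0e-4
    amp_undershoot: float = 2.5e-4
    timing: dict[str, PhaseTiming] = field(
        default_factory=lambda: dict(DEFAULT_SPARSE_TIMING)
    )

    def __post_init__(self) -> None:
        for attr in ("amp_dip", "amp_overshoot", "amp_undershoot"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.footprint_sigma_px <= 0:
            raise ValueError("footprint_sigma_px must be positive")
        t = self.timing
        if not (
            t["initial_dip"].peak_s < t["overshoot"].peak_s < t["undershoot"].peak_s
        ):
            raise ValueError("phase peaks must be ordered dip < overshoot < undershoot")

    def amplitude(self, phase: str) -> float:
        return {
            "initial_dip": self.amp_dip,
            "overshoot": self.amp_overshoot,
            "undershoot": self.amp_undershoot,
        }[phase]

    def scaled(self, factor: float) -> "ResponseGroundTruth":
        return replace(
            self,
            amp_dip=self.amp_dip * factor,
            amp_overshoot=self.amp_overshoot * factor,
            amp_undershoot=self.amp_undershoot * factor,
        )


def default_truth(
    frame_size: tuple[int, int] = (128, 128), protocol_name: str = "sparse"
) -> ResponseGroundTruth:
    """Default ground truth scaled to the raster size.

    The footprint sigma scales with the raster so the WFR always spans the
    same ~0.7 mm (sigma) of the 7 mm field.  Condensed-protocol responses are
    dip-only with the dip still growing at trial end.
    """
    rows, cols = frame_size
    center = (int(round(0.45 * rows)), int(round(0.55 * cols)))
    sigma = 12.0 * rows / 128.0
    if protocol_name == "condensed":
        return ResponseGroundTruth(
            center_px=center,
            footprint_sigma_px=sigma,
            amp_overshoot=0.0,
            amp_undershoot=0.0,
            timing=dict(DEFAULT_CONDENSED_TIMING),
        )
    return ResponseGroundTruth(center_px=center, footprint_sigma_px=sigma)


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological and instrumental noise injected by the generator.

    All amplitudes are in fractional-change units per 100 ms raw frame.
    Vessel streaks are a static multiplicative pattern on the baseline image
    whose pixels additionally pulse with the cardiac component, leaving the
    black/white streak artifacts seen in ratio images.
    """

    pixel_sd: float = 1e-4
    drift_amp: float = 5e-5
    cardiac_hz: float = 6.0
    resp_hz: float = 1.0
    physio_amp: float = 3e-5
    vessel_streaks: int = 3
    vessel_width_px: float = 2.0
    vessel_contrast: float = 0.15

    def __post_init__(self) -> None:
        for attr in (
            "pixel_sd",
            "drift_amp",
            "cardiac_hz",
            "resp_hz",
            "physio_amp",
            "vessel_width_px",
            "vessel_contrast",
        ):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.vessel_streaks < 0:
            raise ValueError("vessel_streaks must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        """Noise-free spec for oracle tests."""
        return cls(
            pixel_sd=0.0,
            drift_amp=0.0,
            physio_amp=0.0,
            vessel_streaks=0,
            vessel_contrast=0.0,
        )


def expected_response_scale(group_id: int, session: str) -> float:
    """Response scale implied by the study design.

    Lactate-transport blockade (groups 2 and 4) silences the WFR while the
    drug is present; only group 4 (occlusion + blockade) stays eliminated at
    24 h, group 2 fully recovers, and groups 1 and 3 are never affected.
    """
    if group_id not in GROUPS:
        raise ValueError(f"unknown group id {group_id!r}")
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r}")
    if session == "during_drug" and group_id in (2, 4):
        return 0.0
    if session == "24h" and group_id == 4:
        return 0.0
    return 1.0


@dataclass(frozen=True)
class ScenarioSpec:
    """One imaging scenario: a group/session cell of the study design."""

    group_id: int
    session: str
    response_scale: float | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    slit_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = expected_response_scale(self.group_id, self.session)
        scale = self.response_scale
        if scale is None:
            object.__setattr__(self, "response_scale", expected)
            return
        if not 0.0 <= scale <= 1.0:
            raise ValueError("response_scale must be in [0, 1]")
        if scale != expected:
            raise ValueError(
                f"group {self.group_id} at {self.session} requires "
                f"response_scale={expected}, got {scale}"
            )


@dataclass(frozen=True)
class LesionModel:
    """Linear slit-size -> infarct-volume model for the lesion generator.

    Defaults are calibrated so that, with the default slit areas (8 subjects,
    1-6 mm2), the ordinary-least-squares R2 of volume on slit area averages
    ~0.87 (E[R2] ~ 1 - (n-2) sd^2 / (slope^2 Sxx + (n-1) sd^2)).
    """

    slope_mm3_per_mm2: float = 12.0
    intercept_mm3: float = 5.0
    noise_sd_mm3: float = 9.0
    n_slices: int = 6
    slice_thickness_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.slope_mm3_per_mm2 <= 0:
            raise ValueError("slope must be positive")
        if self.noise_sd_mm3 < 0:
            raise ValueError("noise_sd_mm3 must be >= 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be positive")


#: default total skull-dura slit areas for the n = 8 lesioned subjects, mm2
DEFAULT_SLIT_AREAS_MM2: tuple[float, ...] = tuple(np.linspace(1.0, 6.0, 8))
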