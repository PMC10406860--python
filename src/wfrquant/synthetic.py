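"""Synthetic ISOI sessions, TTC slice sets, and full four-group studies.

The generator emulates the statistical structure the analysis assumes: a
triphasic evoked hemodynamic response (gamma-variate lobes with signs
- / + / - for initial dip, overshoot, undershoot) on a Gaussian spatial
footprint, embedded multiplicatively in 100 ms camera frames at ~1e4 counts,
with pixel noise, slow drift, cardiac/respiratory sinusoids and vessel-streak
artifacts; plus TTC coronal slice images whose unstained (white) region
reproduces a drawn infarct volume that is linear in total slit area.

Everything is driven by a single seed so identical (spec, seed) inputs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histology import SliceSet
from .protocols import (
    DEFAULT_SLIT_AREAS_MM2,
    FIELD_OF_VIEW_MM,
    GROUPS,
    LesionModel,
    NoiseSpec,
    ProtocolSpec,
    PROTOCOLS,
    ResponseGroundTruth,
    ScenarioSpec,
    default_truth,
)
from .ratio import FrameStack

GAMMA_SHAPE = 3.0
BASELINE_COUNTS = 1.0e4
DRIFT_HZ = 0.05


def gamma_lobe(t: np.ndarray, timing) -> np.ndarray:
    """Gamma-variate lobe normalized to peak 1 at ``timing.peak_s``.

    ``g(t) = tau**a * exp(a * (1 - tau))`` with
    ``tau = (t - latency) / (peak - latency)`` and shape ``a = 3``; zero
    before the onset latency.
    """
    t = np.asarray(t, dtype=float)
    tau = (t - timing.latency_s) / (timing.peak_s - timing.latency_s)
    out = np.zeros_like(tau)
    pos = tau > 0
    out[pos] = tau[pos] ** GAMMA_SHAPE * np.exp(GAMMA_SHAPE * (1.0 - tau[pos]))
    return out


def triphasic_kernel(
    t: np.ndarray, truth: ResponseGroundTruth, scale: float = 1.0
) -> np.ndarray:
    """Temporal FC kernel at the footprint center: -dip +overshoot -undershoot."""
    t = np.asarray(t, dtype=float)
    k = np.zeros_like(t)
    for phase, sign in (("initial_dip", -1), ("overshoot", +1), ("undershoot", -1)):
        amp = truth.amplitude(phase)
        if amp > 0:
            k += sign * amp * gamma_lobe(t, truth.timing[phase])
    return scale * k


def gaussian_footprint(
    frame_size: tuple[int, int], center: tuple[float, float], sigma: float
) -> np.ndarray:
    rows, cols = frame_size
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    d2 = (r - center[0]) ** 2 + (c - center[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def vessel_pattern(
    frame_size: tuple[int, int], noise: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """Signed multiplicative vessel-streak pattern (alternating dark/bright)."""
    rows, cols = frame_size
    v = np.zeros(frame_size)
    if noise.vessel_streaks == 0 or noise.vessel_contrast == 0:
        return v
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    for j in range(noise.vessel_streaks):
        theta = rng.uniform(0, np.pi)
        p0 = rng.uniform(0.2, 0.8, size=2) * (rows, cols)
        # signed distance to the line through p0 with direction theta
        d = (r - p0[0]) * np.sin(theta) - (c - p0[1]) * np.cos(theta)
        sign = 1.0 if j % 2 else -1.0
        v += sign * noise.vessel_contrast * np.exp(
            -(d**2) / (2.0 * noise.vessel_width_px**2)
        )
    return np.clip(v, -0.45, 0.45)


def _baseline_image(
    frame_size: tuple[int, int], vessel_map: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Static reflectance image: smooth illumination gradient plus vessels."""
    rows, cols = frame_size
    gr = np.linspace(-1, 1, rows)[:, None]
    gc = np.linspace(-1, 1, cols)[None, :]
    a, b = rng.uniform(-0.03, 0.03, size=2)
    illum = 1.0 + a * gr + b * gc
    return BASELINE_COUNTS * illum * (1.0 + vessel_map)


def generate_session(
    protocol: ProtocolSpec,
    scenario: ScenarioSpec,
    truth: ResponseGroundTruth,
    n_trials: int | None = None,
    frame_size: tuple[int, int] = (128, 128),
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    dtype=np.float32,
) -> tuple[FrameStack, dict]:
    """Simulate one imaging session: raw 100 ms frames for ``n_trials`` trials.

    The embedded evoked signal is ``baseline * (1 + FC(t, x, y))`` with
    ``FC = triphasic_kernel(t) * gaussian_footprint(x, y) * response_scale``,
    evaluated at raw-frame midpoints.  Frames are only acquired within trials;
    trial start times carry the (possibly jittered) inter-trial interval.

    Returns the stack and a ground-truth record (scaled amplitudes, footprint,
    reference-frame index, per-trial start times).
    """
    rows, cols = frame_size
    if rows < 32 or cols < 32:
        raise ValueError("frame_size must be at least 32 x 32")
    if n_trials is None:
        n_trials = protocol.trials_per_block
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    noise = scenario.noise
    scale = float(scenario.response_scale)

    dt = protocol.raw_frame_ms / 1000.0
    n_f = protocol.frames_per_trial
    t_mid = (np.arange(n_f) + 0.5) * dt  # in-trial, from acquisition start
    t_rel = t_mid - protocol.stim_onset_s

    kern = triphasic_kernel(t_rel, truth, scale=scale)
    foot = gaussian_footprint(frame_size, truth.center_px, truth.footprint_sigma_px)
    signal = (kern[:, None, None] * foot[None]).astype(dtype)

    vessel_map = vessel_pattern(frame_size, noise, rng)
    baseline = _baseline_image(frame_size, vessel_map, rng).astype(dtype)
    if noise.vessel_contrast > 0:
        cardiac_weight = (0.5 + np.abs(vessel_map) / noise.vessel_contrast).astype(dtype)
    else:
        cardiac_weight = np.full(frame_size, 0.5, dtype=dtype)

    frames = np.empty((n_trials * n_f, rows, cols), dtype=dtype)
    trial_index = np.repeat(np.arange(n_trials), n_f)
    trial_start = np.empty(n_trials)
    t0 = 0.0
    for k in range(n_trials):
        trial_start[k] = t0
        t_abs = (t0 + t_mid).astype(dtype)
        fc = signal.copy()
        if noise.pixel_sd > 0:
            fc += noise.pixel_sd * rng.standard_normal(
                (n_f, rows, cols), dtype=np.float32
            )
        glob = np.zeros(n_f, dtype=dtype)
        if noise.drift_amp > 0:
            glob += noise.drift_amp * np.sin(
                2 * np.pi * DRIFT_HZ * t_abs + rng.uniform(0, 2 * np.pi)
            ).astype(dtype)
        if noise.physio_amp > 0:
            glob += noise.physio_amp * np.sin(
                2 * np.pi * noise.resp_hz * t_abs + rng.uniform(0, 2 * np.pi)
            ).astype(dtype)
            cardiac = noise.physio_amp * np.sin(
                2 * np.pi * noise.cardiac_hz * t_abs + rng.uniform(0, 2 * np.pi)
            ).astype(dtype)
            fc += cardiac[:, None, None] * cardiac_weight[None]
        fc += glob[:, None, None]
        frames[k * n_f : (k + 1) * n_f] = baseline[None] * (1.0 + fc)
        iti = protocol.iti_base_s
        if protocol.iti_jitter_s > 0:
            iti += rng.uniform(-protocol.iti_jitter_s, protocol.iti_jitter_s)
        t0 += protocol.trial_s + iti

    # first raw frame of the 500 ms reference window immediately before onset
    ref_raw = int(round((protocol.stim_onset_s - 0.5) / dt))
    if ref_raw < 0:
        raise ValueError("protocol pre-stimulus segment shorter than 500 ms")

    meta = {
        "protocol": protocol.name,
        "prestim_s": protocol.prestim_s,
        "pixel_size_mm": FIELD_OF_VIEW_MM / rows,
        "group_id": scenario.group_id,
        "session": scenario.session,
        "response_scale": scale,
    }
    if (
        protocol.nominal_trial_s is not None
        and protocol.nominal_trial_s != protocol.trial_s
    ):
        meta["nominal_trial_s"] = protocol.nominal_trial_s
        meta["segment_trial_s"] = protocol.trial_s
        meta["trial_length_note"] = (
            "segment durations sum to "
            f"{protocol.trial_s} s but the protocol is nominally "
            f"{protocol.nominal_trial_s} s; frames follow the segments"
        )

    stack = FrameStack(
        frames=frames,
        frame_ms=protocol.raw_frame_ms,
        trial_index=trial_index,
        prestim_ref_index=np.full(n_trials, ref_raw, dtype=int),
        trial_start_s=trial_start,
        meta=meta,
    )
    record = {
        "center_px": list(truth.center_px),
        "footprint_sigma_px": truth.footprint_sigma_px,
        "amp_dip": truth.amp_dip * scale,
        "amp_overshoot": truth.amp_overshoot * scale,
        "amp_undershoot": truth.amp_undershoot * scale,
        "response_scale": scale,
        "prestim_ref_raw_index": ref_raw,
        "trial_start_s": trial_start.tolist(),
    }
    return stack, record


# ---------------------------------------------------------------------------
# TTC lesion generator
# ---------------------------------------------------------------------------


@dataclass
class LesionGroundTruth:
    """Generator-side record of one subject's lesion."""

    subject_id: str
    slit_area_mm2: float
    volume_mm3: float
    slice_areas_mm2: list[float]
    blemish_area_mm2: float
    exclusion_rois: list[np.ndarray | None] | None = None


def _ellipse_mask(shape, center_mm, semi_mm, mm_per_px) -> np.ndarray:
    rows, cols = shape
    r = (np.arange(rows)[:, None] + 0.5) * mm_per_px
    c = (np.arange(cols)[None, :] + 0.5) * mm_per_px
    return ((r - center_mm[0]) / semi_mm[0]) ** 2 + (
        (c - center_mm[1]) / semi_mm[1]
    ) ** 2 <= 1.0


def generate_lesion_dataset(
    model: LesionModel,
    slit_areas_mm2,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    mm_per_px: float = 0.1,
    slice_shape: tuple[int, int] = (160, 224),
    render: bool = True,
    swelling_frac: float = 0.0,
    blemish_area_mm2: float = 0.5,
    subject_ids: list[str] | None = None,
) -> tuple[list[LesionGroundTruth], list[SliceSet | None]]:
    """Draw infarct volumes linear in slit area and render TTC slice sets.

    Per subject the volume is ``slope * area + intercept + N(0, sd)``
    truncated at 0, split over the interior slices, and rendered as a white
    (unstained) ellipse concentric with the ipsilateral hemisphere so its
    summed area x thickness reproduces the drawn volume within rasterization
    error.  A small white surgical-site blemish is placed on the first slice,
    away from the lesion, with a declared exclusion ROI, to exercise the
    exclusion logic.
    """
    slit_areas = np.asarray(list(slit_areas_mm2), dtype=float)
    if slit_areas.size == 0:
        raise ValueError("slit area list must not be empty")
    if np.any(slit_areas < 0):
        raise ValueError("slit areas must be >= 0")
    rng = np.random.default_rng(seed)
    if subject_ids is None:
        subject_ids = [f"L{k + 1:02d}" for k in range(len(slit_areas))]

    n = model.n_slices
    # lesion spans interior slices with a parabolic profile; slice 0 is spared
    # so the surgical blemish there is always disjoint from the main lesion
    idx = np.arange(n, dtype=float)
    w = np.zeros(n)
    if n > 1:
        interior = idx[1:]
        mid = interior.mean()
        half = max(interior.max() - mid, 1.0)
        w[1:] = np.maximum(0.05, 1.0 - 0.8 * ((interior - mid) / half) ** 2)
    else:
        w[0] = 1.0

    rows, cols = slice_shape
    h_mm, w_mm = rows * mm_per_px, cols * mm_per_px
    rv, rh = 0.34 * h_mm, 0.155 * w_mm  # hemisphere semi-axes
    cy = 0.5 * h_mm
    gap = 0.015 * w_mm
    ipsi_c = (cy, 0.5 * w_mm - rh - gap)
    contra_c = (cy, 0.5 * w_mm + rh + gap)
    aspect = rv / rh
    blemish_r = float(np.sqrt(blemish_area_mm2 / np.pi))
    blemish_c = (0.30 * h_mm, ipsi_c[1])

    records: list[LesionGroundTruth] = []
    slice_sets: list[SliceSet | None] = []
    for sid, area in zip(subject_ids, slit_areas):
        vol = model.slope_mm3_per_mm2 * area + model.intercept_mm3
        if model.noise_sd_mm3 > 0:
            vol += model.noise_sd_mm3 * rng.standard_normal()
        if area == 0 and model.intercept_mm3 == 0 and model.noise_sd_mm3 == 0:
            vol = 0.0
        vol = max(vol, 0.0)
        slice_areas = (vol * w / w.sum() / model.slice_thickness_mm) if vol > 0 else np.zeros(n)

        sliceset = None
        exclusion: list[np.ndarray | None] = [None] * n
        if render:
            slices, hemis = [], []
            for i in range(n):
                a_inf = slice_areas[i]
                # ischemic swelling grows the ipsilateral hemisphere by a
                # fraction of the slice's infarct area
                swell_area = swelling_frac * a_inf
                s = np.sqrt(1.0 + swell_area / (np.pi * rv * rh))
                ipsi = _ellipse_mask(slice_shape, ipsi_c, (rv * s, rh * s), mm_per_px)
                contra = _ellipse_mask(slice_shape, contra_c, (rv, rh), mm_per_px)
                img = np.empty((rows, cols, 3), dtype=float)
                img[:] = (12.0, 12.0, 14.0)
                tissue = ipsi | contra
                img[tissue] = (186.0, 62.0, 58.0)
                if a_inf > 0:
                    b = np.sqrt(a_inf / (np.pi * aspect))
                    inf_mask = _ellipse_mask(
                        slice_shape, ipsi_c, (aspect * b, b), mm_per_px
                    )
                    img[inf_mask] = (235.0, 226.0, 214.0)
                if i == 0 and blemish_area_mm2 > 0:
                    bl = _ellipse_mask(
                        slice_shape, blemish_c, (blemish_r, blemish_r), mm_per_px
                    )
                    img[bl & ipsi] = (235.0, 226.0, 214.0)
                    exclusion[0] = _ellipse_mask(
                        slice_shape,
                        blemish_c,
                        (max(3 * blemish_r, 1.0),) * 2,
                        mm_per_px,
                    )
                img += rng.normal(0.0, 5.0, img.shape)
                slices.append(np.clip(img, 0, 255).astype(np.uint8))
                hemis.append({"ipsi": ipsi, "contra": contra})
            sliceset = SliceSet(
                slices=slices,
                thickness_mm=model.slice_thickness_mm,
                mm_per_px=mm_per_px,
                hemisphere_masks=hemis,
            )
        records.append(
            LesionGroundTruth(
                subject_id=sid,
                slit_area_mm2=float(area),
                volume_mm3=float(vol),
                slice_areas_mm2=list(map(float, slice_areas)),
                blemish_area_mm2=blemish_area_mm2,
                exclusion_rois=exclusion if render else None,
            )
        )
        slice_sets.append(sliceset)
    return records, slice_sets


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


@dataclass
class Study:
    """A generated four-group study: design table plus deterministic access
    to every subject's imaging sessions and (group 4 only) lesion data.

    Sessions are synthesized on demand from per-(subject, protocol, session)
    seeds derived from the root seed, so the object stays small while two
    studies built from the same inputs are identical.
    """

    design: pd.DataFrame
    seed: int
    protocols: tuple[str, ...]
    sessions: tuple[str, ...]
    frame_size: tuple[int, int]
    n_trials: dict[str, int]
    noise: NoiseSpec
    lesion_model: LesionModel
    subject_amp_cv: float = 0.05

    def subject_row(self, subject_id: str) -> pd.Series:
        rows = self.design[self.design.subject_id == subject_id]
        if rows.empty:
            raise KeyError(f"unknown subject {subject_id}")
        return rows.iloc[0]

    def truth_for(self, subject_id: str, protocol_name: str) -> ResponseGroundTruth:
        row = self.subject_row(subject_id)
        return default_truth(self.frame_size, protocol_name).scaled(
            float(row.amp_factor)
        )

    def session_stack(
        self, subject_id: str, protocol_name: str = "sparse", session: str = "baseline"
    ) -> tuple[FrameStack, dict]:
        row = self.subject_row(subject_id)
        protocol = PROTOCOLS[protocol_name]
        scenario = ScenarioSpec(
            group_id=int(row.group), session=session, noise=self.noise
        )
        ss = np.random.SeedSequence(
            [
                self.seed,
                int(row.subject_index),
                list(PROTOCOLS).index(protocol_name),
                list(self.sessions).index(session) if session in self.sessions else 9,
            ]
        )
        stack, record = generate_session(
            protocol,
            scenario,
            self.truth_for(subject_id, protocol_name),
            n_trials=self.n_trials[protocol_name],
            frame_size=self.frame_size,
            seed=ss,
        )
        stack.meta["subject_id"] = subject_id
        record["subject_id"] = subject_id
        return stack, record

    def lesion_dataset(
        self, render: bool = True, **kwargs
    ) -> tuple[list[LesionGroundTruth], list[SliceSet | None]]:
        """Lesion data for the lesioned group (group 4) only."""
        g4 = self.design[self.design.group == 4]
        if g4.empty:
            return [], []
        return generate_lesion_dataset(
            self.lesion_model,
            g4.slit_area_mm2.to_numpy(),
            seed=np.random.SeedSequence([self.seed, 999983]),
            render=render,
            subject_ids=list(g4.subject_id),
            **kwargs,
        )


def generate_study(
    design: dict[int, int] | None = None,
    seed: int = 0,
    protocols: tuple[str, ...] = ("sparse", "condensed"),
    sessions: tuple[str, ...] = ("baseline", "24h"),
    frame_size: tuple[int, int] = (128, 128),
    n_trials: dict[str, int] | None = None,
    noise: NoiseSpec | None = None,
    lesion_model: LesionModel | None = None,
    slit_areas_mm2=DEFAULT_SLIT_AREAS_MM2,
    subject_amp_cv: float = 0.05,
) -> Study:
    """Generate a full study design: 4 groups (default n = 8 each).

    Subjects are randomly assigned to groups from the seeded stream; each
    subject carries a mild amplitude factor (lognormal-like, cv ~5%) applied
    identically at baseline and 24 h.  Only group 4 receives slit areas (and
    hence a lesion dataset); its slit areas are a seeded permutation of
    ``slit_areas_mm2`` (cycled if the group is larger).
    """
    if design is None:
        design = {g: 8 for g in GROUPS}
    for g, n in design.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group id {g!r}")
        if n < 1:
            raise ValueError(f"group {g} size must be positive")
    for p in protocols:
        if p not in PROTOCOLS:
            raise ValueError(f"unknown protocol {p!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    n_subjects = int(sum(design.values()))
    subject_ids = [f"S{k + 1:02d}" for k in range(n_subjects)]
    groups = np.concatenate([np.full(n, g, dtype=int) for g, n in sorted(design.items())])
    rng.shuffle(groups)
    amp_factor = np.exp(rng.normal(0.0, subject_amp_cv, n_subjects)) if subject_amp_cv > 0 else np.ones(n_subjects)

    slit = np.full(n_subjects, np.nan)
    g4_idx = np.flatnonzero(groups == 4)
    if g4_idx.size:
        pool = np.asarray(list(slit_areas_mm2), dtype=float)
        reps = int(np.ceil(g4_idx.size / pool.size))
        areas = np.tile(pool, reps)[: g4_idx.size]
        rng.shuffle(areas)
        slit[g4_idx] = areas

    df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "subject_index": np.arange(n_subjects),
            "group": groups,
            "amp_factor": amp_factor,
            "slit_area_mm2": slit,
        }
    )
    return Study(
        design=df,
        seed=seed,
        protocols=tuple(protocols),
        sessions=tuple(sessions),
        frame_size=frame_size,
        n_trials={
            p: (n_trials or {}).get(p, PROTOCOLS[p].trials_per_block)
            for p in PROTOCOLS
        },
        noise=noise or NoiseSpec(),
        lesion_model=lesion_model or LesionModel(),
        subject_amp_cv=subject_amp_cv,
    )
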