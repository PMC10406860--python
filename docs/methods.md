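# Methods

## The study design being modeled

Four groups of rats (n = 8 each by default) are imaged at baseline and 24 h.
Group 1 receives vehicle only, group 2 sham occlusion plus a
monocarboxylate-transporter (MCT) inhibitor that blocks astrocyte→neuron
lactate transport, group 3 permanent middle-cerebral-artery occlusion (pMCAo)
plus vehicle, and group 4 pMCAo plus the MCT inhibitor; all receive immediate
post-occlusion whisker stimulation (four sparse blocks of 64 trials = 256
trials).  The design's expected outcome, which the synthetic generator
encodes as its `response_scale` rules, is: the drug silences the whisker
functional representation (WFR) in groups 2 and 4 while present; at 24 h only
group 4 stays eliminated (and develops an infarct under its skull-dura
slits), group 2 fully recovers, and groups 1 and 3 are never affected.

## Synthetic imaging sessions

**Acquisition model.** Frames of 100 ms are acquired only within trials.
The sparse protocol collects 1.5 s pre-stimulus, 1 s stimulus (5 Hz, 9°
deflection) and 13.5 s post-stimulus per trial with a 6 ± 5 s uniform-jitter
inter-trial interval; the condensed protocol collects 1.5 + 1 + 2 s with a
constant 1 s interval.  The sparse protocol's segment sum (16 s) differs
from its nominal 15 s trial length; the generator follows the segments and
records the nominal value in the stack metadata so downstream users can see
the discrepancy.  Both interpretations are available by constructing a
`ProtocolSpec` with other segment durations.

**Evoked response.** The embedded signal is separable:
`FC(t, x, y) = k(t) · G(x, y) · response_scale`, with `G` an isotropic
Gaussian footprint (default σ = 12 px of a 128-px / 7 mm field ≈ 0.66 mm)
and `k` a sum of three gamma-variate lobes
`g(τ) = τ³ exp(3(1 − τ))`, `τ = (t − latency)/(peak − latency)`, signed
− / + / − for dip, overshoot, undershoot.  Gamma lobes are the standard
smooth unimodal shape for hemodynamic impulse responses; shape 3 gives
realistic rise/fall asymmetry.  Default timing (latency, peak in s after
onset): dip (0.25, 1.75), overshoot (2.0, 4.0), undershoot (6.0, 8.5);
condensed responses are dip-only with peak 2.5 s so the dip is still growing
at trial end.  Default amplitudes 3.5 / 4.0 / 2.5 × 10⁻⁴ ΔR/R keep every
phase above its quantification threshold after the 5-px smoothing and the
partial cancellation between overlapping lobes, at the ±2.5 × 10⁻⁴ display
scale of real recordings.  Frames are `baseline × (1 + FC)` with the
baseline near 10⁴ counts of a 16-bit camera.

**Noise.**  Per 100 ms frame and pixel, Gaussian noise (default
σ = 1 × 10⁻⁴ FC); a 0.05 Hz sinusoidal drift (5 × 10⁻⁵); respiratory (1 Hz)
and cardiac (6 Hz) sinusoids (3 × 10⁻⁵ each, the cardiac one weighted onto
vessels); and 3 static multiplicative vessel streaks (2 px wide, 15%
contrast) whose cardiac pulsation leaves the familiar black/white streak
artifacts in ratio images.  Subject-level variability enters as a ~5%
lognormal amplitude factor applied identically at both sessions.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: motion and registration errors, photon
shot noise statistics, spatially correlated physiological noise, vascular
anatomy beyond straight streaks, drug pharmacokinetics, and any
electrophysiology.  Its value is that the analysis-facing statistical
structure (triphasic signal on a compact footprint, trial-to-trial noise,
group × session design) is exact and seeded.

**Numerical representation.** Stacks are float in memory; the 16-bit
unsigned representation is applied on TIFF export.  Quantizing a 2 × 10⁻⁴
fractional signal at 10⁴ counts would inject ±0.5-count rounding error
comparable to the signal itself, which would contaminate the noise-free
closed-form checks; keeping counts in float preserves them exactly while the
disk format stays faithful to the camera.

## Ratio imaging conventions

Fractional change is `frame / reference − 1` so 0 means no change and the
dip/overshoot thresholds are symmetric about zero.  The reference is the
single 500 ms frame immediately before stimulus onset; pre-stimulus frames
are converted too (temporal baselines need them).  Pixels with non-positive
reference values are masked, never turned into infinities.  Trial
aggregation uses the framewise *mean*, so FC magnitudes are per-frame and
areal-extent thresholds apply regardless of trial count; "summed" trial
counts are display language.  Frame summation never crosses trial
boundaries and drops (with a warning) a trailing remainder.

## Spatial quantification

The Gaussian filter's half width (FWHM) of 5 px maps to σ = 5/2.3548 ≈
2.123 px; boundaries are reflective, and masked pixels are excluded by
normalized convolution (which also fills them with the local weighted mean).
Because the FWHM is fixed in pixels, the blur in millimetres grows as the
raster shrinks — at 64 px/7 mm the smoothing attenuates the default
footprint's peak by ~11%, which is why recovered peak amplitudes sit
slightly below the generated ones.

Areal extent counts the largest 8-connected suprathreshold component
containing the phase's extremal pixel (or nearest to it when the extremum
is subthreshold) rather than all suprathreshold pixels, so disjoint noise
islands are not accumulated.  Frame selection maximizes this extent inside
per-phase search windows (dip 0–3.5 s, overshoot 2–7 s, undershoot
6–13.5 s post-onset, clipped to the series duration and configurable); ties
resolve to the earliest frame, and an all-zero window returns its first
frame flagged with zero extent.  Peak amplitude ties resolve row-major.
The analysis ROI is the skull-dura-slit mask dilated by 2 px.  The
undershoot is quantified with the dip's threshold but excluded from default
reports, matching the practice of analyzing only the first two phases.

## Temporal parameters

All parameters use half-maximum conventions with linear interpolation
between the 500 ms samples (coarse sampling makes interpolation matter):
half-time is the first crossing of half the peak magnitude on the rising
limb, duration the width at half magnitude, rates the half-to-peak magnitude
over the corresponding interval, AUC the trapezoidal integral of FC over the
above-half span, and the minimum-to-maximum ratio is |dip peak| / |overshoot
peak|.  A phase whose window peak stays below its quantification threshold
is *undefined*, never zero.  A falling limb that does not return to half
magnitude inside the window (the condensed growing dip) is truncated at the
window end and flagged.  Session comparisons report follow-up / baseline
ratios per defined parameter; since the exact between- vs within-session
reading of "half-time ratio" admits two interpretations, both are computed:
the between-session ratio of half-times (`half_time_ratio`) and the
within-session half-time/peak-time pair
(`within_session_half_over_peak`).  The peak pixel is re-selected within
the ROI at each session (frozen-pixel mode is a one-line change: pass the
baseline pixel to `extract_time_course`).

## TTC volumetry

Slices are segmented on the red-chroma channel `R − (G + B)/2` within
tissue with a two-class Otsu split, accepted only when the classes are
separated by ≥ 0.15 chroma and the low-chroma class is the lighter one —
so a fully stained slice yields an empty mask instead of a spurious split.
Volume is Σ area × 2 mm.  Edema is corrected with the indirect
(contralateral) method, `contra − (ipsi − infarct)` per slice, chosen
because it is the standard edema-robust estimator and reduces exactly to
the raw area for symmetric hemispheres; it is an interchangeable strategy
behind `edema_correct`.  Surgical-site exclusion has two modes: with a
declared surgical ROI, components overlapping it are removed; without one,
components smaller than 1 mm² and disjoint from the largest component are
removed.  The modes are alternatives because small genuine lesion areas on
edge slices would otherwise be eaten by the size rule.  Damage contiguous
with the main lesion is necessarily part of its component and is retained
(flagged when the ROI touches it).

The lesion generator draws volumes `12 · slit_area + 5 + N(0, 9)` mm³
(truncated at 0), calibrated from the closed-form relation between slope,
slit-area spread (1–6 mm² over 8 subjects) and noise so the OLS R² averages
≈ 0.87, and distributes each volume over the interior slices with a
parabolic profile (slice 0 is spared so the 0.5 mm² surgical blemish placed
there is always disjoint from the lesion).  Rendering uses concentric
ellipses inside the ipsilateral hemisphere, so the rasterized area matches
the drawn area to well under the 3% tolerance the recovery tests assert.
Optional swelling grows the ipsilateral hemisphere by a fraction of each
slice's infarct area to exercise the edema correction.

## Statistics

The imaging metrics form a balanced two-way mixed design (between: group;
within: baseline vs 24 h).  Sums of squares are computed from cell means;
group is tested against subjects-within-groups, time and group × time
against the within-subject residual.  With two within-subject levels
sphericity holds trivially, so no correction is applied.  Degenerate inputs
resolve explicitly: zero effect variance → F = 0, p = 1; zero error variance
with nonzero effect → F = ∞, p = 0.  Post hoc contrasts are per-group paired
t-tests with Bonferroni adjustment `min(1, p × m)`.  Infarct volumes use
Welch (unequal-variance) t-tests — the conservative default when only
"two-sample t-tests" is specified — and baseline equivalence a one-way
ANOVA.  Cells with an eliminated WFR enter the ANOVA as 0 for area/peak
metrics and are flagged in the report; entering them as missing instead is
supported by filtering the measurement table before calling the stats layer.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the whole suite
completes in a few minutes while every statistical margin stays wide:
noise-free oracles at 64 px with 1–2 trials; study-level sweeps at 48 px
with 8 trials/session, sparse protocol, 4 × 8 subjects, 20 seeds; lesion
sweeps at 50 seeds × 8 subjects with full rendering and segmentation.  The
full-scale configuration (128 or 512 px, 64-trial blocks, both protocols)
is the generator default and runs through the identical code path.

## Known limitations

- The fixed-pixel smoothing kernel couples metric values to raster size;
  compare areal extents only across sessions analyzed at the same scale.
- The connected-component extent rule is one defensible reading of
  "areal extent at a threshold"; global suprathreshold counting would give
  slightly larger areas on noisy frames.
- No image registration or motion correction (stable thinned-skull
  preparation assumed).
- Segmentation assumes TTC-like color statistics (red stain vs white
  infarct); calibration `mm_per_px` must be supplied for real photographs.
- Timing parameters are nonparametric; no hemodynamic model is fit.
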