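# wfrquant

Quantification of **whisker functional representations (WFR)** from
**intrinsic signal optical imaging (ISOI)**, built for the analysis design of
a four-group rat stroke-neuroprotection study: ratio imaging, spatial and
temporal phase metrics, TTC infarct volumetry with edema correction, the
slit-size → infarct-volume regression, and the study's inferential layer
(mixed-design RM-ANOVA, Bonferroni contrasts, Welch t-tests).  A first-class
synthetic-data generator emulates the imaging sessions and histology with
known ground truth, so every stage of the pipeline is verifiable without
animal data.

Intended users: imaging labs quantifying evoked hemodynamic responses
(barrel-cortex ISOI, stroke models) and anyone needing a tested, seeded
reference implementation of thresholded areal-extent analysis.

## The measurements

**Ratio imaging.** Raw 100 ms camera frames are summed within trials to
500 ms frames, then converted to fractional change against the single 500 ms
pre-stimulus reference frame collected immediately before stimulus onset:

```
FC_t(x, y) = frame_t(x, y) / frame_ref(x, y) − 1        (ΔR/R units)
```

Trials (64 per sparse block, 40 per condensed block) are aggregated by the
framewise mean.  The evoked response under a long-trial *sparse* protocol is
triphasic — initial dip (−), overshoot (+), undershoot (−) — while the
naturalistic *condensed* protocol shows a single growing initial dip.

**Spatial metrics.** Per phase, the frame with the maximum thresholded areal
extent in its search window is selected and Gaussian filtered (FWHM 5 px).
Areal extent is the largest 8-connected component beyond the threshold
(1.75 × 10⁻⁴ for the dip and undershoot, 2.5 × 10⁻⁴ for the overshoot, away
from zero) containing the extremal pixel; peak amplitude is the extremal FC
value within that extent, evaluated inside the skull-dura-slit ROI.

**Temporal metrics.** The peak pixel's FC time course yields half-maximum
timing parameters per phase (onset, half-time, peak time, duration, rise and
fall rates, AUC, dip-to-overshoot ratio) and 24 h / baseline ratio tables.

**Histology.** TTC slice photographs are segmented (two-class split on red
chroma: unstained white tissue = infarct), surgical-site damage is excluded,
volume is Σ slice area × 2 mm thickness, corrected for edema with the
indirect contralateral-hemisphere method, and regressed on total slit area
by OLS.

## Worked example

```python
from wfrquant.protocols import SPARSE, ScenarioSpec, default_truth
from wfrquant.synthetic import generate_session
from wfrquant.pipeline import analyze_session, analysis_roi, roi_from_truth

truth = default_truth((64, 64))                       # WFR ground truth
scenario = ScenarioSpec(group_id=1, session="baseline")
stack, record = generate_session(SPARSE, scenario, truth,
                                 n_trials=16, frame_size=(64, 64), seed=7)
roi = analysis_roi(roi_from_truth(truth, (64, 64)))   # slit mask + 2 px
result = analyze_session(stack, roi=roi)

for phase in ("initial_dip", "overshoot"):
    m = result.phases[phase]
    print(f"{phase:12s} frame t={m.selected_time_s:+.2f} s  "
          f"area={m.areal_extent_mm2:.2f} mm^2  peak={m.peak_fc:+.2e} dR/R")
```

prints

```
initial_dip  frame t=+1.75 s  area=1.64 mm^2  peak=-2.98e-04 dR/R
overshoot    frame t=+4.25 s  area=0.79 mm^2  peak=+3.19e-04 dR/R
```

i.e. the dip is largest 1.75 s after stimulus onset, covers 1.64 mm² of the
7 mm field above the 1.75 × 10⁻⁴ threshold, and its peak magnitude
(−2.98 × 10⁻⁴ after smoothing) recovers the embedded 3.5 × 10⁻⁴ amplitude to
within the expected smoothing attenuation; the overshoot follows at 4.25 s
with the opposite sign.  A full four-group study is available through
`wfrquant.synthetic.generate_study` / `wfrquant.pipeline.analyze_study`, or
from the command line:

```sh
wfrquant simulate --out ds --seed 3 --n-per-group 8
wfrquant analyze --dataset ds --out results_ds
```

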