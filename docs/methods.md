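# Methods

## The problem and the model

Esophageal peristalsis is usually read from manometry alone, but
intraluminal pressure is only half of the mechanics: whether circular
muscle is actively contracting, actively relaxing, or passively
following the bolus can only be decided by looking at luminal geometry
and pressure *together*. `mechstate` implements mechanical-state
analysis: at every time sample and every catheter site it pairs the
category of luminal change with the category of pressure change and
maps the pair to one of twelve mechanical states.

The luminal signal is either fluoroscopically measured diameter (mm)
or admittance (mS), the inverse of intraluminal impedance, which
tracks luminal cross-section while a conductive bolus is present.
Running both variants on the same swallow and measuring their
concordance (Pearson correlation of the two signals over the luminal
event; percent of samples with identical state labels) is what
justifies using the catheter-only admittance variant when fluoroscopy
is unavailable.

### Category definitions

Per site, the *luminal event* is detected from gradient inflexions of
the (smoothed) luminal signal:

* **O**, first lumen opening — first sample whose gradient reaches
  +2 mm/s (diameter) or +1 mS/s (admittance);
* **C**, final lumen closure — last sample whose gradient reaches
  −2 mm/s / −1 mS/s;
* **M**, maximal luminal extent — time of the maximum signal value in
  [O, C]; a flat maximum is resolved to the midpoint of the maximal
  run (symmetric tie-break).

Outside [O, C] the lumen category is **occluded**. Inside it, the
signal gradient is compared against per-site change thresholds: for
diameter, the 10th percentile *by magnitude* of the phase gradients
(opening phase O→M for the increase threshold, closing phase M→C for
the decrease threshold; percentiles interpolate linearly between order
statistics). We take the percentile of |gradient| and apply the
phase's sign: when every phase gradient has the phase's sign this is
exactly the ascending 10th (opening) / 90th (closing) percentile of
the signed gradients, and unlike those it cannot produce a
wrong-signed threshold when noise pushes a few near-peak samples
across zero. A `literal` orientation (ascending 10th percentile in
both phases, i.e. the steepest decile of the closing slopes) is kept
behind a config switch because the published wording admits both
readings; the magnitude orientation is the default since the steepest
decile would label ~90% of the closing phase static, contradicting the
dominance of contraction states between M and C. For admittance the
change thresholds are fixed at ±0.57 mS/s. Pressure change always
uses ±10 mmHg/s.

Thresholds are inclusive (a gradient exactly at a threshold counts as
change), so "static" is the open interval between them.

### The 12-state grid

| lumen \ pressure | static | increasing | decreasing |
|---|---|---|---|
| **occluded**   | oq (passive) | oimc | oimr |
| **static**     | dq (passive) | dipi | dipd |
| **increasing** | itr | pd (passive) | atr |
| **decreasing** | itc | atc | ps (passive) |

oq occluded quiescence; oimc/oimr occluded isometric
contraction/relaxation; dq distended quiescence; dipi/dipd distended
isometric pressure increase/decrease; itr/itc isotonic
relaxation/contraction; atr/atc auxotonic relaxation/contraction; pd
passive dilatation; ps passive shortening. Eight states are active,
four passive, and the grid is total: every category pair maps to
exactly one state. We expand dipi/dipd as *distended isometric*
states (static-open lumen with pressure change) — the reading
consistent with the 4×3 grid and the 8-active/4-passive split.

Classification is instantaneous and deterministic; no smoothing or
hidden-state model is applied to the label sequence. Brief threshold
chatter at category boundaries therefore appears as transient
single-sample deviations; `dominant_sequence` reports the order of
states after collapsing runs shorter than 3 samples (0.15 s at
20 Hz), which is the view used when checking canonical state orders.

## Preprocessing

Fixed order, enforced by the pipeline: impedance→admittance inversion
(Y = 1000/Z, mS); diameter calibration (pixel scale, minus the 3.2 mm
catheter, clamped at 0 so an occlusive lumen reads exactly 0 mm);
linear interpolation of all channels onto the pressure clock (20 Hz)
over their overlap; Gaussian smoothing; central-difference gradients.

The published smoothing is "a time window of 0.25 s" without a stated
σ; we interpret the window as the total kernel support with
σ = window/4 (truncation at ±2σ), normalized to unit sum with edge
renormalization, and expose the window in `PreprocessConfig` so the
choice can be swept. Smoothing precedes differentiation so that
derivative noise does not dominate the percentile thresholds; whether
the original analysis smoothed before or after timebase alignment is
unstated, and we fix align→smooth.

## Epochs, concordance, maps

Each timeline is binned into four epochs — [start, O), [O, M), [M, C),
[C, end] — and per-epoch state proportions are reported (each
non-empty epoch sums to 1). The diameter–admittance correlation is
computed on the smoothed, aligned traces over the window
[O − 0.1·(C−O), C + 0.1·(C−O)] clipped to the recording, so event
samples are ≥ 80% of the window by construction; the exact window rule
around "the main event" is not published and the 10% pad is our
documented choice. Correlation sets are summarized overall and per
bolus-type × posture stratum (mean, median, SD), with low outliers
flagged at Q1 − 1.5·IQR (quartiles by linear interpolation; the rule
is sensitive to the quartile definition, so it is fixed and
documented). Strata that are never observed — solid boluses in the
decubitus position are not administered — are absent, not zero-filled.

State maps stack per-site timelines in axial order (cm below the UES,
proximal at the top); regional summaries split sites at the transition
zone (a site exactly on the boundary is distal) and may omit occluded
quiescence, renormalizing the remainder (which preserves the ratios of
the remaining states). Sites excluded from analysis are rendered in a
reserved code/color. The fixed palette groups families: quiescence
grays/greens, relaxations blues, contractions oranges/reds, passive
dilatation gray.

Sites are excluded, with a logged reason, when (a) opening is detected
but closure never follows (incomplete event), or (b) a phase has fewer
than 5 gradient samples or yields a wrong-signed adaptive threshold.
Sites with no detected event at all are labelled occluded quiescence
throughout for map rendering but contribute no epoch statistics.

## The synthetic generator

No clinical recordings are distributed, so the generator produces
seeded, phenomenological swallows with analytic ground truth:

* **Opening pulse**: trapezoid, peak 12 mm, rise 2 s, plateau 0.2 s,
  fall 2 s, delayed per site by position/velocity (3 cm/s). The short
  plateau serves two purposes: it gives distended quiescence a
  resolvable dwell between isotonic relaxation and contraction, and it
  pins the maximal-extent time — with the midpoint tie-break, M
  detection under noise is bounded by the plateau half-width plus a
  couple of samples, whereas a smooth (raised-cosine) peak is flat
  enough that noise can move the argmax several samples. Raised-cosine
  is available as an option.
* **Pressure**: 5 mmHg baseline; an optional bolus-pressure ramp
  (15 mmHg over 1 s, leading opening by 0.1 s) on sites proximal of
  the transition zone, which yields passive dilatation as the bolus
  distends the striated-muscle wall; and a 100 mmHg trapezoidal-cosine
  contraction wave whose upstroke begins 0.8 s *before* closure — so
  auxotonic contraction precedes closure, as in the canonical sequence
  — and peaks just after it, then falls over 1.8 s. The ramp decays
  exponentially (τ = 3 s) after closure.
* **Admittance**: Y = y0 + k1·d + k2·d² (y0 = 2 mS, k1 = 1 mS/mm,
  k2 = 0.05 mS/mm²), monotone in diameter; impedance is 1000/Y. The
  mild quadratic term reflects admittance tracking cross-sectional
  area; a pure quadratic coupling is available but lowers the
  linear-correlation ceiling over the event window to ~0.97. An
  optional post-closure admittance offset emulates the elevated
  post-swallow baseline seen in practice (residual conductive
  coating); it is off by default.
* **Noise**: band-limited Gaussian (0.5 s correlation time), scaled by
  the channel range and, for lumen channels, by the aperture with a
  0.2 floor when occluded. This is a measurement model: a
  fluoroscopically occluded lumen reads a stable 0 mm by the
  calibration convention, margin-tracking error grows with the open
  aperture, and acquisition chains band-limit their output. White
  per-sample noise of the same SD would put several mm/s of noise on
  the gradients and make the first-crossing opening rule fire on
  baseline noise, which real recordings analyzed with these exact
  thresholds evidently do not do. The correlation time was set so
  that, at 5% noise, detected O/M/C stay within 3 samples of truth —
  the generator's stated recovery property.
* **Ground truth**: per-site O/M/C and per-sample states computed from
  the noiseless, unsmoothed waveforms pushed through the same event
  rules, adaptive thresholds and state grid the classifier uses.
  Truth is thus well defined without circularity: the classifier sees
  smoothed (and possibly noisy) data instead, and at zero noise
  reproduces truth at ≥ 99% of samples, disagreeing only within 3
  samples of truth state transitions where smoothing shifts threshold
  crossings.

Default geometry spans the esophageal body (8 sites at 2 cm, three
proximal of the transition zone at 7 cm, EGJ at 24 cm); the `distal`
preset (8 distal sites, no ramp) matches the distal-validation
setting. Cohorts cycle liquid/semisolid/solid × upright/decubitus
without solid×decubitus; thicker boluses get a larger ramp (+8/+14
mmHg) and a longer pulse (+0.4/+0.8 s). Default noise is 2% of
channel range — a clean clinical recording; analytic checks use 0.

### What the generator does and does not emulate

It reproduces the *timing structure* a classifier must parse —
propagating opening, quiescent distension, overlapping closure and
contraction, bolus-pressure loading, monotone admittance coupling,
occluded baselines — with known truth. It is not a biomechanical
(tube-law/fluid) simulation: waveform shapes are templates, noise is
stationary and Gaussian, there is no air artifact, no swallow-to-swallow
morphology variation beyond the stratum presets and noise, and no
pathological motility. Passing tests therefore demonstrate that the
implementation applies the method's rules correctly and recovers known
structure under realistic noise; they do not validate the method's
clinical accuracy, and the published clinical concordance figures
(e.g. mean r ≈ 0.90, 93.4% inter-method agreement on fluoroscopy
studies) are properties of those recordings, which are not deposited,
and are not reproduced here.

## Numerical choices

* Percentiles/quartiles: linear interpolation between order statistics
  throughout (numpy default).
* Threshold comparisons inclusive (≥ / ≤).
* Timestamps must be uniform within 1 µs; timelines are compared on a
  shared timebase within the same tolerance.
* Gradient: `numpy.gradient` (central differences, one-sided ends).
* Event detection uses the smoothed gradient (the raw-vs-smoothed
  choice at "reached 2 mm/s" is unstated in the source method;
  smoothed is used consistently).
* Degenerate inputs: constant traces give an undefined correlation
  (excluded, logged); empty epochs are flagged, not fabricated;
  all-quiescent regional summaries renormalize to NaN proportions and
  are flagged rather than dropped silently.

## Problem sizes used in tests and the acceptance script

Checks run on 20 s, 20 Hz, 8-site recordings (400 samples/site):
single swallows for sequence checks, 20-swallow cohorts for the
common-state census, 50 swallows (400 events) for parameter recovery
at 5% noise, and 5–6 swallow cohorts per noise level for concordance,
chosen to exercise every stratum and keep the whole suite fast.

## Known limitations

* The correlation-window pad rule and the smoothing σ convention are
  documented choices where the published method is silent; both are
  configurable.
* Adaptive thresholds need ≥ 5 gradient samples per phase; very short
  events are excluded rather than classified with unstable thresholds.
* At high noise (≥ 10% of range) sites are increasingly excluded via
  the wrong-signed-threshold guard; agreement between methods degrades
  accordingly, which is the expected failure mode, but no attempt is
  made to rescue such sites.
* The renderer aims for a readable, consistently keyed map, not an
  exact visual replica of published figures.
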