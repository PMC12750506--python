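# Methods

This note records the models, algorithms and numerical choices behind
`hoofline`, in the order the pipeline runs them, together with what the
synthetic data generator does and does not emulate.

## The synthetic trotting horse

The generator stands in for a markerless pose-estimation network: it
produces exactly what such a network would — per-frame 2D pixel keypoints
with visibility flags — from a known ground truth, so recovery can be
measured exactly.

**Trunk model.** Each trunk landmark (eye, withers, back, croup) follows

    z(t) = z0 − A·cos(4πf t + φk) + a·sin(2πf t + ψ)

with stride frequency `f` (default 1.25 Hz), symmetric second-harmonic
amplitude `A` (`trunk_amp`, default 30 mm) and a stride-frequency
component `a` (`asym_amp`, default 0) that models impact/push-off
asymmetry. This two-harmonic form is the minimal signal with independent
Maxdiff and Mindiff: at the trunk maxima the 1f term contributes `+a` on
one diagonal and `−a` on the other, so ground-truth Maxdiff ≈ 2a (first
order), while at phase ψ = 0 the minima are untouched. All per-stride
ground truth is computed by dense-grid search (10⁴ samples per stride) on
this closed form — the oracle that every downstream test compares against.

**Limb model.** Diagonal pairs (lf+rh, rf+lh) are half a stride apart.
During stance (`duty_factor`, default 0.45, of the stride) the hoof is on
the ground plane (z = 0 exactly) and translates backwards at belt speed
(default 4.8 m/s); during swing it returns at constant horizontal velocity
while lifting along a half-sine of apex `hoof_lift` (default 80 mm). The
reference fore hooves touch down at stride phase 0.875, placing all four
trunk extrema strictly inside an onset-to-onset stride (at 12.5%, 37.5%,
62.5% and 87.5% of the stride). Fetlock and carpus/tarsus keypoints are
carried as plausible smooth functions of the hoof; only the hooves matter
downstream.

**A planar horse.** All keypoints lie in the sagittal plane (world y = 0).
Real horses have ~20 cm of lateral hoof offset; ignoring it makes stance
hooves exactly collinear with the projected ground trace in every view and
keeps the problem strictly 2D, which is the input contract of the
analysis. Consequences for realism: no left/right depth disparity, so
oblique views are slightly cleaner than reality.

**Cameras.** Standard pinhole projection, y-down image coordinates,
look-at orientation toward a point 1 m above the treadmill midline. The
default rig mirrors a treadmill lab: six stationary views (50° oblique
front/rear at 100 cm, perpendicular right-side views at 50/100/160 cm, a
left-side view at 2.5 m) plus a handheld right-side view at 160 cm. Focal
lengths (1500 px at 3 m, 1250 px at 2.5 m; 1920×1080 image) give a
withers-height scale of ≈ 2 mm/px, so the default 1 px keypoint noise is
≈ 2 mm of apparent landmark motion. The handheld camera's origin is
displaced per frame by a seeded vertical sinusoid (default 20 mm at 1 Hz,
an operator stepping in place) plus low-pass-filtered jitter, with half
that amplitude horizontally; its orientation stays fixed, so the bounce is
a pure translation in world space. Detection noise is i.i.d. Gaussian per
keypoint-frame; occlusion flips visibility with a given probability. The
generator does not emulate: lens distortion, motion blur, detector biases
that correlate across frames or with pose, hair/skin movement over
landmarks, or inter-stride biological variability beyond the injected
harmonics. Passing tests therefore demonstrate correct recovery of the
modelled signal under the modelled noise, not detector-specific behaviour.

## Stance detection

A stance hoof on a treadmill is *not* stationary in the image (it moves
with the belt), and under a handheld camera everything moves. Height is
therefore measured against a coarse robust reference line (two-iteration
L1 fit through the per-frame lowest hoof pixels — the slope matters in
oblique views), and camera common-mode motion is removed by tracking the
median-filtered lowest-hoof envelope. A frame is stance when the hoof is
within `d_thresh` (5 px) of that ground level and its vertical speed
relative to it is below `v_thresh` (1.5 px/frame, on a 5-frame-smoothed
track). Conservative runs (≥ `min_stance` = 3 frames, ≤ 2-frame dropouts
bridged) are then grown outward along frames that stay near the ground,
with a growth threshold adapted to the measured keypoint jitter — the
smoothing otherwise erodes one or two frames at each stance edge. With a
single hoof present there is no common mode to separate and the reference
stays static, so a hoof that never rests yields no events.

In the full pipeline detection runs twice: the second pass measures
heights against the first-pass dynamic groundline, which is sharper under
camera motion and in oblique views.

## Dynamic groundline

Per frame, all visible stance hoof pixels within a sliding window
(default 15 frames ≈ 0.5 s) are fitted with a least-absolute-residual
line. The fit is exact: an L1-optimal line with vertical residuals
interpolates at least two sample points, so all point pairs are enumerated
and the minimum-cost candidate kept (duplicate abscissae are merged first;
the tests cross-check against an independent linear-programming
formulation). Frames with fewer than two distinct support abscissae are
invalid and filled by linear interpolation of neighbouring parameters.

A windowed fit cannot follow fast camera motion, so the fit is
translation-compensated: a per-frame vertical shift — the median residual
of the frame's own stance pixels against a global static line — is
removed from the support points before the windowed fit and added back to
each frame's intercept. Numerical details that matter here: the global
line must itself be fitted on de-bounced points (three fit/shift
iterations), gaps in the shift series (suspension phases, twice per
stride) are bridged with a cubic spline because linear interpolation would
imprint a gait-locked ripple, the series is smoothed by a zero-phase
3rd-order Butterworth at `fps/(2·offset_track)` (default 3.75 Hz) rather
than a moving average (which would lag the ~1 Hz bounce), and tracking is
disabled when the estimated motion is below 1 px RMS — for a genuinely
static camera the "motion" is support noise and subtracting it would only
inject that noise into every frame. Stance-event edge frames, which may
sit marginally off the ground, are trimmed from the angle-fit support.

Under pure image translation the resulting VDS is invariant to ≈ 0.2 mm
MAE. A *world-space* camera bounce additionally produces a real parallax
error: with the handheld camera at 160 cm, the withers sits ~10% nearer in
depth than the ground trace, so a 20 mm bounce leaks ~2 mm into the raw
VDS at the bounce frequency (mostly removed by the high-pass). This
residual is physical, irreducible from a single 2D view, and is part of
what the handheld-vs-stationary comparison quantifies.

Angle convention: degrees in (−90, 90], positive when the line rises
left-to-right on screen; offset is the signed perpendicular distance from
the image origin. Stated once, used everywhere, so signed error
histograms are reproducible.

## VDS, calibration, filtering

The raw VDS is the perpendicular distance (px) of a trunk keypoint to the
per-frame groundline, positive above the line; hidden frames propagate as
gaps and are never silently imputed. Calibration divides the horse's
withers height (mm) by the *median* withers-to-groundline distance —
median, not mean, for robustness to transient extremes; the statistic is
configurable. Each groundline variant (dynamic/fixed) self-calibrates.

Stride frequency is estimated from a limb-derived signal (a hoof's
vertical track): the Hann-windowed periodogram is searched in
[0.5, 2.5] Hz; candidate fundamentals are validated by requiring spectral
support at their second harmonic, guarding against mistaking the trunk's
dominant 2f line for f, and the lowest validated candidate wins (falling
back to the band maximum for single-tone inputs). A peak must carry ≥ 20%
of the in-band power, otherwise no periodicity is declared and the caller
gets an error instead of a number. Sub-bin refinement is by parabolic
interpolation on log power.

The high-pass is a 3rd-order Butterworth with cutoff 0.95 f, applied
forward and backward. Zero-phase filtering preserves extrema timing
(which drives stride splitting) at the cost of squaring the attenuation;
the known two-pass gains are compensated downstream. A companion
zero-phase low-pass (default 6 Hz, config-exposed, disable with
`smooth_hz=None`) suppresses broadband detector jitter while passing the
trot's 2f component with < 1% two-pass loss. Gaps are bridged linearly
before filtering and re-masked after.

## Stride metrics

Strides run from one stance onset of the reference forelimb (left fore
when detected) to the next; the contralateral fore's onset splits the
stride into its two diagonal half-cycles, giving every extremum a
left/right association. A stride is excluded — never force-fitted — when
the target keypoint is hidden in any frame, when the VDS does not show
exactly two prominent maxima and two minima (prominence ≥ 20% of the
stride's peak-to-peak; counted on a ±2-frame-extended window so a
one-frame onset jitter cannot hide a boundary extremum), when the stride
model fit is poor (below), or when it touches the warm-up margin — by
default one high-pass cutoff period at each end of the recording, where
the zero-phase IIR's edge transient (which lasts about two strides and
cannot be removed by padding) corrupts the signal. A stance run truncated
by the start of the recording cannot supply an onset and is ignored.

Extrema are *not* read off the samples. The filtered VDS inside the
stride is least-squares fitted with a five-parameter harmonic basis
(constant, sine/cosine at f and 2f, periodic at the robust global
frequency estimate rather than at 1/boundary-spacing, so onset jitter
cannot leak the large 2f component into the small 1f one); the known
two-pass filter gains at f and 2f are divided out of the coefficients;
and the extrema of the compensated closed form are located per half-cycle
on a dense grid. This matters because the protocol's high-pass, cut off
only 5% below f, attenuates the stride-fundamental component — the very
carrier of Maxdiff/Mindiff — to 58% after two passes: sample-level peak
picking would systematically halve the metrics, while the harmonic
reconstruction restores them exactly and is simultaneously the
minimum-variance way to read two extrema out of ~24 noisy samples.
Strides whose fit residual exceeds 20% of the signal RMS are flagged
`poor_fit` (this also catches residual edge transients and spikes).
Maxdiff and Mindiff are left minus right; swapping the labels negates
both exactly, which is the tested sign contract.

Trials are contiguous runs of 17 valid strides (configurable); a final
remainder is kept when it reaches half the target length; trial metrics
are arithmetic means of the member strides'.

## Agreement battery

For any paired-difference vector: mean signed difference, sample SD
(n−1), 95% limits of agreement as mean ± 1.96·SD (the conventional
constant, not a t quantile — appropriate at the pooled sample sizes),
MAE, and an MAE confidence interval by normal approximation on |d| at a
configurable level (99% default; z = 2.576). Stride matching across
synchronized recordings shifts one list by the sync offset and pairs
greedily by temporal overlap (ties favour earlier strides, each stride
used once, pairs below 50% overlap of the shorter stride dropped).
Difference direction is fixed as estimated − fixed and handheld −
stationary.

The session evaluation pools three analyses: per-frame groundline angle
error over all stationary recordings; per-stride Maxdiff/Mindiff
differences between the dynamic- and fixed-groundline pipelines run on
the same trajectories (shared stance events and frequency estimate, as
when one video is processed twice); and stride- plus trial-level
handheld-vs-stationary differences per keypoint and pooled. Stride
accounting reports detected and excluded strides against the theoretical
count `duration × f̂` summed over recordings.

## Problem sizes and defaults

The shipped study conditions: cohorts of eight horses (withers heights
154–168 cm, belt speeds 4.5–5.2 m/s, stride rates 1.20–1.30 Hz, asymmetry
amplitudes spread over 0–4 mm as in an unscreened group), 30 s recordings
through all seven cameras for the agreement analyses; 42 s (≈ 50 strides)
single-camera runs for asymmetry recovery; a 600 s recording with
occlusion 0.00105 per keypoint-frame (≈ 2.5% of strides contain a hidden
frame) for stride accounting, mirroring the few-minute recordings such
protocols use. A master seed expands deterministically into all
per-horse/per-camera noise and bounce seeds; identical configurations are
bit-identical.

## Known limitations

* Oblique (50°) views foreshorten depth differently for the eye, withers
  and croup; absolute amplitudes there are biased by up to ~10–15% even
  though pipeline *agreement* (the quantity evaluated) is unaffected,
  because both groundline variants share the geometry.
* Handheld parallax (above) bounds handheld VDS fidelity at ≈ 1 mm MAE
  for the default 20 mm bounce regardless of estimator quality.
* The left/right association of extrema relies on leg identity labels
  carried by the keypoint schema, as a pose network would provide them;
  the package does not infer leg identity.
* The harmonic stride model assumes trunk motion is contained in the
  first two stride harmonics; gaits or pathologies with substantial 3f+
  trunk content would be flagged as `poor_fit` rather than measured.
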