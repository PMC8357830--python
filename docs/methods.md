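# Methods

This note documents the models, the synthetic study conditions, and the
numerical and design choices behind `gazekit`, in the spirit of a
simulation package's methods appendix.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Gaze regression model

The mapping from eye features to screen coordinates is linear in a fixed
monomial basis: `G = V c`, one row per calibration event, `c ∈ R^{N×2}`
(2N unknowns).  Four named families are shipped:

| name | basis (per row of V) | N |
|---|---|---|
| `quadratic_pupil` | x, y, xy, x², y², 1 | 6 |
| `quadratic_pupil_linear_corner` (default) | x, y, xy, x², y², m, n, 1 | 8 |
| `cubic_pupil_linear_corner` | + x³, x²y, xy², y³ | 12 |
| `full_quadratic` | all monomials of degree ≤ 2 in (x, y, m, n) | 15 |

Arbitrary monomial lists are also accepted.  The solve uses
`numpy.linalg.pinv` with relative rank tolerance `rcond = 1e-10` rather
than forming `(VᵀV)⁻¹` explicitly: the two are equivalent for
well-conditioned data, and the pseudo-inverse returns the minimum-norm
solution (with a warning) when `V` is rank deficient — which happens
routinely, because during an initial calibration at a single head pose the
corner columns `m, n` are constant and collinear with the constant term.
This degeneracy is real, not an artifact: a model calibrated at one pose
has no information about pose dependence, and progressive calibration is
what supplies it.

Progressive calibration appends rows and refits in batch; append-then-fit
is exactly equal to a batch fit on the concatenated data, and no aging or
down-weighting of old rows is applied.  The two eyes carry independent
models whose predictions are averaged with equal weight; if one eye's
features are missing (blink, lost pupil) the other is used alone.

Screen coordinates are normalized to width 1, origin top-left; all errors
are Euclidean distances × 100 (percent of screen width), which makes them
invariant under joint rescaling of the display.

## Synthetic study conditions

The generator emulates sessions at the *feature* level and, optionally,
at the *image* level.  A session script fixes the target sequence
(positions, onsets, durations), a head-pose schedule, and noise
parameters; all stochastic components derive from one seed
(`numpy.random.SeedSequence` children in a fixed order), so a (script,
seed) pair reproduces a session bit-for-bit.

**Forward map.**  The default `TangentForwardMap` converts (true gaze,
head pose) to noise-free features.  For centered screen coordinates
`u = gx − 0.5`, `v = gy − aspect/2`:

```
r(w)  = tan(c·w)/c + a·w²          c = 0.9 (curvature), a = 0.45 (asymmetry)
x     = x₀ + s·(1 + γ·dn)·Gx·r(u) + k·dm
y     = y₀ + s·(1 + γ·dn)·Gy·r(v) + k·dn
m, n  = (m₀ + dm, n₀ + dn)
```

with gains `Gx = 120 px`, `Gy = 110 px`, pose coupling `k = 5.5`, gain
modulation `γ = 0.004/px`, and a per-eye scale `s` (right eye 0.94).  The
design goals, fixed before the evaluation suite was written, were:

1. *No candidate family inverts the map exactly.*  The tangent curvature
   and the even `w²` term (perspective compression of an obliquely mounted
   camera) leave a residual for every polynomial candidate, so model
   comparison is meaningful.
2. *Head-pose changes alter the pupil pattern, not just the anchor.*  A
   pose offset `(dm, dn)` translates the corner, shifts the pupil response
   additively (`k`), and slightly re-scales it (`γ`) — emulating the
   pattern changes a camera sees when the head rotates.  The additive part
   is correctable to first order by the linear `m, n` terms, which is
   precisely why the 8-term family adapts well; the higher-order families
   can fit the pose structure in-sample and generalize worse to unseen
   poses, while the pupil-only family cannot adapt at all.

The pose coupling is deliberately strong (a few px of corner shift move
the pupil response by tens of px): it stands in for head rotation, where
the eyeball re-orients to keep fixation and the pupil-in-camera geometry
changes much more than the canthus position.

**Fixational noise.**  Within fixations the features carry (defaults in
parentheses): white tremor on the pupil (sd 0.3 px/frame), slow ocular
drift as a mean-reverting Ornstein–Uhlenbeck walk (0.15 px/√s, time
constant 2 s) shared by both eyes, Poisson microsaccades (1.5 /s, 1–3 px,
decay 25 ms — the physiological duration scale), and corner measurement
jitter (sd 0.2 px).  Tremor and microsaccades are largely removed by the
per-fixation median; the drift is what survives it, giving fixation
features realistic sub-pixel to pixel-scale noise.  Blinks (0.08 /s,
250 ms) invalidate frames; a fixation must keep ≥ 50% valid frames to
emit a calibration sample.

**Protocols.**  Built-in scripts mirror the standard experiment designs:
a 3 × 5 target grid repeated over 8 head poses (calibration on round 1)
for model selection; a 9-point, 3 s-per-point calibration (27 s) followed
by a target grid — the full layout has 180 targets at the centers of rows
2–11 × columns 2–19 of a 12 × 20 display partition — under smooth pose
drift for the accuracy test (the default harness runs a reduced 5-subject
× 60-target version; `full_scale=True` restores 13 × 180); and a
provocation script with a large scripted pose jump mid-session on top of
continuous drift.  The eight default pose offsets span roughly ±14 px of
corner displacement.

**What the generator does not emulate.**  Photorealistic eye appearance,
eyelashes, corneal glints and the red-eye effect; saccade dynamics between
targets (gaze lands instantaneously); pupil-diameter changes; vergence;
latency.  Passing tests therefore demonstrate the correctness and the
qualitative robustness mechanisms of the pipeline under controlled
conditions — not the numeric accuracy any particular human cohort would
achieve.

## Vision front end

Rendered frames are 640 × 480 grayscale: dark pupil ellipse (anti-aliased
analytically, so its intensity centroid equals the drawn center), iris
disc, concentric-ripple corner landmarks placed at sub-pixel positions,
optional bright specular distractors, eyelid fill on blinks, additive
Gaussian sensor noise.

Pupil segmentation: adaptive threshold at the histogram valley below the
darkest mode (fallback: 5th-percentile quantile), binary opening/closing,
connected-component filtering by area (150–30000 px²) and axis ratio
(< 3), sub-pixel contour of the chosen blob, least-squares ellipse fit
with an RMS residual bound (2 px).  Blinks and occlusions yield
`valid=False`, never an exception.

Corner tracking: normalized cross-correlation of a 32 × 32 template
within a ±20 px search window, quadratic sub-pixel peak refinement,
slow template EMA (α = 0.02) applied only on confident matches, and a
lost flag (confidence < 0.5) that holds the last position through
occlusions.  The backend is pluggable behind a two-method contract
(`start`, `update`); any tracker that follows a translating landmark
within 2 px can be substituted.  The eye-region box spans the two
operator marks inflated by 30% at a fixed 4:3 aspect and translates
rigidly with the tracked corner.

## Interaction and calibration emission

Landing zones are circles in 2D screen space (the deployed system casts a
3D ray into the scene; scene geometry is out of scope here, and a 2D hit
test is the equivalent contract).  Dwell counters reset on zone exit or
after > 200 ms of missing gaze; partial dwell is not retained.  One
trigger per dwell episode; re-arming requires hover exit.  When several
zones contain the gaze point the nearest center wins.  Defaults — dwell
threshold 1.5 s, landing radius 12% shrinking to 6.2% of screen width by
0.4 percentage points per accumulated sample, re-expansion ×1.6 while the
recent prediction error exceeds 8% — are engineering choices; a deployed
system reads them from a parameter file, and only the configurability is
part of the contract.

## Table motion

Dense optical flow (iterative Lucas–Kanade, radius 15, from
scikit-image; a TV-L1 backend is selectable) between consecutive
room-camera frames, averaged over a binary bed mask, gives a 2D
direction-and-speed signal in px/frame; an exponential moving average
(α = 0.3) smooths the streaming output.  The camera-to-table scale is
deliberately left in pixels — no px→cm factor is assumed.

## Evaluation protocol

Events are processed stepwise after an initial calibration set of size
`n_initial`: at event `t` the *regression* estimate uses rows 1..t, the
*prediction* estimate rows 1..t−1, and the *fixed* estimate the initial
set only; estimates whose row count is below the coefficient count are
flagged undefined (NaN) rather than extrapolated.  Percentiles use linear
interpolation between order statistics.  Head displacement per event is
the distance between consecutive (or, for the provocation analysis,
first-to-current) fixation-median corner positions, averaged over the two
eyes, reported in camera pixels; a mm-per-pixel factor, if known, can be
applied by the caller but none is assumed.

Problem sizes in the default harnesses (10 seeded sessions for model
selection, 5 × 60 for the group test, 3 provocation seeds, 300 static
frames for tracker stability, 20 rendered positions for pupil accuracy)
were chosen as the smallest runs that make the qualitative orderings
stable across seeds.

## Known limitations

* The forward map is a phenomenological emulation; its pose-coupling
  constants were designed to exhibit the documented generalization
  behaviour of the model families, not fit to any recording.
* The correlation tracker holds position during occlusion rather than
  re-detecting; a long occlusion combined with fast motion can lose the
  landmark until it re-enters the search window.
* Pupil segmentation assumes the pupil is the darkest coherent blob in
  the eye region; heavy shadowing could defeat the histogram-valley
  threshold (the quantile fallback then applies).
* JSON/CSV session logs store full float precision but no compression;
  long sessions produce large text files.
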