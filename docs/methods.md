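# Methods

This note documents the models, conventions and numerical choices
behind `coartkin`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Task geometry

Four circular targets (diameter 5.4 mm) visited in the closed order
A→B→C→D→A; coordinates in cm, x rightward, y away from the body.  Since
published descriptions of this task do not print target coordinates,
layouts are configuration and every analysis accepts any four-target
geometry.  The shipped default is A=(0,0), B=(6,4), C=(12,0),
D=(7,−3.5).  Two properties of this default are deliberate:

* **Moderate corner angles (~65–70°) at B and D.**  With right-angle
  corners, the vector sum of two overlapping strokes keeps a deep dip
  in tangential speed for any overlap up to 55% (the dip is still ~26%
  of the peak at 55%), so the simulated peak count would never drop
  from 4.  Shallower corners let the blends genuinely merge inside the
  sweep, which is the regime trained subjects reach.
* **No mirror symmetry about the A–C axis.**  In an exactly symmetric
  layout the (1,2) and (3,4) blends are time-reversals of each other
  and both dips vanish at the identical overlap — a degenerate tie that
  would make the peak count jump 4→2.  The mild asymmetry decouples the
  merges (4→3 at ≈48% overlap on the default layout, the 3→2 merge
  falling beyond the sweep).

Transfer transforms: `mirror_layout` reflects x about the midline
between the extreme target x-coordinates (whether the original
experiment mirrored about the screen or the layout midline is not
documented; the layout midline is used and the function is the single
place to change it).  `scale_layout` shrinks inter-target distances
about the centroid while keeping the disc diameter — the "scaled"
transfer uses factor 0.7.

## Preprocessing

* **Smoothing**: least-squares cubic B-spline regression with a knot
  every 6 samples (fixed knot grid, not a tuned penalty).  Velocities
  come analytically from the spline derivative, never from finite
  differences.
* **Boundary treatment**: the samples are extended by symmetric
  reflection (two knot spans on each side) before fitting.  An
  unconstrained least-squares spline lets its derivative blow up in the
  outermost knot intervals; since trials begin and end at rest (the
  task requires a 500 ms dwell on A), even reflection is the physically
  consistent choice and keeps the terminal dwell readable as "stopped".
  The cost is ringing at the edges of records that are *not* at rest at
  their boundaries; the segmentation window never includes those.
* **Segmentation**: onset = last time, before the first velocity peak
  exceeding 35% of the peak speed, that the speed is below 5% of the
  peak; offset = last time above 5%.  Both thresholds are relative, so
  segmentation is invariant to speed rescaling.  A peak must have
  prominence ≥ 5% of the peak speed to count, which keeps residual
  noise ripples from qualifying.
* **Exclusion**: trials whose largest inter-sample gap exceeds 3
  nominal sample periods are dropped as discontinuous recordings.

## The coarticulation score

Peaks are the (up to) 4 largest qualifying local maxima of the
windowed speed profile; trough k is the minimum between consecutive
effective peaks.  Trough ordinals are anchored to the targets: when
fewer than 4 peaks survive, real troughs are assigned to B/C/D by the
time of the path's closest approach to each target (falling back, when
no trajectory is available, to "the deepest trough sits at the forced
reversal C").

**Substitution.**  When a peak/trough pair is missing, the score needs
stand-in heights.  Two regimes, continuous at the handover:

1. while the blended region still contains a *residual dip* — a local
   maximum below the 5% qualification threshold but above a small
   numeric floor (10⁻⁴ of the peak speed) — its real minimum and
   maximum are used;
2. once the region is truly merged, the shoulder inflection point
   (local minimum of |dv/dt| away from the surviving extrema, falling
   back to the sign change of the second derivative) supplies both
   heights.

A hard handover at the 5% threshold would make the score jump by ≈1
point at the merge; the two-regime rule keeps the predicted score
strictly monotone through it.  Substituted heights enter the numerator
(as the missing trough) and the denominator (as the missing peak).

Denominator convention: the mean of *all* effective peak heights (real
plus substituted), not only the peaks flanking troughs 1 and 3.  More
than 4 local maxima: keep the 4 largest, ties to the earlier one.

## Path offset and spatial error

Path offset is the mean, over window samples, of the distance to the
*nearest* of the four inter-target lines (nearest-segment rather than
per-segment assignment by time — robust to corner-cutting where samples
near B belong to neither segment cleanly).  Spatial error sums, over
the four targets, the distance from the disc edge to the path's closest
approach (zero when the disc is entered), evaluated on a 4× oversampled
spline grid so the approach is not limited by the 160 Hz sampling;
target A is counted once although it is both start and end.

## The minimum-jerk superposition model

A simulated trial is the vector sum of four straight minimum-jerk
strokes (quintic profile 10τ³−15τ⁴+6τ⁵; peak speed 15/8·D/T) chained
A→B′→C→D′→A.  Overlap o ∈ [0, 0.55] advances the onset of stroke 2 (4)
by o·T before the end of stroke 1 (3); the (2,3) pair stays strictly
sequential because the task forces a near stop at C.  All strokes share
one duration (default T = 0.5 s, giving a 2 s sequence at zero
overlap).

**Via-points.**  Overlap pulls the blended path inside the corners, so
B′ and D′ are found by optimization such that the superposed path still
passes within 10⁻³ cm of B and D.  The through-the-target condition
alone leaves a one-parameter family of solutions; the solver therefore
searches along the ray from the physical target in the direction of the
corner's outward angle bisector — a bounded, derivative-free scalar
minimization of the squared closest approach (coarse scan + Brent
refinement, closest approach refined analytically below the sampling
step).  This is deterministic, unique, smooth in o, and fast enough
that the 551-point sweep takes seconds; an unrestricted 2-D
Nelder-Mead search with seeded jittered restarts is kept as a fallback
and raises with diagnostics if the tolerance cannot be met.  The two
via-points decouple because B must be crossed while strokes 1–2 are
active and D while strokes 3–4 are.

**Grid measurement.**  The sweep evaluates 551 equally spaced overlaps
from 0 to 55%.  The analytic profile is measured at dt/8 rather than
the 160 Hz recording step: at 1/160 s the extremum heights are
quantized by the sample grid, which puts visible stair-steps on the
otherwise smooth score and curvature curves.  Exported trajectories
remain at 160 Hz.  `estimate_overlap` inverts the monotone score curve
by interpolation, clamping (with a warning) outside the simulated
range.

## The synthetic cohort

The generator emits the full two-day protocol — 60-trial pre-test, six
training blocks (30 physical trials each; 60 for the double-practice
control), 60-trial post-test, and day-2 trained/mirror/scaled tests —
for four groups of 15 subjects.  Programmed dynamics:

| group | overlap | duration | post-test miss rate |
|-------|---------|----------|---------------------|
| OG    | 0 → plateau 0.194 within 5 trials, +0.0029/block | 2.00 s → 1.38 s | 0.65 |
| SOG   | 0 → plateau 0.213, +0.0035/block | 2.00 s throughout | 0.65 |
| RMCG / DPTCG | 0 throughout | 2.00 s throughout | 0.08 |

The overlap plateaus and drifts were calibrated by inverting the
measured pipeline response so that the *measured* post-test score gains
are ≈21 (OG) and ≈25 (SOG) and the training-block score slopes ≈0.73
and ≈0.97 per block; the dissociation between SOG's coarticulation gain
and its unchanged speed is deliberate.  The scaled transfer runs at
0.73× the session duration for every group (smaller distances, same
target size — a Fitts-type speedup).  Noise model: multiplicative
between-subject duration trait (SD 0.15) and trial jitter (SD 0.04),
additive overlap trait (SD 0.03 observation groups) and trial jitter
(SD 0.015), and 0.1 mm Gaussian sensor noise per sample.  The sensor
noise is set so that the segmentation thresholds still read the 500 ms
terminal dwell as rest; at several times this level the smoothed noise
floor exceeds 5% of the peak speed of a slow trial and the offset rule
itself breaks down.

Target misses are injected per trial (Bernoulli per session, excess
clearance exponential) by a Gaussian displacement bump (σ = 0.12 s,
wide relative to the spline cutoff) perpendicular to the local path
direction, pushed outward, with the amplitude calibrated iteratively
against the achieved closest approach — corner geometry otherwise
attenuates the injected miss by the sine of the half-apex angle.  The
observation groups' post-test miss probability (0.65) makes the
transient accuracy cost visible at the subject-median level while
keeping median errors small (hundredths of a mm); it vanishes at day 2.
Recording gaps (~200 ms, 3.3% of trials) exercise the exclusion filter.
Observation/video trials are not emitted — only physical trials were
ever analyzed.

What passing the cohort tests shows: the pipeline recovers programmed
group dynamics, overlap levels (subject means within 0.03), and the
qualitative outcome pattern at n = 15.  What it does not show: the
generator produces superposition-exact strokes with stationary noise;
real subjects produce variable stroke shapes, drifts, pen lifts and
pressure artefacts that are not modeled, so real-data performance of
the thresholds (prominence, continuity gap) is not established by these
tests.

## Statistics

Summaries per (subject, session, block [, 5-trial bin]): median for
duration and spatial error, mean for score, path offset and peak
count.  Normalization to each subject's own pre-test: percent
improvement for duration and path offset, plain difference for the
score (baselines sit near zero).  Mixed-design ANOVAs (pingouin) use
group as the between factor; Greenhouse-Geisser correction is applied
whenever the within factor has ≥3 levels (with 2 levels sphericity is
vacuous).  Subjects missing a cell are dropped listwise.  Training
slopes are per-subject least squares over blocks 1–6, tested one-tailed
(>0) for coarticulation and two-tailed for duration.  Spatial error is
zero-inflated, so its battery is non-parametric (Friedman, Wilcoxon,
Kruskal-Wallis, Mann-Whitney); degenerate inputs (a dv constant across
sessions for every subject) report χ²=0, p=1 rather than NaN.  Post-hoc
families are Bonferroni-corrected; the family for per-group session
gains is the four groups.  `null_interaction_rate` simulates
subject-intercept-only null datasets and checks that the interaction
test rejects at the nominal rate.

## Known limitations

* The overlap→score mapping is geometry-dependent; `estimate_overlap`
  must be given a curve simulated on the same layout as the data.
* The simulation superposes independent strokes; it does not solve the
  global via-point minimum-jerk problem, and its 3-peak profiles arise
  from blending, not from the single-peaked A→C strategy an expert
  might adopt.
* Trough-ordinal assignment assumes the trajectory visits the targets
  in task order; grossly wrong sequences are not detected.
* The exclusion filter only catches temporal discontinuities, not
  spatially aberrant but continuously recorded trials.
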