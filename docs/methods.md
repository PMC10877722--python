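# Methods

This note documents the models implemented in `cavitrack`, the defaults
chosen where the underlying experiment leaves a design decision open, and
what the synthetic benchmark does and does not establish.

## Synthetic trial generator

**Count model.** A trial's grand-total bubble count at temperature `T` is
drawn from a negative binomial with mean `μ(T)` and shape `θ` (variance
`μ + μ²/θ`).  The mean curve interpolates `ln μ` linearly in temperature
through the anchor table (20 °C → 0.12, 30 °C → 0.71, 40 °C → 6.4,
50 °C → 28, 60 °C → 97.5 bubbles), i.e. counts grow geometrically with
temperature; no extrapolation outside 20–60 °C is permitted.  The shape
default `θ = 5` is a stand-in: only mean counts at the anchor temperatures
are known, not trial-to-trial variances.  A negative binomial was chosen
over a Poisson because shock-to-shock variability (diaphragm rupture,
nucleation sites) plausibly overdisperses the counts, and because it
behaves sensibly at the near-zero means of the 20–30 °C trials.  As
`θ → ∞` the model recovers Poisson(μ).

**Rendering.** Each trial is a stack of `frames_per_trial = 50` 8-bit
grayscale frames of `128 × 256` px at a nominal 100,000 fps (so one series
spans 0.5 ms).  Bubbles are soft-edged discs `bubble_contrast = 60`
intensity units darker than the `background_level = 150`, with radii
uniform in 3–8 px and lifetimes uniform in 5–25 frames placed uniformly in
the window; bubbles are stationary (an optional `radius_ramp` flag grows
and collapses the disc over its lifetime).  `n_artifacts = 3` static
bright blobs (radius 5–10 px, +60 intensity) model light reflections from
the chamber; i.i.d. Gaussian sensor noise (`noise_sd = 3`) is added per
pixel per frame and intensities are clipped to [0, 255].  Bubble polarity
(dark) versus artifact polarity (bright) is a modelling choice that makes
artifact rejection testable; the detector itself is polarity-agnostic.

**Placement.** Two bubbles whose lifetimes overlap are rejected-and-
resampled until their discs are disjoint with a ≥ 2 px gap (and separated
by more than `rmin + rmax`), so every concurrent bubble has an
unambiguous boundary and the ground-truth count is well defined for the
detector.  A bubble born within 4 frames of another's collapse must
additionally lie outside the tracker's default gating radius, so a
newcomer can never be linked onto a dead bubble's track.  Temporally
distant bubbles may reuse space — a necessity, since ~100 concurrent
non-overlapping 3–8 px discs do not fit in a 128 × 256 frame.  For the
same geometric reason, rendered counts are truncated at
`max_rendered_bubbles = 120` (the recorded ground truth is then the
rendered count); the truncation never changes a cavitation level, because
every scheme's top bin starts at or below `n = 100`.  Tabular-only
datasets (no rendering) are not truncated.

**What the surrogate does not capture.** Real recordings have non-uniform
illumination, bubble growth/collapse dynamics, motion, out-of-focus blur
and occasional overlapping bubbles.  Passing the synthetic benchmark
therefore shows that the pipeline is internally consistent and meets its
stated tolerances under the modelled imaging conditions, not that it would
achieve the same accuracy on laboratory footage.

## Detection

Frames are cropped to a rectangular region of interest (the chamber
interior), static bright structures are masked (a pixel is an artifact
when its temporal median exceeds the `artifact_quantile = 0.98` quantile of
the whole-series intensity distribution — transient bubbles barely move a
temporal median, stationary reflections dominate it), masked pixels are
replaced by the frame median, and the frame is smoothed with a Gaussian
(`smoothing_sigma = 1` px).

Bubbles are then found by a circular Hough transform over integer radii in
`radius_range = (3, 8)` on the Canny edge map, keeping accumulator peaks
whose normalised vote fraction exceeds `sensitivity = 0.5`.  Two
suppression rules clean the candidate set:

* **Non-maximum suppression** removes any candidate within `rmin` of a
  stronger detection, and any candidate whose circle substantially
  overlaps a stronger one (centre distance < `r₁ + r₂ − 2`).  Physical
  bubbles are disjoint, so overlapping circles are duplicates of one
  bubble.
* **Photometric validation** rejects candidates whose core (inner half of
  the circle) deviates from the frame's median intensity by less than
  `min_contrast = 12`.  This removes the Hough accumulator's caustic
  satellite peaks — rings of spurious votes at distance
  `r_true ± r_accumulator` around every genuine circle — which otherwise
  pass a pure accumulator threshold while enclosing plain background.

These detector defaults were calibrated against the synthetic renderer
(the only ground truth available); with them, the worst per-trial count
error over full 45-trial datasets is 1–3 bubbles across seeds, within the
±5-bubble validation bound adopted for the pipeline.

## Tracking and grand totals

Detections are linked frame-to-frame by greedy nearest-neighbour matching:
candidate (track, detection) pairs with centre distance ≤
`gate_radius = 16` px (twice the maximum bubble radius) are linked in
ascending distance order, each side used at most once; unmatched
detections open new tracks, numbered in order of first appearance (ties
within a frame broken by descending detection score, then scan order).  A
track missing for more than `max_gap = 1` frame is closed; there is no
re-identification, so a bubble reappearing later becomes a new identity.
The trial's grand total is the number of distinct tracks — each bubble
counted once regardless of how many frames it appears in.

## Cavitation levels

Four schemes bin the grand total `n` into an ordinal level with left-open,
right-closed intervals (a count equal to a bound belongs to the lower
level; `n` is always an integer):

| level | scheme 1 | scheme 2 | scheme 3 | scheme 4 |
|------:|---------:|---------:|---------:|---------:|
| upper bounds | 5, 20 | 1, 5, 10, 25, 75 | 1, 5, 10, 25, 50, 100 | 1, 5, 10, 15, 20, 30, 40, 50 |
| levels | 3 | 6 | 7 | 9 |

Schemes 1–2 are data-driven (every level corresponds to observed counts);
schemes 3–4 are distribution-driven (regular widths).  The level
definitions were drawn up for trials at a 207 kPa reference overpressure;
that constant is metadata only.

## Classifiers

Both classifiers use the single scalar feature temperature (°C) and are
implemented from scratch; scikit-learn appears only in tests as an
independent oracle.

**kNN.** Lazy learner, Euclidean distance `d(x, y) = |x − y|`, majority
vote among the `k` nearest training points.  Tie rules are explicit
because temperatures sit on a 5 °C grid: distance ties resolve by training
order; vote ties go to the tied label whose nearest member is closest to
the query, then to the smaller label.  `suggested_k(n) = round(√n)` is
advisory; the evaluation grid sweeps `k = 1, 2, 3, 5, 7` (predominantly
odd, since even `k` invites vote ties).

**Soft-margin linear SVM (1-D).** Minimises
`F(w, b) = ½w² + C Σ max(0, 1 − yᵢ(w xᵢ + b))`.  Because the feature is
one-dimensional, the bias profile `min_b F(w, ·)` is an exact
piecewise-linear problem solved combinatorially (the zero-subgradient
segment lies between the `n₊`-th and `(n₊+1)`-th sorted hinge
breakpoints), and the outer profile is a convex scalar function minimised
by bounded Brent search with a quadratic polish.  The solver is
deterministic and label-flip-symmetric by construction; its objective
matches a nested grid-search oracle to < 10⁻⁶.  Default `C = 1`.

**ECOC.** One-vs-one coding over the observed classes (`L(L−1)/2`
learners, each trained only on its two classes).  Decoding is
loss-weighted hinge decoding — predicted class `c` minimises
`Σⱼ |m_cj| max(0, 1 − m_cj sⱼ(x)) / Σⱼ |m_cj|` — with ties to the smaller
level; Hamming decoding is available behind a flag for sensitivity
checks.  One-vs-one with hinge decoding is the common default for this
model family; the reference experiment does not state its coding design.

## Evaluation

* **Cross-validation**: "adapted holdout" — 10 independent uniformly random,
  unstratified 70/30 splits (`|test| = floor(0.3 n)`, which gives the
  expected 13 test points for 45 trials; floor, not round-half-up); the
  mean of the 10 test accuracies is the CV accuracy.  A test split
  containing a class unseen in training is legitimate and merely counted.
* **Bootstrap**: 10 samples × 10 trained models; the grand mean and the
  standard deviation `s` of the 10 sample means give the interval
  `mean ± 1.96 s`.  A standard-error variant (`s/√10`) and the `z`
  multiplier are exposed as options, since the exact CI convention is a
  genuinely open choice.
* **Accuracy** is exact level match; no ordinal credit for near misses.
* **RNG policy**: one master seed; per-repeat child generators are spawned
  deterministically, so any individual split is reproducible in isolation.

## Observed behaviour on the surrogate

On simulated 45-trial datasets the coarse scheme 1 is well predicted from
temperature (mean CV accuracy typically 0.80–0.95 depending on the seed,
with best-k kNN around 0.88 on average), while the 7- and 9-level schemes
fall to 0.45–0.65.  The ECOC SVM and kNN perform comparably on the
surrogate (their mean difference against a reference one-vs-one linear SVC
is zero); a systematic ECOC advantage on the finer schemes, as seen in the
original experiment's trials, is **not** reproduced by the
negative-binomial surrogate — with a single feature, both families
converge to similar monotone threshold rules, and the advantage evidently
depends on the real trials' label-noise structure that the `θ = 5`
stand-in does not capture.

## Numerical and degenerate-input conventions

Pixel coordinates are 0-based with x = column, y = row; ROI rectangles are
half-open.  Counts are validated as non-negative integers.  Image output
is 8-bit grayscale multi-page TIFF (PNG sequences accepted on input).
Trials whose image stack fails to read are logged and skipped, not fatal.
Single-class training sets raise for the SVM/ECOC; `cross_validate`
requires a valid split (at least one train and one test point).  Problem
sizes in the test suite are the study design itself (45 trials, 2,250
frames) for the end-to-end checks and smaller frames (96 × 128, 15–20
frames) for unit-level image tests.

## Known limitations

* The dispersion `θ`, bubble photometry, lifetimes and artifact model are
  plausible stand-ins, not measured properties.
* No re-identification across track gaps larger than `max_gap`; a bubble
  that vanishes and reappears is counted twice (consistent with
  first-appearance numbering, but a known bias source).
* The detector's radius estimate is quantised to the integer Hough grid
  (±1 px); no sub-pixel refinement.
* Classification uses temperature as the sole feature by design; the
  evaluation machinery, not the feature engineering, is the point.
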