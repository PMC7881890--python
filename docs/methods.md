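# Methods

## Scope

`gazedecode` implements a decoding pipeline for screen-viewing eye-tracking
trials: segmentation of 60 Hz gaze traces into fixations and saccades,
extraction of five per-trial feature families, and three classification
experiments (viewer identity, group membership, per-image group decoding)
with leakage-free folding, feature selection and chance-level statistics.
A synthetic cohort generator stands in for recorded data so every stage is
testable end to end; recorded datasets can be supplied through the trial
CSV schema (an adapter hook maps foreign layouts onto it).

## Coordinate and screen conventions

Gaze positions are normalized screen coordinates, origin top-left, y
increasing downward: x in [0, 1], y in [0, 0.74] (a 4:3-ish viewing
rectangle of width 1.0 and height 0.74).  Timestamps are milliseconds and
strictly increasing within a trial.  Velocity in normalized units per
second converts to visual angle as `2·arctan(v·w/(2d))` with screen width
w = 24.98 cm and viewing distance d = 50 cm by default (one screen width
per second ≈ 28.05 deg/s).  Grid features index cells row-major from the
top-left; right/bottom edges belong to the last cell.

## Event detection (dispersion threshold)

A fixation is a maximal run of consecutive valid samples whose spatial
dispersion stays at or below a threshold; everything between fixations —
classical saccades, glissades and smooth pursuit alike — is pooled into one
broad "saccade" category.  Detection is greedy left-to-right window growth
(I-DT): seed a window of `min_samples`, grow while dispersion stays within
the threshold (ties inclusive), emit, restart after the window; slide by
one sample when the seed window is already too dispersed.

Choices that the classical algorithm leaves open:

* **Dispersion metric.**  Default is the true diameter (max pairwise
  Euclidean distance), reading "diameter" literally; the classical
  x-range + y-range surrogate is available via `metric="range"`.
* **Minimum extent.**  `min_samples = 3` (~50 ms at 60 Hz); fixations
  shorter than that are not physiologically meaningful and the shortest
  duration representable with 3 samples matches the smallest duration bin
  seen in practice.
* **Maximum duration.**  Off by default.  A hard per-fixation time cap is
  supported (`max_duration`) but disabled because real duration
  distributions extend well past 300 ms; enabling it splits long fixations
  at the cap.
* **Saccade bounds.**  Saccade segments are bounded by the adjacent
  fixation endpoint samples, so total fixation time + total saccade time
  equals the valid-sample span exactly (conservation is a tested
  invariant).  Saccade "length" is path length (sum of step lengths),
  which is well defined for the broad category including pursuit; endpoint
  amplitude can be derived from the indices if needed.
* **Invalid samples** are skipped as if absent; a velocity step spanning an
  invalid sample is discarded rather than interpolated.

## Features

Per trial, five named blocks concatenated in a fixed order (defaults in
parentheses):

| block            | length | content                                         |
|------------------|--------|-------------------------------------------------|
| fixation_summary | 4      | mean fixation duration (s), fixation count, mean saccade length (normalized), saccade count |
| fixdur_hist      | 10     | fixation-duration histogram                     |
| sacc_hist        | 10     | saccade path-length histogram                   |
| vel_hist         | 14     | frame-step velocity histogram; bin 1 reserved for exactly-zero steps |
| fixmap           | G²=100 | cumulative fixation duration (s) per cell of a G×G grid |

Total length 138 at G = 10 (438 at G = 20).

Histogram boundaries are **equal-frequency (quantile)** edges: the sorted
training values are cut into equal-count groups and each group's last
member becomes a bin's upper edge (final edge +inf; bins half-open
`(lo, hi]`).  The velocity histogram first strips exactly-zero steps
(|v| ≤ 1e-9 — raw positions carry ~1e-4 resolution, so genuine frame
repeats are exact zeros) into the reserved first bin and splits the
positive remainder into 13 groups.  Edges are refit on **every training
fold**, pooling values across training trials, so validation trials can
never influence feature extraction; this is asserted by tests that
recompute edges with and without a validation trial.

Equal-count splitting is exact (occupancies differ by ≤ 1) whenever the
training values are continuous.  Fixation durations at 60 Hz are
frame-quantized (multiples of 1/60 s) and tie heavily, so the
fixation-duration histogram satisfies a tie-aware bound instead: occupancy
spread is limited by the largest tie-group.  This is a property of
frame-quantized data, not of the estimator.

Histogram entries are relative frequencies (counts / total) by default so
trials with differing valid-sample counts are comparable; raw counts are
available via `normalize=False`.  Summary units: durations in seconds,
lengths in normalized units, counts as raw integers — standardization is
the decoder's job, not the feature module's.

## Decoding experiments

* **Identity (leave-one-image-out).**  One fold per image; all trials of
  the held-out image are validation, so identity prediction cannot exploit
  image-specific content and rests on endogenous (viewer-intrinsic)
  features only.  Chance = 1/n_viewers (1.41% for a 71-viewer cohort).
  Top-5 accuracy counts a trial correct when the true viewer is among the
  five highest decision scores.
* **Group (repeated 70/30 splits).**  14 independent trial-level splits;
  chance fixed at 50% irrespective of group imbalance.  Trial-level
  splitting lets the same viewer appear in both sets; a participant-level
  split would be stricter for group inference and can be built from the
  same fold machinery (validity caveat, not default).
* **Per-image group (leave-one-participant-out).**  Within one image, one
  fold per participant; features are the 20×20 fixation map only;
  classifier is a linear SVM.  Finer grids separate spatial preference
  better than 10×10 at these sample sizes.

Within every fold, in order: bin edges fit on training trials, features
assembled, standardized with training-fold mean/variance (heterogeneous
blocks — counts next to frequencies — cripple margin classifiers
otherwise), feature selection, hyper-parameter tuning, fit, predict.

**Feature selection** fits extremely-randomized-trees importances on the
training fold and keeps features with importance > t × mean importance,
t ∈ {1.7, 1.8, 1.9, 2.0, 2.1}, selector max_depth ∈ {10, 30, 50, 70, 90},
min_samples_split ∈ {2, 5, 10, 15, 20}.  The triple is chosen by 3-fold
stratified inner CV, scoring each candidate mask with the experiment's
classifier family at default hyper-parameters; the classifier's own grid
(C ∈ {0.25, 0.5, 1, 2, 4} for both SVMs; criterion/depth/leaf/split grids
for the decision tree) is then tuned by a second 3-fold inner CV on the
selected features.  Selecting and tuning jointly would multiply the grids
~40-fold for little benefit; the two-stage protocol keeps both searches
leakage-free.  Selection never returns an empty set (all-zero importances
fall back to the single best feature, with a warning).  Ties in inner-CV
scores break toward the earlier grid point; all estimators are seeded.

**Chance-level test.**  Per-fold accuracies are compared to the chance
constant with a two-sided one-sample t test (equivalent to a single-group
ANOVA against a constant).  Zero-variance fold accuracies trigger an exact
fallback: all-equal-to-chance gives (0, 1); a degenerate common value away
from chance gives a signed infinite statistic with p = 0, plus a warning.
The test's type-I error is verified by simulation (2000 null fold sets of
n = 14 from Normal(0.5, 0.05); rejection rate ≈ 0.05 at α = 0.05).

A note on permutation nulls: a single global label permutation evaluated
under cross-validation is known to be slightly pessimistic (the without-
replacement label constraint induces anti-learning), so the null check
averages over three independent permutations before comparing to the
binomial chance interval.

## Synthetic cohorts

The generator emulates the structure of a two-group screen-viewing study —
n_A + n_B viewers × k images × 10 s at 60 Hz — with two planted effects:

* **Individual kinematics.**  Each viewer carries gamma-distributed
  fixation epoch durations (shape, scale), a lognormal per-frame saccade
  step length (log-mean, log-sd), Gaussian within-fixation tremor
  (`tremor_sd`), and a `zero_velocity_rate`: the probability that a
  within-fixation frame repeats the previous position exactly, populating
  the reserved zero-velocity bin.  Saccades glide in a straight line
  toward the next target with a fresh lognormal step per frame — constant-
  speed glides would duplicate step lengths and degenerate the quantile
  bins.  The lognormal families make a viewer's velocity histogram their
  kinematic signature, which is what identity decoding must recover.
* **Group ROI preference.**  Each image carries rectangular regions of
  interest with one sampling weight per group; group membership only
  enters through target choice.  Disjoint weight supports plant a clean
  group signal in fixation maps; identical weights give a signal-free
  control.

Cohort hyper-distributions (uniform ranges): gamma shape 2–5, mean
fixation duration 0.15–0.35 s, saccade log-mean −3.0 to −1.6, log-sd
0.3–0.6, tremor sd 0.001–0.004, zero-velocity rate 0.05–0.4 — typical
scene-viewing kinematics with tremor well under the 0.02 dispersion
threshold.  `make_separated_cohort` additionally spaces saccade log-means
on an even grid (default spacing 0.5) because random draws guarantee no
pairwise separation.  Per-trial seeds are hashed from (seed,
participant_id, image_id), so any subset of a design regenerates
identically.

What the generator does **not** model: main-sequence saccade dynamics
(velocity profiles within a saccade), blinks (an optional dropout
probability marks samples invalid but does not displace them), pupil or
head movement, image content.  Passing tests therefore show that the
pipeline recovers planted kinematic and spatial-preference signal under
clean conditions; they say nothing about effect sizes in recorded human
data, where individual signatures are weaker and noise structure richer.

## Problem sizes

The test suite and the acceptance script run reduced designs chosen to
exercise every code path with comfortable margins: 6 participants × 4
images (3 s trials) for I/O, binning and conservation checks; 12
kinematically separated viewers × 14 images (10 s) for identity decoding;
two 30-viewer groups on one image (10 s) for per-image group decoding; 200
random short traces for the segmentation oracle; 2000 replicates for test
calibration.  The analysis drivers additionally generate the full-size
71 × 14 design for event-level summaries.

## Known limitations

* Equal-frequency binning requires enough distinct positive training
  values; degenerate inputs raise a dedicated error rather than emitting
  collapsed bins.
* Leave-one-out accuracy on small single-image designs is high-variance;
  per-fold accuracies there are 0/1 and only pooled rates are meaningful.
* The decision-tree grid is large (≈ 12k combinations); with the default
  3-fold inner CV it is markedly slower than the SVM families and is
  intended for importance profiling rather than routine decoding.
* The fixation map uses the full screen rectangle as the "image area"; a
  sub-rectangle can be configured when stimulus placement is known.
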