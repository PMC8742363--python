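# Methods

`gaitmetrics` quantifies whole-body movement quality from consumer
depth-camera skeleton streams: 25 named joints (the Kinect V2 skeletal
model), x/y/z positions in meters at a nominal 30 Hz. This note records the
models, conventions and numerical choices behind the package, and what the
synthetic test bed does and does not establish about real recordings.

## Coordinate conventions and body geometry

Axes are fixed package-wide: **y** vertical (up-positive), **x** lateral
(positive toward the skeleton's anatomical left), **z** anterior. Consumer
tracking SDKs do not agree on world axes, so the convention is part of the
file-format contract (`timestamp,<JOINT>_x,<JOINT>_y,<JOINT>_z` columns; an
empty cell marks an untracked joint).

Every frame is translated so the pelvic joint (SpineBase) sits at the
origin before any measure is computed. This makes all downstream
quantities invariant to where the participant stood and to whole-body
drift; it is applied per frame, so it also removes the airborne
translation of jumps — deliberately, since the measures describe limb
configuration, not locomotion.

Efficiency measures are normalized by stature so they compare across
body sizes. Stature is estimated from the skeleton itself: the median,
over frames with a valid head and both ankles, of the head vertical
coordinate minus the mean ankle vertical coordinate. The median makes the
estimate robust to the brief ankle elevation during leg abduction (≈0.2 %
bias at a 0.6 m spread) and to tracking noise. A measured stature supplied
via configuration overrides the estimate.

Joints carry validity flags; a measure refuses a segment in which any
required joint is tracked in less than 95 % of frames. Isolated invalid
samples below that threshold are linearly interpolated; nothing is imputed
beyond that.

## Filtering and derivatives

Two zero-phase (forward–backward) Butterworth low-pass stages:

* **Acquisition, 12 Hz** (order 2 by default, configurable): removes
  tracking jitter from the raw stream. Zero-phase application was chosen —
  and is exposed as a flag — because event timing must not be biased.
* **Cleaning, 3 Hz, 2nd order**: applied to each channel of a movement
  segment before any metric. Voluntary whole-body movement carries
  negligible power above a few hertz; faster content is attributable to
  the pose-extraction process.

Forward–backward filtering squares the magnitude response, so the
effective gain is `1/(1 + (f/fc)^(2·order))`; tests verify the measured
gain against this closed form at 1 Hz and 10 Hz and verify the zero-lag
property by cross-correlation. Edges use odd-reflection padding of length
3·(order+1), which keeps transients acceptable on ~60-frame segments.
Non-uniform timestamps are linearly resampled to the nominal rate first;
recursive filters assume uniform sampling.

Velocities are central differences (one-sided at the ends), exact for
linear signals. Raw channels are never differentiated; smoothing always
precedes differentiation.

## The eleven jumping-jack measures

Computed per jumping-jack segment on pelvis-centered, 3 Hz-smoothed
channels. Four abduction angles θ1..θ4 drive the synchrony family: left
and right shoulder abduction (angle between the shoulder→same-side-hip
axis and shoulder→elbow) and left and right hip abduction (pelvis
down-axis vs hip→knee).

**Efficiency** — K1: time-maximum of wrist elevation above the same-side
shoulder (larger of the two sides), / height; negative when the arms never
pass the shoulders. K2: time-maximum horizontal ankle separation, /
height.

**Synchrony** — H1: sample variance (1/3 · Σ(fᵢ−μ)², Hz²) of the four
dominant frequencies, each the argmax of the mean-removed DFT magnitude
spectrum (resolution rate/N). H2 (MARP): time-mean absolute continuous
relative phase between a configurable pair, default left vs right
shoulder angle; phase angles are `atan2` of velocity and position after
each is centered and amplitude-normalized to [−1, 1] — the standard
continuous-relative-phase construction — and differences are wrapped to
(−π, π], so H2 ∈ [0, π]. H3 (CRP-SD): standard deviation of the unwrapped
relative-phase series (unwrapping removes spurious ±2π jumps when the two
phases wrap at different instants). H4/H5: mean absolute left–right
difference of stop instants of the hand vertical (H4) and ankle lateral
(H5) channels.

A *stop* is a near-zero local minimum of speed: a velocity sign change
(time refined by linear interpolation of the zero crossing, giving
sub-frame resolution) or a dwell — a run of samples below 5 % of peak
speed contributing its minimum-speed instant. Events closer than two
frame periods merge. Left and right stop lists are paired sequentially
and truncated to the shorter side; pairing admits a small free leading
offset (at most two events on one side), chosen to minimize the mean
absolute difference. The offset is necessary because clip edges produce
asymmetric detections — one side may start exactly at rest (a dwell at
t = 0) while the lagged side starts mid-motion — and a rigid
first-to-first pairing would then shift every pair by half a cycle.
Fewer than two stop events on a side yields NaN ("undefined"), never a
silent zero; session means average defined values only.

**Symmetry** — with c1, c2 the absolute lateral offsets of the right and
left hand from the pelvis midline: M1 = time-mean and M2 = time-SD of
|c1 − c2| (meters); M3/M4 = time-mean of ||V⁻ᴿ| − |V⁻ᴸ|| for the
horizontal and vertical hand velocities (m/s). Comparing *absolute*
velocities makes a perfectly mirrored movement score exactly zero.

All eleven measures are invariant to global translation and to sagittal
mirroring (left/right swap with x negated), and K1/K2 scale inversely with
the height normalizer; these invariances are property-tested.

## Synthetic motion generator

The generator stands in for real recordings and knows its own answers. A
2-segment forward-kinematic chain per limb (upper arm 0.186 h, forearm
0.146 h, thigh 0.245 h, shank 0.246 h — standard anthropometric fractions
of stature h) synthesizes all 25 joints; hands, feet and thumbs ride
rigidly on their parent segment. Two conventions tie ground truth to the
analysis exactly: the head joint is placed so the neutral head-to-ankle
vertical gap equals h (the height estimator recovers the profile height),
and shoulders sit directly above the hips so measured shoulder abduction
equals the injected drive angle.

Jumping jacks follow raised-cosine abduction cycles at `jj_frequency`
(default 0.5 Hz). Controllable imperfections: the right side is
amplitude-scaled by `rl_amplitude_ratio` and delayed by `rl_lag`; the leg
cycle can be de-phased from the arms (`armleg_phase`); each cycle's period
is jittered by `1 + U(−j, +j)`; additive Gaussian noise band-limited above
6 Hz emulates pose-extraction noise that the 3 Hz cleaning filter should
remove. A 0.04 m whole-body hop at twice the cycle rate emulates the
airborne phases; it cancels exactly under pelvis centering. The peak hip
abduction is solved (Brent's method) so the realized peak ankle separation
equals `max_ankle_spread`; with an asymmetric ratio the realized peak is
smaller, so the ground-truth object records the value measured on the
noise-free trajectories, and recovery tests compare against that.

The other nine scripted actions are explicit templates: directional jumps
translate the whole body ≥ 0.30 m with a hop; steps translate 0.30 m
without one; a walk is 3–4 strides of alternating leg swing about an
advancing pelvis; touch-nose brings the right hand to the head; idle is
quiet standing with centimeter sway. Sessions concatenate clips with
short held-pose transitions and carry exact segment ground truth. Default
profile: stature 1.58 m (near the study cohort's mean), 150° arm
abduction, 0.55 m spread.

What the generator does *not* emulate: joint-position dropout and
occlusion artifacts, soft-tissue and clothing noise below 6 Hz,
biomechanical dynamics (balance, ground reaction), fatigue drift, or the
idiosyncratic movement vocabularies of real participants. Passing
recovery tests therefore shows the measures are *correct transducers* of
the kinematic quantities they claim to measure — not that they are robust
to every artifact of consumer depth tracking.

## Segmentation

Streams are scanned with 60-frame windows advanced every 15 frames (0.5 s
at 30 Hz); window count follows `floor((N−60)/15)+1`. Features per frame:
all 75 pelvis-centered, height-normalized coordinates plus the pelvis
frame-to-frame displacement ×20 (per-frame centering alone would erase
whole-body translation, i.e. the difference between jump directions and
standing; the gain balances the two blocks' magnitudes).

The reference recognizer is deterministic nearest-template: per label, a
centroid trajectory (exemplars uniformly resampled to 60 rows and
averaged); windows are scored by *subsequence* DTW — free start/end along
the template axis — so a window covering part of a longer action matches
the corresponding stretch of its template. A penalty of 0.05 per
unmatched template fraction prevents near-static windows from trivially
matching the resting prefix of every action template. Ties break by label
order; identical inputs always give identical segments.

Window labels are eager (a window containing any stretch of an active
movement tends to adopt its label), so label-change boundaries are
attributed to the newest 15 frames of the first window of each run — the
streaming interpretation of an update — and then refined: 15-frame blocks
around the provisional boundary are scored against the two adjacent
templates and the boundary moves to the end of the last block still
better explained by the outgoing template. On synthetic sessions this
places boundaries within one hop (±15 frames) of ground truth, and
held-out-profile window accuracy exceeds 0.90. The recurrent-network
recognizer that could replace this module is described declaratively
(3 recurrent layers of 20 units over a 60 × F window, 10-way softmax,
20 % held-out split, 50-epoch early-stopping patience) and deliberately
not trained here.

Augmentation is two-step: sagittal mirroring doubles a clip set (the
anatomically valid reading of a left/right flip — x negated *and* joint
roles swapped), then each clip expands into exactly six time-warped
variants, default factors {0.85, 0.90, 0.95, 1.05, 1.10, 1.15}. A ±20 %
range at 5 % increments would give eight factors, but the pipeline's
bookkeeping (24,000 = 4,000 × 6) fixes six; the set is configurable and
the discrepancy documented. Warping resamples the timeline by linear
interpolation back onto the 30 Hz grid, so a 300-frame clip at factor 1.2
becomes 250 frames.

## Session statistics

Per-segment measures are averaged per (participant, session), NaN
excluded with per-measure counts; change scores are session-6 minus
session-1 means. Spearman's rho is the product-moment correlation of
average ranks; Wilcoxon drops zero differences and ranks absolute
differences with ties averaged. Both default to *exact* small-sample
p-values — full permutation enumeration for Spearman at n ≤ 10 (null
distribution cached per rank multiset; ~8 s once at n = 10, reused across
table cells) and full sign-assignment enumeration for Wilcoxon at n ≤ 12
(dynamic programming over doubled ranks) — because asymptotic
approximations are unreliable at cohort sizes near ten. Above those sizes
the t-approximation and the tie- and continuity-corrected normal
approximation apply. Two-sided tests by default. No multiple-testing
correction by default, matching per-cell reporting at p < .05; a
Benjamini–Hochberg option exists but is off.

The correlation table requires ≥ 4 complete cases per cell and marks
thinner cells missing. An end-to-end simulated cohort (ten participants
whose lag shrinks, amplitude ratio approaches 1 and spread widens, with
an outcome delta that is a noisy monotone function of true improvement)
recovers the expected correlation signs — positive for K2, negative for
H4 and M1 — in at least 9 of 10 seeded replicates. This validates the
pipeline's direction of effect, not any particular published coefficient.

## Adaptive staircase

Difficulty control uses a transformed 3-down/1-up rule over 5 levels:
three consecutive correct responses raise the level, any error lowers it,
clamped to the range. Its analytic convergence point is the success
probability with p³ = ½, p ≈ 0.794 — central in the 75–85 % correct band
the intervention targets — which is why this rule family was chosen; the
up-count is configurable. The virtual responder is a monotone
non-increasing psychometric function, by default logit-linear from 0.95
(level 1) to 0.45 (level 5), bracketing the convergence point. Steady-state
performance is reported over the final half of the trials, discarding the
approach transient; 1 000-trial simulations land in the band in ≥ 95 % of
100 seeded replicates. Real-system "quality of correct movements" is
abstracted to a binary correct/incorrect per trial.

## Problem sizes and reproducibility

Test and acceptance workloads are sized for a single CPU: recovery grids
use 8-cycle jumping jacks (≈480 frames), recognizer checks use 3 training
and 2 held-out profiles over full 10-action sessions, the augmentation
count check uses 12-frame clips, and the end-to-end study uses 10
participants × 2 sessions × 4 segments × 10 replicates. All randomness
flows from explicit integer seeds (`numpy.random.default_rng`); the CLI
derives per-stage child seeds from one master seed via `SeedSequence`, and
every pipeline run writes a manifest sufficient to reproduce it.

## Known limitations

Template recognition assumes the scripted 10-action vocabulary and a
roughly upright mover; it is not a general action recognizer. The phase
pair for H2/H3 defaults to the shoulder angles and is configurable, but
aggregation over several pairs is not attempted. Stop detection assumes
approximately cyclic limb motion; highly irregular movement can produce
unpaired events (reported as NaN). The measures are defined for jumping
jacks only; other actions are segmented but not scored.
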