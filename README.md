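# gaitmetrics

Kinematic analysis of 25-joint skeleton streams from consumer depth
cameras (Kinect-V2-style, 30 Hz), built for movement-based interventions
where a camera watches a player perform scripted whole-body actions and
the system must (a) find the actions in the stream and (b) score how well
the most demanding one — the jumping jack — was performed. It is aimed at
researchers in digital health and movement science who need transparent,
testable movement-quality measures rather than an opaque game engine.

The pipeline:

1. **Preprocess** — zero-phase Butterworth low-pass chain (12 Hz
   acquisition stage, 3 Hz 2nd-order cleaning stage per segment channel)
   and central-difference velocities.
2. **Segment** — 60-frame sliding windows updated every 15 frames
   (0.5 s), classified by a deterministic subsequence-DTW template
   recognizer into 10 action labels (jumping jack, jump
   forward/backward/right/left, walk, step forward/back, touch nose,
   idle), merged into segments with refined boundaries; plus the two-step
   training-set augmentation (mirror doubling, then six time-warp
   variants per clip).
3. **Measure** — eleven jumping-jack measures in three families, computed
   on pelvis-centered, smoothed channels and normalized where appropriate
   by stature *h* estimated from the skeleton:
   - *Efficiency*: K1 = maxₜ(wrist-above-shoulder)/h,
     K2 = maxₜ(ankle separation)/h;
   - *Synchrony*: H1 = var of the four dominant frequencies of the
     shoulder/hip abduction angles θ₁..θ₄; H2 = MARP = Eₜ|PA₁ − PA₂| and
     H3 = CRP-SD = SDₜ(PA₁ − PA₂) with PA = atan2(ŝ′, ŝ) the normalized
     phase-plane angle; H4/H5 = mean |ΔT| of paired left/right hand and
     leg stop instants;
   - *Symmetry*: M1/M2 = meanₜ/SDₜ |c₁ − c₂| of the hands' absolute
     lateral offsets from the midline; M3/M4 = meanₜ ||V̂ᴿ| − |V̂ᴸ|| for
     horizontal/vertical hand velocities.
4. **Analyze** — per-session means, session-change scores, Spearman rank
   correlations against outcome deltas and Wilcoxon signed-rank paired
   tests, with exact enumeration p-values at small n.
5. **Simulate** — a ground-truthed parametric motion generator for all 10
   actions (controllable amplitude, left–right asymmetry, inter-limb lag,
   timing jitter, tracking noise) and a transformed 3-down/1-up adaptive
   staircase whose convergence point (p = 2^(−1/3) ≈ 0.794) sits centrally
   in a 75–85 % correct performance band.

See `docs/methods.md` for formulas, conventions and limitations.

## Worked example

Generate six jumping-jack cycles for a mover with a 0.10 s right-side lag
and a 0.85 right/left amplitude ratio, then score them:

```python
import gaitmetrics as gm

profile = gm.ParticipantProfile(
    height=1.58, rl_lag=0.10, rl_amplitude_ratio=0.85,
    max_ankle_spread=0.55, noise_sd=0.003, timing_jitter=0.03, seed=42,
)
seq, truth = gm.generate_jumping_jack(profile, n_cycles=6)
metrics = gm.compute_all(seq, truth.segments)[0]
for name, value in metrics.as_dict().items():
    print(f"{name:3s} {value:8.4f}")
```

prints

```
K1    0.2892
K2    0.3480
H1    0.0000
H2    0.3117
H3    0.0096
H4    0.1010
H5    0.0997
M1    0.0936
M2    0.0612
M3    0.4021
M4    0.4153
```

Reading the numbers: the wrists peak 0.29 statures above the shoulders
and the ankles spread to 0.348 statures (0.55 m / 1.58 m — the requested
spread, recovered). All four limbs share one dominant frequency (H1 = 0)
but the injected 0.10 s right-side lag is recovered almost exactly by the
stop-time measures (H4 ≈ H5 ≈ 0.10 s) and shows up as a nonzero mean
relative phase (H2 ≈ 0.31 rad). The 15 % amplitude asymmetry plus the lag
leaves a 9.4 cm mean left–right hand-position gap (M1) and ~0.4 m/s mean
absolute velocity differences (M3/M4). A perfectly symmetric, phase-locked
profile drives H1–H5 and M1–M4 to zero.

A config-driven run of the whole chain:

```sh
gaitmetrics run --config examples/session.yaml --seed 7 --out-dir out/
```

writes `raw.csv`, `clean.csv`, `metrics.csv` and a `manifest.json` that
reproduces the run from one seed. Individual stages are available as
`gaitmetrics simulate | preprocess | augment | segment | metrics |
analyze | staircase-sim`.

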