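# Methods

## The problem

Two common running surfaces, grass and asphalt, perturb gait subtly: a
harder surface sharpens the impact transient at foot strike and adds
post-impact vibration, while most of the movement pattern is unchanged.
Classifying the surface from body-worn IMUs is therefore a
small-effect-size problem in which preprocessing and evaluation protocol
choices can dominate the result. This package implements the pipeline and
the factorial comparisons around it; because the kind of raw cohort data
involved is rarely shareable, it ships a synthetic generator that encodes
the assumed data-generating process explicitly, with ground truth for
every downstream stage.

## Synthetic cohort model

**Study design.** Defaults mirror the motivating study design: 40 runners,
80 trials per surface each, straight ~20 m runs at a comfortable pace,
12 triaxial sensors (head, shoulders, upper arms, hands, pelvis, lower
legs, feet) recording 3-axis acceleration and angular velocity, plus a
knee-flexion angle channel. A trial is occasionally flagged as dropped
(Bernoulli, default rate 0.01), emulating a sensor falling off; dropped
trials are flagged rather than deleted so the bookkeeping is auditable.

**Sampling rate** is not dictated by the hardware we model, so it is a
parameter: default 100 Hz. **Trial duration** is derived as
20 m / speed; speeds are drawn N(3.5, 0.15²) m/s clipped to [3.2, 3.7],
and stride (cycle) frequencies N(1.4, 0.07²) Hz clipped to [1.25, 1.55].
These values were chosen once so that (a) a trial holds ~7 gait cycles,
consistent with the study's reported totals (~44,000 cycles from ~6,400
trials), and (b) every trial still leaves ≥4 s after trimming 12.5% at
each end, so the fixed-window comparison condition is always defined.

**Waveforms.** Each channel is a baseline plus Gaussian bumps over cycle
phase φ ∈ [0,1):

    y_c(t) = b_c + Σ_k a'_{c,k} · exp(−(φ(t)−μ_k)² / 2σ_k²) + ε(t)

Cycle boundaries (heel strikes) are laid on the sample grid with
per-cycle duration jitter (CV per surface), so the ground-truth indices
are exact integers. One designated *impact* component per sensor channel
sits just after heel strike (φ≈0.03, narrow width); region amplitudes
fall from feet (~30 m/s²) to head (~3 m/s²); left-side sensors run half
a cycle out of phase. The knee-flexion channel has a large swing-phase
maximum (φ≈0.8), a small stance bump, and a sharp dip whose minimum falls
exactly on the heel-strike sample — the geometry the event detector
relies on. Knee noise is band-limited (2nd-order Butterworth, 8 Hz) since
joint kinematics are smooth; at the default noise level the dip remains
the first local minimum after each swing peak, which is why detection
recovers ground truth exactly in practice and not just in the noise-free
limit.

**Surface effects** act through three parameters per surface, scaled by a
per-channel proximity weight w_c (1.0 at the feet, 0.6 lower legs, 0.3
pelvis, ≤0.15 upper body; angular-velocity channels use 0.4× these, which
makes acceleration the more informative signal by construction):

| parameter | grass | asphalt | meaning |
|---|---|---|---|
| impact_gain | 1.0 | 1.35 | multiplies the impact component amplitude, ×(1 + w_c(gain−1)) |
| hf_noise_sd | 0.25 | 0.5 m/s² | sd of a 0.1 s high-frequency burst after each heel strike, ×w_c |
| cycle_cv | 0.05 | 0.04 | cycle-duration variability |

**Subject signatures.** Each runner owns fixed per-channel, per-component
draws z_{c,k} = ρ·u_k + √(1−ρ²)·v_{c,k} (ρ = 0.7), applied
multiplicatively to amplitudes as (1 + s·z) with s = 0.25, and the shared
impact draw also scales that runner's post-impact burst. The shared
body-wide part u_k is essential: it represents a consistent "impact
style" that channel averaging cannot remove, so a runner's own amplitude
level partially confounds the surface contrast. This single calibration —
made once, before the acceptance checks were frozen — is what gives the
package its central protocol result: a classifier that sees a runner's
other trials (subject-dependent split) reads the surface off that
runner's calibrated amplitude scale, while a subject-wise split must
generalize across impact styles and loses accuracy.

**What the generator does not emulate:** real surface-compliance
biomechanics (it is a phenomenological bump model, not musculoskeletal
simulation), magnetometers, GPS/pace drift, slopes or curves, surface
transitions, fatigue, and within-session drift of sensor placement.
Passing tests therefore show that the *pipeline* behaves correctly under
the assumed effect structure — not that these accuracies would be reached
on real runners.

## Segmentation

Knee-flexion peaks are local maxima with topographic prominence ≥15° and
pairwise separation ≥0.29 s (0.4 of a nominal 1.4 Hz cycle); ties are
thinned highest-first, earliest-first. Heel strike is the *first* local
minimum strictly between consecutive peaks (plateaus resolve to their
first sample). The right knee drives segmentation by default (left
available); cycles are resampled to 100 frames by linear interpolation —
the standard time-normalization in gait analysis — and cycles outside
[0.5, 2.0]× the trial's median duration are rejected and counted. The
fixed-window alternative trims 12.5% of samples at each end (the
acceleration/deceleration phases) and takes the centered 4 s window with
no phase alignment.

## Preprocessing

"Amplitude normalization" divides each channel by its maximum *absolute*
value — a signed maximum could flip or explode channels whose extreme is
negative — computed per trial and applied to that trial's segments
(per-segment at tensor assembly is also available). The pipeline keeps
the knee angle in native degrees during trial normalization because the
event detector's prominence threshold is calibrated in degrees. The
default pipeline is gait cycles + no normalization, the configuration
that performed best in the motivating work. Class encoding is fixed
project-wide: grass = 0, asphalt = 1.

## Classifiers

The **baseline** network is [conv → ReLU → max-pool(2) → dropout] × L
with a dense-ReLU head and 2-way softmax; the **final** network replaces
each block with conv → batch-norm → ReLU → dropout (no pooling). Both are
built on the package's own numpy engine (explicit im2col convolutions,
batch-norm with running statistics, inverted dropout, He initialization,
Adam/RMSprop/SGD), float32 throughout, fully driven by seeded generator
streams so runs are bit-reproducible on one device.

Defaults: 2 conv layers of 64 filters, kernel 5, dropout 0.2, dense 100,
Adam, batch 200, epoch cap 500, early stopping on validation loss with
patience 50 and min_delta 1e-4 (the parameters of the best-validation
epoch are restored). All hyperparameters are validated against the
tuning grid; L1/L2/L1+L2 penalties are implemented but off by default.
The tuner is a seeded uniform random search over that grid (log-uniform
learning rate); each trial draws from its own sub-stream so enlarging
the budget extends rather than reshuffles the trial sequence.

Two numerical choices deserve note. The default learning rate is 3e-4:
un-normalized inputs arrive at physical scale (tens of m/s²), and larger
rates can kill the ReLU stack in the first few updates. Independently,
`train` fits per-channel standardization constants (mean/sd over the
training set only) and applies them to every batch; they are stored on
the fitted model and applied at prediction. This makes optimization
insensitive to input scale, so the raw-vs-normalized comparison measures
information content rather than conditioning — per-trial max-abs
normalization removes between-trial amplitude information, while the
global affine standardization does not.

## Splits and evaluation

Subject-wise splits partition subjects with largest-remainder rounding at
default fractions (0.70, 0.15, 0.15) — at the full 40-subject design that
is leave-6-subjects-out for test. Subject-dependent splits shuffle
segment indices (optionally stratified by surface); sibling cycles from
one trial are deliberately *not* kept together, matching the
shuffle-everything description of that protocol. Every split is asserted
to partition the index set, and `audit_split` reports the
train/test subject overlap (zero for subject-wise, by construction).

Metrics are per-class precision, recall and F1 plus overall accuracy (%),
computed from the 2×2 confusion matrix; zero-denominator cases report 0
with a warning so degenerate all-one-class predictions remain
reportable. The experiment harness trains one model per grid cell per
seed and reports mean ± sd across seeds — the source values being
reproduced were single runs without a stated seed protocol, so multi-seed
aggregation is package policy. Of the published per-class F1 cells, three
are exactly the harmonic mean of their printed precision/recall after
2-decimal rounding and serve as worked examples; the grass-acceleration
row is rounding-inconsistent at printed precision (0.97, 0.95 → 0.96, not
0.95) and is flagged rather than matched.

## Problem sizes

Tests and the acceptance script run the study at desk scale, chosen as
the package's standard small-cohort configuration: 8 subjects × 10
trials/surface (~1,000 cycles) for the directional comparisons with a
32-filter baseline model (45-epoch cap), and 16 subjects × 8
trials/surface for the null calibration so the test set exceeds 500
segments. The directional findings — cycles > fixed windows,
raw ≥ normalized − 2 points, acceleration ≥ angular velocity, feet within
2 points of lower body and above pelvis, subject-dependent >
subject-wise — are reproduced in direction only; magnitudes at this scale
are not comparable to a 40-subject cohort.

## Known limitations

* The generator's effect sizes are calibrated to reproduce directions,
  not magnitudes; absolute accuracies on synthetic data (often ~100%
  subject-dependent at desk scale) exceed what heterogeneous real data
  yields.
* Subject-wise accuracy on synthetic data can sit near chance at small
  cohort sizes — with one or two held-out subjects, per-subject transfer
  is close to all-or-nothing.
* The numpy engine targets clarity and reproducibility over speed; it is
  single-threaded apart from BLAS matmuls and has no GPU path.
* Fixed-window segments carry a different frame count than cycle
  segments, so models trained under one segmentation cannot score the
  other.
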