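# Methods

## Overview

`wristsyn` implements a synergy-based linear regression model (SLRM) for
continuous decoding of two-dimensional wrist angle and grip force from
seven-channel surface-EMG envelopes, together with a synthetic-session
generator that emulates the recording protocol the model assumes.  This
note documents the model, the generator, the numerical choices and the
limitations.

## Signal chain

Raw EMG (2000 Hz) is full-wave rectified and low-pass filtered with a
2nd-order Butterworth at 5 Hz — the "quasi-tension" envelope, which tracks
muscle tension.  Filtering is causal by default (`lfilter`), the correct
choice for on-line control; offline analysis (including the evaluation
harness) uses the `zero_phase=True` flag (`filtfilt`), because a causal
filter's group delay would bias the regression between envelopes and
simultaneously recorded kinematics.  Negative filter undershoot is clipped
to zero so envelopes stay nonnegative.

Each channel is then normalized by its peak over the whole session (all
trials), which cancels electrode-gain differences between channels and
re-attachments; the divisors are stored so later data can be normalized
identically.  Per-channel (rather than single-global-peak) normalization is
the standard practice and is what is implemented.  Finally all streams —
envelope, angle (74 Hz), force (100 Hz) — are linearly interpolated onto a
common 74 Hz grid (the slowest stream's rate) spanning the trial duration.

## Angle representation

Self-paced subjects drift diagonally, so the two wrist axes (X:
flexion–extension, extension positive; Y: radial–ulnar, radial positive)
are normalized by their absolute maxima over the *training* trials only
(frozen at fit time, applied unchanged at test time) and combined into sum
and difference coordinates `u = x/max_x + y/max_y`, `v = x/max_x − y/max_y`.
The transform is linear and exactly invertible; decoded `u, v` are mapped
back to degrees for reporting.

## Synergy extraction

The envelope matrix `E` (time × 7) is factorized as `E ≈ M Sᵀ` with both
factors nonnegative.  The HALS update for component `k` is the projected
exact block-coordinate minimizer

    s_k ← [ s_k + (EᵀM − S MᵀM)_k / (m_kᵀ m_k) ]₊
    m_k ← [ m_k + (E S − M SᵀS)_k / (s_kᵀ s_k) ]₊

with an `eps = 1e-12` floor on denominators.  The Frobenius objective is
non-increasing across sweeps; a column that collapses to zero is reseeded
with a random direction and a zeroed activation (which leaves the objective
unchanged) rather than left dead.  Convergence: relative objective change
below `1e-8` between sweeps, or 500 sweeps.  Ten random restarts
(uniform-positive initialization, seeded) are run and the best objective
kept.  The scale ambiguity is resolved by unit-Euclidean-norm columns of
`S`, with magnitude carried by `M` (applied once at convergence, which
preserves the product).  The factorization is equivariant to channel
permutation only up to column order and optimizer tolerance, because the
random initialization is indexed by channel.

Two strategies build the model's synergy set:

* **SLRM1** — one HALS run on the wrist and grip training trials
  concatenated in time, with `j_wrist + j_grip` components.  The grip
  column is identified *post hoc* as the one with the largest fraction of
  its norm on the finger-flexor channels (FDS, FDP); whether the original
  study constrained it during fitting instead is ambiguous, and post-hoc
  labeling is the implemented reading.
* **SLRM2** — independent HALS runs on the wrist trial (`j_wrist`
  components) and the grip trial (`j_grip` components, one by default),
  columns concatenated wrist-first.

New data are projected onto a frozen basis by nonnegative least squares,
implemented as HALS sweeps over activation columns with `S` fixed (all time
samples vectorized); this solves the per-sample NNLS problems and is
verified against a direct active-set NNLS solver in the tests.

The wrist synergy count is selected as the smallest `j` (scanned over 1–6)
whose minimum VAF across all supplied datasets reaches 0.9, where VAF is
the *uncentered* variance accounted for, `1 − ‖E − MSᵀ‖²_F / ‖E‖²_F`
(whether a mean-centered variant was intended elsewhere is not decidable;
uncentered is the implemented and configurable-in-principle choice).

## Decoder

Sum/difference targets are regressed on the training activations by
ordinary least squares per dimension (statsmodels, giving coefficient
standard errors; rank-deficient designs fall back to the minimum-norm
solution with a warning).  All synergy activations enter the regression by
default, including the grip column — the regression sums over every
activation, and grip-induced angle perturbation is precisely one of the
phenomena of interest; `include_grip_regressor=False` restricts to wrist
columns.  Grip force is the grip-synergy activation times one calibration
gain chosen so the training grip trial's peak activation maps to normalized
force 1.0 — deliberately *not* a second regression, since the grip
activation already tracks force.

## Evaluation

Per held-out trial: Pearson `r` per angle dimension, averaged over the two
dimensions; nRMSE pooled over both dimensions' errors and normalized by
`a = 90°`, the wrist range limit.  Grip-type trials (no movement) report
the angle nRMSE against the zero-angle reference — a perturbation measure —
plus the grip-force correlation.  Cross-validation is exhaustive over
(wrist training trial, grip training trial) pairs drawn from the
comfortable-maximum and grip-only conditions respectively (both
configurable, since the original training pool is described only loosely);
each fold's model is evaluated on every trial outside its training pair,
and fold-level means are aggregated as mean ± SD.  A thin two-sample
t-test helper compares per-fold metrics between models, with no
multiple-testing adjustment.

## Synthetic sessions

The generator emulates the recording protocol: per condition, four
movement directions (flexion, extension, radial, ulnar) × 3 repetitions per
trial, 3 trials per condition; movement conditions comfortable-max,
comfortable-half (half amplitude), stiffened (tonic co-contraction 0.3
added to all wrist synergy drives), and max-with-grip (sustained 0.6
grip); grip-only trials (3 strong + 3 weak pulses) and graded-force trials
at 1.0/0.5/0.25 of maximum.  Repetition count is a parameter rather than a
constant because the source protocol is internally inconsistent about it.
Movements are raised-cosine excursions (0.7 s out, 0.25 s hold, 0.7 s
back), amplitude ±45° by default (half the 90° range used as the nRMSE
normalizer), each direction perturbed by a seeded angular jitter (SD 0.15
rad) emulating diagonal drift.  Streams are emitted at 2000/74/100 Hz.

True activations follow the minimal generative structure consistent with
linear decoding: the positive and negative parts of the normalized sum and
difference coordinates each drive one wrist synergy, whose loadings sit on
the corresponding diagonal muscle groups (`[u]⁺` → ECR+APL, `[u]⁻` → FCU,
`[v]⁺` → ECU, `[v]⁻` → FCR+APL — so flexion recruits FCU/FCR, extension
ECR/ECU, radial ECR/FCR/APL, ulnar ECU/FCU), and the grip-force profile
drives the grip synergy (FDS+FDP).  A small seeded jitter (≤ 0.08 before
normalization) makes ground truths seed-distinct.

Two generator features matter for realism:

* **Noise** is additive Gaussian on the envelope, clipped at zero and
  *band-limited to the envelope bandwidth* (low-passed at 5 Hz) with the
  SNR (dB) defined after band-limiting.  Broadband noise at 2 kHz would be
  almost entirely removed by the downstream 5 Hz envelope filter, so the
  stated SNR would never reach the analysis; band-limited noise survives
  the chain, which is what makes surplus synergies genuinely noise-derived
  and reproduces the overfitting degradation at large synergy counts.
* **Grip spillover** (optional, gain parameter) leaks grip activation into
  the wrist channels with a flexor-weighted spatial profile
  (FCU/FCR dominant), reflecting that the finger-flexor electrodes
  neighbour the wrist flexors and that gripping co-activates them.  The
  asymmetry matters: a uniform leak loads antagonist synergies equally and
  cancels in the linear angle read-out, whereas the flexor-weighted leak
  produces the observed behaviours — separate-trial extraction (SLRM2)
  resists grip-induced angle perturbation better than joint extraction
  (SLRM1), and strong grips perturb the decoded angle more than weak ones.

What the generator does *not* emulate: raw (unrectified) EMG stochastics,
electrode-shift or motion artifacts, fatigue, nonlinear EMG-to-tension
saturation, subject-to-subject anatomical variability, or IMU orientation
estimation (angles are emitted directly).  Passing tests therefore show the
pipeline is correct and self-consistent under its own generative
assumptions — near-ceiling scores on synthetic data say nothing about
absolute performance on recordings, where correlations around 0.8 are the
realistic regime.

## Problem sizes and determinism

The test and acceptance runs use sessions of 3 comfortable-max + 3
grip-only trials (plus force trials where grip grading matters), 3
repetitions per movement, which gives 9 CV folds per strategy — the same
fold structure as a full session while keeping simulations desk-scale.
Stochastic trend checks use 10 independent session seeds and majority
votes.  All randomness (ground truth, trials, HALS restarts) derives from
explicit integer seeds; identical inputs reproduce bit-identical sessions
and factorizations.

## Known limitations

* HALS converges to local optima; ten restarts make the best-restart result
  stable in practice but global optimality is not guaranteed.
* The grip-column labeling in SLRM1 relies on the finger-flexor loading
  ratio and could mislabel under extreme spillover.
* The linear decoder cannot capture EMG-to-angle nonlinearity; on real
  data this is a known error source, not addressed here.
* Group-level statistics are a convenience wrapper only; no correction for
  multiple comparisons is applied.
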