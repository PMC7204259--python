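# wristsyn

Continuous decoding of two-dimensional wrist angle and grip force from
seven-channel surface-EMG envelopes, using muscle synergies and linear
regression.

## The problem

Surface EMG over the forearm mixes the activity of wrist movers (ECR, ECU,
FCU, FCR, APL) with that of the finger flexors lying underneath (FDS, FDP).
A prosthesis or rehabilitation interface needs *continuous* estimates of
both the 2-D wrist angle (flexion–extension and radial–ulnar deviation) and
the grip force, and the crosstalk between muscle groups makes the two
estimates perturb each other.  The synergy-based linear regression model
(SLRM) implemented here addresses this by factorizing the normalized EMG
envelope matrix into a small set of nonnegative muscle synergies and
decoding kinematics linearly from the synergy activations.

## The model

Envelopes ("quasi-tension": rectified EMG, 2nd-order Butterworth low-pass
at 5 Hz, per-channel task-peak normalization) form a time × channel matrix
`E`, factorized as

    E ≈ M Sᵀ,   M ≥ 0 (time × j activations),  S ≥ 0 (channel × j synergies)

by hierarchical alternating least squares (HALS) NMF, which updates one
synergy at a time by projected least squares and remains usable when the
synergy count exceeds the channel count.  Wrist angles `(x, y)` are mapped
to normalized sum/difference coordinates `u = x/max_x + y/max_y`,
`v = x/max_x − y/max_y` (robust to the diagonal drift of self-paced
movements) and regressed on the activations,

    θᵢ = a₀,ᵢ + Σⱼ aⱼ,ᵢ mⱼ + ε ,   i ∈ {sum, diff},

while grip force is read directly off the grip synergy activation with a
single calibration gain.  Two extraction strategies are provided: one joint
factorization of concatenated wrist+grip trials (**SLRM1**) and separate
factorizations per trial type (**SLRM2**).  The wrist synergy count is the
smallest one whose variance-accounted-for (VAF) reaches 0.9 on every
dataset.  Performance is evaluated by exhaustive cross-validation over all
(wrist training trial, grip training trial) pairs, with Pearson `r` and the
RMSE normalized by the 90° wrist range (nRMSE).

Because real recordings of this kind are not publicly deposited, the
package ships a first-class synthetic-session generator with known synergy
structure (directional tuning of the five wrist muscles, a finger-flexor
grip synergy with optional flexor-weighted spillover, band-limited envelope
noise at a stated SNR) so that every stage is testable end to end.

## Worked example

```python
import wristsyn as ws

gt = ws.make_ground_truth(seed=1, noise_snr_db=20.0)       # 4 wrist + 1 grip synergies
protocol = [ws.TrialSpec("comfortable_max") for _ in range(3)] + \
           [ws.TrialSpec("grip_only") for _ in range(3)]
session = ws.generate_session(gt, protocol, seed=1)
trials = ws.preprocess_session(session)                    # envelopes @ 74 Hz, normalized

wrist = [t for t in trials if t.condition == "comfortable_max"]
grip = [t for t in trials if t.condition == "grip_only"]
results = ws.SynergyLRM(wrist[:1], grip[:1], strategy="slrm2",
                        j_wrist=4).fit()
print(f"training VAF: {results.train_vaf:.4f}")

report = ws.exhaustive_cv(trials, strategy="slrm2", j_wrist=4,
                          hals=ws.HALSConfig(seed=1))
print(report.summary())
```

prints

```
training VAF: 0.9976
Exhaustive CV — strategy=slrm2, j_wrist=4, 9 folds
  wrist-motion r      : 0.9981 ± 0.0001
  wrist-motion nRMSE  : 0.0136 ± 0.0003
  grip-trial nRMSE    : 0.0662 ± 0.0328
  grip-force r        : 0.9990 ± 0.0000
```

`wrist-motion r` is the correlation between decoded and reference angle on
held-out movement trials (averaged over the two axes and folds);
`grip-trial nRMSE` is the angle perturbation during gripping, measured
against the zero-angle reference and normalized by the 90° range;
`grip-force r` is the correlation of the calibrated grip-synergy activation
with the reference force.  On clean synthetic data the decoder is nearly
exact; real recordings sit substantially lower.

The same pipeline is available from the shell:

```
wristsyn simulate --out session/ --seed 1
wristsyn extract session/ --strategy slrm2 --j-wrist 4 --out synergies.csv
wristsyn run-all --seed 1 --out results/
```

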