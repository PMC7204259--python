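"""Synthetic recording sessions with known muscle-synergy structure.

The generator emulates a wrist-motion / grip experiment: seven forearm
muscles (five wrist movers, two finger flexors) recorded as surface-EMG
envelopes at 2000 Hz, two-dimensional wrist joint angle at 74 Hz and grip
force at 100 Hz.  Envelopes are produced by the same generative model the
analysis assumes,

    E = M_true @ S_true.T  (+ noise, floored at zero),

where ``S_true`` is a known nonnegative channel-by-synergy mixing matrix and
the true activations ``M_true`` are driven by the kinematics through
rectified directional tuning: the positive and negative parts of the
normalized sum/difference angle coordinates each drive one wrist synergy,
and the grip-force profile drives the grip synergy.  Because decoding is a
linear read-out of those activations, a session generated this way is
exactly solvable in the noiseless limit, which is what the recovery tests
exploit.

Conditions
----------
``comfortable_max``    four directions (flexion/extension/radial/ulnar),
                       full amplitude, ``n_reps`` repetitions each
``comfortable_half``   same, half amplitude
``stiffened``          full amplitude plus tonic co-contraction of all wrist
                       synergies
``max_with_grip``      full amplitude plus a sustained moderate grip
``grip_only``          no wrist motion; ``n_reps`` strong then ``n_reps``
                       weak grip pulses
``force_max/half/quarter``  no wrist motion; grip pulses at 1.0 / 0.5 / 0.25
                       of maximum force

Subjects moving at their own pace tend to drift diagonally, so every
movement direction is perturbed by a seeded angular jitter
(``diagonal_bias``, radians SD).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CHANNELS",
    "WRIST_CONDITIONS",
    "GRIP_CONDITIONS",
    "CONDITIONS",
    "GroundTruth",
    "TrialSpec",
    "Trial",
    "Session",
    "make_ground_truth",
    "simulate_wrist_trajectory",
    "generate_session",
    "default_protocol",
]

#: Electrode channels in recording order: five wrist muscles then the two
#: finger flexors used for grip.
CHANNELS = ("ECR", "ECU", "FCU", "FCR", "APL", "FDS", "FDP")
_N_WRIST_CH = 5
_FINGER_CH = (5, 6)

EMG_RATE = 2000.0
ANGLE_RATE = 74.0
FORCE_RATE = 100.0

WRIST_CONDITIONS = frozenset(
    {"comfortable_max", "comfortable_half", "stiffened", "max_with_grip"}
)
GRIP_CONDITIONS = frozenset(
    {"grip_only", "force_max", "force_half", "force_quarter"}
)
CONDITIONS = WRIST_CONDITIONS | GRIP_CONDITIONS

# Movement directions in the angle plane: X = flexion-extension (extension
# positive), Y = radial-ulnar deviation (radial positive).
_DIRECTION_ANGLE = {
    "flexion": math.pi,
    "extension": 0.0,
    "radial": math.pi / 2,
    "ulnar": -math.pi / 2,
}
_DIRECTION_ORDER = ("flexion", "extension", "radial", "ulnar")

# Wrist synergy drives, in order.  u = x/mx + y/my, v = x/mx - y/my; the
# positive/negative parts of u and v each recruit one muscle group sitting on
# the corresponding diagonal of the wrist plane:
#   [u]+ (extension+radial)  -> ECR, APL
#   [u]- (flexion+ulnar)     -> FCU
#   [v]+ (extension+ulnar)   -> ECU
#   [v]- (flexion+radial)    -> FCR, APL
# so flexion recruits FCU+FCR, extension ECR+ECU, radial ECR+FCR+APL and
# ulnar ECU+FCU, matching the anatomical roles of the five wrist muscles.
_WRIST_TUNING = ("sum_pos", "sum_neg", "diff_pos", "diff_neg")
_WRIST_TEMPLATES = {
    "sum_pos": {"ECR": 1.0, "APL": 0.5},
    "sum_neg": {"FCU": 1.0},
    "diff_pos": {"ECU": 1.0},
    "diff_neg": {"FCR": 1.0, "APL": 0.4},
}

# Timing constants (seconds).
_T_PRE = 0.25
_T_OUT = 0.7
_T_HOLD = 0.25
_T_BACK = 0.7
_T_REST = 0.35
_T_MOVE = _T_OUT + _T_HOLD + _T_BACK + _T_REST  # 2.0 s per repetition

_G_RAMP = 0.4
_G_HOLD = 1.2
_G_REST = 0.6
_T_GRIP = 2 * _G_RAMP + _G_HOLD + _G_REST  # 2.6 s per grip pulse

_T_TAIL = 0.25

#: Bandwidth of the synthetic envelope noise (Hz); matches the quasi-tension
#: envelope bandwidth so the stated SNR survives preprocessing.
_ENVELOPE_BANDWIDTH_HZ = 5.0

#: Relative grip-spillover weight per wrist channel (ECR, ECU, FCU, FCR,
#: APL): crosstalk and co-contraction during grip load the wrist flexors
#: most.
_GRIP_SPILL_PROFILE = np.array([0.15, 0.15, 1.0, 1.0, 0.3])


@dataclass(frozen=True)
class GroundTruth:
    """Known generative structure of a synthetic session.

    Attributes
    ----------
    S_true : (n_channels, j_wrist + j_grip) ndarray
        Nonnegative mixing matrix with unit-norm columns; wrist synergies
        first, grip synergies last.
    tuning : tuple of str
        Per-column drive label: one of ``sum_pos/sum_neg/diff_pos/diff_neg``
        for tuned wrist synergies, ``untuned`` for surplus wrist columns and
        ``grip`` for grip columns.
    noise_snr_db : float or None
        Envelope signal-to-noise ratio in dB; ``None`` (or ``inf``) means
        noiseless.
    spillover : float
        Gain of grip-synergy leakage into the wrist channels (0 = the grip
        column loads only FDS/FDP).
    seed : int
    channel_labels : tuple of str
    """

    S_true: np.ndarray
    tuning: tuple
    noise_snr_db: float | None
    spillover: float
    seed: int
    channel_labels: tuple = CHANNELS

    @property
    def n_channels(self) -> int:
        return self.S_true.shape[0]

    @property
    def j_total(self) -> int:
        return self.S_true.shape[1]

    @property
    def j_wrist(self) -> int:
        return sum(1 for t in self.tuning if t != "grip")

    @property
    def j_grip(self) -> int:
        return sum(1 for t in self.tuning if t == "grip")

    @property
    def grip_columns(self) -> tuple:
        return tuple(k for k, t in enumerate(self.tuning) if t == "grip")


def make_ground_truth(
    n_channels: int = 7,
    j_wrist: int = 4,
    j_grip: int = 1,
    seed: int = 0,
    *,
    noise_snr_db: float | None = 20.0,
    spillover: float = 0.0,
) -> GroundTruth:
    """Build a reproducible ground-truth mixing matrix.

    Wrist synergies load direction-consistent muscle groups (see module
    docstring); the grip synergy loads FDS and FDP only, plus an optional
    ``spillover`` leakage into the wrist channels that models shared-muscle
    crosstalk during strong grips.  A small seeded jitter on every loading
    makes ground truths from different seeds distinct.
    """
    if n_channels <= 0 or j_wrist <= 0 or j_grip <= 0:
        raise ValueError("n_channels, j_wrist and j_grip must be positive")
    if n_channels != len(CHANNELS):
        raise ValueError(
            f"the muscle tuning templates define {len(CHANNELS)} channels; "
            f"got n_channels={n_channels}"
        )
    if spillover < 0:
        raise ValueError("spillover must be nonnegative")
    if j_wrist + j_grip > n_channels:
        warnings.warn(
            "more synergies than channels: the factorization is overcomplete",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    cols = []
    tuning = []
    for k in range(j_wrist):
        col = np.zeros(n_channels)
        if k < len(_WRIST_TUNING):
            label = _WRIST_TUNING[k]
            for ch, w in _WRIST_TEMPLATES[label].items():
                col[CHANNELS.index(ch)] = w
        else:
            label = "untuned"
            col[:_N_WRIST_CH] = rng.uniform(0.2, 1.0, _N_WRIST_CH)
        col[:_N_WRIST_CH] += rng.uniform(0.0, 0.08, _N_WRIST_CH)
        cols.append(col)
        tuning.append(label)
    for _ in range(j_grip):
        col = np.zeros(n_channels)
        col[_FINGER_CH[0]] = 1.0
        col[_FINGER_CH[1]] = 0.8
        col[list(_FINGER_CH)] += rng.uniform(0.0, 0.05, 2)
        if spillover > 0:
            # Grip leakage into the wrist channels is flexor-dominant:
            # FDS/FDP electrodes neighbour the wrist flexors (FCU, FCR) and
            # gripping co-activates them, so the crosstalk pattern is
            # spatially asymmetric rather than uniform.
            col[:_N_WRIST_CH] += (
                spillover
                * _GRIP_SPILL_PROFILE
                * rng.uniform(0.7, 1.3, _N_WRIST_CH)
            )
        cols.append(col)
        tuning.append("grip")

    S = np.column_stack(cols)
    S /= np.linalg.norm(S, axis=0, keepdims=True)
    return GroundTruth(
        S_true=S,
        tuning=tuple(tuning),
        noise_snr_db=noise_snr_db,
        spillover=spillover,
        seed=seed,
    )


@dataclass(frozen=True)
class TrialSpec:
    """Parameters of one simulated trial.

    ``amplitude`` is the comfortable-maximum radial excursion in degrees;
    the half condition automatically moves at half of it.  ``diagonal_bias``
    is the SD (radians) of the per-repetition direction jitter emulating
    self-paced diagonal drift.
    """

    condition: str
    n_reps: int = 3
    amplitude: float = 45.0
    diagonal_bias: float = 0.15
    stiffen_level: float = 0.3
    grip_with_motion_level: float = 0.6
    weak_grip_level: float = 0.4
    emg_rate: float = EMG_RATE
    angle_rate: float = ANGLE_RATE
    force_rate: float = FORCE_RATE

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of "
                f"{sorted(CONDITIONS)}"
            )
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if min(self.emg_rate, self.angle_rate, self.force_rate) <= 0:
            raise ValueError("sampling rates must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def movement_amplitude(self) -> float:
        """Radial excursion of this trial in degrees (0 for grip trials)."""
        if self.condition in GRIP_CONDITIONS:
            return 0.0
        if self.condition == "comfortable_half":
            return 0.5 * self.amplitude
        return self.amplitude


@dataclass(frozen=True)
class Trial:
    """One simulated trial: three streams at their native rates, plus the
    generative truth for validation."""

    condition: str
    emg: np.ndarray            # (m, n_channels) envelope at emg_rate
    emg_rate: float
    angles: np.ndarray         # (n, 2) degrees at angle_rate
    angle_rate: float
    force: np.ndarray | None   # (p,) normalized force at force_rate
    force_rate: float
    activations_true: np.ndarray   # (m, j) true synergy drives at emg_rate
    spec: TrialSpec
    seed: int


@dataclass(frozen=True)
class Session:
    ground_truth: GroundTruth
    trials: tuple
    seed: int

    def trials_by(self, *conditions: str) -> list:
        wanted = set(conditions)
        return [t for t in self.trials if t.condition in wanted]


# ---------------------------------------------------------------------------
# trial plans and rendering


def _plan_moves(spec: TrialSpec, rng: np.random.Generator):
    """Movement plan: list of (start time, direction angle, amplitude)."""
    amp = spec.movement_amplitude
    moves = []
    t = _T_PRE
    for direction in _DIRECTION_ORDER:
        base = _DIRECTION_ANGLE[direction]
        for _ in range(spec.n_reps):
            theta = base + rng.normal(0.0, spec.diagonal_bias)
            moves.append((t, theta, amp))
            t += _T_MOVE
    return moves, t + _T_TAIL


def _plan_grips(spec: TrialSpec, rng: np.random.Generator):
    """Grip plan: list of (start time, level)."""
    if spec.condition == "grip_only":
        levels = [1.0] * spec.n_reps + [spec.weak_grip_level] * spec.n_reps
    elif spec.condition == "force_max":
        levels = [1.0] * spec.n_reps
    elif spec.condition == "force_half":
        levels = [0.5] * spec.n_reps
    elif spec.condition == "force_quarter":
        levels = [0.25] * spec.n_reps
    else:
        return [], 0.0
    grips = []
    t = _T_PRE
    for level in levels:
        grips.append((t, level))
        t += _T_GRIP
    return grips, t + _T_TAIL


def _plan_trial(spec: TrialSpec, rng: np.random.Generator):
    if spec.condition in WRIST_CONDITIONS:
        moves, dur = _plan_moves(spec, rng)
        grips, _ = _plan_grips(spec, rng)
        return {"moves": moves, "grips": grips, "duration": dur}
    grips, dur = _plan_grips(spec, rng)
    return {"moves": [], "grips": grips, "duration": dur}


def _move_shape(tau: np.ndarray) -> np.ndarray:
    """Raised-cosine out / hold / raised-cosine back profile on [0, 1]."""
    out = np.zeros_like(tau)
    up = (tau >= 0) & (tau < _T_OUT)
    out[up] = 0.5 * (1 - np.cos(np.pi * tau[up] / _T_OUT))
    hold = (tau >= _T_OUT) & (tau < _T_OUT + _T_HOLD)
    out[hold] = 1.0
    down = (tau >= _T_OUT + _T_HOLD) & (tau < _T_OUT + _T_HOLD + _T_BACK)
    out[down] = 0.5 * (1 + np.cos(np.pi * (tau[down] - _T_OUT - _T_HOLD) / _T_BACK))
    return out


def _grip_shape(tau: np.ndarray) -> np.ndarray:
    """Ramp / plateau / release profile of a grip pulse on [0, 1]."""
    out = np.zeros_like(tau)
    up = (tau >= 0) & (tau < _G_RAMP)
    out[up] = 0.5 * (1 - np.cos(np.pi * tau[up] / _G_RAMP))
    hold = (tau >= _G_RAMP) & (tau < _G_RAMP + _G_HOLD)
    out[hold] = 1.0
    down = (tau >= _G_RAMP + _G_HOLD) & (tau < 2 * _G_RAMP + _G_HOLD)
    out[down] = 0.5 * (1 + np.cos(np.pi * (tau[down] - _G_RAMP - _G_HOLD) / _G_RAMP))
    return out


def _time_axis(duration: float, rate: float) -> np.ndarray:
    n = int(round(duration * rate)) + 1
    return np.arange(n) / rate


def _render_angles(plan: dict, rate: float) -> np.ndarray:
    t = _time_axis(plan["duration"], rate)
    xy = np.zeros((t.size, 2))
    for t0, theta, amp in plan["moves"]:
        shape = amp * _move_shape(t - t0)
        xy[:, 0] += shape * math.cos(theta)
        xy[:, 1] += shape * math.sin(theta)
    return xy


def _render_force(plan: dict, spec: TrialSpec, rate: float) -> np.ndarray | None:
    t = _time_axis(plan["duration"], rate)
    if spec.condition == "max_with_grip":
        # Sustained moderate grip across the whole trial with soft edges.
        ramp = 0.5
        f = np.ones_like(t)
        f = np.minimum(f, np.clip(t / ramp, 0, 1))
        f = np.minimum(f, np.clip((t[-1] - t) / ramp, 0, 1))
        return spec.grip_with_motion_level * f
    if not plan["grips"]:
        return None
    f = np.zeros_like(t)
    for t0, level in plan["grips"]:
        f += level * _grip_shape(t - t0)
    return f


def _render_activations(
    plan: dict, spec: TrialSpec, gt: GroundTruth, rate: float
) -> np.ndarray:
    """True synergy drives at ``rate``: rectified sum/difference tuning for
    wrist columns, force profile for grip columns."""
    xy = _render_angles(plan, rate)
    amax = spec.amplitude  # session-level normalizer: the comfortable max
    u = xy[:, 0] / amax + xy[:, 1] / amax
    v = xy[:, 0] / amax - xy[:, 1] / amax
    drives = {
        "sum_pos": np.clip(u, 0, None),
        "sum_neg": np.clip(-u, 0, None),
        "diff_pos": np.clip(v, 0, None),
        "diff_neg": np.clip(-v, 0, None),
    }
    force = _render_force(plan, spec, rate)
    n = xy.shape[0]
    M = np.zeros((n, gt.j_total))
    for k, label in enumerate(gt.tuning):
        if label == "grip":
            if force is not None:
                M[:, k] = force
        elif label in drives:
            M[:, k] = drives[label]
            if spec.condition == "stiffened":
                M[:, k] += spec.stiffen_level
        # "untuned" columns stay silent
    return M


def simulate_wrist_trajectory(spec: TrialSpec, seed: int = 0) -> np.ndarray:
    """Simulate the 2-D wrist-angle stream of one trial at the angle rate.

    Returns an (n, 2) array in degrees: column 0 is flexion-extension
    (extension positive), column 1 radial-ulnar deviation (radial positive).
    The trajectory starts and ends at (0, 0); each repetition is a smooth
    raised-cosine excursion whose radial peak equals the trial amplitude.
    """
    rng = np.random.default_rng(seed)
    plan = _plan_trial(spec, rng)
    return _render_angles(plan, spec.angle_rate)


def _simulate_trial(spec: TrialSpec, gt: GroundTruth, seed: int) -> Trial:
    rng = np.random.default_rng(seed)
    plan = _plan_trial(spec, rng)

    M_true = _render_activations(plan, spec, gt, spec.emg_rate)
    E = M_true @ gt.S_true.T

    snr = gt.noise_snr_db
    if snr is not None and np.isfinite(snr):
        # Envelope noise is band-limited to the envelope bandwidth: white
        # Gaussian noise low-passed at 5 Hz, scaled to the requested SNR
        # after filtering.  Unfiltered white noise at 2 kHz would be removed
        # almost entirely by the downstream 5 Hz envelope filter, so the
        # stated SNR would never reach the analysis.
        from scipy import signal as _signal

        noise = rng.normal(0.0, 1.0, E.shape)
        sos = _signal.butter(2, _ENVELOPE_BANDWIDTH_HZ, btype="low",
                             fs=spec.emg_rate, output="sos")
        noise = _signal.sosfiltfilt(sos, noise, axis=0)
        target_rms = np.sqrt(np.mean(E**2)) * 10.0 ** (-snr / 20.0)
        noise *= target_rms / max(np.sqrt(np.mean(noise**2)), 1e-300)
        E = np.clip(E + noise, 0.0, None)

    angles = _render_angles(plan, spec.angle_rate)
    force = _render_force(plan, spec, spec.force_rate)
    return Trial(
        condition=spec.condition,
        emg=E,
        emg_rate=spec.emg_rate,
        angles=angles,
        angle_rate=spec.angle_rate,
        force=force,
        force_rate=spec.force_rate,
        activations_true=M_true,
        spec=spec,
        seed=seed,
    )


def generate_session(
    ground_truth: GroundTruth, protocol: list, seed: int = 0
) -> Session:
    """Generate one session: one :class:`Trial` per :class:`TrialSpec`.

    All randomness (direction jitter, envelope noise) derives from ``seed``
    through per-trial spawned seed sequences, so identical
    ``(ground_truth, protocol, seed)`` gives a bit-identical session.
    """
    if not protocol:
        raise ValueError("protocol must contain at least one TrialSpec")
    if ground_truth.n_channels != len(ground_truth.channel_labels):
        raise ValueError("ground truth channel count/label mismatch")
    children = np.random.SeedSequence(seed).spawn(len(protocol))
    trials = []
    for spec, child in zip(protocol, children):
        trial_seed = int(child.generate_state(1)[0] % (2**31))
        trials.append(_simulate_trial(spec, ground_truth, trial_seed))
    return Session(ground_truth=ground_truth, trials=tuple(trials), seed=seed)


def default_protocol(
    n_trials: int = 3, n_reps: int = 3, **spec_kwargs
) -> list:
    """The study protocol: three trials each of the four wrist-movement
    conditions and of grip-only, plus one graded-force trial per level."""
    protocol = []
    for cond in ("comfortable_max", "comfortable_half", "stiffened",
                 "max_with_grip", "grip_only"):
        protocol += [
            TrialSpec(condition=cond, n_reps=n_reps, **spec_kwargs)
            for _ in range(n_trials)
        ]
    for cond in ("force_max", "force_half", "force_quarter"):
        protocol.append(TrialSpec(condition=cond, n_reps=n_reps, **spec_kwargs))
    return protocol
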