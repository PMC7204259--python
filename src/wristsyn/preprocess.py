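"""Raw EMG to normalized quasi-tension, and cross-stream alignment.

The envelope ("quasi-tension") chain is: full-wave rectification, 2nd-order
Butterworth low-pass at 5 Hz, normalization of each channel by its peak over
the whole task, and resampling of all streams onto a common rate (the 74 Hz
angle rate by default, the slowest stream).

Filtering is causal (single-pass ``lfilter``) by default, the appropriate
choice for on-line prosthesis control; ``zero_phase=True`` switches to
forward-backward ``filtfilt`` for offline analysis, where filter lag would
bias the regression between envelopes and kinematics.  Filter undershoot is
clipped at zero so envelopes stay nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import DataError, DegenerateDataError
from .simulate import CHANNELS, Session

__all__ = [
    "RawEMG",
    "EnvelopeMatrix",
    "AlignedTrial",
    "rectify",
    "lowpass_envelope",
    "normalize_by_task_peak",
    "resample_series",
    "preprocess_session",
]


@dataclass(frozen=True)
class RawEMG:
    """Time-by-channel EMG samples (may be negative) with rate and labels."""

    samples: np.ndarray
    rate: float
    channel_labels: tuple = CHANNELS

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D time-by-channel array")
        if len(self.channel_labels) != self.samples.shape[1]:
            raise ValueError("channel label count does not match columns")


@dataclass(frozen=True)
class EnvelopeMatrix:
    """Nonnegative time-by-channel envelope matrix.

    ``normalization_peaks`` holds the per-channel divisors once the envelope
    has been task-peak normalized (``None`` before normalization).
    """

    E: np.ndarray
    rate: float
    channel_labels: tuple = CHANNELS
    normalization_peaks: np.ndarray | None = None


def rectify(raw: RawEMG) -> RawEMG:
    """Full-wave rectification (elementwise absolute value)."""
    if np.isnan(raw.samples).any():
        raise DataError("EMG contains NaN samples")
    return RawEMG(np.abs(raw.samples), raw.rate, raw.channel_labels)


def lowpass_envelope(
    raw: RawEMG,
    cutoff: float = 5.0,
    order: int = 2,
    *,
    zero_phase: bool = False,
) -> EnvelopeMatrix:
    """Butterworth low-pass of a rectified signal, clipped at zero.

    Parameters
    ----------
    cutoff : float
        Cutoff frequency in Hz; must be below the Nyquist rate.
    order : int
        Filter order (2 by default).
    zero_phase : bool
        Apply the filter forward and backward (``filtfilt``) instead of the
        causal single pass.
    """
    if cutoff <= 0 or order < 1:
        raise ValueError("cutoff must be positive and order >= 1")
    if cutoff >= raw.rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz is not below the Nyquist rate {raw.rate / 2} Hz"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=raw.rate, output="sos")
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, raw.samples, axis=0)
    else:
        filtered = signal.sosfilt(sos, raw.samples, axis=0)
    return EnvelopeMatrix(
        np.clip(filtered, 0.0, None), raw.rate, raw.channel_labels
    )


def normalize_by_task_peak(
    envelopes: list[EnvelopeMatrix],
    peaks: np.ndarray | None = None,
) -> tuple[list[EnvelopeMatrix], np.ndarray]:
    """Divide each channel by its peak over all provided trials.

    Session-level electrode-gain differences cancel under this shared
    per-channel normalization.  Pass previously fitted ``peaks`` to apply the
    same divisors to later data.

    Returns the normalized envelopes and the peak vector used.
    """
    if not envelopes:
        raise ValueError("need at least one envelope")
    labels = envelopes[0].channel_labels
    for env in envelopes:
        if env.channel_labels != labels:
            raise ValueError("inconsistent channel sets across trials")
    if peaks is None:
        peaks = np.max(
            [env.E.max(axis=0) for env in envelopes], axis=0
        )
    peaks = np.asarray(peaks, dtype=float)
    zero = np.flatnonzero(peaks <= 0)
    if zero.size:
        names = ", ".join(labels[i] for i in zero)
        raise DegenerateDataError(
            f"channel(s) with zero peak activation: {names}"
        )
    out = [
        EnvelopeMatrix(env.E / peaks, env.rate, env.channel_labels, peaks)
        for env in envelopes
    ]
    return out, peaks


def resample_series(
    series: np.ndarray, from_rate: float, to_rate: float
) -> np.ndarray:
    """Linear interpolation onto a grid at ``to_rate`` spanning the same
    duration; the first and last samples are preserved."""
    if from_rate <= 0 or to_rate <= 0:
        raise ValueError("rates must be positive")
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise DataError("series must have at least 2 samples to resample")
    duration = (n - 1) / from_rate
    t_src = np.arange(n) / from_rate
    n_out = max(2, int(round(duration * to_rate)) + 1)
    t_out = np.linspace(0.0, duration, n_out)
    out = np.column_stack([np.interp(t_out, t_src, x[:, c]) for c in range(x.shape[1])])
    return out[:, 0] if squeeze else out


def _resample_to_grid(series: np.ndarray, rate: float, t_out: np.ndarray) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    t_src = np.arange(x.shape[0]) / rate
    out = np.column_stack([np.interp(t_out, t_src, x[:, c]) for c in range(x.shape[1])])
    return out[:, 0] if squeeze else out


@dataclass(frozen=True)
class AlignedTrial:
    """One trial with all streams on a common time grid, envelope normalized."""

    condition: str
    E: np.ndarray             # (n, n_channels) normalized envelope
    angles: np.ndarray        # (n, 2) degrees
    force: np.ndarray | None  # (n,) normalized grip force
    rate: float
    channel_labels: tuple = CHANNELS


def preprocess_session(
    session: Session,
    *,
    cutoff: float = 5.0,
    order: int = 2,
    zero_phase: bool = True,
    target_rate: float = 74.0,
    rectify_filter: bool = True,
) -> list[AlignedTrial]:
    """Full preprocessing of a simulated (or loaded) session.

    Each trial's EMG is rectified and low-pass filtered (skip with
    ``rectify_filter=False`` when the input is already an envelope), all
    streams are resampled onto the ``target_rate`` grid defined by the trial
    duration, and channels are normalized by their peak across the whole
    session.  Offline analysis defaults to zero-phase filtering.
    """
    labels = session.ground_truth.channel_labels
    envelopes = []
    grids = []
    for trial in session.trials:
        raw = RawEMG(trial.emg, trial.emg_rate, labels)
        if rectify_filter:
            env = lowpass_envelope(rectify(raw), cutoff, order, zero_phase=zero_phase)
        else:
            env = EnvelopeMatrix(np.clip(raw.samples, 0.0, None), raw.rate, labels)
        duration = (trial.angles.shape[0] - 1) / trial.angle_rate
        n_out = max(2, int(round(duration * target_rate)) + 1)
        t_out = np.linspace(0.0, duration, n_out)
        grids.append(t_out)
        env_rs = _resample_to_grid(env.E, env.rate, t_out)
        envelopes.append(EnvelopeMatrix(np.clip(env_rs, 0.0, None), target_rate, labels))

    envelopes, peaks = normalize_by_task_peak(envelopes)

    aligned = []
    for trial, env, t_out in zip(session.trials, envelopes, grids):
        angles = _resample_to_grid(trial.angles, trial.angle_rate, t_out)
        force = (
            _resample_to_grid(trial.force, trial.force_rate, t_out)
            if trial.force is not None
            else None
        )
        aligned.append(
            AlignedTrial(
                condition=trial.condition,
                E=env.E,
                angles=angles,
                force=force,
                rate=target_rate,
                channel_labels=labels,
            )
        )
    return aligned
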