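"""Raw EMG to normalized linear envelopes.

The chain is the standard one for gait EMG: zero-lag 4th-order Butterworth
high-pass at 20 Hz (removes motion artifact and offset), demean, full-wave
rectification, zero-lag 4th-order Butterworth low-pass at 25 Hz (the linear
envelope), then amplitude normalization to the averaged per-stride peak.
Peak-during-walking normalization is used instead of maximum voluntary
contraction because MVC is unreliable in populations with impaired
voluntary drive (post-stroke hemiparesis in particular).

"Zero lag" is realized by running each filter forward and backward
(``scipy.signal.sosfiltfilt``) with reflected padding, so burst timing is
not skewed by filter group delay. Tiny negative excursions left by the
low-pass ringing are clipped to zero so integrated amplitudes stay
nonnegative.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import ConfigError, DegenerateChannelError, InsufficientDataError
from .io import EmgRecording

__all__ = ["EnvelopeRecording", "filter_chain", "normalize_to_step_peaks"]

HIGHPASS_HZ = 20.0
LOWPASS_HZ = 25.0
FILTER_ORDER = 4

#: divisors below this are treated as a flat (degenerate) channel
_FLAT_EPS = 1e-12


@dataclass
class EnvelopeRecording:
    """Per-channel nonnegative linear envelopes.

    ``normalization_peaks`` holds the per-channel averaged stride peak used
    as divisor (``None`` before normalization). After normalization the
    envelope is on an averaged-peak-relative scale: individual strides may
    exceed 1, but the mean stride peak is 1 by construction.
    """

    envelopes: np.ndarray
    rate_hz: float
    channel_names: tuple[str, ...]
    leg: str = "left"
    subject_id: str = ""
    normalization_peaks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.envelopes = np.atleast_2d(np.asarray(self.envelopes, dtype=float))
        self.channel_names = tuple(self.channel_names)
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be positive")
        if self.envelopes.shape[0] != len(self.channel_names):
            raise ConfigError("channel count does not match channel_names")
        if np.any(self.envelopes < 0):
            raise ConfigError("envelopes must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.envelopes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.envelopes.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def channel(self, name: str) -> np.ndarray:
        return self.envelopes[self.channel_names.index(name)]


def filter_chain(
    emg: EmgRecording,
    highpass_hz: float = HIGHPASS_HZ,
    lowpass_hz: float = LOWPASS_HZ,
    order: int = FILTER_ORDER,
) -> EnvelopeRecording:
    """High-pass, demean, rectify, low-pass: raw EMG -> unnormalized envelope.

    The demean step is kept after the high-pass (its effect is negligible
    once DC is removed, but the processing order is part of the contract).
    """
    nyquist = emg.rate_hz / 2.0
    if lowpass_hz >= nyquist or highpass_hz >= nyquist:
        raise ConfigError(
            f"sampling rate {emg.rate_hz} Hz too low for cutoffs "
            f"{highpass_hz}/{lowpass_hz} Hz"
        )
    sos_hp = signal.butter(order, highpass_hz, "highpass", fs=emg.rate_hz, output="sos")
    sos_lp = signal.butter(order, lowpass_hz, "lowpass", fs=emg.rate_hz, output="sos")
    x = signal.sosfiltfilt(sos_hp, emg.signals, axis=1, padtype="even")
    x = x - x.mean(axis=1, keepdims=True)
    x = np.abs(x)
    x = signal.sosfiltfilt(sos_lp, x, axis=1, padtype="even")
    np.clip(x, 0.0, None, out=x)
    return EnvelopeRecording(
        envelopes=x,
        rate_hz=emg.rate_hz,
        channel_names=emg.channel_names,
        leg=emg.leg,
        subject_id=emg.subject_id,
    )


def normalize_to_step_peaks(env: EnvelopeRecording, strides: Sequence) -> EnvelopeRecording:
    """Normalize each channel to its averaged peak activation across strides.

    The divisor for a channel is the mean, over all complete strides, of the
    envelope maximum within that stride. A channel whose divisor is ~0 is
    flat and cannot be normalized meaningfully.
    """
    if len(strides) < 1:
        raise InsufficientDataError("normalization needs at least one complete stride")
    t = env.times
    dt = 1.0 / env.rate_hz
    peaks = np.zeros((env.n_channels, len(strides)))
    for j, seg in enumerate(strides):
        t0, t1 = seg.boundaries[0], seg.boundaries[-1]
        sel = (t >= t0) & (t < t1)
        if not sel.any():
            raise InsufficientDataError(
                f"stride [{t0:.3f}, {t1:.3f}) s contains no envelope samples "
                f"(dt = {dt:.4f} s)"
            )
        peaks[:, j] = env.envelopes[:, sel].max(axis=1)
    divisors = peaks.mean(axis=1)
    for name, d in zip(env.channel_names, divisors):
        if d <= _FLAT_EPS:
            raise DegenerateChannelError(
                f"channel {name!r} is flat (averaged stride peak {d:.3g})"
            )
    return EnvelopeRecording(
        envelopes=env.envelopes / divisors[:, None],
        rate_hz=env.rate_hz,
        channel_names=env.channel_names,
        leg=env.leg,
        subject_id=env.subject_id,
        normalization_peaks=divisors,
    )
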