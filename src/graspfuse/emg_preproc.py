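"""Surface-EMG preprocessing chain.

Raw multichannel EMG is band-pass filtered (40--500 Hz Butterworth,
zero-phase), converted to a sliding root-mean-square envelope
(150 samples, 96 ms at 1,562.5 Hz), normalized per channel to the
maximum envelope value of a maximum-voluntary-contraction (MVC)
recording processed the same way, and finally cut into sliding windows
of 320 ms with 32 ms overlap between consecutive windows.  Feature
extraction and classification operate on those windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "DEFAULT_RATE_HZ",
    "MUSCLES",
    "EmgTrial",
    "EnvelopeSeries",
    "WindowConfig",
    "EmgWindow",
    "DegenerateReferenceError",
    "bandpass_filter",
    "rms_envelope",
    "mvc_normalize",
    "make_windows",
    "preprocess_trial",
]

#: Sampling rate of the EMG acquisition chain, in Hz.
DEFAULT_RATE_HZ = 1562.5

#: The 12 recorded muscles (arm, forearm and hand), in channel order.
MUSCLES = (
    "FDI", "APB", "FDM", "EI", "EDC", "FDS",
    "BRD", "ECR", "ECU", "FCU", "BIC", "TRI",
)


class DegenerateReferenceError(ValueError):
    """Raised when an MVC reference channel has a non-positive envelope maximum."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class EmgTrial:
    """One multichannel EMG recording.

    ``samples`` is a C x N float matrix (C channels, N samples); volts at
    arbitrary amplifier gain.  ``gesture_id`` is the grasp label executed
    during the trial (0 = open palm / rest, 1..13 = grasp taxonomy).
    """

    samples: np.ndarray
    rate_hz: float = DEFAULT_RATE_HZ
    channel_names: tuple[str, ...] = MUSCLES
    gesture_id: int = 0
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a C x N matrix")
        c, n = self.samples.shape
        if len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if n < 1:
            raise ValueError("trial must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class EnvelopeSeries:
    """Non-negative RMS envelope, same C x N shape as its source trial."""

    values: np.ndarray
    rate_hz: float
    channel_names: tuple[str, ...]
    rms_window_samples: int = 150

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("envelope must be a C x N matrix")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class WindowConfig:
    """Sliding-window geometry: 320 ms windows overlapping by 32 ms."""

    window_ms: float = 320.0
    overlap_ms: float = 32.0
    rate_hz: float = DEFAULT_RATE_HZ
    window_samples: int = field(init=False)
    stride_samples: int = field(init=False)

    def __post_init__(self) -> None:
        self.window_samples = _round_half_up(self.window_ms * self.rate_hz / 1000.0)
        overlap = _round_half_up(self.overlap_ms * self.rate_hz / 1000.0)
        if not 0 <= overlap < self.window_samples:
            raise ValueError("overlap must satisfy 0 <= overlap < window")
        self.stride_samples = self.window_samples - overlap


@dataclass
class EmgWindow:
    """One C x window_samples slice with the timestamp of its last sample."""

    X: np.ndarray
    t_end_s: float
    start: int

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    def center_sample(self) -> int:
        return self.start + self.X.shape[1] // 2


def bandpass_filter(
    trial: EmgTrial, low_hz: float = 40.0, high_hz: float = 500.0, order: int = 4
) -> EmgTrial:
    """Zero-phase Butterworth band-pass, applied independently per channel.

    The high-pass edge removes motion artifact and DC; the low-pass edge
    removes high-frequency noise outside the usual surface-EMG band.  The
    filter is applied forward-backward (``sosfiltfilt``), so the envelope
    timing is not delayed relative to the raw signal.
    """
    nyq = trial.rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"cutoffs must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=trial.rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, trial.samples, axis=1)
    return EmgTrial(
        samples=filtered,
        rate_hz=trial.rate_hz,
        channel_names=trial.channel_names,
        gesture_id=trial.gesture_id,
        trial_id=trial.trial_id,
    )


def rms_envelope(trial: EmgTrial, window_samples: int = 150) -> EnvelopeSeries:
    """Sliding root-mean-square amplitude envelope.

    Element ``i`` is the RMS of the centered length-``window_samples``
    neighbourhood of sample ``i``; at the edges the window is truncated to
    the available samples, so the output keeps the input's C x N shape.
    """
    n = trial.n_samples
    if window_samples > n:
        raise ValueError(
            f"envelope window ({window_samples}) longer than signal ({n})"
        )
    if window_samples < 1:
        raise ValueError("window_samples must be >= 1")
    sq = trial.samples**2
    csum = np.concatenate(
        [np.zeros((trial.n_channels, 1)), np.cumsum(sq, axis=1)], axis=1
    )
    idx = np.arange(n)
    half = window_samples // 2
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (window_samples - half), n)
    counts = (hi - lo).astype(float)
    mean_sq = (csum[:, hi] - csum[:, lo]) / counts
    return EnvelopeSeries(
        values=np.sqrt(np.maximum(mean_sq, 0.0)),
        rate_hz=trial.rate_hz,
        channel_names=trial.channel_names,
        rms_window_samples=window_samples,
    )


def mvc_normalize(env: EnvelopeSeries, mvc_env: EnvelopeSeries) -> EnvelopeSeries:
    """Divide each channel by that channel's MVC envelope maximum.

    The MVC recording must have been processed with the same filter and
    envelope settings as the task data.  Output is dimensionless (fraction
    of maximum voluntary contraction).
    """
    if env.channel_names != mvc_env.channel_names:
        raise ValueError("task and MVC envelopes have different channel sets")
    ref = mvc_env.values.max(axis=1)
    bad = np.flatnonzero(ref <= 0)
    if bad.size:
        names = ", ".join(env.channel_names[i] for i in bad)
        raise DegenerateReferenceError(
            f"MVC envelope maximum is zero on channel(s): {names}"
        )
    return EnvelopeSeries(
        values=env.values / ref[:, None],
        rate_hz=env.rate_hz,
        channel_names=env.channel_names,
        rms_window_samples=env.rms_window_samples,
    )


def make_windows(env: EnvelopeSeries, cfg: WindowConfig | None = None) -> list[EmgWindow]:
    """Cut an envelope into sliding windows; trailing partial samples are dropped.

    Window count is ``floor((N - window) / stride) + 1``.  Each window
    records the timestamp of its last sample.
    """
    if cfg is None:
        cfg = WindowConfig(rate_hz=env.rate_hz)
    w, s = cfg.window_samples, cfg.stride_samples
    n = env.n_samples
    if n < w:
        raise ValueError(f"signal ({n} samples) shorter than one window ({w})")
    starts = range(0, n - w + 1, s)
    return [
        EmgWindow(
            X=env.values[:, st : st + w],
            t_end_s=(st + w - 1) / env.rate_hz,
            start=st,
        )
        for st in starts
    ]


def preprocess_trial(
    trial: EmgTrial,
    mvc: EmgTrial,
    cfg: WindowConfig | None = None,
    low_hz: float = 40.0,
    high_hz: float = 500.0,
    rms_window_samples: int = 150,
) -> list[EmgWindow]:
    """Full chain: filter -> envelope -> MVC-normalize -> windows."""
    env = rms_envelope(bandpass_filter(trial, low_hz, high_hz), rms_window_samples)
    mvc_env = rms_envelope(bandpass_filter(mvc, low_hz, high_hz), rms_window_samples)
    norm = mvc_normalize(env, mvc_env)
    return make_windows(norm, cfg)
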