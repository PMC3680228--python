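"""Noise and background-activity removal for surface EMG.

The chain is: zero-phase Butterworth bandpass (10–450 Hz, 4th order per
pass), estimation of a per-subject noise magnitude-spectrum template
from a background (rest) recording, and short-time spectral subtraction
of that template from the flexion recordings.  The template is
re-estimated per subject/session — the spectrum of background activity
varies too much between sessions for a fixed filter to work — which is
what makes the subtraction adaptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import EMGRecording

__all__ = [
    "FilterSpec",
    "NoiseTemplate",
    "DegenerateRecordingError",
    "rms_normalize",
    "bandpass",
    "estimate_noise_template",
    "spectral_subtract",
]


class DegenerateRecordingError(ValueError):
    """Raised for inputs the pipeline cannot meaningfully process (e.g. all-zero)."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass design (applied forward–backward, zero phase)."""

    order: int = 4
    low_hz: float = 10.0
    high_hz: float = 450.0

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high_hz={self.high_hz} must be below the Nyquist rate {fs / 2}"
            )

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return sps.butter(self.order, [self.low_hz, self.high_hz],
                          btype="bandpass", fs=fs, output="sos")


@dataclass(frozen=True)
class NoiseTemplate:
    """Average one-sided magnitude spectrum of background activity.

    Frames are ``window_len`` samples, Hann-windowed; the template is the
    mean magnitude over ``n_windows_averaged`` frames, matching the STFT
    framing used by :func:`spectral_subtract`.
    """

    magnitude_spectrum: np.ndarray
    window_len: int
    n_windows_averaged: int
    fs: float

    def __post_init__(self):
        spec = np.asarray(self.magnitude_spectrum, dtype=float)
        if np.any(spec < 0):
            raise ValueError("noise template bins must be non-negative")
        if len(spec) != self.window_len // 2 + 1:
            raise ValueError("template length must be window_len/2 + 1 (one-sided)")
        if self.n_windows_averaged < 20:
            raise ValueError("noise template needs at least 20 averaged windows")
        object.__setattr__(self, "magnitude_spectrum", spec)


def _samples(x) -> np.ndarray:
    return x.samples if isinstance(x, EMGRecording) else np.asarray(x, dtype=float)


def _like(x, samples: np.ndarray):
    return x.with_samples(samples) if isinstance(x, EMGRecording) else samples


def rms_normalize(recording):
    """Scale a recording so its root-mean-square value is exactly 1."""
    x = _samples(recording)
    if x.size == 0:
        raise DegenerateRecordingError("empty recording")
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0.0:
        raise DegenerateRecordingError("all-zero recording has undefined RMS scale")
    return _like(recording, x / rms)


def bandpass(recording, spec: FilterSpec = FilterSpec(), fs: float | None = None):
    """Zero-phase bandpass; forward–backward application keeps maxima in place."""
    x = _samples(recording)
    if fs is None:
        if not isinstance(recording, EMGRecording):
            raise ValueError("fs required when filtering a bare array")
        fs = recording.fs
    return _like(recording, sps.sosfiltfilt(spec.sos(fs), x))


def _frames(x: np.ndarray, window_len: int, hop: int) -> np.ndarray:
    """Hann-windowed overlapping frames of a signal padded by half a window."""
    pad = window_len // 2
    xp = np.pad(x, (pad, pad + window_len))
    n_frames = 1 + (len(xp) - window_len) // hop
    idx = np.arange(window_len)[None, :] + hop * np.arange(n_frames)[:, None]
    win = sps.get_window("hann", window_len, fftbins=True)
    return xp[idx] * win[None, :]


def estimate_noise_template(background, window_len: int = 256,
                            n_windows: int | None = None,
                            filter_spec: FilterSpec = FilterSpec(),
                            fs: float | None = None) -> NoiseTemplate:
    """Average the one-sided magnitude spectrum of a rest recording.

    The background trace is bandpassed first; at least 20 Hann windows at
    50% overlap must fit, otherwise the recording is too short.
    """
    if fs is None:
        if not isinstance(background, EMGRecording):
            raise ValueError("fs required for a bare array")
        fs = background.fs
    x = _samples(bandpass(background, filter_spec, fs=fs))
    hop = window_len // 2
    available = 1 + max(len(x) - window_len, 0) // hop
    if n_windows is None:
        n_windows = available
    if n_windows < 20:
        raise ValueError("noise template requires at least 20 windows")
    if available < n_windows:
        need = window_len + (n_windows - 1) * hop
        raise ValueError(
            f"background too short: {len(x)} samples, need {need} for "
            f"{n_windows} windows of {window_len} at 50% overlap"
        )
    win = sps.get_window("hann", window_len, fftbins=True)
    starts = hop * np.arange(n_windows)
    idx = np.arange(window_len)[None, :] + starts[:, None]
    mags = np.abs(np.fft.rfft(x[idx] * win[None, :], axis=1))
    return NoiseTemplate(magnitude_spectrum=mags.mean(axis=0),
                         window_len=window_len,
                         n_windows_averaged=int(n_windows), fs=float(fs))


def spectral_subtract(recording, template: NoiseTemplate,
                      oversubtraction_alpha: float = 1.0):
    """Remove the template spectrum from each short-time frame.

    Frame magnitude becomes ``max(|X| − α·template, 0)``; the noisy phase
    is kept and the signal is rebuilt by overlap-add.  With a Hann
    window at 50% overlap the unmodified transform reconstructs the
    input exactly, so a zero template is the identity.
    """
    x = _samples(recording)
    fs = recording.fs if isinstance(recording, EMGRecording) else template.fs
    if abs(fs - template.fs) > 1e-9:
        raise ValueError("template sampling rate does not match the recording")
    window_len = template.window_len
    hop = window_len // 2
    pad = window_len // 2

    frames = _frames(x, window_len, hop)
    spec = np.fft.rfft(frames, axis=1)
    mag = np.abs(spec)
    new_mag = np.maximum(mag - oversubtraction_alpha * template.magnitude_spectrum, 0.0)
    phase = np.angle(spec)
    rebuilt = np.fft.irfft(new_mag * np.exp(1j * phase), n=window_len, axis=1)

    out = np.zeros(pad + len(x) + pad + window_len)
    for i, frame in enumerate(rebuilt):
        out[i * hop: i * hop + window_len] += frame
    return _like(recording, out[pad: pad + len(x)])
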