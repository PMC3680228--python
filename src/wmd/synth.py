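"""Synthetic single-channel surface EMG.

Generates sparse motor-unit action-potential (MUAP) trains from several
muscle sources, each attenuated by a source-specific volume-conduction
gain, superposed with band-limited additive noise.  Different finger
flexions are encoded as different active sources: because body tissue
attenuates potentials with distance, each muscle's MUAPs arrive at a
fixed electrode with a characteristic amplitude, which is the premise
the downstream wavelet-maxima analysis exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy import signal as sps

__all__ = [
    "MuapTemplate",
    "MuscleSource",
    "EMGRecording",
    "LabeledDataset",
    "make_template",
    "simulate_recording",
    "generate_dataset",
    "BACKGROUND_LABEL",
    "class_label",
]

BACKGROUND_LABEL = "background"

_SEED_MOD = 2**31


def class_label(k: int) -> str:
    """Canonical label for flexion class ``k`` (1-based)."""
    return f"class{k}"


@dataclass(frozen=True)
class MuapTemplate:
    """A single motor-unit action-potential waveform.

    ``samples`` is peak-normalized (max absolute value 1) and zero-mean;
    ``duration_ms`` is the support of the waveform in milliseconds.
    """

    samples: np.ndarray
    duration_ms: float

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(s)):
            raise ValueError("MUAP template contains non-finite samples")
        peak = np.max(np.abs(s))
        if not np.isclose(peak, 1.0):
            raise ValueError("MUAP template must be peak-normalized to 1")
        if abs(s.mean()) > 0.05 * peak:
            raise ValueError("MUAP template mean exceeds 5% of peak")
        if not (5.0 <= self.duration_ms <= 20.0):
            raise ValueError("MUAP duration must lie in [5, 20] ms")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class MuscleSource:
    """One muscle as seen by the electrode.

    ``amplitude_gain`` models volume-conduction attenuation (larger =
    closer muscle); ``firing_rate`` is the motor-unit discharge rate in
    pulses/s; ``jitter_cv`` the coefficient of variation of the
    inter-pulse interval of the renewal firing process.
    """

    template: MuapTemplate
    amplitude_gain: float
    firing_rate: float
    jitter_cv: float = 0.15

    def __post_init__(self):
        if self.amplitude_gain <= 0:
            raise ValueError("amplitude_gain must be > 0")
        if self.firing_rate != 0 and not (5.0 <= self.firing_rate <= 35.0):
            raise ValueError("firing_rate must be 0 or in [5, 35] pulses/s")
        if not (0.0 <= self.jitter_cv <= 0.5):
            raise ValueError("jitter_cv must lie in [0, 0.5]")


@dataclass(frozen=True)
class EMGRecording:
    """A sampled single-channel sEMG trace with trial metadata."""

    samples: np.ndarray
    fs: float
    label: str = BACKGROUND_LABEL
    trial_id: int = 0
    subject_id: str = "S1"

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float)
        )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "EMGRecording":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class LabeledDataset:
    """Flexion recordings plus background segments for one synthetic subject."""

    recordings: list[EMGRecording]
    class_names: list[str]
    seed: int
    amplitude_gains: list[float] = field(default_factory=list)

    @property
    def flexions(self) -> list[EMGRecording]:
        return [r for r in self.recordings if r.label != BACKGROUND_LABEL]

    @property
    def background(self) -> list[EMGRecording]:
        return [r for r in self.recordings if r.label == BACKGROUND_LABEL]


def make_template(duration_ms: float, n_phases: int = 2, fs: float = 1024.0) -> MuapTemplate:
    """Build a smooth biphasic or triphasic MUAP waveform.

    The shape is the first (biphasic) or second (triphasic) derivative of
    a Gaussian — the standard idealization of a propagating action
    potential seen through a bipolar electrode.  Deterministic: the same
    arguments always yield the same waveform.
    """
    if duration_ms <= 0 or fs <= 0:
        raise ValueError("duration_ms and fs must be positive")
    if not (5.0 <= duration_ms <= 20.0):
        raise ValueError("duration_ms must lie in [5, 20] ms")
    if n_phases not in (2, 3):
        raise ValueError("n_phases must be 2 or 3")
    if fs <= 2 * 450.0:
        raise ValueError("fs must exceed twice the 450 Hz signal band")
    n = int(round(duration_ms * fs / 1000.0))
    n = max(n, 3)
    t = np.linspace(-1.0, 1.0, n)
    sigma = 0.35
    g = np.exp(-(t**2) / (2 * sigma**2))
    w = -t * g if n_phases == 2 else (t**2 / sigma**2 - 1.0) * g
    w = w - w.mean()
    w = w / np.max(np.abs(w))
    return MuapTemplate(samples=w, duration_ms=float(duration_ms))


def _spike_times(rate: float, jitter_cv: float, duration_s: float, rng) -> np.ndarray:
    """Renewal process: Gaussian-jittered inter-pulse intervals."""
    if rate <= 0:
        return np.empty(0)
    mean_ipi = 1.0 / rate
    # First firing uniform within one mean interval so trains are not phase-locked.
    t = rng.uniform(0.0, mean_ipi)
    times = []
    while t < duration_s:
        times.append(t)
        ipi = mean_ipi * (1.0 + jitter_cv * rng.standard_normal())
        t += max(ipi, 0.1 * mean_ipi)
    return np.asarray(times)


def _bandlimited_noise(n: int, fs: float, rms: float, rng,
                       band=(20.0, 450.0), drift_amplitude: float = 0.0,
                       drift_hz: float = 0.5) -> np.ndarray:
    """White Gaussian noise shaped to the amplifier band, exact target RMS."""
    if rms <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    high = min(band[1], 0.99 * fs / 2)
    sos = sps.butter(4, [band[0], high], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    shaped *= rms / np.sqrt(np.mean(shaped**2))
    if drift_amplitude > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        shaped = shaped + drift_amplitude * np.sin(2 * np.pi * drift_hz * t + phase)
    return shaped


def simulate_recording(sources: list[MuscleSource], duration_s: float, fs: float,
                       noise_rms: float, seed: int, *, active_index: int | None = None,
                       label: str = BACKGROUND_LABEL, trial_id: int = 0,
                       subject_id: str = "S1",
                       drift_amplitude: float = 0.0) -> EMGRecording:
    """Superpose gain-scaled MUAP trains from every source plus noise.

    Each source draws its spike train from an independent stream seeded
    by ``seed + source index`` so that simulating a union of sources
    equals the sample-wise sum of the separate simulations (noise off).
    The noise stream uses its own offset.
    """
    if not sources:
        raise ValueError("at least one muscle source is required")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if noise_rms < 0:
        raise ValueError("noise_rms must be >= 0")
    if active_index is not None and not (0 <= active_index < len(sources)):
        raise ValueError("active_index out of range")

    n = int(round(duration_s * fs))
    out = np.zeros(n)
    for i, src in enumerate(sources):
        rng = default_rng((seed + i) % _SEED_MOD)
        times = _spike_times(src.firing_rate, src.jitter_cv, duration_s, rng)
        tpl = src.amplitude_gain * src.template.samples
        m = len(tpl)
        for t in times:
            start = int(round(t * fs))
            stop = min(start + m, n)
            if start < n:
                out[start:stop] += tpl[: stop - start]
    if noise_rms > 0 or drift_amplitude > 0:
        noise_rng = default_rng((seed + 999983) % _SEED_MOD)
        out = out + _bandlimited_noise(n, fs, noise_rms, noise_rng,
                                       drift_amplitude=drift_amplitude)
    return EMGRecording(samples=out, fs=fs, label=label,
                        trial_id=trial_id, subject_id=subject_id)


def default_gains(n_classes: int, ratio: float = 1.5, base: float = 1.0) -> list[float]:
    """Geometric amplitude-gain ladder: adjacent muscles differ by ``ratio``."""
    return [base * ratio**k for k in range(n_classes)]


def _trial_seed(master: int, counter: int) -> int:
    """Stable per-trial sub-seed derived from a master seed and a counter."""
    return int(SeedSequence(master, spawn_key=(counter,)).generate_state(1)[0] % _SEED_MOD)


def generate_dataset(n_classes: int = 4, reps: int = 12, flexion_s: float = 7.5,
                     fs: float = 1024.0, amplitude_gains: list[float] | None = None,
                     noise_rms: float = 0.1, seed: int = 0, *,
                     background_s: float = 10.0, active_rate: float = 20.0,
                     background_rate: float = 5.0, jitter_cv: float = 0.15,
                     template: MuapTemplate | None = None,
                     subject_id: str = "S1") -> LabeledDataset:
    """Emulate one subject's recording session.

    ``reps`` flexions of ``flexion_s`` seconds per class; during a
    class-k flexion source k fires at ``active_rate`` pulses/s and the
    other muscles keep a low ``background_rate``.  One background
    recording (no firing, noise only) is included for noise-template
    estimation.
    """
    if amplitude_gains is None:
        amplitude_gains = default_gains(n_classes)
    if len(amplitude_gains) != n_classes:
        raise ValueError("need one amplitude gain per class")
    if len(set(np.round(amplitude_gains, 12))) != n_classes:
        raise ValueError("amplitude gains must be distinct (classes indistinguishable)")
    tpl = template or make_template(10.0, 2, fs)
    class_names = [class_label(k + 1) for k in range(n_classes)]

    recordings: list[EMGRecording] = []
    counter = 0
    bg_sources = [MuscleSource(tpl, g, 0.0, jitter_cv) for g in amplitude_gains]
    recordings.append(
        simulate_recording(bg_sources, background_s, fs, noise_rms,
                           _trial_seed(seed, counter), label=BACKGROUND_LABEL,
                           trial_id=0, subject_id=subject_id))
    counter += 1
    for k in range(n_classes):
        for rep in range(reps):
            sources = [
                MuscleSource(tpl, g,
                             active_rate if j == k else background_rate,
                             jitter_cv)
                for j, g in enumerate(amplitude_gains)
            ]
            recordings.append(
                simulate_recording(sources, flexion_s, fs, noise_rms,
                                   _trial_seed(seed, counter),
                                   active_index=k, label=class_names[k],
                                   trial_id=rep, subject_id=subject_id))
            counter += 1
    return LabeledDataset(recordings=recordings, class_names=class_names,
                          seed=seed, amplitude_gains=list(amplitude_gains))
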