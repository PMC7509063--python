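"""Sine–cosine reference signals and a synthetic multi-subject SSVEP generator.

A steady-state visually evoked potential is an oscillatory occipital response
at the flicker frequency of an attended stimulus and its harmonics.  The
reference signal for stimulus frequency ``f`` stacks sine/cosine pairs at
harmonics ``1..Nh`` sampled on ``t = 1/Fs, 2/Fs, …, M/Fs`` (the time axis
starts at 1/Fs, not 0 — this shifts absolute phases and is kept consistent
everywhere).

The synthetic generator emulates a multi-subject, multi-class SSVEP recording:
each trial is a harmonic series at the stimulus frequency with a
stimulus-specific phase, a subject-specific latency-like phase offset and a
small trial-to-trial phase jitter, projected to the channels through a fixed
forward-mixing profile and buried in white or pink (1/f) noise at a
subject-specific broadband SNR.  A configurable fraction of trials are
attention lapses containing noise only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .msi_core import EpochArray

logger = logging.getLogger(__name__)

__all__ = [
    "StimulusConfig",
    "ReferenceBank",
    "SyntheticSpec",
    "Dataset",
    "make_reference",
    "build_reference_bank",
    "simulate_dataset",
    "twelve_class_keypad",
]


# ---------------------------------------------------------------------------
# stimulus layout


@dataclass(frozen=True)
class StimulusConfig:
    """Stimulus frequency (and optional phase) table for a K-class speller."""

    frequencies: tuple
    phases: tuple | None = None
    refresh_note: str = ""

    def __post_init__(self):
        freqs = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if len(freqs) < 2:
            raise ValueError("need at least 2 stimulus classes")
        if any(f <= 0 for f in freqs):
            raise ValueError("stimulus frequencies must be positive")
        if len(set(freqs)) != len(freqs):
            raise ValueError("stimulus frequencies must be pairwise distinct")
        if self.phases is not None:
            ph = tuple(float(p) for p in self.phases)
            if len(ph) != len(freqs):
                raise ValueError("len(phases) must equal number of frequencies")
            object.__setattr__(self, "phases", ph)

    @property
    def K(self) -> int:
        return len(self.frequencies)

    def phase(self, i: int) -> float:
        return 0.0 if self.phases is None else self.phases[i]


def twelve_class_keypad() -> StimulusConfig:
    """The 12-target joint frequency–phase keypad layout.

    Frequencies span 9.25–14.75 Hz in 0.5 Hz steps arranged in a 4x3 grid;
    phases advance by 0.5π per keypad row (0 to 1.5π).
    """
    freqs, phases = [], []
    for row in range(4):
        for col in range(3):
            freqs.append(9.25 + 0.5 * row + 2.0 * col)
            phases.append(0.5 * np.pi * row)
    return StimulusConfig(tuple(freqs), tuple(phases),
                          refresh_note="60 Hz LCD refresh")


# ---------------------------------------------------------------------------
# sine–cosine references


def make_reference(f: float, fs: float, n_samples: int, n_harmonics: int) -> np.ndarray:
    """Sine–cosine reference matrix for one stimulus frequency.

    Returns a ``2*n_harmonics x n_samples`` matrix whose row ``2h-2`` is
    ``sin(2π·h·f·t)`` and row ``2h-1`` is ``cos(2π·h·f·t)`` for harmonic
    ``h = 1..n_harmonics``, with ``t = 1/fs, 2/fs, …, n_samples/fs``.
    """
    if f <= 0:
        raise ValueError("stimulus frequency must be positive")
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if n_harmonics * f >= fs / 2:
        warnings.warn(
            f"harmonic {n_harmonics}·{f} Hz at or above Nyquist ({fs / 2} Hz)",
            stacklevel=2,
        )
    t = np.arange(1, n_samples + 1) / fs
    rows = []
    for h in range(1, n_harmonics + 1):
        arg = 2.0 * np.pi * h * f * t
        rows.append(np.sin(arg))
        rows.append(np.cos(arg))
    return np.vstack(rows)


class ReferenceBank:
    """Per-class sine–cosine reference matrices at a common full length.

    Window scoring slices columns, which is identical to regenerating the
    reference at the shorter length because the time axis is a fixed grid.
    """

    def __init__(self, stim: StimulusConfig, fs: float, n_samples: int,
                 n_harmonics: int = 3) -> None:
        self.stim = stim
        self.fs = float(fs)
        self.n_samples = int(n_samples)
        self.n_harmonics = int(n_harmonics)
        self._refs = [
            make_reference(f, fs, n_samples, n_harmonics)
            for f in stim.frequencies
        ]

    @property
    def n_classes(self) -> int:
        return self.stim.K

    def reference(self, i: int, n_samples: int | None = None) -> np.ndarray:
        ref = self._refs[i]
        if n_samples is None:
            return ref
        if n_samples > self.n_samples:
            raise ValueError("requested window exceeds bank length")
        return ref[:, : int(n_samples)]


def build_reference_bank(stim: StimulusConfig, fs: float, n_samples: int,
                         n_harmonics: int = 3) -> ReferenceBank:
    return ReferenceBank(stim, fs, n_samples, n_harmonics)


# ---------------------------------------------------------------------------
# synthetic cohort


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic multi-subject SSVEP cohort.

    ``subject_snr_db`` gives each subject's broadband signal-to-noise ratio
    (mean signal power over mean noise power across channels, in dB); the
    default spreads ten subjects evenly over −12…−4 dB, calibrated so that
    the cohort's difficulty profile matches public 12-class SSVEP recordings
    (the weakest subject leaves template methods around 70–90% at 4 s, the
    strongest saturates, and 0.5 s windows are hard for everyone).
    Harmonic amplitudes decay as 1/h through the 5th harmonic: real SSVEPs
    carry harmonic content beyond the truncated sine–cosine references,
    which is precisely what individual-template methods exploit.
    """

    n_subjects: int = 10
    n_trials_per_class: int = 15
    n_channels: int = 8
    duration_s: float = 4.0
    fs: float = 256.0
    harmonic_amplitudes: tuple = (1.0, 1 / 2, 1 / 3, 1 / 4, 1 / 5)
    subject_snr_db: tuple | None = None
    subject_phase_jitter_rad: float = 0.2
    trial_phase_jitter_rad: float = 0.05
    noise_model: str = "pink"
    channel_mixing: np.ndarray | None = None
    lapse_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_trials_per_class", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        if self.noise_model not in ("white", "pink"):
            raise ValueError("noise_model must be 'white' or 'pink'")
        if self.subject_snr_db is None:
            self.subject_snr_db = tuple(
                np.linspace(-12.0, -4.0, self.n_subjects)
            )
        else:
            self.subject_snr_db = tuple(float(s) for s in self.subject_snr_db)
            if len(self.subject_snr_db) != self.n_subjects:
                raise ValueError("need one SNR per subject")
        if self.channel_mixing is None:
            # occipital-gradient forward profile: one source, decaying gains
            self.channel_mixing = np.linspace(1.0, 0.6, self.n_channels)[:, None]
        else:
            self.channel_mixing = np.atleast_2d(np.asarray(self.channel_mixing, float))
            if self.channel_mixing.shape[0] != self.n_channels:
                raise ValueError("channel_mixing must have n_channels rows")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


class Dataset:
    """Nested synthetic/real SSVEP collection: subject → class → trials.

    ``data`` has shape ``(n_subjects, K, n_trials, n_channels, n_samples)``;
    ``lapse_flags`` marks noise-only trials.
    """

    def __init__(self, data: np.ndarray, fs: float, stim: StimulusConfig,
                 lapse_flags: np.ndarray | None = None,
                 subject_snr_db: tuple | None = None) -> None:
        data = np.asarray(data, dtype=float)
        if data.ndim != 5:
            raise ValueError(
                "data must be (subjects, classes, trials, channels, samples)"
            )
        if data.shape[1] != stim.K:
            raise ValueError("class axis does not match stimulus table")
        self.data = data
        self.fs = float(fs)
        self.stim = stim
        if lapse_flags is None:
            lapse_flags = np.zeros(data.shape[:3], dtype=bool)
        self.lapse_flags = np.asarray(lapse_flags, dtype=bool)
        if self.lapse_flags.shape != data.shape[:3]:
            raise ValueError("lapse_flags shape mismatch")
        self.subject_snr_db = subject_snr_db

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_classes(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    @property
    def n_samples(self) -> int:
        return self.data.shape[4]

    def trial(self, subject: int, klass: int, h: int) -> EpochArray:
        return EpochArray(self.data[subject, klass, h], fs=self.fs)

    def trials(self, subject: int, klass: int, indices=None) -> np.ndarray:
        """Stack of trials (n, channels, samples) for one subject/class."""
        if indices is None:
            return self.data[subject, klass]
        return self.data[subject, klass][np.asarray(indices, dtype=int)]


# -- noise -------------------------------------------------------------------


def _white_noise(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.standard_normal(shape)


def _pink_noise(rng: np.random.Generator, shape) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit variance per channel."""
    *lead, n = shape
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite; it is removed by normalization anyway
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n=n, axis=-1)
    out -= out.mean(axis=-1, keepdims=True)
    out /= out.std(axis=-1, keepdims=True)
    return out


def _source_waveform(f: float, phase: float, amplitudes, t: np.ndarray) -> np.ndarray:
    # harmonic h inherits phase h·φ, consistent with a latency shift of a
    # periodic response
    sig = np.zeros_like(t)
    for h, amp in enumerate(amplitudes, start=1):
        sig += amp * np.sin(2.0 * np.pi * h * f * t + h * phase)
    return sig


def simulate_dataset(spec: SyntheticSpec, stim: StimulusConfig) -> Dataset:
    """Generate a reproducible synthetic SSVEP cohort.

    Each non-lapse trial is ``mix @ source`` plus noise scaled per trial so
    that the broadband SNR (mean signal power / mean noise power across
    channels) matches the subject's nominal SNR.  Lapse trials contain only
    noise and are flagged.  All randomness flows from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_s, K = spec.n_subjects, stim.K
    n_n, n_c, M = spec.n_trials_per_class, spec.n_channels, spec.n_samples
    t = np.arange(1, M + 1) / spec.fs
    mix = spec.channel_mixing
    noise_fn = _pink_noise if spec.noise_model == "pink" else _white_noise

    data = np.empty((n_s, K, n_n, n_c, M))
    lapse = np.zeros((n_s, K, n_n), dtype=bool)
    subj_phase = rng.normal(0.0, spec.subject_phase_jitter_rad, size=n_s)

    for p in range(n_s):
        snr_lin = 10.0 ** (spec.subject_snr_db[p] / 10.0)
        for i in range(K):
            f, phi = stim.frequencies[i], stim.phase(i)
            for h in range(n_n):
                noise = noise_fn(rng, (n_c, M))
                if rng.random() < spec.lapse_rate:
                    lapse[p, i, h] = True
                    data[p, i, h] = noise
                    continue
                jitter = rng.normal(0.0, spec.trial_phase_jitter_rad)
                source = _source_waveform(
                    f, phi + subj_phase[p] + jitter, spec.harmonic_amplitudes, t
                )
                signal = mix[:, :1] @ source[None, :] if mix.shape[1] == 1 \
                    else mix @ np.tile(source, (mix.shape[1], 1))
                sig_power = np.mean(signal ** 2)
                noise_power = np.mean(noise ** 2)
                scale = np.sqrt(sig_power / (snr_lin * noise_power))
                data[p, i, h] = signal + scale * noise
    return Dataset(data, fs=spec.fs, stim=stim, lapse_flags=lapse,
                   subject_snr_db=spec.subject_snr_db)
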