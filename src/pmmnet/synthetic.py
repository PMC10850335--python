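"""Seeded generator of EEG-like labeled segments.

Each segment is colored background noise plus (optionally) a class-specific
oscillatory burst: a low-frequency sinusoid sharpened into spike-wave
morphology by the sign-preserving transform sign(sin) * |sin|^(1/s), placed
at a seeded random offset and covering a configurable fraction of the
segment.  Raising the burst amplitude moves the classes apart, so the same
machinery produces anything from a null (label-free) control to a cleanly
separable benchmark.

Segments are grouped into pseudo-recordings of 23 windows, mirroring the
23-chunks-per-recording structure of the real corpora, so group-aware
cross-validation has genuine groups to respect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import Dataset

WINDOWS_PER_RECORDING = 23


@dataclass(frozen=True)
class ClassProfile:
    """Burst morphology of one class."""

    burst_freq: float = 3.0       # cycles per segment (spike-wave-like)
    burst_amplitude: float = 0.0  # 0 disables the burst entirely
    burst_duty: float = 0.3       # fraction of the segment covered
    spike_sharpness: float = 3.0  # waveform exponent; 1 = plain sinusoid

    def __post_init__(self):
        if not 0.0 <= self.burst_duty <= 1.0:
            raise ValueError("burst_duty must lie in [0, 1]")
        if self.burst_amplitude < 0:
            raise ValueError("burst_amplitude must be >= 0")
        if self.spike_sharpness < 1:
            raise ValueError("spike_sharpness must be >= 1")


@dataclass(frozen=True)
class SynthConfig:
    n_per_class: int = 200
    segment_len: int = 178
    classes: tuple[ClassProfile, ...] = (ClassProfile(burst_amplitude=0.0),
                                         ClassProfile(burst_amplitude=5.0))
    noise_sd: float = 1.0
    background: str = "pink"  # pink | white | ar1
    ar_rho: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.segment_len < 16:
            raise ValueError("segment_len must be >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background not in ("pink", "white", "ar1"):
            raise ValueError(f"unknown background {self.background!r}")


def spike_wave(phase: np.ndarray, sharpness: float) -> np.ndarray:
    """Sign-preserving sharpened sinusoid: sign(sin) * |sin|^(1/sharpness)."""
    s = np.sin(phase)
    return np.sign(s) * np.abs(s) ** (1.0 / sharpness)


def _background(rng: np.random.Generator, n: int, length: int, config: SynthConfig) -> np.ndarray:
    """n segments of background noise with marginal SD == noise_sd."""
    if config.noise_sd == 0:
        return np.zeros((n, length))
    if config.background == "white":
        return rng.normal(0.0, config.noise_sd, (n, length))
    if config.background == "ar1":
        rho = config.ar_rho
        eps = rng.normal(0.0, 1.0, (n, length))
        out = np.empty((n, length))
        out[:, 0] = eps[:, 0]
        for t in range(1, length):
            out[:, t] = rho * out[:, t - 1] + np.sqrt(1 - rho ** 2) * eps[:, t]
        return out * config.noise_sd
    # pink: shape white noise by 1/sqrt(f) in the Fourier domain, renormalize
    white = rng.normal(0.0, 1.0, (n, length))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(length)
    weight = np.zeros_like(freqs)
    weight[freqs > 0] = 1.0 / np.sqrt(freqs[freqs > 0])
    shaped = np.fft.irfft(spectrum * weight, n=length, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    return shaped / sd * config.noise_sd


def generate(config: SynthConfig) -> Dataset:
    """Deterministic labeled dataset for the given configuration."""
    rng = np.random.default_rng(config.seed)
    L = config.segment_len
    segments, labels, rec_ids = [], [], []
    for class_idx, profile in enumerate(config.classes):
        noise = _background(rng, config.n_per_class, L, config)
        for i in range(config.n_per_class):
            seg = noise[i].copy()
            if profile.burst_amplitude > 0 and profile.burst_duty > 0:
                burst_len = max(1, int(round(profile.burst_duty * L)))
                offset = int(rng.integers(0, L - burst_len + 1))
                phase0 = rng.uniform(0, 2 * np.pi)
                t = np.arange(burst_len)
                phase = 2 * np.pi * profile.burst_freq * t / L + phase0
                seg[offset:offset + burst_len] += (
                    profile.burst_amplitude * spike_wave(phase, profile.spike_sharpness))
            segments.append(seg)
            labels.append(class_idx)
            recording = i // WINDOWS_PER_RECORDING
            rec_ids.append(f"synth-c{class_idx}-r{recording:04d}")
    return Dataset(np.asarray(segments), np.asarray(labels, dtype=int),
                   np.asarray(rec_ids))


def binary_preset(n_per_class: int = 200, seed: int = 0,
                  amplitude: float = 5.0, noise_sd: float = 1.0,
                  segment_len: int = 178) -> SynthConfig:
    """Separable two-class benchmark: silent background vs spike-wave bursts."""
    return SynthConfig(
        n_per_class=n_per_class, segment_len=segment_len, noise_sd=noise_sd,
        classes=(ClassProfile(burst_amplitude=0.0),
                 ClassProfile(burst_amplitude=amplitude)),
        seed=seed)


def null_preset(n_per_class: int = 200, seed: int = 0,
                noise_sd: float = 1.0, segment_len: int = 178) -> SynthConfig:
    """Null-separability control: both classes are pure background noise."""
    return SynthConfig(
        n_per_class=n_per_class, segment_len=segment_len, noise_sd=noise_sd,
        classes=(ClassProfile(burst_amplitude=0.0),
                 ClassProfile(burst_amplitude=0.0)),
        seed=seed)


PRESETS = {"binary": binary_preset, "null": null_preset}


def export(dataset: Dataset, path) -> None:
    """Write the UCI CSV dialect (id, X1..Xn, y) readable by read_uci_csv."""
    path = Path(path)
    length = dataset.X.shape[1] if len(dataset) else 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id"] + [f"X{i}" for i in range(1, length + 1)] + ["y"])
        for x, y, rid in zip(dataset.X, dataset.y, dataset.record_ids):
            # y column follows the UCI convention: 1 = seizure-like positive
            writer.writerow([rid] + [repr(float(v)) for v in x] + [1 if y == 1 else y + 2])
    return None
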