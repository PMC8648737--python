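"""Deterministic signal-processing primitives shared by every pipeline stage.

Conventions
-----------
The STFT is centered: the signal is reflect-padded by ``nfft // 2`` on the
left, and on the right by whatever completes the last frame, so that the
frame count is exactly ``1 + ceil(len / hop)``.  A periodic Hann analysis
window is applied; inversion applies the same window again as a synthesis
window, overlap-adds, and divides by the accumulated squared window, which
makes ``istft(stft(w))`` exact (to rounding) for any hop at most ``nfft/2``.

dB scaling uses ``20 * log10(magnitude + eps)`` with ``eps = 1e-8`` so the
transform is invertible and finite on silent cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import fftconvolve, firwin, get_window

__all__ = [
    "Waveform",
    "StftConfig",
    "TimeFrequencyRepresentation",
    "SincFilterSpec",
    "stft",
    "istft",
    "db_scale",
    "inv_db_scale",
    "design_highpass",
    "apply_highpass",
    "fix_duration",
    "target_length",
    "read_wav",
    "write_wav",
    "DB_EPS",
]

DB_EPS = 1e-8


@dataclass
class Waveform:
    """Fixed-length mono signal: sample vector plus sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform requires a 1-D sample vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return len(self) / self.rate


@dataclass(frozen=True)
class StftConfig:
    nfft: int
    hop: int
    window: str = "hann"
    centered: bool = True

    def __post_init__(self):
        if not (0 < self.hop <= self.nfft // 2):
            raise ValueError(
                f"hop must satisfy 0 < hop <= nfft/2 for invertibility "
                f"(got nfft={self.nfft}, hop={self.hop})"
            )

    @property
    def n_bins(self) -> int:
        return self.nfft // 2 + 1

    def n_frames(self, length: int) -> int:
        if self.centered:
            return 1 + math.ceil(length / self.hop)
        return 1 + (length - self.nfft) // self.hop


@dataclass
class TimeFrequencyRepresentation:
    """T' x F magnitude (linear or dB) with optional phase and its transform."""

    magnitude: np.ndarray
    phase: np.ndarray | None
    config: StftConfig
    scale: str = "linear"  # {"linear", "db"}

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        if self.magnitude.shape[1] != self.config.n_bins:
            raise ValueError(
                f"expected {self.config.n_bins} frequency bins, got {self.magnitude.shape[1]}"
            )
        if self.scale == "linear" and np.any(self.magnitude < 0):
            raise ValueError("linear-scale magnitude must be nonnegative")


@dataclass(frozen=True)
class SincFilterSpec:
    """Windowed-sinc high-pass: cutoff and transition bandwidth are in
    normalized frequency (cycles/sample, Nyquist = 0.5)."""

    cutoff: float
    transition_bandwidth: float = 0.08
    taps: int | None = None

    def __post_init__(self):
        if not (0.0 < self.cutoff < 0.5):
            raise ValueError("cutoff must lie strictly between 0 and 0.5 cycles/sample")
        if self.transition_bandwidth <= 0:
            raise ValueError("transition bandwidth must be positive")
        if self.taps is not None and self.taps % 2 == 0:
            raise ValueError("taps must be odd (linear-phase Type I FIR)")

    @property
    def n_taps(self) -> int:
        if self.taps is not None:
            return self.taps
        return 2 * math.ceil(2.0 / self.transition_bandwidth) + 1


# -- STFT layout helpers (shared with the differentiable implementation) -------


def stft_layout(length: int, cfg: StftConfig):
    """Return (pad_map, frame_idx, window) realizing the centered-STFT
    convention.  ``pad_map`` indexes the original signal to produce the
    reflect-padded one; ``frame_idx`` is (T', nfft) into the padded signal."""
    if length < cfg.nfft:
        raise ValueError(f"signal of {length} samples shorter than one window ({cfg.nfft})")
    win = get_window(cfg.window, cfg.nfft, fftbins=True)
    if cfg.centered:
        n_fr = cfg.n_frames(length)
        left = cfg.nfft // 2
        right = (n_fr - 1) * cfg.hop + cfg.nfft - length - left
        pad_map = np.pad(np.arange(length), (left, max(right, 0)), mode="reflect")
        if right < 0:  # cannot happen for hop <= nfft/2, kept for safety
            pad_map = pad_map[: length + left + right]
    else:
        n_fr = cfg.n_frames(length)
        pad_map = np.arange(length)
    frame_idx = cfg.hop * np.arange(n_fr)[:, None] + np.arange(cfg.nfft)[None, :]
    return pad_map, frame_idx, win


def stft(w: Waveform, cfg: StftConfig) -> TimeFrequencyRepresentation:
    """Magnitude/phase STFT of a waveform."""
    pad_map, frame_idx, win = stft_layout(len(w), cfg)
    frames = w.samples[pad_map][frame_idx] * win
    spec = np.fft.rfft(frames, axis=-1)
    return TimeFrequencyRepresentation(
        magnitude=np.abs(spec), phase=np.angle(spec), config=cfg, scale="linear"
    )


def istft(rep: TimeFrequencyRepresentation, length: int) -> np.ndarray:
    """Invert an STFT to exactly ``length`` samples (weighted overlap-add).

    Linear-scale input must carry phase; dB input is converted back to
    linear first (and must also carry phase).
    """
    if rep.phase is None:
        raise ValueError("istft requires phase; pair the magnitude with a phase source")
    mag = rep.magnitude
    if rep.scale == "db":
        mag = 10.0 ** (mag / 20.0) - DB_EPS
        mag = np.maximum(mag, 0.0)
    cfg = rep.config
    pad_map, frame_idx, win = stft_layout(length, cfg)
    if frame_idx.shape[0] != mag.shape[0]:
        raise ValueError(
            f"length {length} implies {frame_idx.shape[0]} frames, "
            f"representation has {mag.shape[0]}"
        )
    spec = mag * np.exp(1j * rep.phase)
    frames = np.fft.irfft(spec, n=cfg.nfft, axis=-1) * win
    padded_len = pad_map.shape[0]
    out = np.zeros(padded_len)
    np.add.at(out, frame_idx, frames)
    denom = np.zeros(padded_len)
    np.add.at(denom, frame_idx, np.broadcast_to(win**2, frame_idx.shape))
    out = out / np.maximum(denom, 1e-12)
    left = cfg.nfft // 2 if cfg.centered else 0
    return out[left : left + length]


def db_scale(rep: TimeFrequencyRepresentation) -> TimeFrequencyRepresentation:
    if rep.scale != "linear":
        raise ValueError("db_scale expects a linear-scale representation")
    return replace(rep, magnitude=20.0 * np.log10(rep.magnitude + DB_EPS), scale="db")


def inv_db_scale(rep: TimeFrequencyRepresentation) -> TimeFrequencyRepresentation:
    if rep.scale != "db":
        raise ValueError("inv_db_scale expects a dB-scale representation")
    mag = np.maximum(10.0 ** (rep.magnitude / 20.0) - DB_EPS, 0.0)
    return replace(rep, magnitude=mag, scale="linear")


def design_highpass(spec: SincFilterSpec) -> np.ndarray:
    """Linear-phase windowed-sinc high-pass FIR.

    A Blackman-windowed sinc low-pass (unit DC gain) is spectrally inverted:
    ``h = delta - lowpass``, which nulls DC exactly.  Kernel length defaults
    to ``2*ceil(2/transition_bandwidth) + 1`` taps, the classic design rule
    relating transition width to window length.
    """
    taps = spec.n_taps
    # scipy normalizes frequency to Nyquist = 1
    lowpass = firwin(taps, 2.0 * spec.cutoff, window="blackman")
    h = -lowpass
    h[taps // 2] += 1.0
    return 0.5 * (h + h[::-1])  # enforce bit-exact linear-phase symmetry


def apply_highpass(w: Waveform, spec: SincFilterSpec) -> Waveform:
    """Zero-phase-aligned 'same'-length high-pass filtering."""
    h = design_highpass(spec)
    return Waveform(fftconvolve(w.samples, h, mode="same"), w.rate)


def fix_duration(w: Waveform, T: int) -> Waveform:
    """Truncate to, or zero-pad up to, exactly ``T`` samples.  Truncation
    keeps the leading samples (call onsets carry identity cues)."""
    if T <= 0:
        raise ValueError("target length must be positive")
    if len(w) >= T:
        return Waveform(w.samples[:T].copy(), w.rate)
    out = np.zeros(T)
    out[: len(w)] = w.samples
    return Waveform(out, w.rate)


def target_length(durations, rule: str = "mean_plus_3sigma") -> int:
    """Common segment length (in samples) for a corpus of call durations.

    rules: ``mean_plus_3sigma`` (population sigma), ``max``, or ``fixed:T``.
    """
    durations = np.asarray(list(durations), dtype=np.float64)
    if durations.size == 0:
        raise ValueError("duration list is empty")
    if rule == "mean_plus_3sigma":
        return int(math.ceil(durations.mean() + 3.0 * durations.std(ddof=0)))
    if rule == "max":
        return int(durations.max())
    if rule.startswith("fixed:"):
        return int(rule.split(":", 1)[1])
    raise ValueError(f"unknown rule {rule!r}")


# -- WAV I/O -------------------------------------------------------------------


def read_wav(path, expected_rate: float | None = None, resample: bool = False) -> Waveform:
    rate, data = wavfile.read(Path(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported sample format {data.dtype}")
    if expected_rate is not None and rate != expected_rate:
        if not resample:
            raise ValueError(
                f"{path}: rate {rate} != expected {expected_rate}; pass resample=True"
            )
        frac = Fraction(int(expected_rate), int(rate)).limit_denominator(1000)
        from scipy.signal import resample_poly

        samples = resample_poly(samples, frac.numerator, frac.denominator)
        rate = expected_rate
    return Waveform(samples, rate)


def write_wav(path, w: Waveform, pcm16: bool = False):
    if pcm16:
        data = np.clip(np.round(w.samples * 32767.0), -32768, 32767).astype(np.int16)
    else:
        data = w.samples.astype(np.float32)
    wavfile.write(Path(path), int(w.rate), data)
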