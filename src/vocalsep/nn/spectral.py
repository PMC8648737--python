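"""Differentiable STFT / iSTFT built from matmul DFT bases.

These mirror the conventions of :mod:`vocalsep.dsp` exactly (centered reflect
padding, periodic Hann window, frame count ``1 + ceil(len/hop)``), so a
representation produced here is interchangeable with the reference one; tests
assert bitwise-level agreement.  The forward DFT is realized as two matrix
products with cosine/sine bases, which reverse-mode differentiation handles
with no special casing.
"""

from __future__ import annotations

import numpy as np

from ..dsp import StftConfig, stft_layout
from . import functional as F
from .tensor import Tensor, as_tensor

__all__ = ["SpectralTransform"]


class SpectralTransform:
    """Precomputed differentiable STFT/iSTFT for a fixed signal length."""

    def __init__(self, cfg: StftConfig, length: int):
        self.cfg = cfg
        self.length = length
        self.pad_map, self.frame_idx, self.window = stft_layout(length, cfg)
        self.n_frames, nfft = self.frame_idx.shape
        self.n_bins = cfg.n_bins
        k = np.arange(nfft)[:, None]
        f = np.arange(self.n_bins)[None, :]
        ang = 2.0 * np.pi * k * f / nfft
        self._cos = np.cos(ang)  # (nfft, F): re = frames @ cos
        self._sin = -np.sin(ang)  # rfft sign convention
        # inverse bases: frame = re @ inv_re + im @ inv_im
        eye = np.eye(self.n_bins)
        self._inv_re = np.fft.irfft(eye, n=nfft, axis=-1)  # (F, nfft)
        self._inv_im = np.fft.irfft(1j * eye, n=nfft, axis=-1)
        self.padded_len = self.pad_map.shape[0]
        denom = np.zeros(self.padded_len)
        np.add.at(denom, self.frame_idx, np.broadcast_to(self.window**2, self.frame_idx.shape))
        self._denom = np.maximum(denom, 1e-12)
        self._left = cfg.nfft // 2 if cfg.centered else 0

    # -- forward -------------------------------------------------------------

    def frames(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        padded = x.take(self.pad_map)
        return padded.take(self.frame_idx) * Tensor(self.window)

    def stft_complex(self, x: Tensor) -> tuple[Tensor, Tensor]:
        fw = self.frames(x)
        return fw @ Tensor(self._cos), fw @ Tensor(self._sin)

    def stft_magnitude(self, x: Tensor, eps: float = 1e-12) -> Tensor:
        """(T', F) magnitude; a tiny floor inside the square root keeps the
        gradient finite on silent cells."""
        re, im = self.stft_complex(x)
        return (re * re + im * im + eps**2).sqrt()

    # -- inverse -------------------------------------------------------------

    def istft(self, re: Tensor, im: Tensor) -> Tensor:
        """Invert a complex STFT (given as real/imag (T', F) tensors)."""
        frames = re @ Tensor(self._inv_re) + im @ Tensor(self._inv_im)
        frames = frames * Tensor(self.window)
        sig = F.overlap_add(frames, self.cfg.hop, self.padded_len)
        sig = sig * Tensor(1.0 / self._denom)
        return sig[np.arange(self._left, self._left + self.length)]

    def istft_from_magnitude(self, mag: Tensor, phase: np.ndarray) -> Tensor:
        """Phase-unaware inversion: differentiable magnitude combined with a
        fixed (e.g. mixture) phase array."""
        cos_p = Tensor(np.cos(phase))
        sin_p = Tensor(np.sin(phase))
        return self.istft(mag * cos_p, mag * sin_p)
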