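"""Masking U-Net source separator.

The separator maps a mixture waveform to N estimated source waveforms in
three stages: a representation encoder (STFT magnitude, dB-scaled STFT, or a
learnable Conv1d filterbank), a 2-D U-Net that predicts one mask per source,
and an inverse-transform decoder (iSTFT reusing the mixture phase — the
default is phase-unaware — dB-aware iSTFT, or a learnable ConvTranspose1d).
Masks are multiplied cellwise with the encoded mixture representation, so
with a sigmoid activation each separated magnitude is bounded by the
mixture's.

Representations are oriented (time, frequency) and zero-padded up to the
next multiple of ``pool**depth`` per axis so the contracting path divides
evenly; upsampled feature maps then match the skip shapes exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import dsp
from .dsp import DB_EPS, StftConfig, Waveform
from .nn import (
    BatchNorm2d,
    Conv1d,
    Conv2d,
    ConvTranspose1d,
    Module,
    SpectralTransform,
    Tensor,
    concat,
    no_grad,
    pad_constant,
)
from .nn import functional as F
from .presets import SPECIES, SpeciesConfig

__all__ = [
    "SeparatorConfig",
    "Separator",
    "UNet2d",
    "apply_masks",
    "ideal_binary_masks",
    "OracleMaskSeparator",
]

_ENCODER_DECODER_PAIRS = {
    ("stft", "istft"),
    ("stft_db", "istft_db"),
    ("free_conv", "free_deconv"),
}

_LN10_OVER_20 = np.log(10.0) / 20.0


@dataclass(frozen=True)
class SeparatorConfig:
    species: SpeciesConfig
    N: int = 2
    encoder: str = "stft"
    decoder: str = "istft"
    depth: int | None = None  # defaults to the species preset
    pool: int | None = None
    base_channels: int = 16
    mask_activation: str = "sigmoid"
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if (self.encoder, self.decoder) not in _ENCODER_DECODER_PAIRS:
            raise ValueError(
                f"unsupported encoder/decoder pair ({self.encoder}, {self.decoder}); "
                f"supported: {sorted(_ENCODER_DECODER_PAIRS)}"
            )
        if self.mask_activation not in ("sigmoid", "relu"):
            raise ValueError(f"unknown mask activation {self.mask_activation!r}")

    @property
    def unet_depth(self) -> int:
        return self.depth if self.depth is not None else self.species.unet_depth

    @property
    def unet_pool(self) -> int:
        return self.pool if self.pool is not None else self.species.unet_pool

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species"] = asdict(self.species)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SeparatorConfig":
        d = dict(d)
        sp = d["species"]
        if isinstance(sp, str):
            d["species"] = SPECIES[sp]
        else:
            sp = dict(sp)
            if sp.get("highpass") is not None:
                sp["highpass"] = dsp.SincFilterSpec(**sp["highpass"])
            d["species"] = SpeciesConfig(**sp)
        return cls(**d)


class _DoubleConv(Module):
    """Two 3x3 convolutions, each followed by leaky ReLU then BatchNorm."""

    def __init__(self, cin: int, cout: int, slope: float, rng):
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.bn2 = BatchNorm2d(cout)
        self.slope = slope

    def forward(self, x):
        x = self.bn1(self.conv1(x).leaky_relu(self.slope))
        return self.bn2(self.conv2(x).leaky_relu(self.slope))


class UNet2d(Module):
    """Contracting/expanding 2-D convolutional network with skip connections,
    returning N masks shaped like its input."""

    def __init__(self, n_masks: int, depth: int, pool: int, base_channels: int,
                 rng, slope: float = 0.01, mask_activation: str = "sigmoid"):
        self.depth = depth
        self.pool = pool
        self.mask_activation = mask_activation
        chans = [base_channels * 2**i for i in range(depth + 1)]
        self.down = []
        cin = 1
        for c in chans[:-1]:
            self.down.append(_DoubleConv(cin, c, slope, rng))
            cin = c
        self.middle = _DoubleConv(chans[-2] if depth else 1, chans[-1], slope, rng)
        self.up = []
        cin = chans[-1]
        for c in reversed(chans[:-1]):
            self.up.append(_DoubleConv(cin + c, c, slope, rng))
            cin = c
        self.final = Conv2d(cin, n_masks, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        div = self.pool**self.depth
        if h % div or w % div:
            raise ValueError(
                f"U-Net input {h}x{w} not divisible by pool**depth = {div}; "
                "pad the representation first"
            )
        skips = []
        for block in self.down:
            x = block(x)
            skips.append(x)
            x = F.max_pool2d(x, self.pool)
        x = self.middle(x)
        for block, skip in zip(self.up, reversed(skips)):
            x = F.upsample_bilinear2d(x, self.pool)
            x = concat([x, skip], axis=1)
            x = block(x)
        masks = self.final(x)
        if self.mask_activation == "sigmoid":
            return masks.sigmoid()
        return masks.relu()


def apply_masks(rep, masks):
    """Elementwise product of the mixture representation with each mask."""
    out = []
    for mask in masks:
        if hasattr(rep, "data") or hasattr(mask, "data"):
            out.append(mask * rep)
        else:
            out.append(np.asarray(mask) * np.asarray(rep))
    return out


class Separator(Module):
    """Encoder -> U-Net -> masked decoding, mixture waveform to N sources."""

    def __init__(self, config: SeparatorConfig):
        self.config = config
        sp = config.species
        rng = np.random.default_rng(config.seed)
        self.stft_cfg = sp.stft
        self.transform = SpectralTransform(self.stft_cfg, sp.T)
        if config.encoder in ("stft", "stft_db"):
            self.grid = (self.transform.n_frames, self.transform.n_bins)
            self.enc = None
            self.dec = None
        else:
            n_ch = self.stft_cfg.n_bins
            self.enc = Conv1d(1, n_ch, sp.nfft, rng, stride=sp.hop,
                              padding=sp.nfft // 2)
            self.dec = ConvTranspose1d(n_ch, 1, sp.nfft, rng, stride=sp.hop,
                                       padding=sp.nfft // 2)
            self._free_len = (sp.T + 2 * (sp.nfft // 2) - sp.nfft) // sp.hop + 1
            self.grid = (self._free_len, n_ch)
        div = config.unet_pool**config.unet_depth
        self.padded_grid = tuple(-(-g // div) * div for g in self.grid)
        self.unet = UNet2d(config.N, config.unet_depth, config.unet_pool,
                           config.base_channels, rng, slope=config.leaky_slope,
                           mask_activation=config.mask_activation)

    # -- pipeline stages ------------------------------------------------------

    def encode(self, mixtures: np.ndarray):
        """Encode a (B, T) batch; returns the padded network input tensor and
        the side-info needed for decoding (magnitudes/phases, or learned
        activations)."""
        sp = self.config.species
        if mixtures.ndim != 2 or mixtures.shape[1] != sp.T:
            raise ValueError(f"expected (batch, {sp.T}) mixtures, got {mixtures.shape}")
        h, w = self.grid
        hp, wp = self.padded_grid
        if self.config.encoder in ("stft", "stft_db"):
            mags, phases = [], []
            for row in mixtures:
                rep = dsp.stft(Waveform(row, sp.rate), self.stft_cfg)
                mags.append(rep.magnitude)
                phases.append(rep.phase)
            mag = np.stack(mags)
            if self.config.encoder == "stft_db":
                values = 20.0 * np.log10(mag + DB_EPS)
            else:
                values = mag
            padded = np.zeros((mixtures.shape[0], 1, hp, wp))
            padded[:, 0, :h, :w] = values
            net_in = Tensor(padded)
            side = {"values": values, "phases": phases}
        else:
            x = Tensor(mixtures[:, None, :])
            act = self.enc(x).relu()  # (B, C, L)
            rep = act.transpose(0, 2, 1).reshape(
                mixtures.shape[0], 1, self._free_len, self.stft_cfg.n_bins
            )
            net_in = pad_constant(rep, ((0, 0), (0, 0), (0, hp - h), (0, wp - w)))
            side = {"rep": rep}
        return net_in, side

    def unet_forward(self, net_in: Tensor) -> Tensor:
        """(B, 1, Hp, Wp) representation to (B, N, Hp, Wp) masks."""
        return self.unet(net_in)

    def decode(self, masks: Tensor, side: dict, batch_index: int):
        """Decode the N masked representations of one example to waveforms."""
        sp = self.config.species
        h, w = self.grid
        outputs = []
        for i in range(self.config.N):
            mask = masks[(batch_index, i, slice(0, h), slice(0, w))]
            if self.config.encoder == "stft":
                masked = mask * Tensor(side["values"][batch_index])
                wav = self.transform.istft_from_magnitude(
                    masked, side["phases"][batch_index]
                )
            elif self.config.encoder == "stft_db":
                masked_db = mask * Tensor(side["values"][batch_index])
                mag = ((masked_db * _LN10_OVER_20).exp() - DB_EPS).relu()
                wav = self.transform.istft_from_magnitude(
                    mag, side["phases"][batch_index]
                )
            else:
                rep = side["rep"][(batch_index, 0, slice(0, h), slice(0, w))]
                masked = (mask * rep).transpose(1, 0).reshape(1, w, h)
                wav = self.dec(masked).reshape(-1)
                t = wav.shape[0]
                if t < sp.T:
                    wav = pad_constant(wav, ((0, sp.T - t),))
                else:
                    wav = wav[np.arange(sp.T)]
            outputs.append(wav)
        return outputs

    # -- end-to-end -----------------------------------------------------------

    def forward_waveforms(self, mixtures: np.ndarray) -> list:
        """Differentiable forward pass: (B, T) -> B lists of N waveform
        tensors of length T."""
        net_in, side = self.encode(mixtures)
        masks = self.unet_forward(net_in)
        return [self.decode(masks, side, b) for b in range(mixtures.shape[0])]

    def separate(self, mixture: Waveform) -> list:
        """Inference: one mixture waveform to N estimated source waveforms."""
        self.eval()
        with no_grad():
            outputs = self.forward_waveforms(mixture.samples[None, :])[0]
        return [Waveform(o.data, self.config.species.rate) for o in outputs]

    # -- persistence ----------------------------------------------------------

    def save(self, path):
        state = self.named_state()
        state["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "Separator":
        archive = np.load(path)
        config = SeparatorConfig.from_dict(
            json.loads(bytes(archive["__config__"]).decode())
        )
        model = cls(config)
        model.load_state({k: archive[k] for k in archive.files if k != "__config__"})
        model.eval()
        return model


# -- oracle masking (upper-bound harness) --------------------------------------


def ideal_binary_masks(sources, stft_cfg: StftConfig) -> list:
    """Ground-truth binary masks: cell -> the source with the largest STFT
    magnitude.  Isolates representation/inversion quality from learning."""
    mags = np.stack([dsp.stft(s, stft_cfg).magnitude for s in sources])
    winner = np.argmax(mags, axis=0)
    return [(winner == i).astype(float) for i in range(len(sources))]


class OracleMaskSeparator:
    """Separator stand-in that applies externally supplied (e.g. ideal binary)
    masks to the mixture STFT and inverts with the mixture phase."""

    def __init__(self, species: SpeciesConfig):
        self.species = species
        self.transform = SpectralTransform(species.stft, species.T)

    def separate_with_masks(self, mixture: Waveform, masks) -> list:
        rep = dsp.stft(mixture, self.species.stft)
        out = []
        for mask in masks:
            masked = dsp.TimeFrequencyRepresentation(
                magnitude=rep.magnitude * mask, phase=rep.phase,
                config=self.species.stft,
            )
            out.append(Waveform(dsp.istft(masked, len(mixture)), mixture.rate))
        return out
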