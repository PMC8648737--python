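"""CNN identity classifier: labels a waveform with its vocalizer.

Pipeline: optional frozen windowed-sinc high-pass -> non-dB STFT magnitude ->
convolutional blocks (two 3x3 convolutions with leaky ReLU, then max pooling)
-> time-average pooling -> dense layer with leaky ReLU and dropout -> linear
layer with log-softmax over the V individuals.  Used standalone and as the
downstream evaluation probe for separation quality.

Time-average pooling (mean over the frame axis before the dense layer) makes
the features invariant to call onset, complementing the random onset-shift
augmentation used during training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import dsp
from .datasets import augment_onset, split_corpus
from .dsp import Waveform
from .nn import Conv2d, Linear, Module, Tensor, no_grad
from .nn import tensor as tensor_mod
from .nn import functional as F
from .nn.optim import Adam
from .presets import SPECIES, SpeciesConfig

__all__ = ["ClassifierConfig", "ClassifierOutput", "IdentityClassifier",
           "train_classifier", "accuracy", "nll_loss"]


@dataclass(frozen=True)
class ClassifierConfig:
    species: SpeciesConfig
    n_blocks: int | None = None  # defaults to the species preset (4)
    pool: int | None = None  # defaults to the species preset (4)
    dropout: float | None = None  # 0.25 macaque, 0.5 dolphin/bat
    base_channels: int = 16
    dense_width: int = 128
    leaky_slope: float = 0.01
    seed: int = 0

    @property
    def blocks(self) -> int:
        return self.n_blocks if self.n_blocks is not None else self.species.clf_blocks

    @property
    def pool_size(self) -> int:
        return self.pool if self.pool is not None else self.species.clf_pool

    @property
    def p_dropout(self) -> float:
        return self.dropout if self.dropout is not None else self.species.clf_dropout

    @property
    def V(self) -> int:
        return self.species.V

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species"] = asdict(self.species)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierConfig":
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


@dataclass
class ClassifierOutput:
    log_probs: np.ndarray  # length V, logsumexp == 0


class IdentityClassifier(Module):
    def __init__(self, config: ClassifierConfig):
        self.config = config
        sp = config.species
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        self.stft_cfg = sp.stft
        n_frames = self.stft_cfg.n_frames(sp.T)
        n_bins = self.stft_cfg.n_bins
        pool = config.pool_size
        div = pool**config.blocks
        self.padded_grid = (-(-n_frames // div) * div, -(-n_bins // div) * div)
        self.grid = (n_frames, n_bins)
        self.convs = []
        cin = 1
        chans = [config.base_channels * 2**i for i in range(config.blocks)]
        for c in chans:
            self.convs.append(Conv2d(cin, c, 3, rng))
            self.convs.append(Conv2d(c, c, 3, rng))
            cin = c
        feat_w = self.padded_grid[1] // div
        self.dense = Linear(cin * feat_w, config.dense_width, rng)
        self.head = Linear(config.dense_width, config.V, rng)
        if sp.highpass is not None:
            # frozen windowed-sinc FIR; contributes no trainable parameters
            self._hp_kernel = dsp.design_highpass(sp.highpass)
        else:
            self._hp_kernel = None

    # -- feature extraction ---------------------------------------------------

    def _features(self, waveforms: list) -> Tensor:
        sp = self.config.species
        mags = []
        for w in waveforms:
            if len(w) != sp.T:
                raise ValueError(f"expected length-{sp.T} waveform, got {len(w)}")
            if self._hp_kernel is not None:
                w = Waveform(
                    np.convolve(w.samples, self._hp_kernel, mode="same"), w.rate
                )
            mags.append(dsp.stft(w, self.stft_cfg).magnitude)
        mag = np.stack(mags)
        hp, wp = self.padded_grid
        padded = np.zeros((len(waveforms), 1, hp, wp))
        padded[:, 0, : self.grid[0], : self.grid[1]] = mag
        return Tensor(padded)

    def forward(self, waveforms: list) -> Tensor:
        """Batch of waveforms to (B, V) log-probabilities."""
        x = self._features(waveforms)
        pool = self.config.pool_size
        for k in range(0, len(self.convs), 2):
            x = self.convs[k](x).leaky_relu(self.config.leaky_slope)
            x = self.convs[k + 1](x).leaky_relu(self.config.leaky_slope)
            x = F.max_pool2d(x, pool)
        x = x.mean(axis=2)  # average over time frames
        x = x.reshape(x.shape[0], x.shape[1] * x.shape[2])
        x = self.dense(x).leaky_relu(self.config.leaky_slope)
        x = F.dropout(x, self.config.p_dropout, self._dropout_rng, self.training)
        return F.log_softmax(self.head(x), axis=-1)

    def classify(self, w: Waveform) -> ClassifierOutput:
        self.eval()
        with no_grad():
            log_probs = self.forward([w]).data[0]
        return ClassifierOutput(log_probs=log_probs)

    # -- persistence ----------------------------------------------------------

    def save(self, path):
        state = self.named_state()
        state["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "IdentityClassifier":
        archive = np.load(path)
        config = ClassifierConfig.from_dict(
            json.loads(bytes(archive["__config__"]).decode())
        )
        model = cls(config)
        model.load_state({k: archive[k] for k in archive.files if k != "__config__"})
        model.eval()
        return model


def nll_loss(log_probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of the true labels."""
    batch = log_probs.shape[0]
    picked = log_probs[(np.arange(batch), np.asarray(labels))]
    return -picked.mean()


def accuracy(model: IdentityClassifier, waveforms: list, labels) -> float:
    """Fraction of waveforms whose argmax log-probability matches the label."""
    model.eval()
    with no_grad():
        log_probs = model.forward(list(waveforms)).data
    return float(np.mean(np.argmax(log_probs, axis=1) == np.asarray(labels)))


def train_classifier(corpus, config: ClassifierConfig, epochs: int,
                     batch_size: int, lr: float = 3e-4, seed: int = 0,
                     checkpoint_dir=None, callback=None, dtype: str = "float32"):
    """Train on an 80/20 call split with random onset-shift augmentation on
    both subsets; the epoch checkpoint with the highest validation accuracy
    is restored at the end.  Returns (model, history)."""
    counts = np.bincount(corpus.labels)
    if np.any(counts[np.unique(corpus.labels)] < 2):
        raise ValueError("every class needs at least 2 calls")
    sp = config.species
    model = IdentityClassifier(config)
    dt = np.float32 if dtype == "float32" else np.float64
    model.astype(dt)
    rng = np.random.default_rng(seed)
    train_c, val_c = split_corpus(corpus, train_fraction=0.8, seed=seed)
    opt = Adam(model.parameters(), lr=lr)
    history = []
    best = (-np.inf, None)
    val_waves = [augment_onset(c, sp.T, rng) for c in val_c.calls]
    with tensor_mod.default_dtype(dt):
        for epoch in range(epochs):
            model.train()
            order = rng.permutation(len(train_c))
            epoch_losses = []
            for start in range(0, len(order), batch_size):
                idx = order[start : start + batch_size]
                waves = [augment_onset(train_c.calls[i], sp.T, rng) for i in idx]
                labels = train_c.labels[idx]
                log_probs = model.forward(waves)
                loss = nll_loss(log_probs, labels)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(loss.item())
            val_acc = accuracy(model, val_waves, val_c.labels)
            row = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                   "val_accuracy": val_acc}
            history.append(row)
            if val_acc > best[0]:
                best = (val_acc, {k: v.copy() for k, v in model.named_state().items()})
            if checkpoint_dir is not None:
                model.save(f"{checkpoint_dir}/clf_epoch_{epoch:03d}.npz")
            if callback is not None:
                callback(row)
    if best[1] is not None:
        model.load_state(best[1])
    model.eval()
    return model, history
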