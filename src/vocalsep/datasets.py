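"""Supervised mixture datasets: duration fixing, additive mixing with random
onset shifts, call-level 80/20 splits, closed- and open-speaker regimes.

A mixture example holds the mixed waveform ``x``, the N shifted ground-truth
sources ``s^i`` with ``x = sum_i s^i`` exactly, and the identity labels.  The
construction mirrors the WSJ0-2mix recipe: draw calls from N distinct
individuals, place each at a random onset inside the fixed-length segment,
and sum — no gain normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dsp import SincFilterSpec, Waveform, apply_highpass, fix_duration
from .synth import Corpus

__all__ = [
    "MixtureExample",
    "DatasetSpec",
    "split_corpus",
    "holdout_individuals",
    "sample_shift",
    "sample_shifts",
    "make_mixture",
    "build_dataset",
    "augment_onset",
    "save_dataset",
    "load_dataset",
]


@dataclass
class MixtureExample:
    mixture: Waveform
    sources: list  # list[Waveform], shifted and duration-fixed
    labels: list  # distinct individual ids
    shifts: list  # onset offset in samples per source
    targets: list | None = None  # filtered targets when denoising, else None

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("mixture labels must be distinct")

    @property
    def training_targets(self) -> list:
        return self.targets if self.targets is not None else self.sources


@dataclass(frozen=True)
class DatasetSpec:
    N: int = 2
    n_mixtures: int = 100
    T: int = 2048
    seed: int = 0
    regime: str = "closed"  # {"closed", "open"}
    split: str = "train"  # {"train", "val", "test"}
    overlap_required: bool = True
    target_highpass: SincFilterSpec | None = None  # denoising variant
    gain_jitter_db: float = 0.0  # optional relative gain jitter, default off


def split_corpus(corpus: Corpus, train_fraction: float = 0.8, seed: int = 0):
    """Stratified per-individual call split into (train, heldout) corpora."""
    rng = np.random.default_rng(seed)
    train_idx, held_idx = [], []
    for label in corpus.individuals:
        idx = np.flatnonzero(corpus.labels == label)
        if idx.size < 2:
            raise ValueError(f"individual {label} has fewer than 2 calls; cannot split")
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # both sides nonempty
        train_idx.extend(idx[:n_train])
        held_idx.extend(idx[n_train:])
    return corpus.subset(sorted(train_idx)), corpus.subset(sorted(held_idx))


def holdout_individuals(corpus: Corpus, k: int, seed: int = 0):
    """Reserve ``k`` individuals (all their calls) for the open-speaker regime."""
    individuals = corpus.individuals
    if k >= individuals.size:
        raise ValueError(f"cannot hold out {k} of {individuals.size} individuals")
    rng = np.random.default_rng(seed)
    open_ids = set(rng.choice(individuals, size=k, replace=False).tolist())
    open_idx = np.flatnonzero([l in open_ids for l in corpus.labels])
    closed_idx = np.flatnonzero([l not in open_ids for l in corpus.labels])
    return corpus.subset(closed_idx), corpus.subset(open_idx)


def sample_shift(call_length: int, T: int, rng: np.random.Generator) -> int:
    """Uniform onset over the feasible placements [0, T - call_length]."""
    if call_length > T:
        raise ValueError("call longer than segment; run fix_duration first")
    return int(rng.integers(0, T - call_length + 1))


def sample_shifts(call_lengths, T: int, overlap_required: bool,
                  rng: np.random.Generator, max_tries: int = 1000) -> list[int]:
    """Joint onset draw; with ``overlap_required`` redraw until every pair of
    placed sources shares at least one sample."""
    for _ in range(max_tries):
        shifts = [sample_shift(n, T, rng) for n in call_lengths]
        if not overlap_required or len(shifts) < 2:
            return shifts
        ok = all(
            max(shifts[i], shifts[j]) < min(shifts[i] + call_lengths[i],
                                            shifts[j] + call_lengths[j])
            for i in range(len(shifts))
            for j in range(i + 1, len(shifts))
        )
        if ok:
            return shifts
    raise RuntimeError(
        "could not find overlapping placements; calls may be too short for T"
    )


def _place(call: Waveform, shift: int, T: int) -> Waveform:
    out = np.zeros(T)
    out[shift : shift + len(call)] = call.samples
    return Waveform(out, call.rate)


def make_mixture(calls, labels, T: int, rng: np.random.Generator,
                 overlap_required: bool = True,
                 target_highpass: SincFilterSpec | None = None,
                 gain_jitter_db: float = 0.0) -> MixtureExample:
    """Additively mix N calls at random onsets; ``x = sum_i s^i`` exactly."""
    if len(set(labels)) != len(labels):
        raise ValueError("mixture requires distinct individual labels")
    calls = [fix_duration(c, T) if len(c) > T else c for c in calls]
    lengths = [len(c) for c in calls]
    shifts = sample_shifts(lengths, T, overlap_required, rng)
    sources = []
    for call, shift in zip(calls, shifts):
        if gain_jitter_db:
            gain = 10.0 ** (rng.uniform(-gain_jitter_db, gain_jitter_db) / 20.0)
            call = Waveform(call.samples * gain, call.rate)
        sources.append(_place(call, shift, T))
    mixture = Waveform(np.sum([s.samples for s in sources], axis=0), calls[0].rate)
    targets = None
    if target_highpass is not None:
        targets = [apply_highpass(s, target_highpass) for s in sources]
    return MixtureExample(mixture=mixture, sources=sources, labels=list(labels),
                          shifts=shifts, targets=targets)


def build_dataset(corpus: Corpus, spec: DatasetSpec) -> list[MixtureExample]:
    """Deterministic dataset of ``spec.n_mixtures`` examples from a call pool.

    Speaker tuples are drawn uniformly without replacement per mixture; a
    call may recur across mixtures.
    """
    individuals = corpus.individuals
    if individuals.size < spec.N:
        raise ValueError(
            f"corpus has {individuals.size} individuals, need at least {spec.N}"
        )
    rng = np.random.default_rng(spec.seed)
    pools = {int(l): np.flatnonzero(corpus.labels == l) for l in individuals}
    examples = []
    for _ in range(spec.n_mixtures):
        chosen = rng.choice(individuals, size=spec.N, replace=False)
        calls, labels = [], []
        for label in chosen:
            idx = int(rng.choice(pools[int(label)]))
            calls.append(corpus.calls[idx])
            labels.append(int(label))
        examples.append(
            make_mixture(calls, labels, spec.T, rng,
                         overlap_required=spec.overlap_required,
                         target_highpass=spec.target_highpass,
                         gain_jitter_db=spec.gain_jitter_db)
        )
    return examples


def save_dataset(examples, directory):
    """Write a mixture dataset as WAV files plus a JSON manifest."""
    import json
    from pathlib import Path

    from .dsp import write_wav

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, ex in enumerate(examples):
        paths = {"mixture": f"mix_{k:05d}.wav"}
        write_wav(directory / paths["mixture"], ex.mixture)
        paths["sources"] = []
        for i, s in enumerate(ex.sources):
            name = f"mix_{k:05d}_src{i}.wav"
            write_wav(directory / name, s)
            paths["sources"].append(name)
        if ex.targets is not None:
            paths["targets"] = []
            for i, t in enumerate(ex.targets):
                name = f"mix_{k:05d}_tgt{i}.wav"
                write_wav(directory / name, t)
                paths["targets"].append(name)
        rows.append({**paths, "labels": [int(l) for l in ex.labels],
                     "shifts": [int(s) for s in ex.shifts]})
    manifest = {"rate": examples[0].mixture.rate, "N": len(examples[0].sources),
                "examples": rows}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_dataset(directory) -> list:
    """Read a mixture dataset written by :func:`save_dataset`."""
    import json
    from pathlib import Path

    from .dsp import read_wav

    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    rate = manifest["rate"]
    examples = []
    for row in manifest["examples"]:
        mixture = read_wav(directory / row["mixture"], expected_rate=rate)
        sources = [read_wav(directory / p, expected_rate=rate) for p in row["sources"]]
        targets = None
        if "targets" in row:
            targets = [read_wav(directory / p, expected_rate=rate)
                       for p in row["targets"]]
        examples.append(MixtureExample(mixture=mixture, sources=sources,
                                       labels=row["labels"], shifts=row["shifts"],
                                       targets=targets))
    return examples


def augment_onset(call: Waveform, T: int, rng: np.random.Generator) -> Waveform:
    """Place a call at a random onset within a length-T segment (classifier
    training augmentation)."""
    call = fix_duration(call, T) if len(call) > T else call
    return _place(call, sample_shift(len(call), T, rng), T)
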