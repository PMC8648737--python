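"""Species presets: sampling rates, segment lengths, transform and model sizes.

The three field presets describe the corpora the pipeline targets —
macaque coo calls, bottlenose dolphin signature whistles, and Egyptian fruit
bat calls — at their native sampling rates.  Segment lengths are fixed per
species (mean + 3 sigma of call durations for macaques/dolphins, a fixed
1.0 s for bats).  The ``toy`` preset is a scaled-down 8 kHz configuration for
tests and desk-scale experiments on synthetic calls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dsp import SincFilterSpec, StftConfig

__all__ = ["SpeciesConfig", "SPECIES", "get_species"]


@dataclass(frozen=True)
class SpeciesConfig:
    name: str
    rate: float  # Hz
    T: int  # fixed segment length, samples
    nfft: int
    hop: int
    highpass: SincFilterSpec | None  # applied before feature extraction
    V: int  # identity class count
    unet_depth: int  # down/up block count B
    unet_pool: int  # max-pool size per block
    clf_dropout: float
    clf_blocks: int = 4
    clf_pool: int = 4

    @property
    def stft(self) -> StftConfig:
        return StftConfig(nfft=self.nfft, hop=self.hop)

    @property
    def segment_seconds(self) -> float:
        return self.T / self.rate


SPECIES: dict[str, SpeciesConfig] = {
    "macaque": SpeciesConfig(
        name="macaque", rate=24414, T=23156, nfft=1024, hop=64,
        highpass=None, V=8, unet_depth=4, unet_pool=2, clf_dropout=0.25,
    ),
    "dolphin": SpeciesConfig(
        name="dolphin", rate=96000, T=290680, nfft=1024, hop=256,
        highpass=SincFilterSpec(cutoff=4700 / 96000, transition_bandwidth=0.08),
        V=8, unet_depth=3, unet_pool=6, clf_dropout=0.5,
    ),
    "bat": SpeciesConfig(
        name="bat", rate=250000, T=250000, nfft=2048, hop=512,
        highpass=None, V=12, unet_depth=4, unet_pool=3, clf_dropout=0.5,
    ),
    # desk-scale preset for synthetic experiments and the test suite
    "toy": SpeciesConfig(
        name="toy", rate=8000, T=2048, nfft=128, hop=64,
        highpass=None, V=6, unet_depth=2, unet_pool=2, clf_dropout=0.25,
        clf_blocks=2, clf_pool=4,
    ),
}


def get_species(name: str) -> SpeciesConfig:
    try:
        return SPECIES[name]
    except KeyError:
        raise KeyError(f"unknown species preset {name!r}; choose from {sorted(SPECIES)}")
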