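"""Separator model: shape safety, mask semantics, reconstruction bounds,
ideal-mask oracle, parameter accounting, persistence."""

import numpy as np
import pytest

from vocalsep import DatasetSpec, SeparatorConfig, build_dataset, dsp
from vocalsep.metrics import input_si_sdr, perm_max_metric, si_sdr
from vocalsep.nn import Tensor
from vocalsep.presets import SPECIES
from vocalsep.separator import (
    OracleMaskSeparator,
    Separator,
    apply_masks,
    ideal_binary_masks,
)


@pytest.fixture(scope="module")
def toy_model(toy):
    return Separator(SeparatorConfig(species=toy, N=2, base_channels=8, seed=0))


@pytest.fixture(scope="module")
def toy_mixtures(two_voice_corpus, toy):
    return build_dataset(two_voice_corpus,
                         DatasetSpec(N=2, n_mixtures=6, T=toy.T, seed=13))


class TestForwardShapes:
    @pytest.mark.parametrize("encoder,decoder", [
        ("stft", "istft"), ("stft_db", "istft_db"), ("free_conv", "free_deconv"),
    ])
    def test_toy_preset_outputs_n_waveforms_of_length_t(self, toy, toy_mixtures,
                                                        encoder, decoder):
        cfg = SeparatorConfig(species=toy, N=2, encoder=encoder, decoder=decoder,
                              base_channels=4, seed=1)
        model = Separator(cfg)
        outs = model.separate(toy_mixtures[0].mixture)
        assert len(outs) == 2
        for o in outs:
            assert len(o) == toy.T
            assert np.all(np.isfinite(o.samples))

    @pytest.mark.parametrize("species", ["macaque", "dolphin", "bat"])
    def test_species_presets_forward_pass(self, species, rng):
        """Each field preset survives a full forward pass at its native
        segment length and returns (N, T)."""
        sp = SPECIES[species]
        cfg = SeparatorConfig(species=sp, N=2, base_channels=2, seed=0)
        model = Separator(cfg)
        mix = dsp.Waveform(rng.normal(size=sp.T).astype(np.float32), sp.rate)
        outs = model.separate(mix)
        assert len(outs) == 2
        assert all(len(o) == sp.T for o in outs)

    def test_wrong_length_rejected(self, toy, toy_model):
        with pytest.raises(ValueError, match="expected"):
            toy_model.encode(np.zeros((1, toy.T + 1)))

    def test_mismatched_encoder_decoder_rejected(self, toy):
        with pytest.raises(ValueError, match="pair"):
            SeparatorConfig(species=toy, N=2, encoder="free_conv", decoder="istft")

    def test_unet_rejects_non_divisible_input(self, toy_model):
        with pytest.raises(ValueError, match="divisible"):
            toy_model.unet(Tensor(np.zeros((1, 1, 35, 67))))


class TestMasks:
    def test_sigmoid_masks_bounded_and_magnitude_dominated(self, toy_model,
                                                           toy_mixtures):
        mix = toy_mixtures[0].mixture
        net_in, side = toy_model.encode(mix.samples[None, :])
        masks = toy_model.unet_forward(net_in)
        assert masks.shape[1] == 2
        assert np.all(masks.data >= 0.0) and np.all(masks.data <= 1.0)
        h, w = toy_model.grid
        for i in range(2):
            masked = masks.data[0, i, :h, :w] * side["values"][0]
            assert np.all(masked <= side["values"][0] + 1e-12)

    def test_apply_masks_algebra(self, rng):
        rep = rng.uniform(size=(5, 7))
        ones = np.ones_like(rep)
        assert np.array_equal(apply_masks(rep, [ones])[0], rep)
        assert np.all(apply_masks(rep, [np.zeros_like(rep)])[0] == 0)
        binary = (rng.uniform(size=rep.shape) > 0.5).astype(float)
        parts = apply_masks(rep, [binary, 1.0 - binary])
        np.testing.assert_allclose(parts[0] + parts[1], rep)

    def test_identity_masks_reconstruct_mixture(self, toy_model, toy_mixtures):
        mix = toy_mixtures[1].mixture
        net_in, side = toy_model.encode(mix.samples[None, :])
        ones = Tensor(np.ones((1, 2) + toy_model.padded_grid))
        outs = toy_model.decode(ones, side, 0)
        for o in outs:
            err = np.max(np.abs(o.data - mix.samples)) / np.max(np.abs(mix.samples))
            assert err < 1e-3


class TestIdealMaskOracle:
    def test_disjoint_two_tone_sources_exceed_20_db(self, toy):
        """Ground-truth binary masks plus mixture-phase inversion achieve
        >= 20 dB on strictly DUET-disjoint two-tone mixtures, validating the
        mask-and-invert path independently of any learning."""
        from vocalsep import SynthPreset, make_corpus

        preset = SynthPreset(n_individuals=2, f0_band=(300.0, 1800.0),
                             n_harmonics=1, duration_range=(0.15, 0.23))
        corpus = make_corpus(preset, calls_per_individual=6, seed=23)
        mixtures = build_dataset(corpus, DatasetSpec(N=2, n_mixtures=10,
                                                     T=toy.T, seed=24))
        oracle = OracleMaskSeparator(toy)
        values = []
        for ex in mixtures:
            masks = ideal_binary_masks(ex.sources, toy.stft)
            estimates = oracle.separate_with_masks(ex.mixture, masks)
            values.append(perm_max_metric(estimates, ex.sources, si_sdr).value)
        assert np.mean(values) >= 20.0
        # and the mixture baseline is far worse
        base = np.mean([input_si_sdr(ex.mixture, ex.sources) for ex in mixtures])
        assert np.mean(values) > base + 15.0


class TestParameterAccounting:
    def test_free_encoder_adds_exactly_the_filterbank_parameters(self, toy):
        stft_model = Separator(SeparatorConfig(species=toy, N=2,
                                               base_channels=4, seed=0))
        free_model = Separator(SeparatorConfig(
            species=toy, N=2, encoder="free_conv", decoder="free_deconv",
            base_channels=4, seed=0))
        c = toy.nfft // 2 + 1
        expected_extra = (c * toy.nfft + c) + (c * toy.nfft + 1)
        assert (free_model.count_parameters() - stft_model.count_parameters()
                == expected_extra)

    def test_doubling_width_roughly_quadruples_conv_parameters(self, toy):
        small = Separator(SeparatorConfig(species=toy, N=2, base_channels=8,
                                          seed=0)).count_parameters()
        large = Separator(SeparatorConfig(species=toy, N=2, base_channels=16,
                                          seed=0)).count_parameters()
        assert 3.4 < large / small < 4.1

    def test_frozen_highpass_contributes_no_parameters(self):
        from vocalsep.classifier import ClassifierConfig, IdentityClassifier

        dolphin_like = SPECIES["toy"]
        from dataclasses import replace

        with_hp = replace(dolphin_like,
                          highpass=dsp.SincFilterSpec(cutoff=0.05))
        a = IdentityClassifier(ClassifierConfig(species=dolphin_like,
                                                base_channels=4, seed=0))
        b = IdentityClassifier(ClassifierConfig(species=with_hp,
                                                base_channels=4, seed=0))
        assert a.count_parameters() == b.count_parameters()


class TestDeterminismAndPersistence:
    def test_same_seed_same_outputs(self, toy, toy_mixtures):
        mix = toy_mixtures[2].mixture
        a = Separator(SeparatorConfig(species=toy, N=2, base_channels=4, seed=3))
        b = Separator(SeparatorConfig(species=toy, N=2, base_channels=4, seed=3))
        for oa, ob in zip(a.separate(mix), b.separate(mix)):
            np.testing.assert_array_equal(oa.samples, ob.samples)

    def test_repeated_inference_is_bit_identical(self, toy_model, toy_mixtures):
        mix = toy_mixtures[3].mixture
        first = toy_model.separate(mix)
        second = toy_model.separate(mix)
        for a, b in zip(first, second):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_checkpoint_round_trip(self, tmp_path, toy, toy_model, toy_mixtures):
        path = tmp_path / "model.npz"
        toy_model.save(path)
        restored = Separator.load(path)
        assert restored.config.N == 2
        mix = toy_mixtures[4].mixture
        for a, b in zip(toy_model.separate(mix), restored.separate(mix)):
            np.testing.assert_array_equal(a.samples, b.samples)
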