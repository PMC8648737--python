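"""Training objective: loss-term reference values, brute-force PIT oracle
equivalence, permutation invariance, and gradient correctness on a micro
separator."""

import itertools

import numpy as np
import pytest

from conftest import finite_difference_gradient
from vocalsep import SeparatorConfig, dsp
from vocalsep.dsp import SincFilterSpec, StftConfig
from vocalsep.losses import (
    LossConfig,
    TrainingSchedule,
    channel_loss,
    l1_term,
    neg_si_sdr_term,
    pit_loss,
    spectral_convergence_term,
    stft_l1_term,
    total_loss,
    train_separator,
)
from vocalsep.nn import Tensor
from vocalsep.presets import SpeciesConfig
from vocalsep.separator import Separator

CFG = StftConfig(nfft=64, hop=16)
LC = LossConfig(stft_cfg=CFG)
RNG = np.random.default_rng(3)


def tone(freq=1000.0, n=512, rate=8000.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / rate)


class TestLossTerms:
    def test_l1_reference_values(self):
        assert l1_term([0.0, 1.0], [1.0, 0.0]).item() == pytest.approx(1.0)
        assert l1_term([1.0, 2.0], [1.0, 2.0]).item() == 0.0
        a, b = RNG.normal(size=32), RNG.normal(size=32)
        assert l1_term(a, b).item() == pytest.approx(l1_term(b, a).item())

    def test_stft_l1_zero_estimate_equals_mean_target_magnitude(self):
        s = tone()
        expected = dsp.stft(dsp.Waveform(s, 8000), CFG).magnitude.mean()
        got = stft_l1_term(np.zeros_like(s), s, CFG).item()
        assert got == pytest.approx(expected, rel=1e-6)

    def test_stft_l1_invariant_to_global_sign_flip(self):
        s = tone()
        e = RNG.normal(size=s.size)
        assert stft_l1_term(e, s, CFG).item() == pytest.approx(
            stft_l1_term(-e, s, CFG).item(), rel=1e-9)

    def test_spectral_convergence_reference_values(self):
        s = tone()
        assert spectral_convergence_term(s, s, CFG).item() == pytest.approx(0.0, abs=1e-9)
        assert spectral_convergence_term(np.zeros_like(s), s, CFG).item() == (
            pytest.approx(1.0, abs=1e-9))
        assert spectral_convergence_term(2 * s, s, CFG).item() == pytest.approx(
            1.0, abs=1e-6)

    def test_spectral_convergence_zero_target_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            spectral_convergence_term(tone(), np.zeros(512), CFG)

    def test_neg_si_sdr_matches_metric(self):
        from vocalsep.metrics import si_sdr

        e, s = RNG.normal(size=128), RNG.normal(size=128)
        assert -neg_si_sdr_term(e, s).item() == pytest.approx(si_sdr(e, s), abs=1e-6)

    def test_channel_loss_weight_composition(self):
        e, s = RNG.normal(size=512), tone()
        only_l1 = LossConfig(stft_cfg=CFG, w_l1=1, w_stft_l1=0,
                             w_spectral_convergence=0)
        assert channel_loss(e, s, only_l1).item() == pytest.approx(
            l1_term(e, s).item())
        mixed = LossConfig(stft_cfg=CFG, w_l1=0.5, w_stft_l1=2.0,
                           w_spectral_convergence=0.25)
        expected = (0.5 * l1_term(e, s).item()
                    + 2.0 * stft_l1_term(e, s, CFG).item()
                    + 0.25 * spectral_convergence_term(e, s, CFG).item())
        assert channel_loss(e, s, mixed).item() == pytest.approx(expected, rel=1e-9)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(stft_cfg=CFG, w_l1=0, w_stft_l1=0, w_spectral_convergence=0)


class TestPitLoss:
    def test_matched_sets_give_zero_and_identity(self):
        s = [tone(500.0), tone(1500.0)]
        res = pit_loss(s, s, LC)
        assert res.value.item() == pytest.approx(0.0, abs=1e-9)
        assert res.sigma == (0, 1)

    def test_swapped_sets_recover_transposition(self):
        s = [tone(500.0), tone(1500.0)]
        res = pit_loss([s[1], s[0]], s, LC)
        assert res.value.item() == pytest.approx(0.0, abs=1e-9)
        assert res.sigma == (1, 0)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_equals_independent_enumeration(self, n):
        estimates = [RNG.normal(size=256) for _ in range(n)]
        targets = [RNG.normal(size=256) + tone(300.0 * (i + 1), 256)
                   for i in range(n)]
        res = pit_loss(estimates, targets, LC)
        pair = np.array([[channel_loss(e, t, LC).item() for t in targets]
                         for e in estimates])
        brute = min(
            sum(pair[sigma[i], i] for i in range(n)) / n
            for sigma in itertools.permutations(range(n))
        )
        assert res.value.item() == pytest.approx(brute, rel=1e-12)

    def test_invariant_under_target_relabeling(self):
        estimates = [RNG.normal(size=256) for _ in range(3)]
        targets = [RNG.normal(size=256) for _ in range(3)]
        base = pit_loss(estimates, targets, LC).value.item()
        for sigma in itertools.permutations(range(3)):
            permuted = [targets[i] for i in sigma]
            assert pit_loss(estimates, permuted, LC).value.item() == pytest.approx(
                base, rel=1e-12)

    def test_cap_enforced(self):
        s = [np.ones(64)] * 5
        with pytest.raises(ValueError, match="cap"):
            pit_loss(s, s, LC)


def micro_separator():
    species = SpeciesConfig(name="micro", rate=8000, T=64, nfft=16, hop=8,
                            highpass=None, V=2, unet_depth=1, unet_pool=2,
                            clf_dropout=0.0)
    cfg = SeparatorConfig(species=species, N=2, base_channels=2, seed=0)
    return Separator(cfg), species


class TestTotalLoss:
    def test_lambda_zero_equals_batch_mean_pit(self):
        sets = [[tone(500.0, 128), tone(900.0, 128)] for _ in range(3)]
        ests = [[s + 0.1 * RNG.normal(size=128) for s in st] for st in sets]
        lc = LossConfig(stft_cfg=StftConfig(nfft=32, hop=8))
        expected = np.mean([pit_loss(e, t, lc).value.item()
                            for e, t in zip(ests, sets)])
        assert total_loss(ests, sets, lc).item() == pytest.approx(expected, rel=1e-12)

    def test_l2_penalty_zero_for_zero_parameters(self):
        lc = LossConfig(stft_cfg=StftConfig(nfft=32, hop=8), l2_lambda=0.5)
        params = [Tensor(np.zeros(3), requires_grad=True)]
        sets = [[tone(500.0, 128)]]
        base = total_loss(sets, sets, lc, parameters=params).item()
        assert base == pytest.approx(0.0, abs=1e-12)

    def test_gradient_matches_finite_differences_on_micro_model(self):
        """End-to-end autodiff through encoder, U-Net, masking, iSTFT and the
        full PIT objective agrees with central finite differences."""
        model, species = micro_separator()
        lc = LossConfig(stft_cfg=species.stft, l2_lambda=1e-3)
        mix = RNG.normal(size=(1, species.T))
        targets = [[Tensor(RNG.normal(size=species.T)) for _ in range(2)]]
        params = model.parameters()
        # eval mode freezes batch-norm statistics so the loss is a pure
        # function of the parameters
        model.eval()

        def loss_eval():
            out = model.forward_waveforms(mix)
            return total_loss(out, targets, lc, parameters=params)

        loss = loss_eval()
        for p in params:
            p.grad = None
        loss.backward()
        worst = 0.0
        for p in params[:6] + params[-2:]:  # first blocks + final conv
            flat = p.data.ravel()
            grad = np.zeros_like(flat) if p.grad is None else p.grad.ravel()
            idx = RNG.choice(flat.size, size=min(5, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + 1e-6
                up = loss_eval().item()
                flat[i] = orig - 1e-6
                down = loss_eval().item()
                flat[i] = orig
                numeric = (up - down) / 2e-6
                denom = max(abs(numeric), abs(grad[i]), 1e-8)
                worst = max(worst, abs(grad[i] - numeric) / denom)
        assert worst < 1e-4


class TestTrainSeparator:
    def test_loss_decreases_and_runs_are_reproducible(self, two_voice_corpus):
        from vocalsep import DatasetSpec, build_dataset
        from vocalsep.presets import SPECIES

        toy = SPECIES["toy"]
        ds = build_dataset(two_voice_corpus,
                           DatasetSpec(N=2, n_mixtures=24, T=toy.T, seed=5))
        lc = LossConfig(stft_cfg=toy.stft)
        sched = TrainingSchedule(epochs=3, batch_size=8, seed=6, warm_epochs=1)

        def run():
            cfg = SeparatorConfig(species=toy, N=2, base_channels=4, seed=7)
            model = Separator(cfg)
            return train_separator(ds, model, lc, sched)

        _, hist_a = run()
        _, hist_b = run()
        assert hist_a[-1]["train_loss"] < hist_a[0]["train_loss"]
        assert hist_a == hist_b

    def test_empty_dataset_rejected(self):
        model, species = micro_separator()
        lc = LossConfig(stft_cfg=species.stft)
        with pytest.raises(ValueError, match="empty"):
            train_separator([], model, lc, TrainingSchedule(epochs=1))
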