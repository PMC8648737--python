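"""Signal-processing primitives: STFT round trips, dB scaling, FIR design,
duration fixing."""

import numpy as np
import pytest
from scipy import signal as ss

from vocalsep import dsp
from vocalsep.presets import SPECIES


class TestStft:
    def test_zero_waveform_gives_zero_magnitude(self):
        cfg = dsp.StftConfig(nfft=256, hop=64)
        rep = dsp.stft(dsp.Waveform(np.zeros(2048), 8000), cfg)
        assert np.all(rep.magnitude == 0)

    def test_pure_tone_peaks_at_expected_bin(self):
        # bin = round(f * nfft / rate) = round(1000 * 256 / 8000) = 32
        rate, nfft = 8000, 256
        t = np.arange(4096) / rate
        w = dsp.Waveform(np.sin(2 * np.pi * 1000.0 * t), rate)
        rep = dsp.stft(w, dsp.StftConfig(nfft=nfft, hop=64))
        interior = rep.magnitude[5:-5]
        assert np.all(np.argmax(interior, axis=1) == 32)

    def test_matches_scipy_on_shared_convention(self, rng):
        # scipy's boundary='even' is reflect padding; spectrum scaling differs
        # by the window sum
        x = rng.normal(size=2048)
        cfg = dsp.StftConfig(nfft=256, hop=64)
        rep = dsp.stft(dsp.Waveform(x, 8000), cfg)
        _, _, Z = ss.stft(x, window="hann", nperseg=256, noverlap=192,
                          boundary="even", padded=True, scaling="spectrum")
        win_sum = ss.get_window("hann", 256).sum()
        assert Z.shape[1] == rep.magnitude.shape[0]
        np.testing.assert_allclose(np.abs(Z.T) * win_sum, rep.magnitude, atol=1e-10)

    def test_linearity(self, rng):
        cfg = dsp.StftConfig(nfft=64, hop=16)
        a, b = rng.normal(size=512), rng.normal(size=512)
        za = dsp.stft(dsp.Waveform(a, 8000), cfg)
        zb = dsp.stft(dsp.Waveform(b, 8000), cfg)
        zab = dsp.stft(dsp.Waveform(a + b, 8000), cfg)
        ca = za.magnitude * np.exp(1j * za.phase)
        cb = zb.magnitude * np.exp(1j * zb.phase)
        cab = zab.magnitude * np.exp(1j * zab.phase)
        np.testing.assert_allclose(cab, ca + cb, atol=1e-9)

    def test_signal_shorter_than_window_rejected(self):
        cfg = dsp.StftConfig(nfft=256, hop=64)
        with pytest.raises(ValueError, match="shorter than one window"):
            dsp.stft(dsp.Waveform(np.zeros(100), 8000), cfg)

    def test_invalid_hop_rejected(self):
        with pytest.raises(ValueError, match="hop"):
            dsp.StftConfig(nfft=256, hop=200)


class TestIstft:
    @pytest.mark.parametrize("species", ["toy", "macaque", "dolphin", "bat"])
    def test_perfect_reconstruction_on_species_presets(self, species, rng):
        sp = SPECIES[species]
        x = rng.normal(size=sp.T)
        w = dsp.Waveform(x, sp.rate)
        rep = dsp.stft(w, sp.stft)
        rec = dsp.istft(rep, sp.T)
        assert np.max(np.abs(rec - x)) < 1e-6 * np.max(np.abs(x))

    def test_zero_magnitude_gives_zero_waveform(self):
        cfg = dsp.StftConfig(nfft=64, hop=16)
        n_frames = cfg.n_frames(512)
        rep = dsp.TimeFrequencyRepresentation(
            magnitude=np.zeros((n_frames, cfg.n_bins)),
            phase=np.zeros((n_frames, cfg.n_bins)), config=cfg)
        assert np.all(dsp.istft(rep, 512) == 0)

    def test_missing_phase_rejected(self):
        cfg = dsp.StftConfig(nfft=64, hop=16)
        rep = dsp.TimeFrequencyRepresentation(
            magnitude=np.ones((cfg.n_frames(512), cfg.n_bins)), phase=None,
            config=cfg)
        with pytest.raises(ValueError, match="phase"):
            dsp.istft(rep, 512)

    def test_linearity_on_complex_representations(self, rng):
        cfg = dsp.StftConfig(nfft=64, hop=16)
        a, b = rng.normal(size=512), rng.normal(size=512)
        za = dsp.stft(dsp.Waveform(a, 8000), cfg)
        zb = dsp.stft(dsp.Waveform(b, 8000), cfg)
        ca = za.magnitude * np.exp(1j * za.phase) + zb.magnitude * np.exp(1j * zb.phase)
        summed = dsp.TimeFrequencyRepresentation(
            magnitude=np.abs(ca), phase=np.angle(ca), config=cfg)
        np.testing.assert_allclose(
            dsp.istft(summed, 512), dsp.istft(za, 512) + dsp.istft(zb, 512),
            atol=1e-9)


class TestDbScale:
    def test_reference_values(self):
        cfg = dsp.StftConfig(nfft=64, hop=16)
        mag = np.full((cfg.n_frames(512), cfg.n_bins), 1.0)
        mag[0, 0] = 10.0
        rep = dsp.TimeFrequencyRepresentation(magnitude=mag, phase=None, config=cfg)
        db = dsp.db_scale(rep)
        assert db.scale == "db"
        assert abs(db.magnitude[1, 1]) < 1e-6  # 1.0 -> 0 dB
        assert abs(db.magnitude[0, 0] - 20.0) < 1e-6  # 10.0 -> 20 dB

    def test_round_trip(self, rng):
        cfg = dsp.StftConfig(nfft=64, hop=16)
        mag = rng.uniform(1e-3, 10.0, size=(cfg.n_frames(512), cfg.n_bins))
        rep = dsp.TimeFrequencyRepresentation(magnitude=mag, phase=None, config=cfg)
        back = dsp.inv_db_scale(dsp.db_scale(rep))
        assert np.max(np.abs(back.magnitude - mag) / mag) < 1e-6

    def test_scale_contract_errors(self):
        cfg = dsp.StftConfig(nfft=64, hop=16)
        rep = dsp.TimeFrequencyRepresentation(
            magnitude=np.ones((cfg.n_frames(512), cfg.n_bins)), phase=None,
            config=cfg)
        with pytest.raises(ValueError):
            dsp.inv_db_scale(rep)
        with pytest.raises(ValueError):
            dsp.db_scale(dsp.db_scale(rep))


class TestHighpass:
    def test_kernel_properties(self):
        spec = dsp.SincFilterSpec(cutoff=0.049, transition_bandwidth=0.08)
        h = dsp.design_highpass(spec)
        assert len(h) == 51  # 2*ceil(2/0.08) + 1
        assert len(h) % 2 == 1
        np.testing.assert_array_equal(h, h[::-1])  # linear phase
        assert abs(h.sum()) < 1e-3  # DC killed

    def test_passband_gain_near_unity(self):
        spec = dsp.SincFilterSpec(cutoff=0.049, transition_bandwidth=0.08)
        h = dsp.design_highpass(spec)
        w, resp = ss.freqz(h, worN=4096)
        gain = np.abs(resp)[np.argmin(np.abs(w / (2 * np.pi) - 0.25))]
        assert abs(gain - 1.0) < 0.01

    def test_stopband_attenuation(self):
        # transition band must fit below the cutoff for the stopband spec
        spec = dsp.SincFilterSpec(cutoff=0.25, transition_bandwidth=0.08)
        h = dsp.design_highpass(spec)
        w, resp = ss.freqz(h, worN=8192)
        f = w / (2 * np.pi)
        stop = np.abs(resp)[f <= spec.cutoff / 2]
        assert 20 * np.log10(stop.max()) < -40.0

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            dsp.SincFilterSpec(cutoff=0.5)

    @pytest.mark.parametrize("freq,expected", [(100.0, "stop"), (20000.0, "pass")])
    def test_tone_response_at_dolphin_cutoff(self, freq, expected):
        rate = 96000.0
        spec = dsp.SincFilterSpec(cutoff=4700 / rate, transition_bandwidth=0.08)
        t = np.arange(int(0.2 * rate)) / rate
        x = dsp.Waveform(np.sin(2 * np.pi * freq * t), rate)
        y = dsp.apply_highpass(x, spec)
        ratio = np.sqrt(np.mean(y.samples**2)) / np.sqrt(np.mean(x.samples**2))
        if expected == "stop":
            assert ratio < 0.05
        else:
            assert abs(ratio - 1.0) < 0.05

    def test_zero_in_zero_out_and_length(self):
        spec = dsp.SincFilterSpec(cutoff=0.1)
        y = dsp.apply_highpass(dsp.Waveform(np.zeros(777), 8000), spec)
        assert len(y) == 777
        assert np.all(y.samples == 0)


class TestDurations:
    def test_fix_duration_pads_and_truncates(self):
        w = dsp.Waveform(np.arange(5, dtype=float), 100)
        padded = dsp.fix_duration(w, 8)
        assert len(padded) == 8
        np.testing.assert_array_equal(padded.samples[:5], w.samples)
        assert np.all(padded.samples[5:] == 0)
        long = dsp.Waveform(np.arange(10, dtype=float), 100)
        cut = dsp.fix_duration(long, 8)
        np.testing.assert_array_equal(cut.samples, long.samples[:8])
        same = dsp.fix_duration(w, 5)
        np.testing.assert_array_equal(same.samples, w.samples)

    def test_target_length_rules(self):
        # population sigma of [100, 200, 300] is 81.6497; ceil(200 + 3*sigma) = 445
        assert dsp.target_length([100, 200, 300], "mean_plus_3sigma") == 445
        assert dsp.target_length([7, 7, 7], "mean_plus_3sigma") == 7
        assert dsp.target_length([7, 7, 7], "max") == 7
        assert dsp.target_length([1, 2], "fixed:250000") == 250000
        with pytest.raises(ValueError):
            dsp.target_length([], "max")


class TestWavIO:
    @pytest.mark.parametrize("pcm16", [False, True])
    def test_round_trip(self, tmp_path, rng, pcm16):
        w = dsp.Waveform(rng.uniform(-0.9, 0.9, size=1000), 8000)
        path = tmp_path / "x.wav"
        dsp.write_wav(path, w, pcm16=pcm16)
        back = dsp.read_wav(path, expected_rate=8000)
        tol = 1e-4 if pcm16 else 1e-6
        assert np.max(np.abs(back.samples - w.samples)) < tol

    def test_rate_mismatch_rejected_without_resample(self, tmp_path, rng):
        w = dsp.Waveform(rng.normal(size=1000), 8000)
        path = tmp_path / "x.wav"
        dsp.write_wav(path, w)
        with pytest.raises(ValueError, match="resample"):
            dsp.read_wav(path, expected_rate=16000)
        resampled = dsp.read_wav(path, expected_rate=16000, resample=True)
        assert len(resampled) == 2000
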