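"""Mel frontend, standardization, and the Gaussian degradation contract."""

import numpy as np
import pytest
from scipy.io import wavfile

from speechmanifold import (
    DegenerateDataError,
    FormatError,
    FrontendConfig,
    InvalidInputError,
    MelSpectrogram,
    NoiseConfig,
    Waveform,
    degrade,
    degrade_split,
    generate_dataset,
    load_waveform,
    mel_transform,
    standardize,
)
from speechmanifold.synthetic_speech import DatasetSplit


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + f / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


class TestLoadWaveform:
    def test_pcm16_mono(self, tmp_path):
        path = tmp_path / "a.wav"
        data = (np.sin(2 * np.pi * 440 * np.arange(16000) / 16000) * 32000).astype(np.int16)
        wavfile.write(path, 16000, data)
        w = load_waveform(path)
        assert len(w.samples) == 16000 and w.sample_rate == 16000
        assert np.max(np.abs(w.samples)) <= 1.0

    def test_stereo_averaged_to_mono(self, tmp_path):
        path = tmp_path / "st.wav"
        left = np.full(100, 16000, dtype=np.int16)
        right = np.zeros(100, dtype=np.int16)
        wavfile.write(path, 8000, np.stack([left, right], axis=1))
        w = load_waveform(path)
        assert w.samples.shape == (100,)
        np.testing.assert_allclose(w.samples, 16000 / 32768.0 / 2, rtol=1e-6)

    def test_non_wav_rejected(self, tmp_path):
        path = tmp_path / "not.wav"
        path.write_text("this is not audio")
        with pytest.raises(FormatError, match="not.wav"):
            load_waveform(path)


class TestMelTransform:
    CFG = FrontendConfig(n_mels=64, window_length=400, hop_length=160, sample_rate=16000.0)

    def test_frame_count(self):
        w = Waveform(samples=np.zeros(16000), sample_rate=16000.0)
        spec = mel_transform(w, self.CFG)
        assert spec.values.shape == (64, 98)

    def test_zero_waveform_hits_log_floor(self):
        w = Waveform(samples=np.zeros(1000), sample_rate=16000.0)
        spec = mel_transform(w, self.CFG)
        assert np.allclose(spec.values, np.log(self.CFG.log_floor))

    def test_sine_lands_in_bracketing_mel_band(self):
        # Independent oracle: band edges recomputed here from the Mel-scale
        # formula; the per-frame argmax band must bracket the tone.
        f_tone = 1000.0
        t = np.arange(16000) / 16000.0
        w = Waveform(samples=np.sin(2 * np.pi * f_tone * t), sample_rate=16000.0)
        spec = mel_transform(w, self.CFG)
        edges = _mel_to_hz(np.linspace(_hz_to_mel(0.0), _hz_to_mel(8000.0), 64 + 2))
        argmax_bands = spec.values.argmax(axis=0)
        for b in argmax_bands:
            assert edges[b] <= f_tone <= edges[b + 2]

    def test_short_waveform_rejected(self):
        w = Waveform(samples=np.zeros(100), sample_rate=16000.0)
        with pytest.raises(InvalidInputError):
            mel_transform(w, self.CFG)


class TestWavDirectory:
    def test_keyword_layout_end_to_end(self, tmp_path):
        # tiny two-word corpus synthesized from the harmonic source model
        from speechmanifold import load_wav_directory, synth_waveform

        words = {"lo": 220.0, "hi": 880.0}
        for word, f0 in words.items():
            folder = tmp_path / word
            folder.mkdir()
            for i in range(4):
                w = synth_waveform(f0, [f0 * 3], 0.3, 16000.0, seed=i)
                wavfile.write(
                    folder / f"{i}.wav", 16000, (w.samples * 32000).astype(np.int16)
                )
        cfg = FrontendConfig()
        split = load_wav_directory(tmp_path, cfg, n_frames=20, train_fraction=0.5, seed=0)
        assert split.lexicon == ["hi", "lo"]
        assert len(split.train) == 4 and len(split.test) == 4
        for s in split.train + split.test:
            assert s.values.shape == (64, 20)
            assert s.label in (0, 1)
        ids = {s.exemplar_id for s in split.train} | {s.exemplar_id for s in split.test}
        assert len(ids) == 8


class TestStandardize:
    def test_training_stats_forced(self):
        split = generate_dataset(4, 10, 0.5, seed=3, n_bands=16, n_frames=8)
        out, stats = standardize(split)
        cells = np.concatenate([s.values.ravel() for s in out.train])
        assert abs(cells.mean()) < 1e-6
        assert abs(cells.std() - 1.0) < 1e-6
        assert stats["sd"] > 0

    def test_test_split_uses_training_stats(self):
        split = generate_dataset(4, 10, 0.5, seed=3, n_bands=16, n_frames=8)
        out, stats = standardize(split)
        for raw, tx in zip(split.test, out.test):
            np.testing.assert_allclose(tx.values, (raw.values - stats["mean"]) / stats["sd"])
        test_cells = np.concatenate([s.values.ravel() for s in out.test])
        assert test_cells.mean() != pytest.approx(0.0, abs=1e-12)

    def test_constant_training_data_rejected(self):
        specs = [
            MelSpectrogram(values=np.ones((4, 4)), label=i % 2, exemplar_id=f"e{i}")
            for i in range(4)
        ]
        split = DatasetSplit(train=specs[:2], test=specs[2:], lexicon=["a", "b"], split_seed=0)
        with pytest.raises(DegenerateDataError):
            standardize(split)


class TestDegrade:
    def _std_spec(self, shape=(64, 64), seed=0):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(shape)
        return MelSpectrogram(values=(v - v.mean()) / v.std(), exemplar_id="x01", label=0)

    def test_zero_multiplier_is_identity(self):
        spec = self._std_spec()
        out = degrade(spec, NoiseConfig(sd_multiplier=0.0, dataset_sd=1.0, seed=5))
        assert np.array_equal(out.values, spec.values)
        assert out.condition == "degraded"

    def test_noise_sd_matches_contract(self):
        # chi-square bound: SE of the sample SD of n iid cells ~ sigma/sqrt(2(n-1))
        spec = self._std_spec()
        out = degrade(spec, NoiseConfig(sd_multiplier=0.1, dataset_sd=1.0, seed=5))
        diff = out.values - spec.values
        n = diff.size
        se = 0.1 / np.sqrt(2 * (n - 1))
        assert abs(diff.std(ddof=1) - 0.1) < 3 * se

    def test_noise_mean_zero(self):
        spec = self._std_spec(shape=(64, 128))
        out = degrade(spec, NoiseConfig(sd_multiplier=0.1, dataset_sd=1.0, seed=8))
        diff = out.values - spec.values
        assert abs(diff.mean()) < 3 * 0.1 / np.sqrt(diff.size)

    def test_frozen_per_exemplar(self):
        spec = self._std_spec()
        cfg = NoiseConfig(sd_multiplier=0.1, dataset_sd=1.0, seed=5)
        a = degrade(spec, cfg)
        b = degrade(spec, cfg)
        assert np.array_equal(a.values, b.values)
        other = self._std_spec(seed=1)
        other.exemplar_id = "x02"
        c = degrade(other, cfg)
        assert not np.array_equal(a.values - spec.values, c.values - other.values)

    def test_degraded_split_bookkeeping_identical(self):
        split = generate_dataset(4, 10, 0.5, seed=3, n_bands=16, n_frames=8)
        split, _ = standardize(split)
        deg = degrade_split(split, NoiseConfig(0.1, 1.0, seed=2))
        assert [s.exemplar_id for s in deg.train] == [s.exemplar_id for s in split.train]
        assert [s.label for s in deg.test] == [s.label for s in split.test]
        assert deg.lexicon == split.lexicon
        assert all(s.condition == "degraded" for s in deg.train + deg.test)
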