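"""Waveform-to-Mel-spectrogram frontend, standardization, and degradation.

The frontend mirrors a conventional speech pipeline: short-time Fourier
frames (Hann window, no padding), a 64-band triangular Mel filterbank on the
power spectrum, and a floored log.  ``standardize`` defines the unit in which
the degradation operates: after it, the training-split cells have mean 0 and
SD 1, so "0.1 standard deviations of Gaussian noise" is simply additive
N(0, 0.1**2) noise per cell.  Noise is frozen per exemplar — the degraded
dataset is a fixed transformed copy of the clean one, not fresh noise per
presentation — and the two condition arms differ in nothing else.
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

from .errors import DegenerateDataError, FormatError, InvalidInputError
from .synthetic_speech import DatasetSplit, MelSpectrogram, Waveform

__all__ = [
    "FrontendConfig",
    "NoiseConfig",
    "load_waveform",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "mel_transform",
    "load_wav_directory",
    "standardize",
    "degrade",
    "degrade_split",
]


@dataclass(frozen=True)
class FrontendConfig:
    """Mel frontend parameters (defaults: 16 kHz speech, 25 ms / 10 ms)."""

    n_mels: int = 64
    window_length: int = 400
    hop_length: int = 160
    sample_rate: float = 16000.0
    fmin: float = 0.0
    fmax: float | None = None  # None -> Nyquist
    log_floor: float = 1e-10

    def __post_init__(self):
        fmax = self.fmax if self.fmax is not None else self.sample_rate / 2.0
        if not (0 <= self.fmin < fmax <= self.sample_rate / 2.0):
            raise InvalidInputError("need 0 <= fmin < fmax <= Nyquist")
        if self.hop_length > self.window_length:
            raise InvalidInputError("hop_length must be <= window_length")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive Gaussian degradation: sigma = sd_multiplier * dataset_sd."""

    sd_multiplier: float = 0.1
    dataset_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.sd_multiplier < 0:
            raise InvalidInputError("sd_multiplier must be >= 0")
        if self.dataset_sd <= 0:
            raise InvalidInputError("dataset_sd must be > 0")


def load_waveform(path) -> Waveform:
    """Read a PCM WAV file; integer samples scaled to [-1, 1], stereo averaged."""
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad files
        raise FormatError(f"cannot read WAV file {path!s}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    return Waveform(samples=x, sample_rate=float(rate))


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(config: FrontendConfig) -> tuple[np.ndarray, np.ndarray]:
    """Triangular filters on rfft bins; returns (filters, edge frequencies).

    ``edges`` has n_mels + 2 entries; filter i spans (edges[i], edges[i+2])
    with its peak at edges[i+1].
    """
    fmax = config.fmax if config.fmax is not None else config.sample_rate / 2.0
    n_fft = config.window_length
    edges = mel_to_hz(np.linspace(hz_to_mel(config.fmin), hz_to_mel(fmax), config.n_mels + 2))
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / config.sample_rate)
    fb = np.zeros((config.n_mels, len(fft_freqs)))
    for i in range(config.n_mels):
        lo, center, hi = edges[i], edges[i + 1], edges[i + 2]
        rise = (fft_freqs - lo) / max(center - lo, 1e-12)
        fall = (hi - fft_freqs) / max(hi - center, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(rise, fall))
    return fb, edges


def mel_transform(waveform: Waveform, config: FrontendConfig) -> MelSpectrogram:
    """Log Mel power spectrogram, shape (n_mels, 1 + (len - window) // hop)."""
    x = np.asarray(waveform.samples, dtype=np.float64)
    win, hop = config.window_length, config.hop_length
    if len(x) < win:
        raise InvalidInputError(
            f"waveform of {len(x)} samples is shorter than one {win}-sample window"
        )
    n_frames = 1 + (len(x) - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hanning(win)[None, :]
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2  # (n_frames, n_bins)
    fb, _ = mel_filterbank(config)
    mel = power @ fb.T  # (n_frames, n_mels)
    values = np.log(np.maximum(mel, config.log_floor)).T  # (n_mels, n_frames)
    return MelSpectrogram(values=values)


def _fit_frames(values: np.ndarray, n_frames: int, fill: float) -> np.ndarray:
    """Center-crop or right-pad a spectrogram to exactly n_frames columns."""
    have = values.shape[1]
    if have == n_frames:
        return values
    if have > n_frames:
        start = (have - n_frames) // 2
        return values[:, start : start + n_frames]
    out = np.full((values.shape[0], n_frames), fill)
    out[:, :have] = values
    return out


def load_wav_directory(
    root,
    config: FrontendConfig,
    n_frames: int,
    train_fraction: float,
    seed: int = 0,
) -> DatasetSplit:
    """Load a keyword-corpus directory layout ``<root>/<word>/<file>.wav``.

    Each word folder becomes one lexicon entry; every readable WAV inside is
    converted to a log-Mel spectrogram cropped/padded to ``n_frames`` and
    assigned to the train or test split by a per-word seeded shuffle.  This
    path is optional: the synthetic generator is the default data source.
    """
    import os

    root = os.fspath(root)
    words = sorted(
        d for d in os.listdir(root) if os.path.isdir(os.path.join(root, d))
    )
    if len(words) < 2:
        raise InvalidInputError(f"{root} must contain at least two word folders")
    rng = np.random.default_rng(seed)
    fill = float(np.log(config.log_floor))
    train, test = [], []
    for label, word in enumerate(words):
        folder = os.path.join(root, word)
        files = sorted(f for f in os.listdir(folder) if f.lower().endswith(".wav"))
        specs = []
        for fname in files:
            spec = mel_transform(load_waveform(os.path.join(folder, fname)), config)
            spec.values = _fit_frames(spec.values, n_frames, fill)
            spec.label = label
            spec.exemplar_id = f"{word}/{fname}"
            specs.append(spec)
        if len(specs) < 2:
            raise InvalidInputError(f"word folder {word!r} needs >= 2 readable WAVs")
        n_train = int(round(len(specs) * train_fraction))
        n_train = min(max(n_train, 1), len(specs) - 1)
        order = rng.permutation(len(specs))
        for rank, idx in enumerate(order):
            (train if rank < n_train else test).append(specs[idx])
    return DatasetSplit(train=train, test=test, lexicon=words, split_seed=seed)


def standardize(split: DatasetSplit) -> tuple[DatasetSplit, dict]:
    """Standardize all spectrograms by the training split's global cell stats.

    The mean and SD are computed over every cell of every training
    spectrogram; both splits are transformed with those training statistics
    (the test split's own mean is therefore not forced to zero).
    """
    cells = np.concatenate([s.values.ravel() for s in split.train])
    mean = float(cells.mean())
    sd = float(cells.std())
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateDataError("training split has zero cell variance")

    def _tx(spec: MelSpectrogram) -> MelSpectrogram:
        out = copy.copy(spec)
        out.values = (spec.values - mean) / sd
        return out

    out_split = DatasetSplit(
        train=[_tx(s) for s in split.train],
        test=[_tx(s) for s in split.test],
        lexicon=list(split.lexicon),
        split_seed=split.split_seed,
    )
    return out_split, {"mean": mean, "sd": sd}


def _exemplar_rng(noise: NoiseConfig, exemplar_id: str) -> np.random.Generator:
    # Stable (seed, exemplar_id) -> stream mapping: CRC32 of the id string.
    tag = zlib.crc32(exemplar_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(noise.seed), tag]))


def degrade(spec: MelSpectrogram, noise: NoiseConfig) -> MelSpectrogram:
    """Add iid N(0, (sd_multiplier * dataset_sd)**2) noise, frozen per exemplar."""
    sigma = noise.sd_multiplier * noise.dataset_sd
    out = copy.copy(spec)
    rng = _exemplar_rng(noise, spec.exemplar_id)
    out.values = spec.values + rng.normal(0.0, sigma, size=spec.values.shape)
    out.condition = "degraded"
    return out


def degrade_split(split: DatasetSplit, noise: NoiseConfig) -> DatasetSplit:
    """Degrade every exemplar in both splits; bookkeeping is untouched."""
    return DatasetSplit(
        train=[degrade(s, noise) for s in split.train],
        test=[degrade(s, noise) for s in split.test],
        lexicon=list(split.lexicon),
        split_seed=split.split_seed,
    )
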