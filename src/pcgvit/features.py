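"""MFCC image features for heart-sound recordings.

A phonocardiogram is converted into a fixed 64×64×3 "image": 64
non-overlapping analysis frames (window 1024 samples at 2 kHz), 64
mel-cepstral coefficients per frame, and three channels holding the MFCCs
plus their first (Δ) and second (Δ²) temporal derivatives.  Both
transformer branches consume this same image.

The cepstral pipeline per frame is the classical one: windowed FFT →
power spectrum → triangular mel filter bank → log energies → orthonormal
DCT-II, keeping the first ``n_coeffs`` coefficients (coefficient 0 is
retained).  The mel scale uses the HTK formula m = 2595·log10(1 + f/700).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.fft import dct, rfft
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

DEFAULT_RATE = 2000


class InvalidInputError(ValueError):
    """Raised when a signal or record violates a precondition."""


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent."""


@dataclass(frozen=True)
class HeartSoundRecord:
    """One labeled heart-sound recording.

    ``subject_id`` is mandatory: the evaluation protocol splits by subject,
    never by recording, so every record must be attributable to a patient.
    """

    record_id: str
    subject_id: str
    samples: np.ndarray
    rate: int
    label: str

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise InvalidInputError(f"record {self.record_id}: samples must be a non-empty 1-D array")
        if self.rate <= 0:
            raise InvalidInputError(f"record {self.record_id}: rate must be positive")
        if not self.subject_id:
            raise InvalidInputError(f"record {self.record_id}: subject_id is required")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the MFCC image extractor.

    Defaults reproduce the published setting: 1024-sample windows with no
    overlap (hop = window), 64 mel bands, all 64 DCT coefficients kept, and
    a 64-frame target so the image is exactly 64×64×3.
    """

    window_length: int = 1024
    hop_length: int = 1024
    n_mels: int = 64
    n_coeffs: int = 64
    target_frames: int = 64
    delta_width: int = 2
    log_floor: float = 1e-10
    fmin: float = 0.0
    fmax: float | None = None  # None -> Nyquist
    window: str = "hann"
    standardize: bool = False

    def __post_init__(self):
        if self.window_length <= 0 or self.hop_length <= 0:
            raise ConfigurationError("window_length and hop_length must be positive")
        if self.n_coeffs > self.n_mels:
            raise ConfigurationError("n_coeffs cannot exceed n_mels")
        if self.delta_width < 1:
            raise ConfigurationError("delta_width must be >= 1")
        if self.window not in ("hann", "hamming", "rect"):
            raise ConfigurationError(f"unknown window {self.window!r}")

    def resolved_fmax(self, rate: int) -> float:
        fmax = rate / 2 if self.fmax is None else self.fmax
        if fmax > rate / 2 + 1e-9:
            raise ConfigurationError(f"fmax {fmax} exceeds Nyquist for rate {rate}")
        return fmax


def frame_signal(samples: Sequence[float], cfg: FeatureConfig) -> np.ndarray:
    """Slice a signal into ``window_length`` frames spaced ``hop_length`` apart.

    Trailing samples that do not fill a complete window are discarded; a
    signal shorter than one window yields zero frames (padding is the
    caller's decision).
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise InvalidInputError("samples must be a non-empty 1-D array")
    w, h = cfg.window_length, cfg.hop_length
    if x.size < w:
        return np.empty((0, w), dtype=np.float64)
    n = (x.size - w) // h + 1
    idx = np.arange(w)[None, :] + h * np.arange(n)[:, None]
    return x[idx]


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filter_bank(n_mels: int, n_fft: int, rate: int, fmin: float, fmax: float) -> np.ndarray:
    """Triangular mel filters (n_mels × (n_fft//2 + 1)) on the HTK mel scale."""
    if fmax <= fmin:
        raise ConfigurationError("fmax must exceed fmin")
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, bins.size))
    for i in range(n_mels):
        left, center, right = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bins - left) / max(center - left, 1e-12)
        down = (right - bins) / max(right - center, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_energies(frames: np.ndarray, rate: int, cfg: FeatureConfig) -> np.ndarray:
    """Mel filter-bank energies of each frame (before log and DCT)."""
    w = cfg.window_length
    if frames.shape[1] != w:
        raise ConfigurationError(f"frames have width {frames.shape[1]}, expected {w}")
    if cfg.window == "rect":
        win = np.ones(w)
    else:
        win = get_window(cfg.window, w, fftbins=True)
    spec = np.abs(rfft(frames * win, n=w, axis=1)) ** 2
    fb = mel_filter_bank(cfg.n_mels, w, rate, cfg.fmin, cfg.resolved_fmax(rate))
    return spec @ fb.T


def mfcc_frames(frames: np.ndarray, rate: int, cfg: FeatureConfig) -> np.ndarray:
    """MFCCs of each frame: DCT-II (orthonormal) of log mel energies."""
    energies = mel_energies(frames, rate, cfg)
    logE = np.log(energies + cfg.log_floor)
    coeffs = dct(logE, type=2, norm="ortho", axis=1)
    return coeffs[:, : cfg.n_coeffs]


def delta(coeffs: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression delta over a ±``width`` frame context with edge replication.

    d_t = Σ_{n=1..width} n·(c_{t+n} − c_{t−n}) / (2·Σ n²)
    """
    if width < 1:
        raise ConfigurationError("width must be >= 1")
    c = np.asarray(coeffs, dtype=np.float64)
    if c.ndim != 2:
        raise InvalidInputError("coeffs must be 2-D (frames × coefficients)")
    padded = np.pad(c, ((width, width), (0, 0)), mode="edge")
    denom = 2.0 * sum(n * n for n in range(1, width + 1))
    out = np.zeros_like(c)
    T = c.shape[0]
    for n in range(1, width + 1):
        out += n * (padded[width + n : width + n + T] - padded[width - n : width - n + T])
    return out / denom


def make_feature_image(record: HeartSoundRecord, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Convert a recording into the 64×64×3 MFCC/Δ/Δ² image.

    Signals shorter than ``target_frames`` windows are zero-padded at the
    tail (the padded frames carry the constant silent-frame cepstrum);
    longer signals are truncated to the first ``target_frames`` frames.
    """
    cfg = cfg or FeatureConfig()
    x = record.samples
    if not np.all(np.isfinite(x)):
        raise InvalidInputError(f"record {record.record_id}: non-finite samples")
    needed = cfg.window_length + (cfg.target_frames - 1) * cfg.hop_length
    if x.size < needed:
        x = np.concatenate([x, np.zeros(needed - x.size)])
    frames = frame_signal(x, cfg)[: cfg.target_frames]
    mfcc = mfcc_frames(frames, record.rate, cfg)
    d1 = delta(mfcc, cfg.delta_width)
    d2 = delta(d1, cfg.delta_width)
    img = np.stack([mfcc, d1, d2], axis=-1)
    if not np.all(np.isfinite(img)):
        raise InvalidInputError(f"record {record.record_id}: non-finite feature image")
    return img


def make_feature_tiles(record: HeartSoundRecord, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Split a long recording into consecutive 64-frame segments.

    Alternative to truncation: each segment of ``target_frames`` windows
    becomes one image (the last segment is zero-padded), so inference can
    vote over tiles instead of discarding everything past ~33 s.  Returns
    an (n_tiles, frames, coeffs, 3) array with n_tiles ≥ 1.
    """
    cfg = cfg or FeatureConfig()
    seg = cfg.window_length + (cfg.target_frames - 1) * cfg.hop_length
    x = record.samples
    n_tiles = max(1, int(np.ceil(x.size / seg)))
    tiles = []
    for i in range(n_tiles):
        piece = x[i * seg: (i + 1) * seg]
        sub = HeartSoundRecord(record_id=f"{record.record_id}#t{i}",
                               subject_id=record.subject_id, samples=piece,
                               rate=record.rate, label=record.label)
        tiles.append(make_feature_image(sub, cfg))
    return np.stack(tiles)


def standardize_images(images: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None):
    """Cepstral mean/variance normalization per coefficient and channel.

    Each of the 64×3 coefficient tracks is z-scored over records and
    frames — the standard CMVN treatment for cepstral inputs (a single
    scalar per channel would leave coefficient 0 dominating the image by
    two orders of magnitude).  ``stats=(mean, std)`` is fitted on the
    training images when None and returned for reuse on validation/test.
    """
    images = np.asarray(images, dtype=np.float64)
    axes = (0, 1) if images.ndim == 4 else (0,)
    if stats is None:
        mean = images.mean(axis=axes)
        std = images.std(axis=axes)
        std = np.where(std < 1e-12, 1.0, std)
        stats = (mean, std)
    mean, std = stats
    return (images - mean) / std, stats


# -- WAV and feature-cache I/O ------------------------------------------------

def read_wav(path, target_rate: int = DEFAULT_RATE) -> tuple[np.ndarray, int]:
    """Read a mono WAV (PCM16/32 or float) and resample to ``target_rate``."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if rate != target_rate:
        frac = Fraction(target_rate, rate).limit_denominator(1000)
        data = resample_poly(data, frac.numerator, frac.denominator)
        rate = target_rate
    return data, rate


def write_wav(path, samples: np.ndarray, rate: int = DEFAULT_RATE) -> None:
    """Write float samples as 16-bit PCM, clipping to [-1, 1]."""
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    wavfile.write(path, rate, (x * 32767.0).astype(np.int16))


def save_feature_cache(path, images: dict[str, np.ndarray]) -> None:
    """Persist feature images keyed by record_id as a single NPZ archive."""
    np.savez_compressed(Path(path), **{k: np.asarray(v) for k, v in images.items()})


def load_feature_cache(path) -> dict[str, np.ndarray]:
    with np.load(Path(path)) as archive:
        return {k: archive[k] for k in archive.files}
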