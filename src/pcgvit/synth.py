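"""Synthetic phonocardiogram generator.

Emulates the salient structure of public heart-sound corpora — 2 kHz mono
recordings of 5–120 s, a periodic S1/S2 double transient at a plausible
heart rate, pink background noise, several recordings per subject — with a
single class-separability knob: murmur-positive recordings carry
band-limited (150–400 Hz by default) noise during systole at a chosen SNR
relative to the background.  "Unknown" recordings (three-class mode) carry
a faint, ambiguous murmur.

The generator is plumbing for testing the pipeline, not a physiological
model: S1/S2 are damped sinusoids, systole is a fixed 0.35 of the cardiac
cycle, and no effort is made at clinical murmur morphology.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfilt

from .features import DEFAULT_RATE, HeartSoundRecord, write_wav


class ConfigurationError(ValueError):
    pass


SYSTOLE_FRACTION = 0.35  # fraction of the cardiac cycle from S1 onset to S2 onset


@dataclass(frozen=True)
class SynthConfig:
    """Dataset-level generator parameters.

    ``murmur_snr_db`` sets murmur band power relative to the pink
    background (dB); it is the single knob controlling class separability.
    """

    n_subjects: int = 40
    records_per_subject: int = 3
    rate: int = DEFAULT_RATE
    duration_range: tuple[float, float] = (5.0, 35.0)
    heart_rate_range: tuple[float, float] = (55.0, 95.0)
    murmur_band: tuple[float, float] = (150.0, 400.0)
    murmur_snr_db: float = 10.0
    class_mode: str = "binary"  # binary | three_class
    unknown_fraction: float = 0.2
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.duration_range
        if not (5.0 <= lo <= hi <= 120.0):
            raise ConfigurationError("duration_range must lie within [5, 120] s")
        if self.class_mode not in ("binary", "three_class"):
            raise ConfigurationError(f"unknown class_mode {self.class_mode!r}")
        if self.n_subjects < 2 * self.n_classes:
            raise ConfigurationError("need at least 2 subjects per class")

    @property
    def labels(self) -> tuple[str, ...]:
        return (("normal", "abnormal") if self.class_mode == "binary"
                else ("present", "unknown", "absent"))

    @property
    def n_classes(self) -> int:
        return 2 if self.class_mode == "binary" else 3

    @property
    def positive_labels(self) -> tuple[str, ...]:
        """Labels whose recordings carry a murmur component."""
        return ("abnormal",) if self.class_mode == "binary" else ("present", "unknown")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject physiology: heart rate, transient frequencies, amplitude."""

    subject_id: str
    label: str
    heart_rate: float
    s1_freq: float
    s2_freq: float
    amplitude: float


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise via spectral shaping, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / (np.std(x) + 1e-12)


def _damped_tone(rate: int, freq: float, duration: float, decay: float) -> np.ndarray:
    t = np.arange(int(duration * rate)) / rate
    return np.sin(2 * np.pi * freq * t) * np.exp(-t / decay)


def make_profile(subject_id: str, label: str, cfg: SynthConfig,
                 rng: np.random.Generator) -> SubjectProfile:
    return SubjectProfile(
        subject_id=subject_id,
        label=label,
        heart_rate=float(rng.uniform(*cfg.heart_rate_range)),
        s1_freq=float(rng.uniform(30.0, 80.0)),
        s2_freq=float(rng.uniform(80.0, 150.0)),
        amplitude=float(rng.uniform(0.4, 0.8)),
    )


def generate_recording(profile: SubjectProfile, cfg: SynthConfig, seed: int,
                       record_id: str | None = None,
                       duration: float | None = None) -> HeartSoundRecord:
    """One deterministic synthetic recording for a subject.

    The waveform is an S1/S2 transient train at the subject's heart rate
    plus pink noise; murmur-positive labels add systolic band-limited noise
    at ``murmur_snr_db`` (unknowns at a much lower, ambiguous SNR).
    """
    if profile.label not in cfg.labels:
        raise ConfigurationError(f"label {profile.label!r} not in {cfg.labels}")
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = float(rng.uniform(*cfg.duration_range))
    n = int(round(duration * cfg.rate))
    signal = np.zeros(n)
    cycle = 60.0 / profile.heart_rate
    s1 = _damped_tone(cfg.rate, profile.s1_freq, 0.10, 0.02)
    s2 = _damped_tone(cfg.rate, profile.s2_freq, 0.08, 0.015)

    systole_mask = np.zeros(n, dtype=bool)
    t0 = float(rng.uniform(0, 0.1))
    while t0 * cfg.rate < n:
        i1 = int(t0 * cfg.rate)
        seg = min(len(s1), n - i1)
        signal[i1:i1 + seg] += profile.amplitude * s1[:seg]
        i2 = int((t0 + SYSTOLE_FRACTION * cycle) * cfg.rate)
        if i2 < n:
            seg2 = min(len(s2), n - i2)
            signal[i2:i2 + seg2] += 0.8 * profile.amplitude * s2[:seg2]
        systole_mask[min(i1 + len(s1), n): min(i2, n)] = True
        t0 += cycle

    noise = cfg.noise_level * _pink_noise(n, rng)
    signal += noise

    if profile.label in cfg.positive_labels:
        snr_db = cfg.murmur_snr_db if profile.label in ("abnormal", "present") \
            else cfg.murmur_snr_db - 12.0
        sos = butter(4, cfg.murmur_band, btype="bandpass", fs=cfg.rate, output="sos")
        murmur = sosfilt(sos, rng.standard_normal(n))
        murmur /= np.std(murmur) + 1e-12
        target_rms = cfg.noise_level * 10.0 ** (snr_db / 20.0)
        signal += target_rms * murmur * systole_mask

    peak = np.max(np.abs(signal))
    if peak > 1.0:
        signal = signal / (peak * 1.01)
    rid = record_id or f"{profile.subject_id}_r0"
    return HeartSoundRecord(record_id=rid, subject_id=profile.subject_id,
                            samples=signal, rate=cfg.rate, label=profile.label)


def assign_labels(cfg: SynthConfig, rng: np.random.Generator) -> list[str]:
    """Per-subject class assignment honoring ``unknown_fraction``."""
    n = cfg.n_subjects
    if cfg.class_mode == "binary":
        labels = ["abnormal"] * (n // 2) + ["normal"] * (n - n // 2)
    else:
        n_unknown = int(round(cfg.unknown_fraction * n))
        rest = n - n_unknown
        labels = (["unknown"] * n_unknown + ["present"] * (rest // 2)
                  + ["absent"] * (rest - rest // 2))
    for lab in cfg.labels:
        if labels.count(lab) < 2:
            raise ConfigurationError(f"class {lab!r} would receive fewer than 2 subjects")
    rng.shuffle(labels)
    return labels


def generate_dataset(cfg: SynthConfig) -> list[HeartSoundRecord]:
    """Deterministic labeled dataset with multiple recordings per subject."""
    root_ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root_ss.spawn(1)[0])
    labels = assign_labels(cfg, rng)
    records = []
    for si in range(cfg.n_subjects):
        sid = f"subj{si:03d}"
        profile = make_profile(sid, labels[si], cfg, rng)
        for ri in range(cfg.records_per_subject):
            seed = int(np.random.SeedSequence([cfg.seed, si, ri]).generate_state(1)[0] % (2**31))
            records.append(generate_recording(profile, cfg, seed,
                                              record_id=f"{sid}_r{ri}"))
    return records


def write_dataset(records: list[HeartSoundRecord], out_dir) -> Path:
    """Write WAVs plus a manifest CSV; returns the manifest path.

    The manifest schema (record_id, subject_id, path, label) is identical
    for synthetic and real data, so downstream code is source-agnostic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "subject_id", "path", "label"])
        for r in records:
            wav_path = out_dir / f"{r.record_id}.wav"
            write_wav(wav_path, r.samples, r.rate)
            writer.writerow([r.record_id, r.subject_id, wav_path.name, r.label])
    return manifest


def benchmark_config(seed: int = 0, class_mode: str = "binary") -> SynthConfig:
    """The standard synthetic benchmark used by the learning tests.

    40 subjects × 3 recordings at murmur SNR +10 dB; durations kept to
    5–15 s purely to bound CPU/disk (the model input is a fixed 64×64×3
    image regardless of duration).
    """
    return SynthConfig(n_subjects=40, records_per_subject=3,
                       duration_range=(5.0, 15.0), murmur_snr_db=10.0,
                       class_mode=class_mode, seed=seed)
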