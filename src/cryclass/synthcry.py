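"""Seeded generator of synthetic cry-like clips.

Source-filter synthesis: a glottal-like pulse train at a class-conditional
fundamental frequency (within the 250-600 Hz cry band, with slow vibrato)
is passed through two-pole formant resonators and shaped by a burst/pause
amplitude envelope; the pauses emulate inspiration between expiratory cry
units and exercise end-point detection.  White noise is added at a
configurable SNR.  Every clip carries its ground truth (label, true F0,
voiced intervals, sex tag), so each pipeline stage can be tested offline
against known answers.

Class acoustics are parameterized, not claimed to be realistic: the
``separable`` preset gives the three classes disjoint F0 bands and distinct
formants, while ``overlapping`` gives them identical F0 bands and formants
differing by under 5% — a controlled difficulty knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from .preprocess import AudioClip, write_wav

CLASSES = ("hunger", "sleep", "discomfort")


@dataclass
class ClassAcoustics:
    """Per-class source-filter parameters."""

    f0_range: tuple[float, float]  # Hz, within the cry band
    formants: tuple[float, ...]  # resonance centers, Hz
    formant_bw: float = 150.0  # Hz, shared resonator bandwidth
    formant_jitter: float = 0.05  # per-clip fractional spread (inter-infant variation)
    burst_ms: tuple[float, float] = (600.0, 900.0)
    pause_ms: tuple[float, float] = (200.0, 350.0)

    def __post_init__(self) -> None:
        lo, hi = self.f0_range
        if not (200.0 <= lo < hi <= 700.0):
            raise ValueError(f"f0_range {self.f0_range} must lie within [200, 700] Hz")
        if min(self.burst_ms) <= 0 or min(self.pause_ms) <= 0:
            raise ValueError("burst/pause durations must be positive")


@dataclass
class SynthConfig:
    classes: dict[str, ClassAcoustics]
    sample_rate: int = 16000
    clip_duration_s: float = 2.0
    snr_db: float = 25.0
    vibrato_depth: float = 0.02
    vibrato_rate_hz: float = 5.0
    ramp_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clip_duration_s <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample rate must be positive")
        for label, ac in self.classes.items():
            if max(ac.formants) >= self.sample_rate / 2:
                raise ValueError(
                    f"class {label!r} formant above Nyquist at fs={self.sample_rate}"
                )


def preset(
    name: str = "separable",
    sample_rate: int = 16000,
    clip_duration_s: float = 2.0,
    snr_db: float | None = None,
    seed: int = 0,
) -> SynthConfig:
    """Built-in class-acoustics presets.

    ``separable``: disjoint F0 bands (sleep 260-330, hunger 400-480,
    discomfort 500-590 Hz) and well-spaced formants.  ``overlapping``:
    identical F0 bands and formants differing by < 5%.
    """
    if name == "separable":
        classes = {
            "hunger": ClassAcoustics((400.0, 480.0), (1000.0, 2800.0, 4500.0)),
            "sleep": ClassAcoustics((260.0, 330.0), (700.0, 2200.0, 3600.0)),
            "discomfort": ClassAcoustics((500.0, 590.0), (1400.0, 3200.0, 5300.0)),
        }
    elif name == "overlapping":
        classes = {
            "hunger": ClassAcoustics((350.0, 450.0), (1000.0, 2800.0, 4500.0)),
            "sleep": ClassAcoustics((350.0, 450.0), (1010.0, 2830.0, 4540.0)),
            "discomfort": ClassAcoustics((350.0, 450.0), (990.0, 2770.0, 4460.0)),
        }
    else:
        raise ValueError(f"unknown preset {name!r}")
    cfg = SynthConfig(
        classes=classes,
        sample_rate=sample_rate,
        clip_duration_s=clip_duration_s,
        seed=seed,
    )
    if snr_db is not None:
        cfg = replace(cfg, snr_db=snr_db)
    return cfg


@dataclass
class SynthClip:
    """A generated clip plus its ground truth."""

    clip: AudioClip
    label: str
    f0_track: list[float]  # mean true F0 per burst, Hz
    voiced_intervals: list[tuple[int, int]]  # half-open sample intervals
    sex: str = "unknown"
    seed: int = 0

    @property
    def f0_mean(self) -> float:
        return float(np.mean(self.f0_track)) if self.f0_track else 0.0


def _resonator_sos(freq: float, bw: float, fs: float) -> np.ndarray:
    r = math.exp(-math.pi * bw / fs)
    return np.array([[1.0, 0.0, 0.0, 1.0, -2.0 * r * math.cos(2.0 * math.pi * freq / fs), r * r]])


def _glottal_pulse_train(
    rng: np.random.Generator,
    n: int,
    fs: float,
    f0: float,
    vibrato_depth: float,
    vibrato_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Impulse train at instantaneous F0 with slow vibrato; returns (x, f0_t)."""
    t = np.arange(n) / fs
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    f0_t = f0 * (1.0 + vibrato_depth * np.sin(2.0 * np.pi * vibrato_rate * t + phase0))
    phase = np.cumsum(f0_t) / fs
    x = np.zeros(n)
    x[np.flatnonzero(np.diff(np.floor(phase)) > 0) + 1] = 1.0
    if not x.any():
        x[0] = 1.0
    return x, f0_t


def generate_clip(config: SynthConfig, class_label: str, seed: int) -> SynthClip:
    """Synthesize one labeled clip; deterministic for a given seed."""
    if class_label not in config.classes:
        raise ValueError(f"unknown class {class_label!r}; have {sorted(config.classes)}")
    ac = config.classes[class_label]
    fs = config.sample_rate
    n = int(round(config.clip_duration_s * fs))
    rng = np.random.default_rng(seed)

    signal = np.zeros(n)
    voiced: list[tuple[int, int]] = []
    f0_track: list[float] = []
    ramp = int(round(config.ramp_ms * fs / 1000.0))
    # vocal-tract length varies between infants: jitter formants per clip
    factors = 1.0 + rng.uniform(-ac.formant_jitter, ac.formant_jitter, len(ac.formants))
    sos = np.vstack(
        [_resonator_sos(f * c, ac.formant_bw, fs) for f, c in zip(ac.formants, factors)]
    )

    # leading silence, then alternating burst / pause until the clip is full
    pos = int(round(rng.uniform(*ac.pause_ms) * fs / 2000.0))
    min_burst = int(round(min(ac.burst_ms) * fs / 1000.0))
    while pos + min_burst <= n:
        burst_len = int(round(rng.uniform(*ac.burst_ms) * fs / 1000.0))
        burst_len = min(burst_len, n - pos)
        f0 = rng.uniform(*ac.f0_range)
        pulses, f0_t = _glottal_pulse_train(
            rng, burst_len, fs, f0, config.vibrato_depth, config.vibrato_rate_hz
        )
        burst = scipy.signal.sosfilt(sos, pulses)
        peak = np.max(np.abs(burst))
        if peak > 0:
            burst = burst / peak
        if ramp > 0 and burst_len > 2 * ramp:
            env = np.ones(burst_len)
            env[:ramp] = 0.5 - 0.5 * np.cos(np.pi * np.arange(ramp) / ramp)
            env[-ramp:] = env[:ramp][::-1]
            burst = burst * env
        signal[pos : pos + burst_len] = burst
        voiced.append((pos, pos + burst_len))
        f0_track.append(float(np.mean(f0_t)))
        pos += burst_len + int(round(rng.uniform(*ac.pause_ms) * fs / 1000.0))

    if not voiced:
        raise ValueError(
            f"clip of {config.clip_duration_s}s too short for bursts of {ac.burst_ms} ms"
        )

    if np.isfinite(config.snr_db):
        voiced_mask = np.zeros(n, dtype=bool)
        for a, b in voiced:
            voiced_mask[a:b] = True
        sig_power = float(np.mean(signal[voiced_mask] ** 2))
        noise_power = sig_power / (10.0 ** (config.snr_db / 10.0))
        signal = signal + rng.normal(0.0, math.sqrt(noise_power), n)

    signal = 0.9 * signal / np.max(np.abs(signal))
    clip = AudioClip(signal, fs, label=class_label, source_id=f"{class_label}_{seed}")
    return SynthClip(clip, class_label, f0_track, voiced, seed=seed)


def generate_dataset(
    config: SynthConfig,
    n_per_class: int | dict[str, int],
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[SynthClip], pd.DataFrame]:
    """Generate a labeled dataset with alternating sex tags and a manifest.

    ``n_per_class`` is either one count for every class or a per-class
    mapping.  When ``out_dir`` is given, 16-bit PCM WAV files and a
    manifest CSV (file, label, sex, seed, f0_true_mean) are written there.
    """
    if isinstance(n_per_class, int):
        if n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        counts = {label: n_per_class for label in config.classes}
    else:
        counts = dict(n_per_class)
    rng = np.random.default_rng(seed)
    clips: list[SynthClip] = []
    records = []
    i = 0
    for label in config.classes:
        for _ in range(counts.get(label, 0)):
            clip_seed = int(rng.integers(2**31))
            sex = "male" if i % 2 == 0 else "female"
            sc = generate_clip(config, label, clip_seed)
            sc.sex = sex
            sc.clip.source_id = f"{label}_{i:04d}"
            clips.append(sc)
            records.append(
                {
                    "file": f"{sc.clip.source_id}.wav",
                    "label": label,
                    "sex": sex,
                    "seed": clip_seed,
                    "f0_true_mean": sc.f0_mean,
                }
            )
            i += 1
    manifest = pd.DataFrame(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sc, rec in zip(clips, records):
            write_wav(out_dir / rec["file"], sc.clip)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return clips, manifest
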