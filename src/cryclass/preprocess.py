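"""Audio preprocessing for infant-cry analysis.

The chain turns a raw WAV clip into windowed, FFT-transformed frames
restricted to detected cry units (contiguous voiced expiratory segments):

    normalize -> cry-unit detection -> pre-emphasis -> framing
              -> Hamming window -> FFT magnitude

Cry-unit detection runs on the un-preemphasized signal because short-time
energy thresholds are more stable before the high-pass pre-emphasis filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.io.wavfile


class DegenerateSignalError(ValueError):
    """Raised for all-zero or otherwise unusable audio."""


class AudioFormatError(ValueError):
    """Raised when a file cannot be read as PCM WAV."""


@dataclass
class AudioClip:
    """A mono waveform with its sample rate and optional class label.

    ``samples`` are dimensionless amplitudes, in [-1, 1] after
    :func:`normalize`.  ``label`` is one of hunger / sleep / discomfort
    when known.
    """

    samples: np.ndarray
    sample_rate: int
    label: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise DegenerateSignalError("AudioClip requires a non-empty 1-D signal")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class CryUnit:
    """Half-open sample interval [start_sample, end_sample) of one cry unit."""

    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_sample < self.end_sample:
            raise ValueError(f"invalid cry unit [{self.start_sample}, {self.end_sample})")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class FrameSequence:
    """Matrix of fixed-length analysis frames.

    Row j is the time-domain signal S_j(n), n = 0..N-1, of the j-th frame.
    ``cry_unit_mask`` flags frames lying inside a detected cry unit.
    """

    frames: np.ndarray  # (n_frames, N)
    frame_length: int
    hop: int
    sample_rate: int
    cry_unit_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=np.float64))
        if self.frame_length <= 0 or not 0 < self.hop <= self.frame_length:
            raise ValueError("require frame_length > 0 and 0 < hop <= frame_length")
        if self.frames.shape[1] != self.frame_length:
            raise ValueError("frame rows must have exactly frame_length samples")
        if self.cry_unit_mask is None:
            self.cry_unit_mask = np.ones(len(self.frames), dtype=bool)
        self.cry_unit_mask = np.asarray(self.cry_unit_mask, dtype=bool)
        if self.cry_unit_mask.shape != (len(self.frames),):
            raise ValueError("cry_unit_mask length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class SpectrumSequence:
    """One-sided FFT magnitude spectra, one row |S'_j(i)| per frame."""

    spectra: np.ndarray  # (n_frames, N//2 + 1)
    sample_rate: int
    frame_length: int

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=np.float64))

    @property
    def bin_hz(self) -> float:
        """Frequency resolution in Hz per FFT bin."""
        return self.sample_rate / self.frame_length


# ---------------------------------------------------------------------------
# WAV I/O

_INT_SCALE = {np.dtype(np.int16): 32768.0, np.dtype(np.int32): 2147483648.0}


def read_wav(path: str | Path, label: str | None = None) -> AudioClip:
    """Read a PCM WAV file as a mono :class:`AudioClip`.

    Integer samples are scaled to [-1, 1) by full-scale division; stereo is
    mixed down by channel averaging (the recordings this pipeline targets
    come from a single camcorder microphone).
    """
    path = Path(path)
    try:
        sample_rate, data = scipy.io.wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any decode failure
        raise AudioFormatError(f"cannot read {path} as PCM WAV: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise AudioFormatError(f"{path} contains no samples")
    if data.dtype in _INT_SCALE:
        samples = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32/float64 subtypes are already full-scale
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioClip(samples, int(sample_rate), label=label, source_id=path.stem)


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV."""
    data = np.clip(clip.samples, -1.0, 1.0)
    scipy.io.wavfile.write(str(path), clip.sample_rate, (data * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# The seven-step chain

def normalize(clip: AudioClip) -> AudioClip:
    """Peak-normalize so that max |sample| is exactly 1."""
    peak = np.max(np.abs(clip.samples))
    if peak == 0.0:
        raise DegenerateSignalError(f"clip {clip.source_id!r} is all-zero; cannot normalize")
    return replace(clip, samples=clip.samples / peak)


def preemphasize(samples: np.ndarray, alpha: float = 0.97) -> np.ndarray:
    """First-order high-pass y[n] = x[n] - alpha * x[n-1], y[0] = x[0]."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    x = np.asarray(samples, dtype=np.float64)
    y = x.copy()
    y[1:] -= alpha * x[:-1]
    return y


def frame_signal(
    segment: np.ndarray,
    frame_length: int,
    hop: int,
    sample_rate: int,
    cry_unit_mask: np.ndarray | None = None,
) -> FrameSequence:
    """Slice a signal into overlapping frames; trailing samples are dropped."""
    x = np.asarray(segment, dtype=np.float64)
    if x.size < frame_length:
        raise ValueError(
            f"segment of {x.size} samples is shorter than frame_length={frame_length}"
        )
    n_frames = (x.size - frame_length) // hop + 1
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    return FrameSequence(x[idx], frame_length, hop, sample_rate, cry_unit_mask)


def hamming_window(n: int) -> np.ndarray:
    """Hamming window w[n] = 0.54 - 0.46 cos(2 pi n / (N - 1))."""
    if n == 1:
        return np.ones(1)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * np.arange(n) / (n - 1))


def window_and_fft(frames: FrameSequence) -> SpectrumSequence:
    """Hamming-window each frame and keep the one-sided FFT magnitude."""
    if frames.n_frames == 0:
        raise ValueError("empty FrameSequence")
    windowed = frames.frames * hamming_window(frames.frame_length)[None, :]
    spectra = np.abs(np.fft.rfft(windowed, axis=1))
    return SpectrumSequence(spectra, frames.sample_rate, frames.frame_length)


# ---------------------------------------------------------------------------
# End-point / cry-unit detection

def short_time_energy(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Mean squared amplitude per analysis window."""
    n = (x.size - win) // hop + 1
    if n <= 0:
        return np.array([np.mean(x**2)])
    idx = np.arange(win)[None, :] + hop * np.arange(n)[:, None]
    return np.mean(x[idx] ** 2, axis=1)


def frame_zcr(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Sign-change rate per analysis window (zeros inherit the previous sign)."""
    n = (x.size - win) // hop + 1
    if n <= 0:
        return np.array([_zcr_1d(x)])
    idx = np.arange(win)[None, :] + hop * np.arange(n)[:, None]
    return np.array([_zcr_1d(row) for row in x[idx]])


def _zcr_1d(frame: np.ndarray) -> float:
    s = np.sign(frame)
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    return float(np.count_nonzero(s[1:] != s[:-1])) / max(frame.size - 1, 1)


def detect_cry_units(
    clip: AudioClip,
    energy_hi: float = 0.10,
    energy_lo: float = 0.02,
    zcr_max: float = 0.5,
    min_unit_ms: float = 100.0,
    min_gap_ms: float = 50.0,
    win_ms: float = 20.0,
    hop_ms: float = 10.0,
) -> list[CryUnit]:
    """Double-threshold end-point detection of cry units.

    Analysis windows whose short-time energy reaches ``energy_hi`` times the
    clip's maximum window energy seed a unit; the unit is expanded outward
    while the energy stays above ``energy_lo`` times the maximum and the
    zero-crossing rate stays at or below ``zcr_max`` (the ZCR guard rejects
    fricative-like noise tails).  Units closer than ``min_gap_ms`` are
    merged; units shorter than ``min_unit_ms`` are discarded.  Pure silence
    yields an empty list.
    """
    x = clip.samples
    win = max(int(round(win_ms * clip.sample_rate / 1000.0)), 2)
    hop = max(int(round(hop_ms * clip.sample_rate / 1000.0)), 1)
    if x.size < win:
        return []
    energy = short_time_energy(x, win, hop)
    e_max = energy.max()
    if e_max == 0.0:
        return []
    zcr = frame_zcr(x, win, hop)
    hi = energy >= energy_hi * e_max
    lo = (energy >= energy_lo * e_max) & (zcr <= zcr_max)

    n = energy.size
    active = np.zeros(n, dtype=bool)
    for seed in np.flatnonzero(hi):
        if active[seed]:
            continue
        a = seed
        while a > 0 and lo[a - 1]:
            a -= 1
        b = seed
        while b < n - 1 and lo[b + 1]:
            b += 1
        active[a : b + 1] = True

    # each active window contributes its hop span; using the full window
    # length would over-extend unit tails into silence by win - hop samples
    intervals: list[list[int]] = []
    for j in np.flatnonzero(active):
        start = j * hop
        end = min(j * hop + hop, x.size)
        if intervals and start <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], end)
        else:
            intervals.append([start, end])

    # merge across short gaps, then drop short units
    min_gap = int(round(min_gap_ms * clip.sample_rate / 1000.0))
    merged: list[list[int]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < min_gap:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)
    min_len = int(round(min_unit_ms * clip.sample_rate / 1000.0))
    return [CryUnit(a, b) for a, b in merged if b - a >= min_len]
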