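"""The twelve acoustic features used for cry classification.

Time domain (per frame): magnitude, average, variance, zero-crossing rate.
Frequency domain: pitch (autocorrelation F0), bandwidth (spectral spread),
peak/valley (log mean of the largest / smallest spectral magnitudes per
subband), formants F1-F6 (LPC root finding), LPCC, MFCC and delta-MFCC.

``extract_features`` composes the preprocessing chain with all extractors
and aggregates per-frame values into one labeled clip-level row (mean and
standard deviation of every dimension over cry-unit frames).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft

from .preprocess import (
    AudioClip,
    _zcr_1d,
    detect_cry_units,
    frame_signal,
    normalize,
    preemphasize,
    window_and_fft,
)

logger = logging.getLogger(__name__)

LOG_FLOOR = 1e-10

CLASSES = ("hunger", "sleep", "discomfort")


class NoCryDetectedError(ValueError):
    """Raised when a clip contains no usable cry unit."""


@dataclass
class FeatureConfig:
    """Extraction parameters.

    Frame geometry is in samples (defaults: 1024-sample frames, 50% hop —
    about 23 ms at 44.1 kHz).  Pitch uses a longer dedicated window because
    a single analysis frame holds too few periods at the low end of the
    250-600 Hz cry band.  ``subband_edges`` are fractions of the Nyquist
    frequency delimiting the peak/valley subbands.
    """

    frame_length: int = 1024
    hop: int = 512
    preemphasis_alpha: float = 0.97
    # end-point detection
    energy_hi: float = 0.10
    energy_lo: float = 0.02
    zcr_max: float = 0.5
    min_unit_ms: float = 100.0
    min_gap_ms: float = 50.0
    # peak / valley
    peak_alpha: float = 0.2
    subband_edges: tuple[float, ...] = (0.0, 1 / 32, 1 / 8, 1 / 2, 1.0)
    peak_valley_mode: str = "sorted"
    # pitch
    f0_min: float = 250.0
    f0_max: float = 600.0
    voicing_threshold: float = 0.3
    pitch_window: int = 4096
    # formants / LPCC
    lpc_order: int = 18
    formant_bw_max: float = 700.0
    n_formants: int = 6
    lpcc_order: int = 12
    # MFCC
    n_mels: int = 26
    n_mfcc: int = 12
    delta_window: int = 2
    # classification unit
    unit: str = "clip"  # "clip" or "frame"

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["subband_edges"] = list(self.subband_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        if "subband_edges" in d:
            d["subband_edges"] = tuple(d["subband_edges"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Time-domain features

def magnitude(frame: np.ndarray) -> float:
    """Sum of absolute amplitudes (distance from zero regardless of sign)."""
    return float(np.sum(np.abs(frame)))


def average(frame: np.ndarray) -> float:
    """Arithmetic mean of the signed samples."""
    return float(np.mean(frame))


def variance(frame: np.ndarray) -> float:
    """Population variance (divisor N)."""
    return float(np.var(frame))


def zero_crossing_rate(frame: np.ndarray) -> float:
    """Fraction of adjacent-sample pairs whose signs differ.

    Zero samples inherit the previous sample's sign; the first sample keeps
    sign zero when it is zero, so a leading zero followed by a nonzero
    sample counts as one crossing.
    """
    return _zcr_1d(np.asarray(frame, dtype=np.float64))


# ---------------------------------------------------------------------------
# Spectral features

def bandwidth(spectrum_row: np.ndarray) -> float:
    """Magnitude-squared-weighted spectral spread about the centroid, in bin^2.

    FB = sum w_i (i - FC)^2 / sum w_i with w_i = |S'(i)|^2 and FC the
    weighted centroid.  An all-zero spectrum yields 0 with a warning.
    """
    w = np.asarray(spectrum_row, dtype=np.float64) ** 2
    total = w.sum()
    if total == 0.0:
        logger.warning("bandwidth of all-zero spectrum defined as 0")
        return 0.0
    i = np.arange(w.size)
    fc = float(np.dot(i, w) / total)
    return float(np.dot(w, (i - fc) ** 2) / total)


def subband_bins(n_bins: int, edges: tuple[float, ...]) -> list[tuple[int, int]]:
    """Convert Nyquist-fraction subband edges to half-open bin ranges."""
    bounds = [int(round(f * n_bins)) for f in edges]
    bounds[0], bounds[-1] = 0, n_bins
    bands = [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]
    if any(b <= a for a, b in bands):
        raise ValueError(f"empty subband in partition {bands} of {n_bins} bins")
    return bands


def peak_valley(
    spectrum_row: np.ndarray,
    subbands: list[tuple[int, int]],
    alpha: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Log mean of the top / bottom ``alpha`` fraction of magnitudes per subband.

    Magnitudes within each subband are sorted descending; the peak is the
    natural log of the mean of the top ceil(alpha * N_k) values and the
    valley the log of the mean of the bottom ceil(alpha * N_k), both floored
    at log(1e-10).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    row = np.asarray(spectrum_row, dtype=np.float64)
    peaks, valleys = [], []
    for a, b in subbands:
        band = np.sort(row[a:b])[::-1]
        if band.size == 0:
            raise ValueError(f"subband [{a}, {b}) is empty")
        m = math.ceil(alpha * band.size)
        peaks.append(math.log(max(band[:m].mean(), LOG_FLOOR)))
        valleys.append(math.log(max(band[band.size - m :].mean(), LOG_FLOOR)))
    return np.array(peaks), np.array(valleys)


def pitch_autocorr(
    segment: np.ndarray,
    sample_rate: float,
    f0_min: float = 250.0,
    f0_max: float = 600.0,
    voicing_threshold: float = 0.3,
) -> float:
    """Fundamental frequency by the normalized-autocorrelation peak.

    Searches lags between 1/f0_max and 1/f0_min seconds; the peak location
    is refined by parabolic interpolation.  Returns 0 (unvoiced) when the
    normalized autocorrelation peak falls below ``voicing_threshold``.
    """
    x = np.asarray(segment, dtype=np.float64)
    min_len = int(math.ceil(2.0 * sample_rate / f0_min))
    if x.size < min_len:
        raise ValueError(
            f"segment of {x.size} samples too short for f0_min={f0_min} Hz "
            f"(need >= {min_len})"
        )
    x = x - x.mean()
    r = _autocorr(x)
    if r[0] <= 0.0:
        return 0.0
    r = r / r[0]
    lag_lo = max(int(sample_rate / f0_max), 1)
    lag_hi = min(int(math.ceil(sample_rate / f0_min)), x.size - 2)
    if lag_hi <= lag_lo:
        return 0.0
    window = r[lag_lo : lag_hi + 1]
    k = int(np.argmax(window)) + lag_lo
    if r[k] < voicing_threshold:
        return 0.0
    lag = k + _parabolic_offset(r[k - 1], r[k], r[k + 1]) if 0 < k < r.size - 1 else k
    return float(sample_rate / lag)


def _autocorr(x: np.ndarray) -> np.ndarray:
    n = x.size
    nfft = scipy.fft.next_fast_len(2 * n - 1)
    spec = np.abs(scipy.fft.rfft(x, nfft)) ** 2
    return scipy.fft.irfft(spec, nfft)[:n]


def _parabolic_offset(ym: float, y0: float, yp: float) -> float:
    denom = ym - 2.0 * y0 + yp
    if denom == 0.0:
        return 0.0
    return float(np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5))


# ---------------------------------------------------------------------------
# Linear prediction

def levinson_durbin(r: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Solve the Toeplitz normal equations for LPC prediction coefficients.

    Returns ``a`` with x_hat[n] = sum_k a[k-1] * x[n-k] and the final
    prediction-error power.  The all-pole error filter is
    A(z) = 1 - sum_k a_k z^-k.
    """
    a = np.zeros(order)
    err = float(r[0])
    if err <= 0.0:
        raise np.linalg.LinAlgError("zero-energy signal; LPC undefined")
    for m in range(1, order + 1):
        acc = r[m] - np.dot(a[: m - 1], r[m - 1 : 0 : -1])
        k = acc / err
        a_new = a.copy()
        a_new[m - 1] = k
        if m > 1:
            a_new[: m - 1] = a[: m - 1] - k * a[m - 2 :: -1]
        a = a_new
        err *= 1.0 - k * k
        if err <= 0.0:
            err = max(err, 0.0)
            break
    return a, err


def lpc_coefficients(frame: np.ndarray, order: int) -> np.ndarray:
    """LPC prediction coefficients by the autocorrelation method."""
    x = np.asarray(frame, dtype=np.float64)
    r = _autocorr(x)[: order + 1]
    if r.size < order + 1:
        r = np.pad(r, (0, order + 1 - r.size))
    a, _ = levinson_durbin(r, order)
    return a


def formants_lpc(
    frame: np.ndarray,
    sample_rate: float,
    lpc_order: int = 18,
    bw_max: float = 700.0,
    n_formants: int = 6,
    f_min: float = 90.0,
) -> np.ndarray:
    """First ``n_formants`` vocal-tract resonances via LPC root finding.

    Roots of the LPC error polynomial with positive imaginary part whose
    3 dB bandwidth -(fs/pi) ln|z| is below ``bw_max`` are converted to
    frequencies; the lowest are returned ascending, zero-padded when fewer
    are found.  Degenerate frames yield all zeros with a warning.
    """
    out = np.zeros(n_formants)
    try:
        a = lpc_coefficients(frame, lpc_order)
    except np.linalg.LinAlgError:
        logger.warning("degenerate LPC fit; formants set to 0")
        return out
    poly = np.concatenate(([1.0], -a))
    roots = np.roots(poly)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * sample_rate / (2.0 * np.pi)
    with np.errstate(divide="ignore"):
        bws = -(sample_rate / np.pi) * np.log(np.abs(roots))
    keep = (bws < bw_max) & (freqs > f_min) & (freqs < sample_rate / 2 - 50.0)
    found = np.sort(freqs[keep])[:n_formants]
    out[: found.size] = found
    return out


def lpcc(frame: np.ndarray, p: int = 12, lpc_order: int | None = None) -> np.ndarray:
    """Cepstral coefficients from LPC via the standard recursion.

    c_m = a_m + sum_{k=1..m-1} (k/m) c_k a_{m-k} for m = 1..p, with a_m = 0
    beyond the LPC order.
    """
    if lpc_order is None:
        lpc_order = p
    try:
        a_full = np.zeros(max(p, lpc_order))
        a_full[:lpc_order] = lpc_coefficients(frame, lpc_order)
    except np.linalg.LinAlgError:
        logger.warning("degenerate LPC fit; LPCC set to 0")
        return np.zeros(p)
    return lpcc_from_lpc(a_full, p)


def lpcc_from_lpc(a: np.ndarray, p: int) -> np.ndarray:
    """Apply the LPC-to-cepstrum recursion to given prediction coefficients."""
    a = np.asarray(a, dtype=np.float64)
    c = np.zeros(p)
    for m in range(1, p + 1):
        am = a[m - 1] if m - 1 < a.size else 0.0
        acc = am
        for k in range(1, m):
            amk = a[m - k - 1] if m - k - 1 < a.size else 0.0
            acc += (k / m) * c[k - 1] * amk
        c[m - 1] = acc
    return c


# ---------------------------------------------------------------------------
# MFCC

def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_bins: int, sample_rate: float) -> np.ndarray:
    """Triangular mel filterbank (HTK mel scale) from 0 Hz to Nyquist.

    Returns an (n_mels, n_bins) matrix applied to one-sided power spectra
    of frame length N = 2 (n_bins - 1).
    """
    nyquist = sample_rate / 2.0
    mel_pts = np.linspace(0.0, hz_to_mel(nyquist), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.arange(n_bins) * sample_rate / (2.0 * (n_bins - 1))
    fb = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        lo, center, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bin_freqs - lo) / (center - lo)
        down = (hi - bin_freqs) / (hi - center)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mfcc(
    spectrum_row: np.ndarray,
    sample_rate: float,
    n_mels: int = 26,
    p: int = 12,
) -> np.ndarray:
    """Mel-frequency cepstral coefficients 1..p (coefficient 0 excluded).

    Log mel-filterbank energies of the magnitude-squared spectrum (floored
    at 1e-10) followed by an orthonormal DCT-II.
    """
    if n_mels < p:
        raise ValueError(f"n_mels={n_mels} must be >= p={p}")
    row = np.asarray(spectrum_row, dtype=np.float64)
    fb = mel_filterbank(n_mels, row.size, sample_rate)
    energies = fb @ (row**2)
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    coeffs = scipy.fft.dct(log_e, type=2, norm="ortho")
    return coeffs[1 : p + 1]


def delta_mfcc(track: np.ndarray, window: int = 2) -> np.ndarray:
    """Regression slope of each coefficient over time, edges replicated.

    delta_c[t] = sum_{m=1..M} m (c[t+m] - c[t-m]) / (2 sum m^2).
    """
    c = np.atleast_2d(np.asarray(track, dtype=np.float64))
    padded = np.pad(c, ((window, window), (0, 0)), mode="edge")
    denom = 2.0 * sum(m * m for m in range(1, window + 1))
    out = np.zeros_like(c)
    for m in range(1, window + 1):
        out += m * (padded[window + m : window + m + c.shape[0]] -
                    padded[window - m : window - m + c.shape[0]])
    return out / denom


# ---------------------------------------------------------------------------
# Feature matrix container

FAMILY_OF = {
    "magnitude": "magnitude",
    "average": "average",
    "variance": "variance",
    "zcr": "zcr",
    "bandwidth": "bandwidth",
    "peak": "peak",
    "valley": "valley",
    "pitch": "pitch",
    "formant": "formant",
    "lpcc": "lpcc",
    "mfcc": "mfcc",
    "dmfcc": "dmfcc",
}


def feature_family(column: str) -> str:
    """Map a column name like ``mfcc_3_mean`` to its feature family."""
    base = column
    for suffix in ("_mean", "_std"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    base = base.rstrip("0123456789").rstrip("_")
    if base not in FAMILY_OF:
        raise KeyError(f"column {column!r} does not belong to a known feature family")
    return FAMILY_OF[base]


class FeatureMatrix:
    """Named feature vectors with class labels and optional row metadata."""

    def __init__(
        self,
        X: pd.DataFrame,
        labels: pd.Series | None = None,
        meta: pd.DataFrame | None = None,
    ) -> None:
        self.X = X.reset_index(drop=True)
        self.labels = None if labels is None else pd.Series(labels).reset_index(drop=True)
        self.meta = None if meta is None else meta.reset_index(drop=True)
        if self.labels is not None and len(self.labels) != len(self.X):
            raise ValueError("labels length must match feature rows")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def schema(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, columns: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.X[columns].copy(), self.labels, self.meta)

    def take(self, idx) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X.iloc[idx],
            None if self.labels is None else self.labels.iloc[idx],
            None if self.meta is None else self.meta.iloc[idx],
        )

    def to_csv(self, path) -> None:
        df = self.X.copy()
        if self.meta is not None:
            for col in self.meta.columns:
                df[col] = self.meta[col].to_numpy()
        if self.labels is not None:
            df["label"] = self.labels.to_numpy()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta_columns: tuple[str, ...] = ("clip_id", "sex", "frame")) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label") if "label" in df.columns else None
        meta_cols = [c for c in meta_columns if c in df.columns]
        meta = df[meta_cols] if meta_cols else None
        return cls(df.drop(columns=meta_cols), labels, meta)


# ---------------------------------------------------------------------------
# End-to-end extraction

def _frame_column_names(config: FeatureConfig) -> list[str]:
    n_bands = len(config.subband_edges) - 1
    names = ["magnitude", "average", "variance", "zcr", "bandwidth"]
    names += [f"peak_{k + 1}" for k in range(n_bands)]
    names += [f"valley_{k + 1}" for k in range(n_bands)]
    names += ["pitch"]
    names += [f"formant_{k + 1}" for k in range(config.n_formants)]
    names += [f"lpcc_{k + 1}" for k in range(config.lpcc_order)]
    names += [f"mfcc_{k + 1}" for k in range(config.n_mfcc)]
    names += [f"dmfcc_{k + 1}" for k in range(config.n_mfcc)]
    return names


def extract_frame_features(clip: AudioClip, config: FeatureConfig) -> pd.DataFrame:
    """Per-frame features over all cry-unit frames of one clip.

    Runs the full preprocessing chain, then every extractor on each frame
    lying inside a detected cry unit.  Unvoiced frames carry pitch 0 and
    missing formants are 0, so the result has no missing values.
    """
    clip = normalize(clip)
    units = detect_cry_units(
        clip,
        energy_hi=config.energy_hi,
        energy_lo=config.energy_lo,
        zcr_max=config.zcr_max,
        min_unit_ms=config.min_unit_ms,
        min_gap_ms=config.min_gap_ms,
    )
    units = [u for u in units if u.n_samples >= config.frame_length]
    if not units:
        raise NoCryDetectedError(f"no cry units detected in clip {clip.source_id!r}")

    rows: list[np.ndarray] = []
    for unit in units:
        raw_seg = clip.samples[unit.start_sample : unit.end_sample]
        seg = preemphasize(raw_seg, config.preemphasis_alpha)
        frames = frame_signal(seg, config.frame_length, config.hop, clip.sample_rate)
        spectra = window_and_fft(frames)
        bands = subband_bins(spectra.spectra.shape[1], config.subband_edges)

        mfcc_track = np.array(
            [mfcc(s, clip.sample_rate, config.n_mels, config.n_mfcc) for s in spectra.spectra]
        )
        dmfcc_track = delta_mfcc(mfcc_track, config.delta_window)

        for j in range(frames.n_frames):
            frame = frames.frames[j]
            spec = spectra.spectra[j]
            peaks, valleys = peak_valley(spec, bands, config.peak_alpha)
            f0 = _frame_pitch(clip.samples, unit, j, config, clip.sample_rate)
            fmts = formants_lpc(
                frame,
                clip.sample_rate,
                config.lpc_order,
                config.formant_bw_max,
                config.n_formants,
            )
            row = np.concatenate(
                [
                    [magnitude(frame), average(frame), variance(frame),
                     zero_crossing_rate(frame), bandwidth(spec)],
                    peaks,
                    valleys,
                    [f0],
                    fmts,
                    lpcc(frame, config.lpcc_order, config.lpc_order),
                    mfcc_track[j],
                    dmfcc_track[j],
                ]
            )
            rows.append(row)
    return pd.DataFrame(rows, columns=_frame_column_names(config))


def _frame_pitch(
    samples: np.ndarray, unit, j: int, config: FeatureConfig, sample_rate: int
) -> float:
    """Pitch from a dedicated window on the un-preemphasized signal.

    The window is centered on the analysis frame and clamped to the cry
    unit so silence outside the unit never enters the autocorrelation.
    """
    center = unit.start_sample + j * config.hop + config.frame_length // 2
    half = config.pitch_window // 2
    a = max(unit.start_sample, center - half)
    b = min(unit.end_sample, center + half)
    min_len = int(math.ceil(2.0 * sample_rate / config.f0_min))
    if b - a < min_len:
        a = max(unit.start_sample, b - min_len)
        if b - a < min_len:
            return 0.0
    return pitch_autocorr(
        samples[a:b],
        sample_rate,
        config.f0_min,
        config.f0_max,
        config.voicing_threshold,
    )


def aggregate_clip(frame_df: pd.DataFrame) -> pd.Series:
    """Mean and standard deviation of each frame feature over a clip.

    Pitch statistics use voiced frames only (pitch > 0); a clip with no
    voiced frame gets pitch_mean = pitch_std = 0.
    """
    out: dict[str, float] = {}
    for col in frame_df.columns:
        vals = frame_df[col].to_numpy()
        if col == "pitch":
            vals = vals[vals > 0]
            if vals.size == 0:
                vals = np.zeros(1)
        out[f"{col}_mean"] = float(np.mean(vals))
        out[f"{col}_std"] = float(np.std(vals))
    return pd.Series(out)


def extract_features(
    clip: AudioClip,
    config: FeatureConfig | None = None,
    sex: str | None = None,
) -> FeatureMatrix:
    """Extract a labeled feature matrix from one clip.

    ``config.unit`` selects clip-level aggregation (one row, the default)
    or frame-level rows sharing the clip's label.
    """
    config = config or FeatureConfig()
    frame_df = extract_frame_features(clip, config)
    meta_cols: dict[str, list] = {"clip_id": []}
    if config.unit == "frame":
        X = frame_df
        n = len(frame_df)
    else:
        X = aggregate_clip(frame_df).to_frame().T
        n = 1
    meta_cols["clip_id"] = [clip.source_id] * n
    if sex is not None:
        meta_cols["sex"] = [sex] * n
    labels = pd.Series([clip.label] * n) if clip.label is not None else None
    return FeatureMatrix(X, labels, pd.DataFrame(meta_cols))


def extract_feature_matrix(
    clips: list[tuple[AudioClip, str | None]] | list[AudioClip],
    config: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Extract and stack feature rows for a list of clips.

    ``clips`` may be plain :class:`AudioClip` items or (clip, sex) pairs.
    """
    config = config or FeatureConfig()
    parts = []
    for item in clips:
        clip, sex = item if isinstance(item, tuple) else (item, None)
        parts.append(extract_features(clip, config, sex=sex))
    X = pd.concat([p.X for p in parts], ignore_index=True)
    labels = (
        pd.concat([p.labels for p in parts], ignore_index=True)
        if parts[0].labels is not None
        else None
    )
    meta = pd.concat([p.meta for p in parts], ignore_index=True)
    return FeatureMatrix(X, labels, meta)
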