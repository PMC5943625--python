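"""Core signal types, windowing and band-power features.

A recording is a uniformly sampled triaxial acceleration series (m/s^2).
All detectors operate on non-overlapping 3.2-s segments (128 samples at
the nominal 40 Hz) characterised by their power spectra.

Spectral estimate: Hann periodogram per segment, with the binned spectrum
rescaled so that its total equals the time-domain variance of the
mean-removed signal.  The rescaling removes the window's energy bias so
band powers over any partition of the spectrum sum exactly to the signal
variance (Parseval consistency); relative spectral shape is untouched.
DC is excluded, which makes every feature invariant to constant
per-channel offsets (gravity / sensor orientation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps


@dataclass(frozen=True)
class AccelRecording:
    """Uniformly sampled 3-axis acceleration, m/s^2."""

    patient_id: str
    fs: float
    samples: np.ndarray  # shape (N, 3)
    start_time: str | None = None  # ISO-8601, metadata only

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
            raise ValueError("samples must have shape (N, 3) with N >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples contain non-finite values")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Segment:
    """One non-overlapping analysis window of a recording."""

    data: np.ndarray  # (length, 3) view into the recording
    start_index: int
    fs: float
    minute_index: int
    period_index: int

    @property
    def length(self) -> int:
        return self.data.shape[0]

    @property
    def start_s(self) -> float:
        return self.start_index / self.fs


@dataclass(frozen=True)
class BandPower:
    lo_hz: float
    hi_hz: float
    per_channel: np.ndarray  # (n_channels,)
    value: float = field(init=False)  # summed across channels

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", float(np.sum(self.per_channel)))


def segment_recording(rec: AccelRecording, window_s: float = 3.2) -> list[Segment]:
    """Tile the recording into non-overlapping windows from sample 0.

    A trailing remainder shorter than one window is discarded.  Each
    segment carries the wall-clock minute and 10-min period its start
    sample falls in (times relative to the recording start).
    """
    if rec.fs <= 0:
        raise ValueError("fs must be > 0")
    n_win = int(rec.fs * window_s)
    if n_win < 1:
        raise ValueError("window shorter than one sample")
    n_seg = rec.n_samples // n_win
    out = []
    for i in range(n_seg):
        s0 = i * n_win
        t0 = s0 / rec.fs
        out.append(
            Segment(
                data=rec.samples[s0 : s0 + n_win],
                start_index=s0,
                fs=rec.fs,
                minute_index=int(t0 // 60.0),
                period_index=int(t0 // 600.0),
            )
        )
    return out


def spectrum_bins(
    x: np.ndarray, fs: float, nfft: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel binned power spectrum, energy-normalised.

    Returns (freqs, powers) where ``powers[i, c]`` is the power of channel
    ``c`` in bin ``i`` and ``powers[:, c].sum()`` equals the variance of
    the mean-removed channel.  The DC bin is dropped.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] < x.shape[1] and x.shape[0] in (1, 2, 3):
        x = x.T  # accept (channels, N) too
    xc = x - x.mean(axis=0, keepdims=True)
    freqs, pxx = sps.periodogram(
        xc, fs=fs, window="hann", nfft=nfft, axis=0, scaling="density", detrend=False
    )
    df = freqs[1] - freqs[0]
    p = pxx[1:] * df  # drop DC
    freqs = freqs[1:]
    var = np.var(xc, axis=0)
    tot = p.sum(axis=0)
    scale = np.divide(var, tot, out=np.zeros_like(var), where=tot > 0)
    return freqs, p * scale


def band_power_array(
    x: np.ndarray, fs: float, lo_hz: float, hi_hz: float, nfft: int | None = None
) -> BandPower:
    """Band power of a raw (N, 3) array over [lo_hz, hi_hz)."""
    if not (0 <= lo_hz < hi_hz):
        raise ValueError("band must satisfy 0 <= lo < hi")
    if hi_hz > fs / 2 + 1e-9:
        raise ValueError("band exceeds Nyquist frequency")
    freqs, p = spectrum_bins(x, fs, nfft=nfft)
    mask = (freqs >= lo_hz) & (freqs < hi_hz)
    return BandPower(lo_hz, hi_hz, per_channel=p[mask].sum(axis=0))


def band_power(seg: Segment, lo_hz: float, hi_hz: float) -> BandPower:
    """Band power of one segment over [lo_hz, hi_hz)."""
    return band_power_array(seg.data, seg.fs, lo_hz, hi_hz)


_LOG_FLOOR = 1e-12


def feature_vector(seg: Segment, featbank: list[float]) -> np.ndarray:
    """Log band powers over a filter bank, per channel plus AC magnitude.

    For B bands the vector has 4*B entries: B per channel and B for the
    magnitude of the mean-removed acceleration vector.  Deterministic and
    invariant to per-channel constant offsets.
    """
    edges = np.asarray(featbank, dtype=float)
    freqs, p = spectrum_bins(seg.data, seg.fs)
    xc = seg.data - seg.data.mean(axis=0, keepdims=True)
    mag = np.linalg.norm(xc, axis=1)
    _, pm = spectrum_bins(mag[:, None], seg.fs)
    feats = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (freqs >= lo) & (freqs < hi)
        feats.append(p[mask].sum(axis=0))  # (3,)
    per_channel = np.concatenate([np.stack(feats)[:, c] for c in range(3)])
    mag_bands = np.array(
        [pm[(freqs >= lo) & (freqs < hi)].sum() for lo, hi in zip(edges[:-1], edges[1:])]
    )
    return np.log(np.concatenate([per_channel, mag_bands]) + _LOG_FLOOR)


def feature_matrix(segments: list[Segment], featbank: list[float]) -> np.ndarray:
    if not segments:
        return np.empty((0, 4 * (len(featbank) - 1)))
    return np.stack([feature_vector(s, featbank) for s in segments])


# ---------------------------------------------------------------------------
# CSV I/O


def read_accel_csv(
    path: str | Path, patient_id: str | None = None, fs_expected: float | None = None
) -> AccelRecording:
    """Read a ``time_s,ax,ay,az`` CSV (m/s^2, fixed sampling step).

    The time column must be monotone with a uniform step; if
    ``fs_expected`` is given the step is validated to within 1%.
    """
    df = pd.read_csv(path, comment="#")
    required = ["time_s", "ax", "ay", "az"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"accelerometer CSV must start with columns {required}")
    if len(df) < 2:
        raise ValueError("accelerometer CSV needs >= 2 rows")
    steps = np.diff(df["time_s"].to_numpy())
    step = np.median(steps)
    if step <= 0 or np.any(steps <= 0):
        raise ValueError("time_s must be strictly increasing")
    if np.max(np.abs(steps - step)) > 0.01 * step:
        raise ValueError("time_s is not uniformly sampled (1% tolerance)")
    fs = 1.0 / step
    if fs_expected is not None:
        if abs(fs - fs_expected) > 0.01 * fs_expected:
            raise ValueError(
                f"sampling rate {fs:.3f} Hz differs from expected {fs_expected}"
            )
        fs = fs_expected  # snap away float noise in the time column
    return AccelRecording(
        patient_id=patient_id or Path(path).stem,
        fs=fs,
        samples=df[["ax", "ay", "az"]].to_numpy(float),
    )


def write_accel_csv(rec: AccelRecording, path: str | Path) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame(
        {"time_s": t, "ax": rec.samples[:, 0], "ay": rec.samples[:, 1], "az": rec.samples[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.6f")
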