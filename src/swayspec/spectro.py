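"""Short-term spectral analysis of the CoP signal.

The sway signal is described by a sequence of power spectral densities
(PSDs) computed on a sliding window (10 s by default).  Each window yields
a PSD vector sampled on a fixed frequency grid (0.1–5.0 Hz in 0.1 Hz
steps, i.e. 50 bins) and expressed in dB.  Each PSD is attributed to the
time instant at the center of its window, so a 180-s trial analyzed with
10-s windows produces spectra for t = 5 s … 175 s.

With a rectangular taper the 10-s window makes the natural DFT bin
spacing exactly 0.1 Hz, so the 50 analysis bins are plain periodogram
ordinates — no interpolation is involved.  A Hann taper is available for
users who prefer reduced leakage over exact bin mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .trial import CoPTrial

#: Clamp for log of (numerically) zero power.  Far below any physical CoP PSD.
DB_FLOOR = -200.0

_CHUNK = 4096  # windows per FFT batch; bounds peak memory


@dataclass
class Spectrogram:
    """Sequence of per-window PSD vectors in dB.

    Attributes
    ----------
    times : numpy.ndarray
        Center time of each window, s; strictly increasing.
    freqs : numpy.ndarray
        Frequency bins, Hz.
    psd_db : numpy.ndarray
        ``(n_windows, n_bins)`` matrix of PSD values, dB re 1 mm²/Hz.
    fs : float
        Sampling frequency of the underlying signal, Hz.
    window_len : float
        Window length, s.
    step : float
        Window placement step, s.
    """

    times: np.ndarray
    freqs: np.ndarray
    psd_db: np.ndarray
    fs: float
    window_len: float
    step: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd_db = np.asarray(self.psd_db, dtype=float)
        if self.psd_db.shape != (self.times.size, self.freqs.size):
            raise ValueError("psd_db shape must be (n_windows, n_bins)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("window times must be strictly increasing")
        if not np.all(np.isfinite(self.psd_db)):
            raise ValueError("psd_db contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns time_s, freq_hz, psd_db."""
        t = np.repeat(self.times, self.freqs.size)
        f = np.tile(self.freqs, self.times.size)
        return pd.DataFrame(
            {"time_s": t, "freq_hz": f, "psd_db": self.psd_db.ravel()}
        )


def _taper(n: int, kind: str) -> np.ndarray:
    if kind == "rect":
        return np.ones(n)
    if kind == "hann":
        return np.hanning(n)
    raise ValueError(f"unknown taper {kind!r} (use 'rect' or 'hann')")


def periodogram_density(
    segments: np.ndarray, fs: float, taper: str = "rect"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram PSD (power per Hz) of mean-removed segments.

    Parameters
    ----------
    segments : numpy.ndarray
        ``(..., n)`` array; the periodogram is taken along the last axis.
    fs : float
        Sampling frequency, Hz.
    taper : str
        ``"rect"`` (default) or ``"hann"``; applied after mean removal.

    Returns
    -------
    freqs : numpy.ndarray
        ``n//2 + 1`` one-sided bin frequencies, Hz.
    pxx : numpy.ndarray
        One-sided PSD, same leading shape as ``segments``.  Satisfies
        ``sum(pxx) * (fs/n) == var(segment)`` exactly for the rectangular
        taper (discrete Parseval identity).
    """
    segments = np.asarray(segments, dtype=float)
    n = segments.shape[-1]
    w = _taper(n, taper)
    x = segments - segments.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(x * w, axis=-1)
    pxx = (spec.real**2 + spec.imag**2) / (fs * np.sum(w**2))
    # fold negative frequencies into the positive bins
    pxx[..., 1:] *= 2.0
    if n % 2 == 0:  # Nyquist bin is its own conjugate
        pxx[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, pxx


def window_psd(
    segment: np.ndarray,
    fs: float,
    fmin: float = 0.1,
    fmax: float = 5.0,
    df: float = 0.1,
    taper: str = "rect",
    db_floor: float = DB_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """PSD of one analysis window on the fixed frequency grid, in dB.

    The segment length must make the natural bin spacing ``fs/n`` equal to
    ``df`` (a 10-s window sampled at 100 Hz gives 0.1 Hz bins), so the
    grid bins are exact periodogram ordinates.  The per-window mean is
    removed, the one-sided PSD (power per Hz) is computed, the bins with
    ``fmin <= f <= fmax`` are retained and converted to ``10*log10``;
    values below ``db_floor`` are clamped.

    Returns
    -------
    freqs, psd_db : numpy.ndarray
        Bin frequencies (50 bins for the defaults) and their dB values.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("segment must be one-dimensional")
    n = segment.size
    native_df = fs / n
    if abs(native_df - df) > 1e-9 * df:
        raise ValueError(
            f"segment length {n} gives bin spacing {native_df:.6g} Hz, "
            f"but df={df:g} Hz was requested; use a window of "
            f"{fs / df:.0f} samples"
        )
    freqs, pxx = periodogram_density(segment, fs, taper=taper)
    sel = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    freqs = freqs[sel]
    with np.errstate(divide="ignore"):
        psd_db = 10.0 * np.log10(pxx[sel])
    return freqs, np.maximum(psd_db, db_floor)


def sliding_psd(
    trial: CoPTrial,
    window_len: float = 10.0,
    step: float = 0.01,
    fmin: float = 0.1,
    fmax: float = 5.0,
    df: float = 0.1,
    taper: str = "rect",
    db_floor: float = DB_FLOOR,
) -> Spectrogram:
    """Sliding-window PSD sequence of a trial.

    Windows of ``window_len`` seconds are placed every ``step`` seconds
    (10 ms by default, i.e. at every sample of a 100 Hz signal); each is
    analyzed with :func:`window_psd`.  The number of windows is
    ``(duration - window_len)/step + 1``.

    Raises
    ------
    ValueError
        If the window is longer than the signal or the step is not a
        multiple of the sampling interval.
    """
    fs = trial.fs
    nwin = round(window_len * fs)
    if nwin > trial.cop_ap.size:
        raise ValueError(
            f"window of {window_len:g} s exceeds the {trial.duration:g} s signal"
        )
    hop_f = step * fs
    hop = round(hop_f)
    if hop < 1 or abs(hop_f - hop) > 1e-6:
        raise ValueError(
            f"step {step:g} s is not a positive multiple of 1/fs = {1/fs:g} s"
        )

    views = sliding_window_view(trial.cop_ap, nwin)[::hop]
    n_windows = views.shape[0]
    freqs = None
    rows = []
    for start in range(0, n_windows, _CHUNK):
        chunk = views[start : start + _CHUNK]
        f, pxx = periodogram_density(chunk, fs, taper=taper)
        if freqs is None:
            sel = (f >= fmin - 1e-9) & (f <= fmax + 1e-9)
            freqs = f[sel]
        with np.errstate(divide="ignore"):
            db = 10.0 * np.log10(pxx[:, sel])
        rows.append(np.maximum(db, db_floor))
    psd_db = np.concatenate(rows, axis=0)
    times = window_len / 2.0 + step * np.arange(n_windows)
    return Spectrogram(
        times=times,
        freqs=freqs,
        psd_db=psd_db,
        fs=fs,
        window_len=window_len,
        step=step,
    )
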