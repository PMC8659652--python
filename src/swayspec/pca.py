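"""Principal component extraction from a trial's spectrogram.

The window-by-frequency dB matrix is decomposed, per trial, by a
covariance PCA (columns centered, no variance scaling: the bins share dB
units).  The first component separates the perturbation-phase spectrum
from the baseline/return spectrum: its eigenvector is a spectral profile
(loadings over the 50 frequency bins) and its score a temporal profile of
how far each window's spectrum lies along that profile.

The score is then normalized per trial to a common scale: mean 0 over the
30–55 s window (mid-baseline) and mean 1 over the 90–115 s window
(mid-perturbation), so scores are comparable across trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectro import Spectrogram

#: Intervals (in window-center seconds) defining the normalized score scale.
ZERO_WINDOW = (30.0, 55.0)
ONE_WINDOW = (90.0, 115.0)


class DegenerateSpectrogramError(ValueError):
    """The spectrogram is constant across windows: no component exists."""


class NoSpectralChangeError(ValueError):
    """The two normalization windows have equal score means."""


@dataclass
class PCResult:
    """First principal component of one trial's spectrogram.

    Attributes
    ----------
    freqs : numpy.ndarray
        Frequency bins of the eigenvector, Hz.
    eigenvector : numpy.ndarray
        Unit-norm loadings over the bins (dimensionless, on dB values).
    times : numpy.ndarray
        Window-center times of the score, s.
    raw_score : numpy.ndarray
        Projection of each (centered) window spectrum on the eigenvector.
    norm_score : numpy.ndarray or None
        Affinely rescaled score (0 on the baseline window, 1 on the
        perturbation window); ``None`` until :func:`normalize_score` ran.
    var_explained : float
        Fraction of total variance carried by the first component.
    column_means : numpy.ndarray
        Per-bin mean spectrum removed before the decomposition, dB.
    """

    freqs: np.ndarray
    eigenvector: np.ndarray
    times: np.ndarray
    raw_score: np.ndarray
    var_explained: float
    column_means: np.ndarray
    norm_score: np.ndarray | None = None

    def eigenvector_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"freq_hz": self.freqs, "loading": self.eigenvector}
        )

    def score_frame(self) -> pd.DataFrame:
        out = {"time_s": self.times, "raw_score": self.raw_score}
        if self.norm_score is not None:
            out["norm_score"] = self.norm_score
        return pd.DataFrame(out)


def _window_mask(times: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    lo, hi = interval
    return (times >= lo - 1e-9) & (times <= hi + 1e-9)


def fit_pc1(
    spectrogram: Spectrogram,
    zero_window: tuple[float, float] = ZERO_WINDOW,
    one_window: tuple[float, float] = ONE_WINDOW,
) -> PCResult:
    """First principal component of the spectrogram (covariance PCA).

    Columns (frequency bins) are centered by their means over windows and
    the dB matrix is decomposed by SVD, which is equivalent to an
    eigendecomposition of the bin-by-bin covariance matrix.  The returned
    eigenvector has unit norm; the raw score is the projection of each
    centered window spectrum onto it; ``var_explained`` is
    ``lambda_1 / sum(lambda)``.

    Sign convention: the component is oriented so that the mean raw score
    over windows centered in ``one_window`` (mid-perturbation, 90–115 s)
    exceeds the mean over ``zero_window`` (mid-baseline, 30–55 s) —
    perturbation-positive.  When both means tie (e.g. the windows fall
    outside the recorded times) the sign is fixed lexicographically: the
    first nonzero loading is made positive.

    Raises
    ------
    DegenerateSpectrogramError
        If the spectrogram is constant across windows (zero variance).
    """
    mat = spectrogram.psd_db
    n, _ = mat.shape
    if n < 2:
        raise ValueError("need at least 2 windows for a PCA")
    column_means = mat.mean(axis=0)
    centered = mat - column_means
    # SVD of the centered matrix == eigendecomposition of its covariance
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0.0 or not np.isfinite(total):
        raise DegenerateSpectrogramError(
            "degenerate spectrogram: constant across windows"
        )
    eigenvector = vt[0]
    raw_score = centered @ eigenvector
    var_explained = float(s[0] ** 2 / total)

    m0 = raw_score[_window_mask(spectrogram.times, zero_window)]
    m1 = raw_score[_window_mask(spectrogram.times, one_window)]
    flip = 0.0
    if m0.size and m1.size:
        flip = float(m1.mean() - m0.mean())
    if flip < 0:
        eigenvector = -eigenvector
        raw_score = -raw_score
    elif flip == 0.0:
        nz = np.flatnonzero(eigenvector)
        if nz.size and eigenvector[nz[0]] < 0:
            eigenvector = -eigenvector
            raw_score = -raw_score

    return PCResult(
        freqs=spectrogram.freqs.copy(),
        eigenvector=eigenvector,
        times=spectrogram.times.copy(),
        raw_score=raw_score,
        var_explained=var_explained,
        column_means=column_means,
    )


def normalize_score(
    raw_score: np.ndarray,
    times: np.ndarray,
    zero_window: tuple[float, float] = ZERO_WINDOW,
    one_window: tuple[float, float] = ONE_WINDOW,
) -> np.ndarray:
    """Affine rescaling of the PC1 score to the common trial scale.

    Maps ``y -> (y - m0) / (m1 - m0)`` where ``m0`` and ``m1`` are the
    score means over the windows centered in ``zero_window`` and
    ``one_window``.  After the map the means are exactly 0 and 1.  The
    map is affine-invariant (idempotent on an already-normalized score).

    Raises
    ------
    NoSpectralChangeError
        If the two window means coincide (within 1e-12 of the score
        range) so that no scale exists.
    """
    raw_score = np.asarray(raw_score, dtype=float)
    times = np.asarray(times, dtype=float)
    if raw_score.shape != times.shape:
        raise ValueError("raw_score and times must have the same shape")
    sel0 = _window_mask(times, zero_window)
    sel1 = _window_mask(times, one_window)
    if not sel0.any() or not sel1.any():
        raise ValueError("a normalization window contains no window centers")
    m0 = float(raw_score[sel0].mean())
    m1 = float(raw_score[sel1].mean())
    scale = np.ptp(raw_score)
    if abs(m1 - m0) <= 1e-12 * max(scale, 1.0):
        raise NoSpectralChangeError(
            "no spectral change between phases: normalization window "
            "means coincide"
        )
    return (raw_score - m0) / (m1 - m0)


def attach_norm_score(
    pc: PCResult,
    zero_window: tuple[float, float] = ZERO_WINDOW,
    one_window: tuple[float, float] = ONE_WINDOW,
) -> PCResult:
    """Convenience: compute and store the normalized score on a PCResult."""
    pc.norm_score = normalize_score(
        pc.raw_score, pc.times, zero_window=zero_window, one_window=one_window
    )
    return pc
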