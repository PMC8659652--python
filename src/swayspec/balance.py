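"""Spectral balance: high-band minus low-band mean PC1 loading.

The PC1 eigenvector is a spectral profile of how the CoP spectrum changes
when the platform oscillates.  Its mean loading over a low band
(0.5–1.2 Hz) and a high band (1.2–3.0 Hz) summarizes where that change
sits in frequency; the balance H − L is positive when the perturbation
pushes relatively more energy above 1.2 Hz.  The 1.2 Hz split sits at the
typical peak of the mean eigenvector; the boundary bin is assigned to the
high band (the low band is half-open), which is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOW_BAND = (0.5, 1.2)
HIGH_BAND = (1.2, 3.0)


@dataclass(frozen=True)
class BalanceScore:
    """H − L spectral balance of one sign-corrected eigenvector."""

    low_mean: float
    high_mean: float
    balance: float
    bands: tuple[tuple[float, float], tuple[float, float]]


def band_bins(
    freqs: np.ndarray,
    band: tuple[float, float],
    include_upper: bool = True,
) -> np.ndarray:
    """Boolean mask of bins whose center frequency lies in ``band``.

    The lower edge is always inclusive; ``include_upper`` controls the
    upper edge (half-open bands let two adjacent bands tile the axis
    without sharing a bin).
    """
    lo, hi = band
    mask = freqs >= lo - 1e-9
    if include_upper:
        mask &= freqs <= hi + 1e-9
    else:
        mask &= freqs < hi - 1e-9
    return mask


def spectral_balance(
    eigenvector: np.ndarray,
    freqs: np.ndarray,
    low_band: tuple[float, float] = LOW_BAND,
    high_band: tuple[float, float] = HIGH_BAND,
    boundary_to_high: bool = True,
) -> BalanceScore:
    """Mean loading difference between the high and low frequency bands.

    Parameters
    ----------
    eigenvector : numpy.ndarray
        Sign-corrected PC1 loadings (perturbation-positive orientation).
    freqs : numpy.ndarray
        Bin center frequencies, Hz.
    low_band, high_band : tuple
        Band edges, Hz.  With ``boundary_to_high`` (default) a bin that
        sits exactly on the shared edge counts in the high band only.

    Raises
    ------
    ValueError
        If either band selects no bin.
    """
    eigenvector = np.asarray(eigenvector, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if eigenvector.shape != freqs.shape:
        raise ValueError("eigenvector and freqs must have the same shape")
    low_mask = band_bins(freqs, low_band, include_upper=not boundary_to_high)
    high_mask = band_bins(freqs, high_band, include_upper=True)
    if not boundary_to_high:
        # boundary bin goes to the low band instead
        high_mask &= freqs > high_band[0] + 1e-9
    if not low_mask.any():
        raise ValueError(f"low band {low_band} selects no frequency bin")
    if not high_mask.any():
        raise ValueError(f"high band {high_band} selects no frequency bin")
    low_mean = float(eigenvector[low_mask].mean())
    high_mean = float(eigenvector[high_mask].mean())
    return BalanceScore(
        low_mean=low_mean,
        high_mean=high_mean,
        balance=high_mean - low_mean,
        bands=(tuple(low_band), tuple(high_band)),
    )
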