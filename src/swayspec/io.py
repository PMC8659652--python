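"""Trial CSV and manifest reading/writing.

One CSV per trial (columns ``time_s``, ``cop_ap_mm``; header mandatory,
UTF-8, decimal point, samples at ``t = k/fs`` starting at 0), plus a
manifest CSV with one row per trial carrying the design metadata.  On
read, the sampling rate is validated from the time stamps (within 1% of
the declared rate) and the record must cover at least the expected
duration; longer records are truncated from the start, never resampled.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trial import CoPTrial, DEFAULT_DURATION_S, DEFAULT_FS_HZ, VISION_LEVELS

MANIFEST_COLUMNS = [
    "participant_id",
    "vision",
    "freq_hz",
    "trial_order",
    "mss",
    "seed",
    "filename",
]


class TrialFormatError(ValueError):
    """The trial file does not have the expected columns/values."""


class SamplingRateError(ValueError):
    """Time stamps disagree with the declared sampling rate."""


class DurationError(ValueError):
    """The record is shorter than the expected duration."""


def trial_filename(participant_id: str, vision: str, freq_hz: float) -> str:
    return f"{participant_id}_{vision}_{freq_hz:g}Hz.csv"


def write_trial(trial: CoPTrial, path: str | Path, precision: int = 6) -> Path:
    """Write one trial as a two-column CSV (time_s, cop_ap_mm)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trial.times, "cop_ap_mm": trial.cop_ap})
    df.to_csv(path, index=False, float_format=f"%.{precision}g")
    return path


def read_trial(
    path: str | Path,
    manifest_row: dict | pd.Series,
    fs: float = DEFAULT_FS_HZ,
    duration: float = DEFAULT_DURATION_S,
    fs_tol: float = 0.01,
) -> CoPTrial:
    """Read one trial CSV, validate its timing, and attach metadata.

    Parameters
    ----------
    path : path
        CSV with columns ``time_s`` and ``cop_ap_mm``.
    manifest_row : mapping
        Design metadata: participant_id, vision, freq_hz, trial_order,
        mss (a ``seed`` entry, if present, lands in ``trial.meta``).
    fs, duration : float
        Declared sampling rate (Hz) and required duration (s).
    fs_tol : float
        Allowed relative deviation of the empirical rate from ``fs``.

    Raises
    ------
    TrialFormatError, SamplingRateError, DurationError
        For missing columns, inconsistent time stamps, or a record
        shorter than ``duration``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time_s", "cop_ap_mm"} - set(df.columns)
    if missing:
        raise TrialFormatError(
            f"{path.name}: missing column(s) {sorted(missing)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    x = df["cop_ap_mm"].to_numpy(dtype=float)
    if t.size < 2:
        raise DurationError(f"{path.name}: fewer than 2 samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise SamplingRateError(f"{path.name}: time stamps not increasing")
    fs_emp = 1.0 / float(np.median(steps))
    if abs(fs_emp - fs) > fs_tol * fs:
        raise SamplingRateError(
            f"{path.name}: empirical rate {fs_emp:.3f} Hz differs from "
            f"declared {fs:g} Hz by more than {fs_tol:.0%}"
        )
    if np.max(np.abs(steps - 1.0 / fs)) > fs_tol / fs:
        raise SamplingRateError(f"{path.name}: irregular sampling intervals")
    n_req = round(duration * fs)
    if x.size < n_req:
        raise DurationError(
            f"{path.name}: {x.size / fs:.2f} s < required {duration:g} s"
        )
    x = x[:n_req]

    row = dict(manifest_row)
    meta = {"source": str(path)}
    if "seed" in row and not pd.isna(row["seed"]):
        meta["seed"] = int(row["seed"])
    return CoPTrial(
        participant_id=str(row["participant_id"]),
        vision=str(row["vision"]),
        platform_freq=float(row["freq_hz"]),
        trial_order=int(row["trial_order"]),
        mss=float(row["mss"]),
        fs=fs,
        cop_ap=x,
        meta=meta,
    )


def write_manifest(rows: Iterable[dict], path: str | Path) -> Path:
    """Write the cohort manifest CSV (one row per trial)."""
    path = Path(path)
    df = pd.DataFrame(list(rows))
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise TrialFormatError(f"manifest missing column(s) {sorted(missing)}")
    df[MANIFEST_COLUMNS].to_csv(path, index=False)
    return path


def read_manifest(path: str | Path, freq_set: Sequence[float] = (0.1, 0.2, 0.4)) -> pd.DataFrame:
    """Read and validate the manifest: unique design cells, known levels."""
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise TrialFormatError(f"manifest missing column(s) {sorted(missing)}")
    bad_vision = set(df["vision"]) - set(VISION_LEVELS)
    if bad_vision:
        raise TrialFormatError(f"manifest has unknown vision levels {bad_vision}")
    bad_freq = set(df["freq_hz"].round(6)) - {round(f, 6) for f in freq_set}
    if bad_freq:
        raise TrialFormatError(f"manifest has unexpected frequencies {bad_freq}")
    dup = df.duplicated(subset=["participant_id", "vision", "freq_hz"])
    if dup.any():
        raise TrialFormatError("manifest has duplicate design cells")
    return df


def write_cohort(
    trials: Sequence[CoPTrial], out_dir: str | Path, precision: int = 6
) -> Path:
    """Write all trials plus the manifest into ``out_dir``; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        fname = trial_filename(trial.participant_id, trial.vision, trial.platform_freq)
        write_trial(trial, out_dir / fname, precision=precision)
        rows.append(
            {
                "participant_id": trial.participant_id,
                "vision": trial.vision,
                "freq_hz": trial.platform_freq,
                "trial_order": trial.trial_order,
                "mss": trial.mss,
                "seed": trial.meta.get("seed", -1),
                "filename": fname,
            }
        )
    return write_manifest(rows, out_dir / "manifest.csv")


def load_cohort(manifest_path: str | Path, **read_kwargs) -> list[CoPTrial]:
    """Load every trial listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    return [
        read_trial(base / row["filename"], row, **read_kwargs)
        for _, row in df.iterrows()
    ]
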