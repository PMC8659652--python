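"""Container for a single posturographic trial.

A trial is one 180-s recording of the antero-posterior (AP) center of
pressure (CoP) sampled at 100 Hz, together with the design metadata needed
by the group-level analysis: participant identifier, visual condition
(eyes open ``EO`` / eyes closed ``EC``), platform oscillation frequency,
position of the trial within the session, and the participant's motion
sickness susceptibility (MSS) score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VISION_LEVELS = ("EO", "EC")

#: Default trial structure: 60 s static, 60 s platform oscillation, 60 s static.
DEFAULT_DURATION_S = 180.0
DEFAULT_FS_HZ = 100.0


@dataclass
class CoPTrial:
    """One antero-posterior CoP record plus design metadata.

    Parameters
    ----------
    participant_id : str
        Identifier of the participant.
    vision : str
        ``"EO"`` (eyes open) or ``"EC"`` (eyes closed).
    platform_freq : float
        Platform oscillation frequency during the perturbation phase, Hz.
    trial_order : int
        Position of the trial within the session (1-based).
    mss : float
        Motion sickness susceptibility score (non-negative).
    fs : float
        Sampling frequency, Hz (100 by default).
    cop_ap : numpy.ndarray
        AP CoP positions in mm, length ``fs * duration``.
    meta : dict
        Free-form provenance (e.g. the seed the generator used).
    """

    participant_id: str
    vision: str
    platform_freq: float
    trial_order: int
    mss: float
    fs: float
    cop_ap: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vision not in VISION_LEVELS:
            raise ValueError(
                f"vision must be one of {VISION_LEVELS}, got {self.vision!r}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.trial_order < 1:
            raise ValueError("trial_order is 1-based and must be >= 1")
        if self.mss < 0:
            raise ValueError("mss must be non-negative")
        self.cop_ap = np.asarray(self.cop_ap, dtype=float)
        if self.cop_ap.ndim != 1:
            raise ValueError("cop_ap must be one-dimensional")
        if not np.all(np.isfinite(self.cop_ap)):
            raise ValueError("cop_ap contains non-finite samples")

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.cop_ap.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.cop_ap.size) / self.fs

    @property
    def key(self) -> tuple:
        """Design key (participant, vision, platform frequency)."""
        return (self.participant_id, self.vision, self.platform_freq)
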