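"""YAML run configuration.

A run config mirrors the generator and analysis parameters (cohort spec,
pendulum parameters, spectrogram window/step, fit subsampling, seed) and
is serialized alongside every run's outputs so results are reproducible
from the config alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import CohortSpec, PendulumParams


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    window_len: float = 10.0
    step: float = 0.01
    taper: str = "rect"
    subsample_dt: float = 1.0
    max_fail_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.cohort.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort_d = dict(d.pop("cohort", {}))
        base_d = cohort_d.pop("base_params", None)
        if base_d is not None:
            cohort_d["base_params"] = PendulumParams(**base_d)
        cohort = CohortSpec(**cohort_d)
        return cls(cohort=cohort, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
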