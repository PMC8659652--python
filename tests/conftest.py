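"""Shared fixtures: analysis grid, surrogate trials, and a full synthetic
cohort analyzed once per session (the expensive end-to-end products that
several test modules interrogate)."""

from __future__ import annotations

import numpy as np
import pytest

from swayspec import pipeline, synth

ANALYSIS_FREQS = np.round(np.arange(0.1, 5.0 + 1e-9, 0.1), 10)

#: Reduced spectrogram step used throughout the tests (the estimate is
#: identical in structure to the default 10 ms step; see docs/methods.md).
TEST_STEP = 0.1


def make_surrogate_schedule(
    platform_freq: float = 0.2,
    return_rate: float = 0.05,
    return_start: float = 0.47,
    amplitude_jitter: float = 0.0,
    **kwargs,
) -> synth.SpectralSchedule:
    base_db = 10 * np.log10(synth.default_baseline_psd(ANALYSIS_FREQS))
    delta = synth.perturbation_delta_db(ANALYSIS_FREQS, platform_freq)
    return synth.SpectralSchedule(
        freqs=ANALYSIS_FREQS,
        baseline_db=base_db,
        perturb_db=base_db + delta,
        return_rate=return_rate,
        return_start=return_start,
        adapt_b=1.18,
        adapt_rate=0.065,
        amplitude_jitter=amplitude_jitter,
        **kwargs,
    )


@pytest.fixture(scope="session")
def exact_surrogate_trial():
    """Noise-free surrogate (deterministic bin amplitudes, C = 0.05)."""
    return synth.simulate_surrogate_trial(make_surrogate_schedule(), seed=11)


@pytest.fixture(scope="session")
def exact_surrogate_analysis(exact_surrogate_trial):
    return pipeline.analyze_trial(exact_surrogate_trial, step=TEST_STEP)


@pytest.fixture(scope="session")
def cohort_spec():
    return synth.CohortSpec(seed=7)


@pytest.fixture(scope="session")
def full_cohort(cohort_spec):
    """Default 43-participant surrogate cohort (258 trials)."""
    return synth.generate_cohort(cohort_spec)


@pytest.fixture(scope="session")
def analyzed_cohort(full_cohort):
    """Full pipeline run over the default cohort at the test step."""
    return pipeline.analyze_cohort(full_cohort, step=TEST_STEP)
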