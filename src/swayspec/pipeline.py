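"""End-to-end per-trial and cohort analysis.

The per-trial chain is sliding PSD -> PC1 -> normalized score ->
spectral balance; the cohort chain adds the joint exponential fits
(perturbation and return phases), per-trial lag scores, and the two
group-level models.  Failing trials are quarantined (with the failing
stage's message) rather than aborting the whole run; the run fails only
if more than ``max_fail_fraction`` of the trials fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import balance as balance_mod
from . import expfit, pca, spectro, stats
from .trial import CoPTrial


@dataclass
class TrialAnalysis:
    """Per-trial products: PC1, normalized score, spectral balance."""

    trial: CoPTrial
    pc: pca.PCResult
    balance: balance_mod.BalanceScore

    @property
    def scored(self) -> expfit.ScoredTrial:
        return expfit.ScoredTrial(
            participant_id=self.trial.participant_id,
            vision=self.trial.vision,
            platform_freq=self.trial.platform_freq,
            trial_order=self.trial.trial_order,
            mss=self.trial.mss,
            times=self.pc.times,
            norm_score=self.pc.norm_score,
        )

    def stat_row(self) -> dict:
        return {
            "participant_id": self.trial.participant_id,
            "vision": self.trial.vision,
            "freq_hz": self.trial.platform_freq,
            "trial_order": self.trial.trial_order,
            "mss": self.trial.mss,
            "balance": self.balance.balance,
            "var_explained": self.pc.var_explained,
        }


@dataclass
class CohortAnalysis:
    """All cohort-level products of one analysis run."""

    trials: list[TrialAnalysis]
    quarantined: list[tuple[tuple, str]]
    stat_table: pd.DataFrame
    fit_perturbation: expfit.ExpFitResult | None = None
    fit_return: expfit.ExpFitResult | None = None
    lag_table: pd.DataFrame | None = None
    balance_result: stats.BalanceModelResult | None = None
    lag_result: stats.LagModelResult | None = None
    params: dict = field(default_factory=dict)


def analyze_trial(
    trial: CoPTrial,
    window_len: float = 10.0,
    step: float = 0.01,
    taper: str = "rect",
    low_band=balance_mod.LOW_BAND,
    high_band=balance_mod.HIGH_BAND,
) -> TrialAnalysis:
    """Run the per-trial chain on one trial."""
    sg = spectro.sliding_psd(trial, window_len=window_len, step=step, taper=taper)
    pc = pca.fit_pc1(sg)
    pca.attach_norm_score(pc)
    bal = balance_mod.spectral_balance(
        pc.eigenvector, pc.freqs, low_band=low_band, high_band=high_band
    )
    return TrialAnalysis(trial=trial, pc=pc, balance=bal)


def analyze_cohort(
    trials: Sequence[CoPTrial],
    window_len: float = 10.0,
    step: float = 0.01,
    taper: str = "rect",
    subsample_dt: float = 1.0,
    max_fail_fraction: float = 0.1,
    fit_perturbation_phase: bool = True,
    run_models: bool = True,
) -> CohortAnalysis:
    """Run the full pipeline over a cohort of trials.

    Raises
    ------
    RuntimeError
        If more than ``max_fail_fraction`` of the trials fail their
        per-trial analysis.
    """
    analyzed: list[TrialAnalysis] = []
    quarantined: list[tuple[tuple, str]] = []
    for trial in trials:
        try:
            analyzed.append(
                analyze_trial(
                    trial, window_len=window_len, step=step, taper=taper
                )
            )
        except Exception as exc:
            quarantined.append((trial.key, str(exc)))
    if len(trials) and len(quarantined) > max_fail_fraction * len(trials):
        lines = "; ".join(f"{k}: {m}" for k, m in quarantined[:5])
        raise RuntimeError(
            f"{len(quarantined)}/{len(trials)} trials failed analysis: {lines}"
        )

    stat_table = pd.DataFrame([a.stat_row() for a in analyzed])
    result = CohortAnalysis(
        trials=analyzed,
        quarantined=quarantined,
        stat_table=stat_table,
        params={
            "window_len": window_len,
            "step": step,
            "taper": taper,
            "subsample_dt": subsample_dt,
        },
    )
    if not analyzed:
        return result

    scored = [a.scored for a in analyzed]
    if fit_perturbation_phase:
        result.fit_perturbation = expfit.fit_exponential(
            scored,
            expfit.ExpModelSpec(phase="perturbation", subsample_dt=subsample_dt),
        )
    result.fit_return = expfit.fit_exponential(
        scored, expfit.ExpModelSpec(phase="return", subsample_dt=subsample_dt)
    )
    lag_table = expfit.lag_scores(result.fit_return, scored)
    result.lag_table = lag_table
    result.stat_table = stat_table.merge(
        lag_table[["participant_id", "vision", "freq_hz", "lag"]],
        on=["participant_id", "vision", "freq_hz"],
        how="left",
    )
    if run_models:
        result.balance_result = stats.balance_model(result.stat_table)
        result.lag_result = stats.lag_model(result.stat_table)
    return result
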