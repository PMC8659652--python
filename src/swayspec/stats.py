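"""Group-level models for the per-trial statistics.

Two models mirror the cohort-level analysis:

* :func:`balance_model` — ordinary linear model of the spectral balance
  on vision (discrete), platform frequency (discrete) and the MSS score
  (continuous), with the vision-by-MSS interaction; sum-to-zero
  contrasts, type-II F tests, and the planned contrast of the 0.4 Hz
  condition against the mean of 0.1 and 0.2 Hz.
* :func:`lag_model` — linear mixed model of the lag score on vision and
  MSS with a participant random intercept (REML), reported as per-vision
  MSS slopes with 95% confidence intervals.  By default the lag is first
  averaged over the three platform frequencies within each
  participant-by-vision cell; per-trial rows can be modeled directly
  instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .trial import VISION_LEVELS

REQUIRED_COLUMNS = ["participant_id", "vision", "freq_hz", "trial_order", "mss"]


@dataclass
class BalanceModelResult:
    """Fitted balance model with its F table and planned contrast."""

    fit: object  # statsmodels OLSResults
    anova: pd.DataFrame  # type-II F tests per term
    contrast_estimate: float  # 0.4 Hz minus mean of 0.1 & 0.2 Hz
    contrast_t: float
    contrast_df: float
    contrast_p: float
    freq_levels: list[float]

    def f_test(self, term: str) -> tuple[float, float, float, float]:
        """(F, df_num, df_den, p) for one model term."""
        row = self.anova.loc[term]
        return (
            float(row["F"]),
            float(row["df"]),
            float(self.fit.df_resid),
            float(row["PR(>F)"]),
        )

    def predict_cells(self, mss_values) -> pd.DataFrame:
        """Predicted balance per vision x frequency cell at given MSS values."""
        rows = []
        for mss in np.atleast_1d(mss_values):
            for vis in VISION_LEVELS:
                for fr in self.freq_levels:
                    rows.append({"vision": vis, "freq_hz": fr, "mss": float(mss)})
        grid = pd.DataFrame(rows)
        grid["freq_str"] = grid["freq_hz"].map(lambda f: f"{f:g}")
        grid["predicted_balance"] = self.fit.predict(grid)
        return grid.drop(columns="freq_str")


@dataclass
class LagModelResult:
    """Per-vision MSS slopes on the lag score, with 95% CIs."""

    fit: object  # MixedLMResults or OLSResults (fallback)
    slopes: dict[str, tuple[float, float, float]]  # vision -> (est, lo, hi)
    random_intercept_var: float | None
    used_random_intercept: bool
    averaged: bool

    def slope_frame(self) -> pd.DataFrame:
        rows = [
            {"vision": v, "slope": est, "ci95_low": lo, "ci95_high": hi}
            for v, (est, lo, hi) in self.slopes.items()
        ]
        return pd.DataFrame(rows)

    def predict_lines(self, mss_grid) -> pd.DataFrame:
        """Regression lines lag(MSS) per vision (fixed effects only)."""
        fe = self.fit.params
        inter = float(fe.get("Intercept", 0.0))
        v_ec = next((k for k in fe.index if "vision" in k and ":" not in k), None)
        m_k = "mss"
        int_k = next((k for k in fe.index if ":" in k), None)
        rows = []
        for mss in np.atleast_1d(mss_grid):
            for vis in VISION_LEVELS:
                y = inter + float(fe[m_k]) * mss
                if vis == "EC":
                    if v_ec is not None:
                        y += float(fe[v_ec])
                    if int_k is not None:
                        y += float(fe[int_k]) * mss
                rows.append({"vision": vis, "mss": float(mss), "predicted_lag": y})
        return pd.DataFrame(rows)


def _check_table(table: pd.DataFrame, response: str) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS + [response]) - set(table.columns)
    if missing:
        raise ValueError(f"table missing column(s) {sorted(missing)}")
    out = table.dropna(subset=REQUIRED_COLUMNS + [response]).copy()
    if out["vision"].nunique() < 2:
        raise ValueError("need both vision levels in the table")
    if (out["mss"] < 0).any():
        raise ValueError("mss must be non-negative")
    return out


def balance_model(table: pd.DataFrame) -> BalanceModelResult:
    """Linear model ``balance ~ vision + frequency + mss + vision:mss``.

    Discrete factors use sum-to-zero contrasts; F statistics are type-II
    (with no three-way terms the choice only matters for the main effects
    in unbalanced tables).  On a complete 258-trial cohort the residual
    degrees of freedom are 252 (6 estimated coefficients).  The planned
    frequency contrast compares the 0.4 Hz cell mean against the average
    of the 0.1 and 0.2 Hz cell means (t test on the corresponding linear
    combination of coefficients).

    Raises
    ------
    ValueError
        If a factor has fewer than 2 levels or the design is rank
        deficient (the aliased term is named).
    """
    data = _check_table(table, "balance")
    if data["freq_hz"].nunique() < 2:
        raise ValueError("need at least 2 frequency levels")
    data["freq_str"] = data["freq_hz"].map(lambda f: f"{f:g}")
    formula = (
        "balance ~ C(vision, Sum) + C(freq_str, Sum) + mss + C(vision, Sum):mss"
    )
    model = smf.ols(formula, data=data)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # locate the aliased column for the error message
        _, r = np.linalg.qr(model.exog)
        bad = model.exog_names[int(np.argmin(np.abs(np.diag(r))))]
        raise ValueError(f"rank-deficient design: term {bad!r} is aliased")
    fit = model.fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table_f = anova_lm(fit, typ=2)
    table_f = table_f.rename(
        index={
            "C(vision, Sum)": "vision",
            "C(freq_str, Sum)": "frequency",
            "C(vision, Sum):mss": "vision:mss",
        }
    )

    freq_levels = sorted(data["freq_hz"].unique())
    # Sum coding over sorted level labels drops the last level; cell
    # effect of the dropped level is minus the sum of the kept ones.
    labels = sorted(data["freq_str"].unique())
    names = fit.params.index
    vec = np.zeros(len(names))
    hi = f"{max(freq_levels):g}"
    kept = [la for la in labels[:-1]]
    for i, name in enumerate(names):
        for la in kept:
            if name == f"C(freq_str, Sum)[S.{la}]":
                # contrast: mu(0.4) - mean(mu(others))
                if la == hi:
                    vec[i] = 1.0 + 1.0 / (len(labels) - 1)
                else:
                    vec[i] = -1.0 / (len(labels) - 1) - 1.0
    if hi not in kept:
        # dropped level: e_hi = -sum(kept effects)
        for i, name in enumerate(names):
            for la in kept:
                if name == f"C(freq_str, Sum)[S.{la}]":
                    vec[i] = -1.0 - 1.0 / (len(labels) - 1)
    tt = fit.t_test(vec)
    return BalanceModelResult(
        fit=fit,
        anova=table_f,
        contrast_estimate=float(np.squeeze(tt.effect)),
        contrast_t=float(np.squeeze(tt.tvalue)),
        contrast_df=float(fit.df_resid),
        contrast_p=float(np.squeeze(tt.pvalue)),
        freq_levels=[float(f) for f in freq_levels],
    )


def lag_model(
    table: pd.DataFrame,
    averaged: bool = True,
    force_ols: bool = False,
) -> LagModelResult:
    """Mixed model of the lag score on vision x MSS.

    ``lag ~ vision * mss`` with a participant random intercept, fitted
    by REML.  With ``averaged`` (default) the lag is first averaged over
    the platform frequencies within each participant-by-vision cell.
    Returns the MSS slope for each vision condition with 95% CIs from
    the large-sample normal approximation.  A singular random-effects
    fit falls back to ordinary least squares with a warning.
    """
    data = _check_table(table, "lag")
    if averaged and "freq_hz" in data.columns and data["freq_hz"].nunique() > 1:
        data = (
            data.groupby(["participant_id", "vision"], as_index=False)
            .agg(mss=("mss", "first"), lag=("lag", "mean"))
        )
    fit = None
    used_re = False
    re_var = None
    if not force_ols:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(
                    "lag ~ vision * mss", data, groups=data["participant_id"]
                )
                mfit = md.fit(reml=True)
            if np.all(np.isfinite(mfit.params)) and np.isfinite(
                float(mfit.cov_re.iloc[0, 0])
            ):
                fit = mfit
                used_re = True
                re_var = float(mfit.cov_re.iloc[0, 0])
        except Exception as exc:  # singular / non-converging random effects
            warnings.warn(
                f"random-intercept fit failed ({exc}); falling back to OLS"
            )
    if fit is None:
        fit = smf.ols("lag ~ vision * mss", data).fit()
        used_re = False

    params = fit.params
    cov = fit.cov_params()
    m_k = "mss"
    int_k = next((k for k in params.index if ":" in k and "mss" in k), None)

    def slope_ci(keys_and_signs):
        est = sum(s * float(params[k]) for k, s in keys_and_signs)
        var = 0.0
        for k1, s1 in keys_and_signs:
            for k2, s2 in keys_and_signs:
                var += s1 * s2 * float(cov.loc[k1, k2])
        half = 1.96 * np.sqrt(max(var, 0.0))
        return est, est - half, est + half

    # treatment coding: EC is the reference-alphabetical first? statsmodels
    # uses the first sorted level as reference; find which got the dummy.
    dummy_level = None
    for k in params.index:
        if k.startswith("vision[T.") and ":" not in k:
            dummy_level = k.split("T.")[1].rstrip("]")
    ref_level = next(v for v in VISION_LEVELS if v != dummy_level)

    slopes = {}
    slopes[ref_level] = slope_ci([(m_k, 1.0)])
    if int_k is not None and dummy_level is not None:
        slopes[dummy_level] = slope_ci([(m_k, 1.0), (int_k, 1.0)])
    return LagModelResult(
        fit=fit,
        slopes=slopes,
        random_intercept_var=re_var,
        used_random_intercept=used_re,
        averaged=averaged,
    )
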