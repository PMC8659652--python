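"""Exponential adaptation/de-adaptation model for normalized PC1 scores.

Within the perturbation phase, and again within the return phase, the
normalized PC1 score relaxes toward an asymptote and is modeled as

    y(t) = A + (B - A) * exp(-C * (t - t0))

where ``t0`` is the phase onset as seen by the analysis (65 s for the
perturbation phase, 125 s for the return phase: windows straddling a
phase boundary mix two conditions and are excluded), ``A`` the asymptote,
``B`` the value at ``t0`` and ``C`` the relaxation rate, whose inverse is
the time constant tau.

Trials are fitted jointly by nonlinear least squares: ``A`` is shared
across all trials of a phase, while ``B`` and ``C`` carry additive
contrasts for the visual condition and the platform frequency plus a
linear slope in the (centered) trial order.  Per-trial lag scores — mean
residual divided by its standard deviation — quantify whether a trial
returns to baseline later (positive) or earlier (negative) than the
fitted group curve predicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .trial import VISION_LEVELS

#: Multi-start grid for the relaxation rate (1/s); exponential fits are
#: initialization-sensitive, so each fit is run from every value and the
#: lowest objective wins.  The negative start lets the optimizer reach
#: diverging (C < 0) solutions, which are flagged downstream.
C_STARTS = (0.01, 0.05, 0.2, -0.05, -0.2)

PHASE_DEFAULTS = {
    "perturbation": (65.0, (65.0, 115.0)),
    "return": (125.0, (125.0, 165.0)),
    "baseline": (5.0, (5.0, 55.0)),
}


@dataclass
class ScoredTrial:
    """Normalized PC1 score of one trial, with its design metadata."""

    participant_id: str
    vision: str
    platform_freq: float
    trial_order: int
    mss: float
    times: np.ndarray
    norm_score: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.norm_score = np.asarray(self.norm_score, dtype=float)
        if self.times.shape != self.norm_score.shape:
            raise ValueError("times and norm_score must have the same shape")

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.vision, self.platform_freq)


@dataclass
class ExpModelSpec:
    """What to fit: phase window and which contrasts B and C carry.

    ``A`` is always shared.  With the default structure, ``B`` and ``C``
    each get a reference value (eyes open, lowest frequency, centered
    order) plus an additive eyes-closed contrast, one contrast per
    non-reference frequency, and a linear centered trial-order slope.
    """

    phase: str = "return"
    t0: float | None = None
    fit_window: tuple[float, float] | None = None
    by_vision: bool = True
    by_freq: bool = True
    order_slope: bool = True
    subsample_dt: float = 1.0  # s between fitted points; 0 keeps every score

    def __post_init__(self) -> None:
        if self.phase not in PHASE_DEFAULTS:
            raise ValueError(f"unknown phase {self.phase!r}")
        d_t0, d_win = PHASE_DEFAULTS[self.phase]
        if self.t0 is None:
            self.t0 = d_t0
        if self.fit_window is None:
            self.fit_window = d_win
        if abs(self.fit_window[0] - self.t0) > 1e-9:
            raise ValueError("fit_window must start at t0")
        if self.fit_window[1] <= self.fit_window[0]:
            raise ValueError("empty fit window")


class FitConvergenceError(RuntimeError):
    """All optimizer starts failed to converge."""


@dataclass
class ExpFitResult:
    """Joint exponential fit of one phase across trials.

    ``b`` and ``c`` map each (vision, freq) cell to its value at the
    centered trial order; ``tau`` holds 1/C (NaN where C <= 0, which is
    also recorded in ``nonpositive_c``).  ``params``/``cov``/``ci95``
    expose the raw parameter vector for uncertainty work; confidence
    intervals come from the local quadratic approximation at the optimum
    (t quantiles on the asymptotic standard errors).
    """

    spec: ExpModelSpec
    param_names: list[str]
    params: np.ndarray
    cov: np.ndarray
    ci95: dict[str, tuple[float, float]]
    A: float
    b: dict[tuple[str, float], float]
    c: dict[tuple[str, float], float]
    tau: dict[tuple[str, float], float]
    nonpositive_c: list[tuple[str, float]]
    residuals: dict[tuple, np.ndarray]
    residual_times: dict[tuple, np.ndarray]
    sse: float
    n_points: int
    vision_levels: list[str] = field(default_factory=list)
    freq_levels: list[float] = field(default_factory=list)
    order_center: float = 0.0

    def _bc_at(self, vision: str, freq: float, order: float) -> tuple[float, float]:
        names = self.param_names
        p = dict(zip(names, self.params))
        out = []
        for which in ("B", "C"):
            v = p[f"{which}0"]
            if vision != self.vision_levels[0] and f"{which}_{vision}" in p:
                v += p[f"{which}_{vision}"]
            key = f"{which}_f{freq:g}"
            if key in p:
                v += p[key]
            if f"{which}_order" in p:
                v += p[f"{which}_order"] * (order - self.order_center)
            out.append(v)
        return out[0], out[1]

    def predict(
        self,
        vision: str,
        freq: float,
        t: np.ndarray,
        order: float | None = None,
    ) -> np.ndarray:
        """Model trajectory for one condition; ``t`` must be >= t0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.spec.t0 - 1e-9):
            raise ValueError("prediction times must be >= t0")
        if order is None:
            order = self.order_center
        b, c = self._bc_at(vision, freq, order)
        return predict(self.A, b, c, self.spec.t0, t)

    def params_frame(self) -> pd.DataFrame:
        """Estimate and 95% CI per raw parameter (S3-style layout)."""
        lo = [self.ci95[n][0] for n in self.param_names]
        hi = [self.ci95[n][1] for n in self.param_names]
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "estimate": self.params,
                "ci95_low": lo,
                "ci95_high": hi,
            }
        )

    def condition_frame(self) -> pd.DataFrame:
        rows = []
        for (vis, fr), bv in self.b.items():
            rows.append(
                {
                    "vision": vis,
                    "freq_hz": fr,
                    "A": self.A,
                    "B": bv,
                    "C": self.c[(vis, fr)],
                    "tau_s": self.tau[(vis, fr)],
                }
            )
        return pd.DataFrame(rows)


def predict(A: float, B: float, C: float, t0: float, t: np.ndarray) -> np.ndarray:
    """Evaluate ``A + (B - A) * exp(-C (t - t0))``.

    At ``t == t0`` the value is exactly ``B``; as C -> 0 the curve tends
    to the constant ``B``; for C > 0 it relaxes to ``A``.
    """
    t = np.asarray(t, dtype=float)
    return A + (B - A) * np.exp(-C * (t - t0))


def time_constant(C: float) -> float:
    """Time constant tau = 1/C in seconds; requires C > 0."""
    if C <= 0:
        raise ValueError(f"time constant undefined for C = {C:g} <= 0")
    return 1.0 / C


def lag_score(
    observed: np.ndarray,
    predicted: np.ndarray,
    min_points: int = 2,
    zero_tol: float = 1e-12,
) -> float:
    """Mean residual over its sample standard deviation (n-1 divisor).

    Positive values mean the observed score stays above the fitted curve
    — a slower-than-predicted return to baseline; negative values an
    earlier return.  The score is invariant to positive scaling of the
    residuals.  When the residuals are (numerically) all zero the score
    is 0 by convention.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have the same shape")
    if observed.size < min_points:
        raise ValueError(f"need at least {min_points} points for a lag score")
    resid = observed - predicted
    sd = float(resid.std(ddof=1))
    scale = max(float(np.abs(observed).max()), 1.0)
    if sd <= zero_tol * scale:
        return 0.0
    return float(resid.mean() / sd)


def _subsample_mask(times: np.ndarray, t0: float, dt: float, step_hint: float) -> np.ndarray:
    if dt <= 0:
        return np.ones(times.size, dtype=bool)
    # keep points lying on the t0 + k*dt grid (tolerance half a step)
    k = np.round((times - t0) / dt)
    return np.abs(times - (t0 + k * dt)) <= max(step_hint / 2.0, 1e-9)


def _design(trials: Sequence[ScoredTrial], spec: ExpModelSpec):
    vision_levels = [v for v in VISION_LEVELS if any(t.vision == v for t in trials)]
    freq_levels = sorted({t.platform_freq for t in trials})
    orders = np.array([t.trial_order for t in trials], dtype=float)
    order_center = float(orders.mean())

    cols: list[str] = ["0"]  # reference level
    if spec.by_vision:
        cols += [f"_{v}" for v in vision_levels[1:]]
    if spec.by_freq:
        cols += [f"_f{f:g}" for f in freq_levels[1:]]
    if spec.order_slope:
        cols += ["_order"]

    rows, keys, y_all, t_all = [], [], [], []
    for trial in trials:
        lo, hi = spec.fit_window
        m = (trial.times >= lo - 1e-9) & (trial.times <= hi + 1e-9)
        tt, yy = trial.times[m], trial.norm_score[m]
        step_hint = float(np.min(np.diff(tt))) if tt.size > 1 else 0.0
        sub = _subsample_mask(tt, spec.t0, spec.subsample_dt, step_hint)
        tt, yy = tt[sub], yy[sub]
        if tt.size == 0:
            raise ValueError(
                f"trial {trial.key} has no score samples in the fit window"
            )
        row = [1.0]
        if spec.by_vision:
            row += [1.0 if trial.vision == v else 0.0 for v in vision_levels[1:]]
        if spec.by_freq:
            row += [
                1.0 if trial.platform_freq == f else 0.0 for f in freq_levels[1:]
            ]
        if spec.order_slope:
            row += [trial.trial_order - order_center]
        rows.append(row)
        keys.append(trial.key)
        y_all.append(yy)
        t_all.append(tt)

    X = np.asarray(rows, dtype=float)
    lengths = np.array([len(y) for y in y_all])
    Xp = np.repeat(X, lengths, axis=0)  # per-point design
    y = np.concatenate(y_all)
    t = np.concatenate(t_all)
    return cols, Xp, keys, y, t, vision_levels, freq_levels, order_center, lengths


def fit_exponential(
    trials: Sequence[ScoredTrial], spec: ExpModelSpec | None = None
) -> ExpFitResult:
    """Joint nonlinear least-squares fit of the exponential model.

    All trials' in-window scores enter one objective; ``A`` is shared and
    ``B``, ``C`` follow the contrast structure in ``spec``.  The
    optimizer is derivative-based least squares with an analytic
    Jacobian, restarted from each rate in ``C_STARTS`` (the best optimum
    is kept), so the fit is deterministic given the data.  Scores are
    subsampled to one point per ``spec.subsample_dt`` seconds; for
    noise-free exponential data the estimate is invariant to uniform
    subsampling.

    Returns
    -------
    ExpFitResult
        Estimates, covariance, 95% confidence intervals, per-trial
        residuals on the fitted time grid, and tau = 1/C per condition.
        A non-positive C estimate is flagged (the model then predicts
        divergence) but the fit is still returned.

    Raises
    ------
    FitConvergenceError
        If no start converges.
    """
    if spec is None:
        spec = ExpModelSpec()
    if len(trials) == 0:
        raise ValueError("no trials to fit")
    (cols, Xp, keys, y, t, vision_levels, freq_levels, order_center, lengths) = _design(
        trials, spec
    )
    dt = t - spec.t0
    p_bc = len(cols)
    n_par = 1 + 2 * p_bc

    def unpack(theta):
        A = theta[0]
        bB = theta[1 : 1 + p_bc]
        bC = theta[1 + p_bc :]
        B = Xp @ bB
        C = Xp @ bC
        return A, B, C

    def residuals(theta):
        A, B, C = unpack(theta)
        return y - (A + (B - A) * np.exp(-C * dt))

    def jacobian(theta):
        A, B, C = unpack(theta)
        e = np.exp(-C * dt)
        J = np.empty((y.size, n_par))
        J[:, 0] = -(1.0 - e)
        J[:, 1 : 1 + p_bc] = -e[:, None] * Xp
        J[:, 1 + p_bc :] = ((B - A) * dt * e)[:, None] * Xp
        return J

    # data-driven starting values: B from scores near t0, A from the tail
    near0 = dt <= (dt.min() + spec.subsample_dt + 1e-9)
    tail = dt >= np.quantile(dt, 0.8)
    B_start = float(y[near0].mean())
    A_start = float(y[tail].mean())

    best = None
    for c0 in C_STARTS:
        theta0 = np.zeros(n_par)
        theta0[0] = A_start
        theta0[1] = B_start
        theta0[1 + p_bc] = c0
        try:
            res = optimize.least_squares(
                residuals, theta0, jac=jacobian, method="lm", xtol=1e-12,
                ftol=1e-12, gtol=1e-12, max_nfev=20000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitConvergenceError(
            f"exponential fit failed from all starts C0 in {C_STARTS} "
            f"(n={y.size} points, {len(keys)} trials)"
        )

    theta = best.x
    r = residuals(theta)
    sse = float(r @ r)
    dof = max(y.size - n_par, 1)
    sigma2 = sse / dof
    J = jacobian(theta)
    JtJ = J.T @ J
    cov = sigma2 * np.linalg.pinv(JtJ)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tq = sps.t.ppf(0.975, dof)

    names = ["A"] + [f"B{c}" for c in cols] + [f"C{c}" for c in cols]
    ci95 = {
        n: (float(v - tq * s), float(v + tq * s))
        for n, v, s in zip(names, theta, se)
    }

    result = ExpFitResult(
        spec=spec,
        param_names=names,
        params=theta,
        cov=cov,
        ci95=ci95,
        A=float(theta[0]),
        b={},
        c={},
        tau={},
        nonpositive_c=[],
        residuals={},
        residual_times={},
        sse=sse,
        n_points=int(y.size),
        vision_levels=vision_levels,
        freq_levels=freq_levels,
        order_center=order_center,
    )
    for vis in vision_levels:
        for fr in freq_levels:
            bv, cv = result._bc_at(vis, fr, order_center)
            result.b[(vis, fr)] = bv
            result.c[(vis, fr)] = cv
            if cv > 0:
                result.tau[(vis, fr)] = 1.0 / cv
            else:
                result.tau[(vis, fr)] = math.nan
                result.nonpositive_c.append((vis, fr))

    # per-trial residuals on the fitted time grid
    offset = 0
    for key, ln in zip(keys, lengths):
        sl = slice(offset, offset + ln)
        result.residuals[key] = r[sl].copy()
        result.residual_times[key] = t[sl].copy()
        offset += ln
    return result


def lag_scores(
    fit: ExpFitResult, trials: Sequence[ScoredTrial]
) -> pd.DataFrame:
    """Per-trial lag scores against the fitted group curve.

    Returns one row per trial with the design metadata and the lag
    (mean residual / sample SD of the residual over the fit window).
    """
    by_key = {t.key: t for t in trials}
    rows = []
    for key, resid in fit.residuals.items():
        trial = by_key[key]
        zeros = np.zeros_like(resid)
        rows.append(
            {
                "participant_id": trial.participant_id,
                "vision": trial.vision,
                "freq_hz": trial.platform_freq,
                "trial_order": trial.trial_order,
                "mss": trial.mss,
                "lag": lag_score(resid, zeros),
            }
        )
    return pd.DataFrame(rows)


def averaged_lag(lag_table: pd.DataFrame) -> pd.DataFrame:
    """Lag averaged over the perturbation frequencies per participant x vision."""
    return (
        lag_table.groupby(["participant_id", "vision"], as_index=False)
        .agg(mss=("mss", "first"), lag=("lag", "mean"))
    )
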