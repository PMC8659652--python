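"""Exponential model fitting: closed forms, recovery, oracles, lag score."""

import itertools

import numpy as np
import pytest

from swayspec import expfit, synth

RETURN_T = np.arange(125.0, 165.0 + 1e-9, 1.0)
CONDITIONS = list(itertools.product(("EO", "EC"), (0.1, 0.2, 0.4)))


def make_trials(param_fn, noise_sd=0.0, seed=None, n_rep=2):
    """ScoredTrials per condition cell (x n_rep) from true (A, B, C).

    Order assignments are reversed between replicates so trial order is
    not collinear with the condition dummies (as counterbalancing
    guarantees in a real cohort).
    """
    trials = []
    counter = 0
    for rep in range(n_rep):
        for i, (vis, fr) in enumerate(CONDITIONS):
            order = i + 1 if rep % 2 == 0 else 6 - i
            A, B, C = param_fn(vis, fr, order)
            y = synth.generate_exponential_trajectory(
                A, B, C, 125.0, RETURN_T, noise_sd=noise_sd,
                seed=None if seed is None else seed + counter,
            )
            trials.append(
                expfit.ScoredTrial(
                    participant_id=f"p{rep}", vision=vis, platform_freq=fr,
                    trial_order=order, mss=0.0, times=RETURN_T, norm_score=y,
                )
            )
            counter += 1
    return trials


class TestPredict:
    def test_value_at_t0_is_exactly_B(self):
        assert expfit.predict(0.3, 1.7, 0.08, 125.0, np.array([125.0]))[0] == 1.7

    def test_unit_rate_time_gives_e_inverse(self):
        y = expfit.predict(0.0, 1.0, 0.05, 0.0, np.array([20.0]))[0]
        assert y == pytest.approx(np.exp(-1.0), abs=1e-12)
        assert y == pytest.approx(0.36788, abs=5e-6)

    def test_zero_rate_limit_is_constant_B(self):
        t = np.linspace(0, 100, 11)
        assert np.allclose(expfit.predict(0.0, 0.8, 0.0, 0.0, t), 0.8)


class TestTimeConstant:
    def test_printed_time_constants(self):
        assert expfit.time_constant(0.050) == pytest.approx(20.0)
        tau_ec = expfit.time_constant(0.050 - 0.021)
        assert tau_ec == pytest.approx(34.48, abs=0.01)
        assert round(tau_ec / 5) * 5 == 35
        assert expfit.time_constant(1.0) == 1.0

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="C"):
            expfit.time_constant(0.0)

    def test_tau_strictly_decreasing_in_rate(self):
        cs = np.linspace(0.01, 1.0, 25)
        taus = [expfit.time_constant(c) for c in cs]
        assert np.all(np.diff(taus) < 0)


class TestFitExponential:
    def test_noise_free_recovery_to_machine_tolerance(self):
        true = dict(A=0.0, B=1.0, C=0.05)
        trials = make_trials(lambda v, f, o: (true["A"], true["B"], true["C"]))
        fit = expfit.fit_exponential(trials, expfit.ExpModelSpec(phase="return"))
        assert fit.A == pytest.approx(true["A"], abs=1e-6)
        for cond in CONDITIONS:
            assert fit.b[cond] == pytest.approx(true["B"], rel=1e-6)
            assert fit.c[cond] == pytest.approx(true["C"], rel=1e-6)
        # optimum at least as good as the generating parameters (both ~0)
        assert fit.sse <= 1e-12

    def test_condition_structure_recovered_noise_free(self):
        def pf(vis, fr, order):
            B = 0.37 + (0.19 if vis == "EC" else 0.0) + 0.01 * (fr == 0.4)
            C = 0.050 - (0.021 if vis == "EC" else 0.0)
            return 0.0, B, C

        fit = expfit.fit_exponential(make_trials(pf))
        assert fit.c[("EO", 0.1)] == pytest.approx(0.050, abs=1e-6)
        assert fit.c[("EC", 0.1)] == pytest.approx(0.029, abs=1e-6)
        assert fit.tau[("EO", 0.1)] == pytest.approx(20.0, abs=1e-3)
        assert fit.tau[("EC", 0.1)] == pytest.approx(34.48, abs=0.01)
        assert fit.b[("EC", 0.2)] - fit.b[("EO", 0.2)] == pytest.approx(0.19, abs=1e-5)

    def test_identical_conditions_give_equal_contrasts(self):
        trials = make_trials(lambda v, f, o: (0.1, 0.9, 0.07))
        fit = expfit.fit_exponential(trials)
        bs = set(round(v, 9) for v in fit.b.values())
        cs = set(round(v, 9) for v in fit.c.values())
        assert len(bs) == 1 and len(cs) == 1

    def test_estimate_invariant_to_uniform_subsampling_noise_free(self):
        trials = make_trials(lambda v, f, o: (0.0, 1.0, 0.05))
        f1 = expfit.fit_exponential(
            trials, expfit.ExpModelSpec(phase="return", subsample_dt=1.0)
        )
        f5 = expfit.fit_exponential(
            trials, expfit.ExpModelSpec(phase="return", subsample_dt=5.0)
        )
        assert f1.A == pytest.approx(f5.A, abs=1e-8)
        assert f1.c[("EO", 0.1)] == pytest.approx(f5.c[("EO", 0.1)], rel=1e-6)

    def test_matches_grid_search_oracle_on_single_trial(self):
        rng = np.random.default_rng(12)
        y = synth.generate_exponential_trajectory(
            0.1, 0.8, 0.06, 125.0, RETURN_T, noise_sd=0.05, seed=42
        )
        trial = expfit.ScoredTrial("p", "EO", 0.1, 1, 0, RETURN_T, y)
        spec = expfit.ExpModelSpec(
            phase="return", by_vision=False, by_freq=False, order_slope=False
        )
        fit = expfit.fit_exponential([trial], spec)
        # independent coarse grid search over (A, B, C)
        grid_best, grid_params = np.inf, None
        dt = RETURN_T - 125.0
        for A in np.linspace(-0.3, 0.5, 33):
            for B in np.linspace(0.3, 1.3, 41):
                for C in np.linspace(0.005, 0.3, 60):
                    r = y - (A + (B - A) * np.exp(-C * dt))
                    sse = float(r @ r)
                    if sse < grid_best:
                        grid_best, grid_params = sse, (A, B, C)
        assert fit.sse <= grid_best + 1e-12
        assert fit.A == pytest.approx(grid_params[0], abs=0.05)
        assert fit.b[("EO", 0.1)] == pytest.approx(grid_params[1], abs=0.05)
        assert fit.c[("EO", 0.1)] == pytest.approx(grid_params[2], abs=0.01)

    def test_bias_vanishes_as_noise_shrinks(self):
        errs = []
        for sd in (0.2, 0.02, 0.002):
            fits = []
            for rep in range(5):
                trials = make_trials(
                    lambda v, f, o: (0.0, 1.0, 0.05), noise_sd=sd, seed=1000 * rep
                )
                fits.append(expfit.fit_exponential(trials).c[("EO", 0.1)])
            errs.append(abs(np.mean(fits) - 0.05))
        assert errs[2] < errs[0]
        assert errs[2] < 1e-3

    def test_nonpositive_c_is_flagged_not_fatal(self):
        # strongly diverging trajectories: C < 0 in truth
        trials = make_trials(lambda v, f, o: (0.0, 0.2, -0.08))
        fit = expfit.fit_exponential(trials)
        assert len(fit.nonpositive_c) == len(CONDITIONS)
        assert all(np.isnan(fit.tau[c]) for c in CONDITIONS)


class TestLagScore:
    def test_hand_computed_residuals(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.zeros(3)
        assert expfit.lag_score(obs, pred) == pytest.approx(2.0, abs=1e-12)

    def test_zero_residuals_convention(self):
        y = np.linspace(0, 1, 10)
        assert expfit.lag_score(y, y) == 0.0

    @pytest.mark.parametrize("k", [0.5, 3.0, 1e-6, 1e6])
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(7)
        resid = rng.normal(size=40)
        base = expfit.lag_score(resid, np.zeros(40))
        scaled = expfit.lag_score(k * resid, np.zeros(40))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_slow_return_gives_positive_lag(self):
        t = RETURN_T
        pred = expfit.predict(0.0, 0.5, 0.05, 125.0, t)
        obs = expfit.predict(0.0, 0.5, 0.03, 125.0, t)  # slower return
        assert expfit.lag_score(obs, pred) > 0

    def test_too_short_window_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            expfit.lag_score(np.array([1.0]), np.array([0.5]))


def test_averaged_lag_is_mean_over_frequencies():
    trials = make_trials(lambda v, f, o: (0.0, 1.0, 0.05), noise_sd=0.05, seed=3)
    fit = expfit.fit_exponential(trials)
    table = expfit.lag_scores(fit, trials)
    avg = expfit.averaged_lag(table)
    assert len(avg) == 4  # two participants x two visions
    for _, row in avg.iterrows():
        sel = (table.participant_id == row.participant_id) & (
            table.vision == row.vision
        )
        assert row.lag == pytest.approx(table.loc[sel, "lag"].mean(), abs=1e-12)
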