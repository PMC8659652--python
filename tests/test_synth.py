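"""Synthetic generators: determinism, physics, schedules, cohort design."""

import numpy as np
import pytest
from scipy import signal

from swayspec import synth
from conftest import ANALYSIS_FREQS, make_surrogate_schedule


class TestExponentialTrajectory:
    def test_boundary_value_is_B(self):
        y = synth.generate_exponential_trajectory(0.2, 1.5, 0.07, 10.0, np.array([10.0]))
        assert y[0] == 1.5

    def test_e_inverse_point(self):
        y = synth.generate_exponential_trajectory(
            0.0, 1.0, 0.05, 0.0, np.array([20.0])
        )
        assert y[0] == pytest.approx(0.3679, abs=5e-5)

    def test_degenerate_A_equals_B_is_constant(self):
        t = np.linspace(0, 100, 11)
        for C in (-1.0, 0.0, 0.3):
            assert np.allclose(
                synth.generate_exponential_trajectory(0.7, 0.7, C, 0.0, t), 0.7
            )

    def test_t_grid_before_t0_rejected(self):
        with pytest.raises(ValueError, match="t_grid"):
            synth.generate_exponential_trajectory(0, 1, 0.1, 5.0, np.array([4.0]))

    def test_noise_is_seeded(self):
        t = np.linspace(0, 50, 51)
        a = synth.generate_exponential_trajectory(0, 1, 0.1, 0, t, 0.2, seed=9)
        b = synth.generate_exponential_trajectory(0, 1, 0.1, 0, t, 0.2, seed=9)
        assert np.array_equal(a, b)


class TestSurrogate:
    def test_deterministic_under_fixed_seed(self):
        sch = make_surrogate_schedule(amplitude_jitter=1.0)
        a = synth.simulate_surrogate_trial(sch, seed=5)
        b = synth.simulate_surrogate_trial(sch, seed=5)
        assert np.array_equal(a.cop_ap, b.cop_ap)
        c = synth.simulate_surrogate_trial(sch, seed=6)
        assert not np.array_equal(a.cop_ap, c.cop_ap)

    def test_negative_power_spectrum_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            synth.SpectralSchedule.from_power(
                ANALYSIS_FREQS,
                -np.ones(ANALYSIS_FREQS.size),
                np.ones(ANALYSIS_FREQS.size),
            )

    def test_welch_spectrum_of_stationary_segment_matches_target(self):
        """Gaussian-mode surrogate: the baseline-phase Welch PSD matches
        the scheduled baseline spectrum within sampling error."""
        base_power = synth.default_baseline_psd(ANALYSIS_FREQS)
        sch = synth.SpectralSchedule.from_power(
            ANALYSIS_FREQS, base_power, base_power, amplitude_jitter=1.0,
            baseline_dur=180.0, perturb_dur=0.01, return_dur=0.01,
        )
        # average several realizations of the stationary process
        ratios = []
        for seed in range(8):
            tr = synth.simulate_surrogate_trial(sch, seed=seed)
            f, pxx = signal.welch(tr.cop_ap, fs=100.0, nperseg=2000)
            sel = (f >= 0.3) & (f <= 4.5)
            target = np.interp(f[sel], ANALYSIS_FREQS, base_power)
            ratios.append(pxx[sel] / target)
        mean_ratio = np.mean(ratios, axis=0)
        assert np.median(mean_ratio) == pytest.approx(1.0, abs=0.25)

    def test_white_target_yields_flat_estimate(self):
        flat = np.full(ANALYSIS_FREQS.size, 1.0)
        sch = synth.SpectralSchedule.from_power(
            ANALYSIS_FREQS, flat, flat, amplitude_jitter=1.0,
            baseline_dur=180.0, perturb_dur=0.01, return_dur=0.01,
        )
        pxxs = []
        for seed in range(6):
            tr = synth.simulate_surrogate_trial(sch, seed=30 + seed)
            f, pxx = signal.welch(tr.cop_ap, fs=100.0, nperseg=1000)
            pxxs.append(pxx)
        pxx = np.mean(pxxs, axis=0)
        sel = (f >= 0.3) & (f <= 4.5)
        db = 10 * np.log10(pxx[sel])
        assert np.ptp(db) < 3.0  # flat within sampling error, dB

    def test_identical_phase_targets_give_flat_score_schedule(self):
        base_db = 10 * np.log10(synth.default_baseline_psd(ANALYSIS_FREQS))
        sch = synth.SpectralSchedule(
            freqs=ANALYSIS_FREQS, baseline_db=base_db, perturb_db=base_db
        )
        # the spectro-temporal plan collapses: spectrum never changes
        t = np.linspace(0, 180, 1801)
        power_span = np.ptp(
            base_db[None, :] + sch.score(t)[:, None] * 0.0, axis=0
        )
        assert np.all(power_span == 0.0)


class TestPendulum:
    def test_no_excitation_stays_at_equilibrium(self):
        p = synth.PendulumParams(torque_noise_sd=0.0, sensor_noise_sd=0.0)
        sch = synth.PhaseSchedule(platform_amplitude=0.0)
        tr = synth.simulate_pendulum_trial(p, sch, seed=0, initial_tilt=0.0)
        assert np.all(tr.cop_ap == 0.0)

    def test_deterministic_under_fixed_seed(self):
        p = synth.PendulumParams()
        sch = synth.PhaseSchedule()
        a = synth.simulate_pendulum_trial(p, sch, seed=4)
        b = synth.simulate_pendulum_trial(p, sch, seed=4)
        assert np.array_equal(a.cop_ap, b.cop_ap)

    def test_default_parameters_are_stable_and_mm_scale(self):
        tr = synth.simulate_pendulum_trial(
            synth.PendulumParams(), synth.PhaseSchedule(), seed=2
        )
        rms = tr.cop_ap[: 6000].std()
        assert 0.5 < rms < 20.0  # baseline sway a few mm

    def test_unstable_gains_raise_named_error(self):
        p = synth.PendulumParams(kp=200.0, kd=0.0)  # insufficient stiffness
        with pytest.raises(synth.UnstableSimulationError, match="tilt"):
            synth.simulate_pendulum_trial(p, synth.PhaseSchedule(), seed=0)

    def test_higher_loop_gain_raises_psd_peak_frequency(self):
        sch = synth.PhaseSchedule(
            baseline_dur=200.0, perturb_dur=0.01, return_dur=0.01,
            platform_amplitude=0.0,
        )
        peaks = []
        for wscale in (1.0, 1.4):
            p0 = synth.PendulumParams()
            p = synth.PendulumParams(
                w_vis=p0.w_vis * wscale,
                w_prop=p0.w_prop * wscale,
                w_vest=p0.w_vest * wscale,
            )
            tr = synth.simulate_pendulum_trial(p, sch, seed=17)
            f, pxx = signal.welch(tr.cop_ap, fs=100.0, nperseg=4096)
            sel = (f >= 0.3) & (f <= 5.0)
            peaks.append(f[sel][np.argmax(pxx[sel])])
        assert peaks[1] > peaks[0]


class TestCohort:
    def test_single_participant_design(self):
        trials = synth.generate_cohort(synth.CohortSpec(n_participants=1, seed=1))
        assert len(trials) == 6
        assert sorted(t.trial_order for t in trials) == [1, 2, 3, 4, 5, 6]
        assert {t.vision for t in trials} == {"EO", "EC"}
        assert {t.platform_freq for t in trials} == {0.1, 0.2, 0.4}

    def test_full_cohort_cardinality_and_cells(self, full_cohort):
        assert len(full_cohort) == 258
        keys = {t.key for t in full_cohort}
        assert len(keys) == 258  # one trial per design cell
        participants = {t.participant_id for t in full_cohort}
        assert len(participants) == 43

    def test_block_order_counterbalanced(self, full_cohort):
        first_block_vision = {}
        for t in full_cohort:
            if t.trial_order <= 3:
                first_block_vision.setdefault(t.participant_id, t.vision)
        n_eo_first = sum(1 for v in first_block_vision.values() if v == "EO")
        assert abs(n_eo_first - 43 / 2) <= 0.5  # half EO-first (odd cohort)

    def test_frequency_orders_vary_across_participants(self, full_cohort):
        orders = {}
        for t in full_cohort:
            if t.trial_order <= 3:
                orders.setdefault(t.participant_id, {})[t.trial_order] = t.platform_freq
        sequences = {tuple(v[i] for i in (1, 2, 3)) for v in orders.values()}
        assert len(sequences) == 6  # all permutations occur

    def test_determinism_bit_identical(self):
        spec_a = synth.CohortSpec(n_participants=2, seed=42)
        spec_b = synth.CohortSpec(n_participants=2, seed=42)
        for ta, tb in zip(synth.generate_cohort(spec_a), synth.generate_cohort(spec_b)):
            assert ta.key == tb.key
            assert np.array_equal(ta.cop_ap, tb.cop_ap)

    def test_trial_seeds_logged(self, full_cohort):
        assert all("seed" in t.meta for t in full_cohort)
        assert all(t.meta["cohort_seed"] == 7 for t in full_cohort)

    def test_pendulum_mode_produces_valid_trials(self):
        spec = synth.CohortSpec(n_participants=1, seed=5, mode="pendulum")
        trials = synth.generate_cohort(spec)
        assert len(trials) == 6
        for t in trials:
            assert t.cop_ap.size == 18000
            assert np.all(np.isfinite(t.cop_ap))
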