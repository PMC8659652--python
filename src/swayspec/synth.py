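"""Synthetic center-of-pressure generators.

Three generators produce CoP trials with the statistical structure the
analysis pipeline assumes, at increasing levels of mechanism:

* :func:`generate_exponential_trajectory` — the bare exponential
  relaxation ``y = A + (B - A) exp(-C (t - t0))`` plus white noise, for
  exercising the curve fitter in isolation.
* :func:`simulate_surrogate_trial` — filtered-noise CoP whose short-term
  spectrum follows a prescribed spectro-temporal schedule: a baseline
  spectrum during the first 60 s, a perturbation spectrum during the
  second, and an exponential relaxation back to baseline during the
  third.  This gives direct control of exactly the structure the
  sliding-PSD / PCA stages must recover.
* :func:`simulate_pendulum_trial` — a mechanistic single-inverted-
  pendulum stance model: body sway with one degree of freedom (the ankle
  angle), stabilized by a PID controller acting on a weighted sum of
  visual, proprioceptive and vestibular sway estimates fed back with a
  neural delay.  The loop gain (sensory weights x proportional gain)
  shapes the sway spectrum: near-critical gain gives a roughly flat CoP
  spectrum, higher gain raises a resonant peak near 1 Hz whose frequency
  grows with the gain.

:func:`generate_cohort` assembles full factorial synthetic cohorts
(participants x {EO, EC} x {0.1, 0.2, 0.4 Hz}) with counterbalanced
block order, programming a vision-by-MSS interaction on the perturbation
spectrum and an MSS-dependent return-phase relaxation rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trial import CoPTrial, DEFAULT_FS_HZ

GRAVITY = 9.81  # m/s^2

PLATFORM_FREQS = (0.1, 0.2, 0.4)

#: All 6 orderings of the three platform frequencies, cycled across
#: participants for counterbalancing.
_FREQ_PERMS = (
    (0.1, 0.2, 0.4),
    (0.1, 0.4, 0.2),
    (0.2, 0.1, 0.4),
    (0.2, 0.4, 0.1),
    (0.4, 0.1, 0.2),
    (0.4, 0.2, 0.1),
)


class UnstableSimulationError(RuntimeError):
    """The closed-loop pendulum diverged (named quantity exceeded bounds)."""


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class PendulumParams:
    """Plant and controller parameters of the stance model.

    The plant is the linearized (small-angle) inverted pendulum
    ``I theta'' = m g h theta + torque``.  The controller produces
    corrective torque ``-(kp s + ki int(s) + kd s')`` from the delayed
    weighted sway estimate
    ``s = w_vis * theta + w_prop * (theta - theta_platform) + w_vest * theta``.
    The visual and vestibular channels sense body-in-space angle; the
    proprioceptive channel senses the ankle angle relative to the
    platform, which is how a platform tilt perturbs the loop.

    Defaults give a comfortably stable loop with unit total weight and a
    baseline sway of a few mm RMS when noise-driven.
    """

    body_mass: float = 70.0  # kg
    com_height: float = 0.9  # m, ankle to center of mass
    moment_of_inertia: float | None = None  # kg m^2; default m h^2
    kp: float = 1000.0  # N m / rad
    ki: float = 15.0  # N m / (rad s)
    kd: float = 320.0  # N m s / rad
    w_vis: float = 0.35
    w_prop: float = 0.45
    w_vest: float = 0.20
    feedback_delay: float = 0.10  # s
    torque_noise_sd: float = 2.0  # N m per sample
    sensor_noise_sd: float = 0.0  # rad per sample, added to s

    def __post_init__(self) -> None:
        if self.body_mass <= 0 or self.com_height <= 0:
            raise ValueError("body_mass and com_height must be positive")
        if self.moment_of_inertia is None:
            object.__setattr__(
                self, "moment_of_inertia", self.body_mass * self.com_height**2
            )
        if self.moment_of_inertia <= 0:
            raise ValueError("moment_of_inertia must be positive")
        for w in (self.w_vis, self.w_prop, self.w_vest):
            if w < 0:
                raise ValueError("sensory weights must be non-negative")
        if self.feedback_delay < 0:
            raise ValueError("feedback_delay must be non-negative")

    @property
    def total_weight(self) -> float:
        return self.w_vis + self.w_prop + self.w_vest

    def gain_vector(self) -> np.ndarray:
        return np.array(
            [self.kp, self.ki, self.kd, self.w_vis, self.w_prop, self.w_vest]
        )


@dataclass(frozen=True)
class PhaseSchedule:
    """Trial phase structure and platform motion.

    60 s static baseline, 60 s sinusoidal platform tilt (amplitude is the
    half-range, i.e. 4 means +/-4 degrees), 60 s static return.
    ``weight_transition_tau`` is the time constant with which the
    controller parameters relax toward their new targets after each phase
    boundary; it is the mechanism that produces exponential adaptation
    and de-adaptation dynamics in the sway spectrum.
    """

    baseline_dur: float = 60.0  # s
    perturb_dur: float = 60.0  # s
    return_dur: float = 60.0  # s
    platform_amplitude: float = 4.0  # deg, half-range
    platform_freq: float = 0.2  # Hz
    weight_transition_tau: float = 20.0  # s

    def __post_init__(self) -> None:
        if min(self.baseline_dur, self.perturb_dur, self.return_dur) <= 0:
            raise ValueError("phase durations must be positive")
        if self.platform_amplitude < 0:
            raise ValueError("platform amplitude must be non-negative")
        if self.platform_freq <= 0:
            raise ValueError("platform frequency must be positive")
        if self.weight_transition_tau < 0:
            raise ValueError("weight_transition_tau must be non-negative")

    @property
    def total_dur(self) -> float:
        return self.baseline_dur + self.perturb_dur + self.return_dur

    def platform_angle(self, t: np.ndarray) -> np.ndarray:
        """Platform tilt in radians at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        t1 = self.baseline_dur
        t2 = t1 + self.perturb_dur
        amp = math.radians(self.platform_amplitude)
        ang = np.zeros_like(t)
        during = (t >= t1) & (t < t2)
        ang[during] = amp * np.sin(2 * np.pi * self.platform_freq * (t[during] - t1))
        return ang


@dataclass
class SpectralSchedule:
    """Per-phase target spectra and return-phase relaxation for surrogates.

    The short-term spectrum (in dB) tracks
    ``S(t, f) = baseline_db(f) + score(t) * (perturb_db(f) - baseline_db(f))``
    where ``score`` is 0 during the baseline phase, relaxes from
    ``adapt_b`` toward 1 with rate ``adapt_rate`` during the perturbation
    phase, and decays as ``return_start * exp(-return_rate * (t - 120))``
    during the return phase.  ``amplitude_jitter`` in [0, 1] blends
    deterministic per-bin amplitudes (0: the window periodogram equals the
    target exactly) with Rayleigh-distributed ones (1: stationary-
    Gaussian-like surrogate whose Welch spectrum matches the target in
    expectation).
    """

    freqs: np.ndarray
    baseline_db: np.ndarray
    perturb_db: np.ndarray
    return_rate: float = 0.05  # 1/s
    return_start: float = 1.0  # score at the start of the return phase
    adapt_b: float = 1.0  # score at perturbation onset (1 = no adaptation)
    adapt_rate: float = 0.0  # 1/s
    baseline_dur: float = 60.0
    perturb_dur: float = 60.0
    return_dur: float = 60.0
    fs: float = DEFAULT_FS_HZ
    amplitude_jitter: float = 0.0
    level_noise_db: float = 0.0  # SD of slow coherent level modulation, dB
    level_noise_tau: float = 15.0  # s, correlation time of that modulation

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.baseline_db = np.asarray(self.baseline_db, dtype=float)
        self.perturb_db = np.asarray(self.perturb_db, dtype=float)
        if not (self.freqs.shape == self.baseline_db.shape == self.perturb_db.shape):
            raise ValueError("freqs, baseline_db and perturb_db must align")
        if self.return_rate < 0:
            raise ValueError("return_rate must be non-negative")
        if not 0.0 <= self.amplitude_jitter <= 1.0:
            raise ValueError("amplitude_jitter must lie in [0, 1]")

    @classmethod
    def from_power(
        cls, freqs, baseline_power, perturb_power, **kwargs
    ) -> "SpectralSchedule":
        """Build a schedule from linear-power target spectra (mm^2/Hz)."""
        baseline_power = np.asarray(baseline_power, dtype=float)
        perturb_power = np.asarray(perturb_power, dtype=float)
        if np.any(baseline_power < 0) or np.any(perturb_power < 0):
            raise ValueError("target spectra must be non-negative")
        tiny = np.finfo(float).tiny
        return cls(
            freqs=freqs,
            baseline_db=10 * np.log10(np.maximum(baseline_power, tiny)),
            perturb_db=10 * np.log10(np.maximum(perturb_power, tiny)),
            **kwargs,
        )

    @property
    def total_dur(self) -> float:
        return self.baseline_dur + self.perturb_dur + self.return_dur

    def score(self, t: np.ndarray) -> np.ndarray:
        """Programmed spectral-interpolation score at times ``t``."""
        t = np.asarray(t, dtype=float)
        t1 = self.baseline_dur
        t2 = t1 + self.perturb_dur
        s = np.zeros_like(t)
        during = (t >= t1) & (t < t2)
        if self.adapt_rate > 0:
            s[during] = 1.0 + (self.adapt_b - 1.0) * np.exp(
                -self.adapt_rate * (t[during] - t1)
            )
        else:
            s[during] = 1.0
        after = t >= t2
        s[after] = self.return_start * np.exp(-self.return_rate * (t[after] - t2))
        return s


@dataclass
class CohortSpec:
    """Design and effect structure of a synthetic cohort.

    The cohort is the full factorial design: every participant in
    {EO, EC} x {0.1, 0.2, 0.4 Hz}, block order counterbalanced (half the
    participants do EO first), frequency order within blocks cycled
    through all six permutations across participants.

    ``ec_balance_shift_per_mss`` (dB per MSS unit, normally negative)
    shifts the high-frequency part of the eyes-closed perturbation
    spectrum with the participant's MSS score, programming a
    vision-by-MSS interaction on the downstream spectral balance.
    ``lag_slope_per_mss`` (lag-score units per MSS unit, normally
    negative) scales the eyes-closed return-phase relaxation rate with
    MSS — a negative value makes high-MSS participants return faster,
    which the lag score downstream reads as a negative EC lag-vs-MSS
    slope.  The magnitude mapping from lag units to rate modulation is
    approximate (the realized lag also depends on the noise level); the
    programmed sign and ordering are exact.
    """

    n_participants: int = 43
    mss_low: int = 0
    mss_high: int = 14  # inclusive; scores drawn uniformly on integers
    ec_balance_shift_per_mss: float = -0.3  # dB per MSS unit
    lag_slope_per_mss: float = -0.05  # lag units per MSS unit (EC)
    lag_rate_scale: float = 0.5  # rate-modulation per lag unit (see docs)
    participant_rate_sd: float = 0.15  # SD of log per-participant rate offset
    base_params: PendulumParams = field(default_factory=PendulumParams)
    mode: str = "surrogate"  # or "pendulum"
    amplitude_jitter: float = 1.0
    level_noise_db: float = 0.0  # slow coherent spectrum-level wander, dB SD
    return_rate_eo: float = 0.050  # 1/s
    return_rate_ec_delta: float = -0.021  # 1/s, EC minus EO
    return_start_eo: float = 0.47  # score level entering the return fit
    return_start_ec: float = 0.65
    adapt_b: float = 1.18
    adapt_rate: float = 0.065  # 1/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.mode not in ("surrogate", "pendulum"):
            raise ValueError("mode must be 'surrogate' or 'pendulum'")


# ---------------------------------------------------------------------------
# elementary generators


def generate_exponential_trajectory(
    A: float,
    B: float,
    C: float,
    t0: float,
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Exponential relaxation ``A + (B - A) exp(-C (t - t0))`` plus noise.

    ``t_grid`` must not precede ``t0``.  With ``A == B`` the output is
    the constant ``A`` (plus noise) for any rate.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < t0 - 1e-12):
        raise ValueError("t_grid must be >= t0")
    y = A + (B - A) * np.exp(-C * (t_grid - t0))
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t_grid.shape)
    return y


def default_baseline_psd(
    freqs: np.ndarray, rms_mm: float = 3.0, corner_hz: float = 0.3, slope: float = 2.0
) -> np.ndarray:
    """Low-pass stabilogram-like baseline PSD (mm^2/Hz) on ``freqs``.

    ``P(f) = p0 / (1 + (f / corner)^slope)`` scaled so the band-limited
    RMS equals ``rms_mm``; quiet-stance CoP power is concentrated well
    below 1 Hz and falls by tens of dB toward 5 Hz.
    """
    freqs = np.asarray(freqs, dtype=float)
    shape = 1.0 / (1.0 + (freqs / corner_hz) ** slope)
    df = float(np.median(np.diff(freqs))) if freqs.size > 1 else 1.0
    p0 = rms_mm**2 / float(np.sum(shape) * df)
    return p0 * shape


def _gauss_bump(freqs: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((freqs - center) / width) ** 2)


def perturbation_delta_db(
    freqs: np.ndarray,
    platform_freq: float,
    high_db: float = 20.0,
    low_db: float = 14.0,
    platform_db: float = 12.0,
    harmonic_db: float = 6.0,
) -> np.ndarray:
    """dB increase of the perturbation-phase spectrum over baseline.

    A broad high-frequency bump (near 1.5 Hz) and a smaller low-frequency
    bump (near 0.7 Hz) model the raised feedback gain during platform
    motion; narrow peaks at the platform frequency and its first
    harmonic model the mechanically driven sway component.
    """
    freqs = np.asarray(freqs, dtype=float)
    delta = high_db * _gauss_bump(freqs, 1.5, 0.55)
    delta += low_db * _gauss_bump(freqs, 0.7, 0.25)
    df = float(np.median(np.diff(freqs))) if freqs.size > 1 else 0.1
    for f0, amp in ((platform_freq, platform_db), (2 * platform_freq, harmonic_db)):
        near = np.abs(freqs - f0) < df / 2
        delta[near] += amp
    return delta


def simulate_surrogate_trial(
    schedule: SpectralSchedule,
    seed: int | None = None,
    participant_id: str = "sim",
    vision: str = "EO",
    platform_freq: float = 0.2,
    trial_order: int = 1,
    mss: float = 0.0,
) -> CoPTrial:
    """Random-phase surrogate CoP with a prescribed spectro-temporal plan.

    The signal is a sum of sinusoids on the schedule's frequency grid
    with per-trial random phases and slowly time-varying amplitudes
    ``sqrt(2 S(t, f) df)``, so a rectangular-window periodogram whose
    bins coincide with the grid reads back the scheduled spectrum
    (exactly, for ``amplitude_jitter = 0`` and a locally constant
    schedule).
    """
    rng = np.random.default_rng(seed)
    n = round(schedule.total_dur * schedule.fs)
    t = np.arange(n) / schedule.fs
    score = schedule.score(t)  # (n,)

    if schedule.amplitude_jitter > 0:
        # Gaussian-process mode: synthesize on a fine frequency grid
        # (several independent Rayleigh components per analysis bin), so
        # short-term periodograms fluctuate realistically around the
        # scheduled spectrum while matching it in expectation.
        df = 0.01
        lo = max(df, float(schedule.freqs.min()) - 0.04)
        hi = float(schedule.freqs.max()) + 0.04
        freqs = np.arange(lo, hi + 1e-9, df)
        baseline_db = np.interp(freqs, schedule.freqs, schedule.baseline_db)
        delta_db = np.interp(
            freqs, schedule.freqs, schedule.perturb_db - schedule.baseline_db
        )
        j = schedule.amplitude_jitter
        u = rng.exponential(1.0, size=freqs.size)
        factor = np.sqrt(1.0 - j + j * u)
    else:
        # exact mode: deterministic amplitudes on the schedule's own grid;
        # a rectangular-window periodogram with matching bins reads the
        # scheduled spectrum back exactly in the stationary phases.
        freqs = schedule.freqs
        df = float(np.median(np.diff(freqs))) if freqs.size > 1 else 1.0
        baseline_db = schedule.baseline_db
        delta_db = schedule.perturb_db - schedule.baseline_db
        factor = np.ones(freqs.size)

    # S_db(t, f) = baseline + score(t) * delta; power = 10^(S_db/10)
    power = 10.0 ** (
        (baseline_db[None, :] + score[:, None] * delta_db[None, :]) / 10.0
    )  # (n, m)
    amps = np.sqrt(2.0 * power * df) * factor[None, :]
    if schedule.level_noise_db > 0:
        # slow coherent gain fluctuation of the whole spectrum (OU in dB):
        # real sway amplitude wanders on a 10-20 s time scale, moving all
        # frequency bins together.
        tau = schedule.level_noise_tau
        dt = 1.0 / schedule.fs
        rho = math.exp(-dt / tau)
        innov = rng.normal(0.0, 1.0, size=n) * math.sqrt(1.0 - rho * rho)
        g = np.empty(n)
        acc = rng.normal(0.0, 1.0)  # stationary start
        for k in range(n):
            acc = rho * acc + innov[k]
            g[k] = acc
        amps = amps * 10.0 ** (schedule.level_noise_db * g[:, None] / 20.0)
    phases = rng.uniform(0.0, 2 * np.pi, size=freqs.size)
    x = np.einsum(
        "nm,nm->n", amps, np.cos(2 * np.pi * t[:, None] * freqs[None, :] + phases[None, :])
    )
    return CoPTrial(
        participant_id=participant_id,
        vision=vision,
        platform_freq=platform_freq,
        trial_order=trial_order,
        mss=mss,
        fs=schedule.fs,
        cop_ap=x,
        meta={"generator": "surrogate", "seed": seed},
    )


# ---------------------------------------------------------------------------
# mechanistic pendulum simulator


def simulate_pendulum_trial(
    params: PendulumParams,
    schedule: PhaseSchedule,
    seed: int | None = None,
    perturb_params: PendulumParams | None = None,
    return_params: PendulumParams | None = None,
    fs: float = DEFAULT_FS_HZ,
    initial_tilt: float = 0.0,
    participant_id: str = "sim",
    vision: str = "EO",
    trial_order: int = 1,
    mss: float = 0.0,
    max_tilt: float = 0.6,
) -> CoPTrial:
    """Closed-loop inverted-pendulum stance simulation.

    The linearized plant ``I theta'' = m g h theta + u`` is advanced with
    an exact zero-order-hold update at the sampling interval; the control
    torque acts on the weighted sensory sway estimate delayed by the
    neural feedback delay.  The CoP is the total ankle torque divided by
    ``m g``, in mm.  Controller parameters switch targets at the phase
    boundaries (``perturb_params`` during platform motion,
    ``return_params`` — default: the baseline ``params`` — afterwards)
    and relax toward each target exponentially with the schedule's
    ``weight_transition_tau``, which is what produces exponential
    spectral adaptation and de-adaptation.

    Raises
    ------
    UnstableSimulationError
        If the body tilt exceeds ``max_tilt`` radians (the loop diverged).
    """
    if perturb_params is None:
        perturb_params = params
    if return_params is None:
        return_params = params
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs
    n = round(schedule.total_dur * fs)
    m, h = params.body_mass, params.com_height
    inertia = params.moment_of_inertia
    a = m * GRAVITY * h / inertia  # 1/s^2, inverted-pendulum instability rate
    sq = math.sqrt(a)
    ch, sh = math.cosh(sq * dt), math.sinh(sq * dt) / sq
    drive = (ch - 1.0) / a  # ZOH position response to unit torque/I

    nd = round(params.feedback_delay * fs)
    t1, t2 = schedule.baseline_dur, schedule.baseline_dur + schedule.perturb_dur
    tau = schedule.weight_transition_tau
    relax = math.exp(-dt / tau) if tau > 0 else 0.0

    g_base = params.gain_vector()
    g_pert = perturb_params.gain_vector()
    g_ret = return_params.gain_vector()
    gains = g_base.copy()

    times = np.arange(n) * dt
    theta_p = schedule.platform_angle(times)
    torque_noise = (
        rng.normal(0.0, params.torque_noise_sd, size=n)
        if params.torque_noise_sd > 0
        else np.zeros(n)
    )
    sensor_noise = (
        rng.normal(0.0, params.sensor_noise_sd, size=n)
        if params.sensor_noise_sd > 0
        else np.zeros(n)
    )

    s_hist = np.zeros(n)
    cop = np.empty(n)
    theta, omega = float(initial_tilt), 0.0
    s_int = 0.0
    s_d_prev = 0.0
    for k in range(n):
        t = times[k]
        if t >= t2:
            target = g_ret
        elif t >= t1:
            target = g_pert
        else:
            target = g_base
        gains = target + (gains - target) * relax
        kp, ki, kd, wv, wp, wvest = gains

        s = wv * theta + wp * (theta - theta_p[k]) + wvest * theta + sensor_noise[k]
        s_hist[k] = s
        s_d = s_hist[k - nd] if k >= nd else 0.0
        s_int += s_d * dt
        s_dot = (s_d - s_d_prev) / dt
        s_d_prev = s_d

        u = -(kp * s_d + ki * s_int + kd * s_dot) + torque_noise[k]
        cop[k] = u / (m * GRAVITY) * 1000.0  # mm

        b = u / inertia
        theta_new = ch * theta + sh * omega + drive * b
        omega = a * sh * theta + ch * omega + sh * b
        theta = theta_new
        if abs(theta) > max_tilt:
            raise UnstableSimulationError(
                f"body tilt diverged: |theta| = {abs(theta):.3f} rad > "
                f"{max_tilt:g} rad at t = {t:.2f} s (check gains/weights)"
            )
    return CoPTrial(
        participant_id=participant_id,
        vision=vision,
        platform_freq=schedule.platform_freq,
        trial_order=trial_order,
        mss=mss,
        fs=fs,
        cop_ap=cop,
        meta={"generator": "pendulum", "seed": seed},
    )


# ---------------------------------------------------------------------------
# cohort generation


def _trial_seed(spec: CohortSpec, p_idx: int, vision: str, freq: float) -> int:
    """Stable per-trial seed derived from (cohort seed, cell)."""
    vis_idx = 0 if vision == "EO" else 1
    freq_idx = PLATFORM_FREQS.index(freq)
    ss = np.random.SeedSequence(
        entropy=spec.seed, spawn_key=(p_idx, vis_idx, freq_idx)
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _surrogate_cohort_trial(
    spec: CohortSpec,
    freqs: np.ndarray,
    participant_id: str,
    p_idx: int,
    vision: str,
    freq: float,
    order: int,
    mss: int,
    rate_offset: float,
) -> CoPTrial:
    baseline = default_baseline_psd(freqs)
    baseline_db = 10 * np.log10(baseline)
    if vision == "EO":
        delta = perturbation_delta_db(freqs, freq)
        rate = spec.return_rate_eo
        start = spec.return_start_eo
    else:
        high = 17.0 + spec.ec_balance_shift_per_mss * mss
        delta = perturbation_delta_db(freqs, freq, high_db=high, low_db=16.0)
        rate = spec.return_rate_eo + spec.return_rate_ec_delta
        # negative lag slope -> faster relaxation at high MSS
        rate *= math.exp(-spec.lag_slope_per_mss * mss * spec.lag_rate_scale)
        start = spec.return_start_ec
    rate *= math.exp(rate_offset)
    schedule = SpectralSchedule(
        freqs=freqs,
        baseline_db=baseline_db,
        perturb_db=baseline_db + delta,
        return_rate=rate,
        return_start=start,
        adapt_b=spec.adapt_b,
        adapt_rate=spec.adapt_rate,
        amplitude_jitter=spec.amplitude_jitter,
        level_noise_db=spec.level_noise_db,
    )
    seed = _trial_seed(spec, p_idx, vision, freq)
    trial = simulate_surrogate_trial(
        schedule,
        seed=seed,
        participant_id=participant_id,
        vision=vision,
        platform_freq=freq,
        trial_order=order,
        mss=mss,
    )
    trial.meta.update({"cohort_seed": spec.seed, "return_rate": rate})
    return trial


def _pendulum_cohort_trial(
    spec: CohortSpec,
    participant_id: str,
    p_idx: int,
    vision: str,
    freq: float,
    order: int,
    mss: int,
    rate_offset: float,
) -> CoPTrial:
    base = spec.base_params
    if vision == "EC":
        # eyes closed: visual weight redistributed to the other channels
        wv = 0.0
        wp = base.w_prop + 0.6 * base.w_vis
        wvest = base.w_vest + 0.4 * base.w_vis
        base = replace(base, w_vis=wv, w_prop=wp, w_vest=wvest)
        gain_boost = 1.30 + 0.01 * spec.ec_balance_shift_per_mss * mss
        tau = 35.0
        tau *= math.exp(spec.lag_slope_per_mss * mss * spec.lag_rate_scale)
    else:
        gain_boost = 1.25
        tau = 20.0
    tau *= math.exp(-rate_offset)
    perturb = replace(base, kp=base.kp * gain_boost, kd=base.kd * 1.05)
    schedule = PhaseSchedule(platform_freq=freq, weight_transition_tau=tau)
    seed = _trial_seed(spec, p_idx, vision, freq)
    trial = simulate_pendulum_trial(
        base,
        schedule,
        seed=seed,
        perturb_params=perturb,
        participant_id=participant_id,
        vision=vision,
        trial_order=order,
        mss=mss,
    )
    trial.meta.update({"cohort_seed": spec.seed, "transition_tau": tau})
    return trial


def generate_cohort(spec: CohortSpec) -> list[CoPTrial]:
    """Generate the full factorial synthetic cohort.

    Returns one trial per participant x vision x platform frequency
    (43 x 2 x 3 = 258 for the defaults).  Half the participants run the
    EO block first; within each block the frequency order cycles through
    all six permutations across participants.  Every trial's seed is
    derived deterministically from ``(spec.seed, participant, vision,
    frequency)``, so any trial is reproducible in isolation; the seed is
    recorded in the trial metadata.
    """
    master = np.random.default_rng(np.random.SeedSequence(spec.seed))
    freqs = np.round(np.arange(0.1, 5.0 + 1e-9, 0.1), 10)
    trials: list[CoPTrial] = []
    for p_idx in range(spec.n_participants):
        pid = f"P{p_idx + 1:02d}"
        mss = int(master.integers(spec.mss_low, spec.mss_high + 1))
        rate_offset = (
            float(master.normal(0.0, spec.participant_rate_sd))
            if spec.participant_rate_sd > 0
            else 0.0
        )
        eo_first = p_idx % 2 == 0
        blocks = ("EO", "EC") if eo_first else ("EC", "EO")
        for b_idx, vision in enumerate(blocks):
            perm = _FREQ_PERMS[(p_idx + 3 * b_idx) % 6]
            for f_idx, freq in enumerate(perm):
                order = 3 * b_idx + f_idx + 1
                if spec.mode == "surrogate":
                    trial = _surrogate_cohort_trial(
                        spec, freqs, pid, p_idx, vision, freq, order, mss, rate_offset
                    )
                else:
                    trial = _pendulum_cohort_trial(
                        spec, pid, p_idx, vision, freq, order, mss, rate_offset
                    )
                trials.append(trial)
    return trials
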