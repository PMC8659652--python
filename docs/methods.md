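# Methods

## The analysis

`swayspec` quantifies how the frequency content of postural sway adapts
to, and recovers from, a support-surface perturbation. The input is the
antero-posterior center-of-pressure (CoP) trace of a 180-s trial sampled
at 100 Hz: 60 s quiet stance (baseline), 60 s sinusoidal platform tilt of
±4° at 0.1, 0.2 or 0.4 Hz (perturbation), 60 s quiet stance (return).

The chain is:

1. **Sliding-window PSD.** One-sided power spectral density (power per
   Hz) on a 10-s window placed every 10 ms, per-window mean removed,
   rectangular taper. A 10-s window at 100 Hz has a native bin spacing
   of exactly 0.1 Hz, so the 50 analysis bins (0.1–5.0 Hz) are plain
   periodogram ordinates. Values are expressed as 10·log10 (dB) with a
   −200 dB floor guarding log of zero. Window centers run from 5 s to
   175 s; windows that straddle a phase boundary mix two regimes and are
   excluded from the curve fits below.
2. **Per-trial PCA.** The windows-by-bins dB matrix is column-centered
   and decomposed (covariance PCA via SVD; no per-bin variance scaling,
   since all bins share dB units). The first component's eigenvector is
   the spectral profile of the perturbation-induced change; its score is
   the temporal profile. The sign is fixed so the mean score over
   windows centered in 90–115 s exceeds the mean over 30–55 s
   (perturbation-positive); exact ties fall back to making the first
   nonzero loading positive.
3. **Score normalization.** Affine map making the score mean exactly 0
   over 30–55 s and exactly 1 over 90–115 s, so trials are comparable.
   A trial whose two window means coincide (no spectral change) is
   rejected with a dedicated error.
4. **Spectral balance.** Mean PC1 loading over 1.2–3.0 Hz minus the mean
   over 0.5–1.2 Hz. The split sits at the typical peak of the mean
   eigenvector; the boundary bin (1.2 Hz) belongs to the high band by
   default (`boundary_to_high=False` flips it).
5. **Exponential fits.** Within the perturbation phase (t0 = 65 s, fit
   window 65–115 s) and the return phase (t0 = 125 s, window 125–165 s),
   the normalized score is modeled as y = A + (B − A)·exp(−C(t − t0)).
   All trials of a phase are fitted jointly: A is shared; B and C carry
   a reference value (eyes open, lowest frequency, centered trial order)
   plus an additive eyes-closed contrast, contrasts per non-reference
   frequency, and a linear centered-order slope. τ = 1/C is the time
   constant. A baseline-phase fit (t0 = 5 s, window 5–55 s) is available
   through `ExpModelSpec(phase="baseline")`.
6. **Lag score.** Per trial, mean of (observed − predicted) over the
   return-phase fit window divided by the sample SD (n−1) of that
   residual; all-zero residuals give 0 by convention. Positive = slower
   than the group curve. For the group model the lag is averaged over
   the three platform frequencies within each participant × vision cell.
7. **Group models.** Spectral balance: OLS `balance ~ vision + frequency
   + mss + vision:mss`, sum-to-zero contrasts, type-II F tests, planned
   contrast 0.4 Hz vs the mean of 0.1/0.2 Hz; on a complete 258-trial
   cohort the residual df is 252. Lag: `lag ~ vision * mss` with a
   participant random intercept (REML), per-vision MSS slopes with
   normal-approximation 95% CIs; singular random-effect fits fall back
   to OLS with a warning. MSS enters uncentered so predictions at MSS 0
   and 14 are direct.

## Numerical choices

- **Taper.** Rectangular by default so the 50-bin mapping is exact; a
  Hann taper is available (`taper="hann"`) where leakage matters more
  than bin exactness. Mean removal is per window in both cases.
- **Optimizer.** Derivative-based least squares (Levenberg–Marquardt)
  with an analytic Jacobian, multi-started from C ∈ {0.01, 0.05, 0.2,
  −0.05, −0.2}; the lowest objective wins, so the fit is deterministic
  given the data. The negative starts let genuinely diverging data reach
  C < 0, which is flagged (`nonpositive_c`, τ = NaN) but still returned.
  Confidence intervals use t quantiles on the asymptotic standard errors
  from the local quadratic approximation at the optimum.
- **Subsampling.** Scores are fitted at 1 sample/s (configurable down to
  the full 100/s); with τ in the 20–35 s range the 10-ms score grid is
  massively oversampled and, for noise-free data, the estimate is
  invariant to uniform subsampling (tested).
- **Spectrogram step.** The default 10-ms step reproduces the
  full-resolution score; the test suite and cohort-level examples use a
  0.1-s step, which leaves every window-count, normalization and fitting
  property unchanged (the score is merely sampled more coarsely).
- **Degenerate inputs.** Constant spectrograms raise
  `DegenerateSpectrogramError`; trials failing anywhere in the chain are
  quarantined by `analyze_cohort` with the failing stage's message, and
  the run aborts only if more than `max_fail_fraction` of trials fail.

## The synthetic generators

No raw study data ships with the package; three generators provide
signals with known ground truth.

**Exponential trajectories** (`generate_exponential_trajectory`) exercise
the fitter alone: y = A + (B − A)exp(−C(t − t0)) plus i.i.d. Gaussian
noise.

**Spectral surrogates** (`simulate_surrogate_trial`) directly control the
spectro-temporal structure the pipeline must recover. The short-term
spectrum in dB is `baseline + score(t) · (perturbation − baseline)`,
where the programmed score is 0 in the baseline phase, relaxes from
`adapt_b` (default 1.18) toward 1 with rate `adapt_rate` (0.065 s⁻¹)
during the perturbation phase, and decays as `return_start ·
exp(−return_rate (t − 120 s))` in the return phase. With
`amplitude_jitter = 0` the signal is a sum of sinusoids on the analysis
grid with deterministic amplitudes: a rectangular-window periodogram
reads the scheduled spectrum back exactly, which pins down the
round-trip tests. With jitter 1 the synthesis moves to a 0.01-Hz grid
with Rayleigh-distributed amplitudes — a Gaussian-process-like surrogate
whose Welch spectrum matches the target in expectation and whose
single-window periodograms fluctuate realistically (χ²-like, ≈1.4 dB SD
per bin). An optional slow coherent level modulation
(`level_noise_db`, an OU process in dB) is available but defaults to 0:
at realistic sizes it rotates PC1 toward the flat direction and masks
the relaxation dynamics.

**Pendulum simulation** (`simulate_pendulum_trial`) is the mechanistic
route: a small-angle single inverted pendulum I·θ″ = mgh·θ + torque
(defaults m = 70 kg, h = 0.9 m, I = mh², g = 9.81 m/s²), stabilized by a
PID controller (kp = 1000 N·m/rad, ki = 15 N·m/rad·s, kd = 320 N·m·s/rad)
acting on the weighted sum of three sway estimates — visual and
vestibular channels sense body-in-space angle, the proprioceptive
channel senses the ankle angle relative to the platform — delayed by
100 ms, plus white torque noise (2 N·m per sample at 100 Hz, giving a
baseline sway of ~3 mm RMS). CoP = total ankle torque / (m·g), in mm.
The plant is advanced with an exact zero-order-hold update per sample;
tilts beyond 0.6 rad raise an explicit instability error. The loop
reproduces the standard gain–spectrum relationship: with total sensory
weight near 1 the CoP spectrum is gently peaked around 1 Hz, and raising
the loop gain raises the peak frequency. The simulated PSD matches the
analytic PSD of the linearized delayed closed loop band-averaged over
0.1–3 Hz within 10% at 600 s of data (tested against an independently
coded transfer-function oracle). Controller parameters switch targets at
the 60-s and 120-s boundaries and relax exponentially with
`weight_transition_tau` — the mechanism that produces exponential
spectral adaptation and de-adaptation.

**Cohorts** (`generate_cohort`) build the full factorial design:
43 participants × {EO, EC} × {0.1, 0.2, 0.4 Hz} = 258 trials, half the
participants running the EO block first, frequency order cycling through
all six permutations across participants, MSS scores uniform on 0–14.
Per-trial seeds derive deterministically from (cohort seed, participant,
vision, frequency), so any trial is reproducible in isolation. The
default mode uses the spectral surrogates; `mode="pendulum"` expresses
the same effects through controller-gain reweighting.

### Generator defaults as study conditions

Where printed values exist they anchor the defaults: return-phase rates
C = 0.050 s⁻¹ (EO) and 0.050 − 0.021 = 0.029 s⁻¹ (EC), i.e. τ ≈ 20 s and
≈ 35 s; score levels entering the return fit at 0.37 (EO) / 0.56 (EC);
perturbation-phase B = 1.18 and rate 0.065 s⁻¹ (midpoints of the
reported intervals). The remaining choices are free and documented here:

- Baseline PSD ∝ 1/(1 + (f/0.3 Hz)²), scaled to 3 mm RMS. Flatter
  slopes were chosen deliberately: with a steeper roll-off the true
  high-frequency floor falls below the rectangular-window leakage of the
  low-frequency and platform-line power, and the leaked floor — not the
  programmed spectrum — then dominates the high bins. That leakage is a
  genuine artifact of boxcar periodograms on steep spectra, worth
  knowing about when applying the pipeline to real data.
- Perturbation-phase spectral change: broad bumps of +20 dB near 1.5 Hz
  and +14 dB near 0.7 Hz (EO); eyes closed uses +17 dB and +16 dB, so
  the EC balance is lower (vision main effect), with the EC high bump
  further shifted by `ec_balance_shift_per_mss` (−0.3 dB per MSS unit)
  — the programmed vision × MSS interaction. Narrow peaks of +12 dB at
  the platform frequency and +6 dB at its first harmonic model the
  mechanically driven component.
- `lag_slope_per_mss` (−0.05 by default) scales the EC return rate as
  C·exp(−slope·mss·`lag_rate_scale`): negative values make high-MSS
  participants de-adapt faster, which the lag score downstream reads as
  a negative EC lag-vs-MSS slope. The mapping from lag units to rate
  modulation is approximate — the realized lag also depends on the noise
  level and saturates in low noise — so the programmed quantity is the
  sign and ordering, not an exact lag magnitude.
- A per-participant lognormal return-rate offset (SD 0.15 in log rate)
  injects between-participant correlation, giving the lag model's random
  intercept something real to absorb.

### What the surrogates do not emulate

Surrogate trials are (locally) stationary Gaussian processes with
independent periodogram noise across bins. Real sway has heavier
low-frequency nonstationarity, coherent level drifts, and occasional
step-like postural corrections. One visible consequence: the PC1
variance-explained of surrogate cohorts sits around 0.4–0.6, below the
~0.9 reported for real data, because the surrogate's periodogram noise
spreads isotropically across the 49 non-PC1 directions. Passing the
cohort-level tests therefore demonstrates correct *recovery of
programmed structure* (signs, orderings, rates, design arithmetic), not
that real data will show the same effect sizes or PC1 dominance.

## Problem sizes used in the tests

The suite runs the full 258-trial cohort once per session with a 0.1-s
spectrogram step, the fitter-coverage check on 200 replications of 12
trials, the type-I-error check on 500 replications of a 258-row null
table, and the pendulum-oracle check on a single 600-s simulation; the
whole suite completes in roughly ten minutes on one CPU.

## Known limitations

- Medio-lateral CoP, multi-segment bodies, falls, and vestibular
  transduction are out of scope; the pendulum is linearized and
  single-jointed.
- The exponential family is the only relaxation model; power-law or
  double-exponential de-adaptation would be misfit.
- CIs are asymptotic (local quadratic/normal approximations), not
  profile or bootstrap intervals.
- The lag score divides by the residual SD of the same trial, so trials
  with near-zero residual variance can produce large finite lags; the
  all-zero convention only guards the exact degenerate case.
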