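# swayspec

Spectro-temporal analysis of postural sway for perturbation trials, plus
synthetic center-of-pressure (CoP) generators with known ground truth.

## The problem

When a person stands on a platform that suddenly starts (and later
stops) oscillating, the frequency content of their body sway changes:
the feedback gains of the postural control loop are re-tuned, shifting
power between low (< 1.2 Hz) and higher (> 1.2 Hz) sway frequencies, and
the change builds up and decays gradually. `swayspec` extracts that
spectro-temporal structure from a single antero-posterior CoP trace and
relates it, across a cohort, to visual condition (eyes open/closed) and
motion sickness susceptibility (MSS score).

The trial format is 180 s at 100 Hz: 60 s static baseline, 60 s of ±4°
sinusoidal platform tilt at 0.1, 0.2 or 0.4 Hz, 60 s static return.

## The method

For each trial, the PSD of the CoP is computed on a 10-s sliding window
(50 bins, 0.1–5 Hz in 0.1-Hz steps, in dB) and the resulting
windows-by-bins matrix is decomposed by PCA. The first component's
eigenvector is the spectral signature of the perturbation; its score is
the time course, normalized to mean 0 over 30–55 s and mean 1 over
90–115 s. From these come:

- the **spectral balance** H − L: mean eigenvector loading over
  1.2–3.0 Hz minus that over 0.5–1.2 Hz;
- the **exponential model** y = A + (B − A)·e^(−C(t−t0)) fitted jointly
  across trials for the perturbation phase (t0 = 65 s) and the return
  phase (t0 = 125 s), with shared asymptote A and condition-specific B,
  C (time constant τ = 1/C);
- the per-trial **lag score**: mean residual from the fitted group
  curve divided by its SD — positive when a trial returns to baseline
  more slowly than predicted;
- group models: balance ~ vision + frequency + MSS + vision:MSS (OLS,
  type-II F), and lag ~ vision × MSS with a participant random
  intercept (REML mixed model).

A synthetic cohort generator (spectral surrogates by default, a
single-inverted-pendulum PID stance simulator optionally) produces
258-trial cohorts with programmed effect structure, so every stage can
be validated without raw study data. See `docs/methods.md` for the
model details and all generator defaults.

## Worked example

```python
import swayspec as sw

spec = sw.CohortSpec(n_participants=8, seed=1)
trials = sw.generate_cohort(spec)          # 8 x 2 visions x 3 freqs = 48 trials
res = sw.analyze_cohort(trials, step=0.1)  # spectro -> PCA -> balance -> fits -> models

fit = res.fit_return
for vis in ("EO", "EC"):
    c = fit.c[(vis, 0.2)]
    print(f"{vis}: C = {c:.3f} 1/s  ->  tau = {sw.time_constant(c):.1f} s")
print(res.lag_result.slope_frame().to_string(index=False))
```

prints

```
EO: C = 0.046 1/s  ->  tau = 21.9 s
EC: C = 0.033 1/s  ->  tau = 30.3 s
vision     slope  ci95_low  ci95_high
    EC -0.078212 -0.096608  -0.059816
    EO  0.000194 -0.018202   0.018590
```

The return-phase relaxation is slower with eyes closed (τ ≈ 30 s vs
≈ 22 s here), and the lag-vs-MSS slope is negative for EC but
indistinguishable from zero for EO — i.e. with eyes closed, the more
motion-sickness-susceptible synthetic participants snap back to their
baseline sway spectrum faster, exactly the structure the generator
programmed. `res.stat_table` holds the per-trial balance and lag values
joined with the design metadata.

The same pipeline is scriptable from the shell:

```bash
swayspec simulate --participants 8 --seed 1 --out cohort/
swayspec analyze --manifest cohort/manifest.csv --out results/ --step 0.1
swayspec report --results results/
```

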