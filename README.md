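# mnpool

Motoneuron-pool simulation and stimulus-evoked motor-unit inhibition
analysis.

## The problem

Electrical stimulation of cutaneous or mixed nerves transiently inhibits the
discharge of spinal motoneurons — the cutaneous silent period (CSP) in hand
muscles, reciprocal Ia inhibition in the ankle dorsiflexors.  High-density
surface EMG decomposition makes many motor units (MUs) observable at once,
and the *duration* of each unit's inhibition turns out to depend strongly on
its background discharge rate, in a participant-specific way.  `mnpool` is
for researchers who quantify such stimulus-locked functional inhibition from
decomposed spike trains and who want an in-silico twin of the experiment:

* a **two-compartment conductance-based motoneuron pool** — soma with Na /
  fast-K / slow-K conductances under pulse-switched first-order gating, a
  dendrite receiving common excitatory drive, synaptic noise and
  alpha-function inhibitory inputs, `C dv/dt = I_ext − Σ g_k (v − E_k)`,
  integrated by RK4, with a size gradient interpolated between a smallest
  and largest S-type cell (soma capacitance ≈ 189–214 pF) and a firing
  threshold `V_th = rheobase × R_in`;
* the **PSTH/PSF CUSUM detector**: peristimulus time histogram (counts) and
  peristimulus frequencygram (instantaneous rates) in 1-ms bins over
  −200..+400 ms, CUSUMed against the −200..−30 ms baseline mean with a
  ±20 ms blanked interval; a trough is genuine when its amplitude exceeds
  the maximal prestimulus CUSUM variation (the *error box*); inhibition
  onset comes from the PSTH-CUSUM, its end from the PSF-CUSUM (which keeps
  falling while units fire below their baseline rate);
* the **statistics layer**: per-participant linear fits (R², slope t-test),
  REML mixed models with random intercept/slope and subject ICC,
  likelihood-ratio model comparison, one-way ICC(1,1) from ANOVA mean
  squares, Hedges' *g* with seeded bootstrap CIs, KS tests;
* **MSE-based model selection**: every sweep realization over inhibition
  amplitude A and time constant τ (CSP grid 1–3 a.u. × 7–20 ms = 154 cells)
  yields a linear model LM_sim of duration on rate; a participant's
  calibrated twin is the LM_sim minimising the mean squared error of its
  predictions at the participant's own firing rates;
* **ground-truthed synthetic data** (gamma-renewal trains with imposed
  silences, hierarchical cohorts, MUAP-convolution surface EMG) so every
  stage is testable without recordings.

## Worked example

```python
import numpy as np
from mnpool import (ProtocolSpec, build_pool, default_pool_spec,
                    run_realization, analyze_train, fit_linear)

pool = build_pool(default_pool_spec(20))          # 189-214 pF S-type pool
spec = ProtocolSpec(plateau_s=200.0,              # 2-s ramps, 200-s plateau
                    inh_amplitude_A=2.8, inh_tau_ms=19.0, seed=1)
trains, stims, _ = run_realization(pool, spec)    # 111 stimuli at ~1.8 s

rates, durs = [], []
for tr in trains:
    est = analyze_train(tr, stims)                # PSTH/PSF CUSUM detector
    if est.detected:
        rates.append(est.firing_rate_hz)
        durs.append(est.duration_ms)

lm_sim = fit_linear(np.array(rates), np.array(durs))
print(f"n={lm_sim.n}  slope={lm_sim.slope:.1f} ms/Hz  "
      f"R^2={lm_sim.r_squared:.2f}  mean duration={np.mean(durs):.0f} ms")
```

prints

```
n=20  slope=-9.0 ms/Hz  R^2=0.85  mean duration=114 ms
```

All 20 units show detectable inhibition; durations average ~114 ms (the
silent-period scale) and shorten by ~9 ms per extra pps of background
discharge — faster-firing units escape the same inhibitory input sooner,
and the firing rate explains most of the duration variance at this
long-τ/high-A parameter point.

The `examples/` directory holds one short script per capability (pool
simulation, detector on ground-truthed trains, cohort statistics,
global-EMG vs single-unit contrast), and the `mnpool` console script exposes
`simulate`, `sweep`, `analyze`, `calibrate`, `size-experiment`,
`robustness`, `synth` and `stats` subcommands for batch use.

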