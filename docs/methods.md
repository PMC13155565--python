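# Methods

## Motoneuron model

Each motoneuron is two coupled cylinders.  Voltages are in mV relative to
rest (E_leak = 0) and obey the conductance-based convention
`C dv/dt = I_ext − Σ g_k (v − E_k)`:

* soma: leak, coupling, Na (m³h), fast K (n⁴), slow K (q²);
* dendrite: leak, coupling, optional Ca (p), excitatory input
  `Exc·G_excit·(v−E_excit)` and inhibitory input `Inh·G_inhib·(v−E_inhib)`.

Passive quantities derive from geometry: compartment capacitance is the
specific capacitance (1 µF/cm²) times the lateral cylinder area π·d·l; the
coupling conductance is the reciprocal of the two half-cylinder axial
resistances `R = Ra·(l/2)/(π r²)` at Ra = 70 Ω·cm.  A pool is built by
linear interpolation of every parameter between a smallest and a largest
endpoint cell, so unit i of n gets `f_i = f_small + (i−1)/(n−1)·Δf`.

The default endpoints are an S-type set assembled from the cat lumbar
literature: soma diameter = length 77.5 → 82.5 µm (soma capacitance
188.7 → 213.8 pF), dendrite 41.5 × 5500 → 62.5 × 6800 µm, membrane
resistivity 1.0 (soma) / 12.0 (dendrite) kΩ·cm², rheobase 3.5 → 6.5 nA.
Input resistance is computed from the passive network (1.96 → 1.24 MΩ), and
the firing threshold is exactly `rheobase × R_in` (6.9 → 8.0 mV), which
makes rheobase the firing boundary for steady somatic current by
construction.

### Spike generation

No printed rate functions exist for the gates, so the model uses the
pulse-switched kinetics of the classic two-compartment pool models: a
threshold crossing triggers a 0.6-ms pulse during which m, n, q relax
toward 1 (rates 22, 1.5, 8 ms⁻¹) and h toward 0 (4 ms⁻¹); outside the pulse
they relax back (13, 0.1, 0.02 and 0.5 ms⁻¹).  The slow-K gate q (τ = 50 ms,
E_Kslow = −25 mV) produces the after-hyperpolarisation that sets the
primary firing range.  A 2-ms re-detection guard suppresses numerical
double-crossings; the pulse episode itself is the physiological refractory.

Because the gate ODEs are linear with piecewise-constant rates, gate values
at the RK4 stage times are computed in closed form (exact exponentials);
only the two voltages are advanced by RK4.  This keeps the scheme stable at
the 0.2-ms step as well as the 0.05-ms default, and spike counts at the two
steps agree within 1% on constant-drive runs.

### Calibration of the free scales

The synaptic scales are not printed anywhere and were calibrated once,
before any downstream statistic was computed, to the stated operating
conditions and then frozen:

* `G_excit` 0.58 → 1.25 µS/a.u. (scaling roughly with dendritic area, as
  synaptic counts do): at the standard common input of 0.2 a.u. the 20-unit
  pool fires 10.7–13.9 Hz on the plateau, decreasing with size, matching
  the 11–14 Hz band; recruitment completes during the 2-s ramp; at
  0.15 a.u. (reciprocal-inhibition protocol) the pool stays active at
  5–11 Hz.
* noise: the model's noise term leaves its scale open.  White per-step
  conductance noise is low-pass filtered into irrelevance by the membrane
  (ISI CoV ≈ 0.04 at any moderate amplitude), so the noise is an
  Ornstein–Uhlenbeck process with 25-ms correlation time — the standard
  effective-synaptic-noise form — with stationary SD 0.2 × the common-drive
  amplitude, which puts the plateau ISI CoV at 0.14–0.25: physiological,
  and inside the CoV < 0.3 retention filter.
* `G_inhib` = 3.0 µS/a.u., E_inhib = −16 mV: at the strong parameter point
  (A = 2.8, τ = 19 ms) per-unit inhibition durations average ≈ 116 ms, the
  experimental silent-period scale, and inhibition remains detectable
  across the sweep grid down to short time constants.

## Protocols

Trapezoidal common drive (2-s ramp up, plateau, 2-s ramp down; 200-s
plateau with 1.8 ± 0.2-s stimulus intervals for the CSP protocol, 300 s
with 2.0 ± 0.2 s for reciprocal inhibition).  The ± jitter is read as
uniform on [−0.2, +0.2] s (the ± notation names a range, not an SD);
stimuli accumulate from plateau start while they remain inside it, giving
111 and 150 stimuli at zero jitter.  The inhibitory input is the alpha
function `A·(t/τ)·e^(−t/τ)` added identically to every unit's inhibitory
conductance at each stimulus onset.  Sweeps run one realization per (A, τ)
cell — 11 × 14 = 154 for the CSP grid, 11 × 4 for the reciprocal grid —
each with a child seed derived from the master seed.  All randomness
(schedule, per-unit noise) descends from the master seed by fixed offsets;
identical seeds give bit-identical spike trains.  Integration runs at
0.05 ms by default (the heavy 40-unit experiments use the coarser 0.2-ms
step, which the convergence property licenses); spike times are reported on
a 2-kHz output grid, which preserves counts because the re-detection guard
exceeds one output sample.

## Inhibition detection

Discharges are cleaned by the outlier rule (instantaneous rate above median
+ 2.5 SD or below 50% of the median); units are retained when the ISI CoV
is < 0.3.  PSTH and PSF are built in 1-ms half-open bins over −200..+400 ms.
One deliberate refinement: PSF rates are referenced to the *un-cleaned*
discharge sequence, so removing an outlier deletes a rate sample rather
than fabricating an artificially long interval — otherwise the outlier rule
deletes genuine low-rate recovery discharges and the re-chained intervals
masquerade as ever-deeper inhibition.

Both histograms are CUSUMed against their baseline (−200..−30 ms) mean;
PSF bins keep their samples (occupied bins contribute their sample mean,
empty bins nothing); the trace is frozen across ±20 ms around the stimulus.
The error box is the max−min CUSUM excursion over the baseline window.

Manual inflexion marking is replaced by a deterministic rule whose
parameters ride along in every estimate:

* onset: first post-blanking bin where the CUSUM falls below (value at
  blanking end − error box) for ≥ 5 ms, back-tracked to the first bin of
  the local decline;
* end: a trough narrower than the 40-ms slope window (e.g. terminated by a
  synchronized rebound) ends at its minimum — the "peak of the trough";
  a wider trough ends at the first bin whose 40-ms forward slope stays
  above −0.5 × error box for 10 ms — the "last deflection point";
* a response is genuine only when both traces contain a trough whose
  onset-to-end amplitude exceeds that trace's own error box.  The final
  estimate combines the PSTH onset with the PSF end.

Window lengths are in milliseconds, so analyses at 2-ms bins use the same
effective smoothing.  Validation on ground-truthed renewal trains (300
stimuli): median onset error 1 ms over a 3 × 3 × 3 grid of onsets, gaps and
rates; every estimated duration covers the imposed gap and stays within one
mean ISI + 25 ms of it; 0/40 modulation-free units detected (false-positive
rate ≤ 5% required).

## Statistics

OLS fits report `R² = 1 − SS_res/SS_tot`, the slope t-test on n−2 df, and
`MSE = SS_res/n` (the shared numerator with R² is what the library
selection minimises).  R² is classed strong/moderate/weak at 0.67/0.33/0.19.
Mixed models are fitted by REML via statsmodels MixedLM; model 1 has a
random intercept per subject, model 2 adds a correlated random slope;
`ICC_subject = σ²_intercept/(σ²_intercept + σ²_residual)`; marginal and
conditional R² follow the variance-partition definition.  A model-2 fit is
flagged singular when the intercept–slope correlation reaches ±0.9 or the
slope component contributes < 1% of the residual variance (REML optimisers
stop near, not at, the boundary).  Model comparison uses the likelihood-
ratio test (df = 2, no boundary correction, as in the standard `compare`
convention) and requires the richer model to win on AIC, BIC, log-likelihood
and p < 0.05 simultaneously.  One-way ICC(1,1) ships in two variants:
"printed" with (k+1)·MSW in the denominator — the form the source analysis
prints, kept as the fidelity default — and "standard" with the usual (k−1);
k is the mean group size.  Hedges' g uses the (n−1)-weighted pooled SD and
seeded percentile-bootstrap CIs (10 000 replicas by default).

## Selection and experiments

Each sweep realization with more than two detected units yields an LM_sim;
realizations below that threshold are logged as unfit.  Selection is an
exhaustive MSE argmin over the library at the participant's own firing
rates, ties resolved to smaller A then smaller τ (ties have not been
observed; the rule is recorded in the output).  The size experiment doubles
the pool to 40 units, fixes (A, τ) at a calibrated point, sweeps the common
input over 0.21–0.28 a.u. (0.01 steps; the 0.20 start is available by
configuration — the source lists both), pools all (capacitance, rate,
duration) records, and asks whether capacitance explains duration within
firing-rate bins.  Both printed bin sets (11–12/13–14/14–15 and
11–12/12–13/13–14 Hz) are shipped; the former is the default.  The
robustness experiment re-analyses identical 40-unit spike data at 1- and
2-ms bins and at 250 vs 500 delivered stimuli and reports paired Hedges' g.

## Synthetic data

The renewal generator draws gamma ISIs (shape 1/CoV², so the target CoV is
exact) and imposes inhibition by thinning: each spike is deleted with the
truth profile's probability at its latency — depth 1 over the silent span,
then a linear 30-ms recovery ramp by default.  Thinning leaves the baseline
process untouched outside the window, making the imposed onset and gap
exact ground truth; unlike the biophysical pool it does not phase-reset the
rhythm, produce a synchronized rebound, or modulate rates gradually.
Passing the recovery suite therefore certifies the detector's calibration
on known truth, not every feature of real decomposed trains.  The cohort
generator draws subject intercepts/slopes and unit rates from the
random-intercept/random-slope generating model the LMM assumes (defaults:
β₁ = −15 ms/Hz, rates 8–16 pps); the EMG synthesiser convolves spike
impulses with Hann-windowed biphasic MUAP templates on a channel grid with
smooth spatial weights plus white noise.  The sEMG silent-period
automation requires the averaged rectified trace to sit 3 baseline-SDs
below baseline for ≥ 5 ms (the average is autocorrelated over a MUAP
length, so the literal below-baseline reading triggers on chance runs).

## Problem sizes and known limitations

The test suite runs the participant-point replications at the full 200-s
plateau with 3 seeds, the size experiment at a 100-s plateau, and the
recovery grid with 2 seeds per cell; `scripts/acceptance.py` uses 5 seeds
for the replications and 3 per recovery cell.  These sizes are the
package's chosen defaults for routine verification; all experiments accept
the full-scale settings.

Limitations worth knowing:

* the default endpoint set is literature-derived; studies with their own
  cell-parameter tables should supply them through the JSON pool-file
  format rather than rely on the defaults.  At the weak-inhibition corner
  (A = 1.8, τ = 7 ms) the model keeps a tight rate–duration coupling
  (R² ≈ 0.7) because the detector dates the narrow trough's end at a
  sharply-defined rebound minimum; experimental datasets at comparable
  parameters can show a looser, merely moderate relationship;
* the pool omits persistent inward currents, dendritic nonlinearities and
  neuromodulation by design;
* short-τ inhibition under the reduced reciprocal drive sits near the
  detection limit: realizations there may legitimately yield fewer than
  three detected units and enter the unfit log rather than the LM library;
* decomposition errors are emulated only as optional uniform spike
  deletion/insertion, not as realistic confusion structure.
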