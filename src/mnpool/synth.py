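"""Ground-truthed synthetic fixtures for every analysis stage.

Three generators emulate the study's data with exactly known ground truth:

* gamma-renewal motor-unit trains with stimulus-locked suppression imposed
  by thinning (probabilistic deletion per a depth profile), so the baseline
  process is untouched outside the inhibition window and the imposed
  onset/duration are exact;
* hierarchical participant-by-unit cohorts drawn from the random-intercept /
  random-slope generating model that the mixed-model analysis assumes;
* composite multichannel surface EMG built by convolving spike trains with
  motor-unit action potential (MUAP) templates plus white noise.

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import InvalidSpecError
from .protocol import SpikeTrain, StimulusTimes

__all__ = [
    "GroundTruthInhibition", "SyntheticCohortSpec", "ParticipantData",
    "renewal_inhibited_train", "hierarchical_cohort",
    "biphasic_muap", "synthesize_hdsemg",
]


@dataclass(frozen=True)
class GroundTruthInhibition:
    """Imposed stimulus-locked suppression: complete (or graded) silence of
    `silent_ms` starting `onset_ms` after each stimulus, then a linear
    recovery of the suppression depth over `recovery_ms`."""

    onset_ms: float = 30.0
    silent_ms: float = 60.0
    depth: float = 1.0          # suppression probability inside the silence
    recovery_ms: float = 30.0   # linear ramp of depth back to 0

    def __post_init__(self):
        if self.onset_ms < 0 or self.silent_ms < 0 or self.recovery_ms < 0:
            raise InvalidSpecError("truth times must be non-negative")
        if not 0.0 <= self.depth <= 1.0:
            raise InvalidSpecError("depth must lie in [0, 1]")

    def suppression_at(self, latency_ms: float) -> float:
        """Deletion probability at a latency after the stimulus."""
        if latency_ms < self.onset_ms:
            return 0.0
        dt = latency_ms - self.onset_ms
        if dt < self.silent_ms:
            return self.depth
        if self.recovery_ms > 0 and dt < self.silent_ms + self.recovery_ms:
            return self.depth * (1.0 - (dt - self.silent_ms) / self.recovery_ms)
        return 0.0


def renewal_inhibited_train(rate_pps: float, isi_cov: float, duration_s: float,
                            stims: StimulusTimes,
                            truth: GroundTruthInhibition | None = None,
                            seed: int = 0,
                            sample_rate_hz: float = 2000.0,
                            unit_id: str = "synth") -> SpikeTrain:
    """Gamma-renewal discharge with imposed stimulus-locked suppression.

    The gamma shape is 1/CoV^2 (renewal ISI CoV is exactly the target);
    suppression deletes each spike with the truth profile's probability at
    its latency after the most recent stimulus (thinning), which leaves the
    underlying renewal process intact outside the window.
    """
    if rate_pps <= 0:
        raise InvalidSpecError("rate must be positive")
    if not 0.0 <= isi_cov <= 0.3:
        raise InvalidSpecError("target ISI CoV outside the plausible [0, 0.3]")
    rng = np.random.default_rng(seed)
    mean_isi = 1.0 / rate_pps
    times = []
    t = rng.uniform(0, mean_isi)
    n_max = int(duration_s * rate_pps * 3) + 100
    if isi_cov == 0:
        isis = np.full(n_max, mean_isi)
    else:
        shape = 1.0 / isi_cov ** 2
        isis = rng.gamma(shape, mean_isi / shape, size=n_max)
    for isi in isis:
        if t > duration_s:
            break
        times.append(t)
        t += isi
    times = np.asarray(times)

    if truth is not None and len(stims):
        onsets = np.asarray(stims.onsets_s)
        keep = np.ones(times.size, bool)
        u = rng.random(times.size)
        for i, ts in enumerate(times):
            k = np.searchsorted(onsets, ts) - 1
            if k >= 0:
                lat_ms = (ts - onsets[k]) * 1000.0
                p = truth.suppression_at(lat_ms)
                if p > 0 and u[i] < p:
                    keep[i] = False
        times = times[keep]

    grid = np.round(times * sample_rate_hz) / sample_rate_hz
    grid = np.unique(grid)
    grid = grid[(grid >= 0) & (grid <= duration_s)]
    return SpikeTrain(unit_id, tuple(grid), duration_s, sample_rate_hz)


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generating model of a participant-by-unit hierarchical dataset.

    duration_ij = (beta0 + b0_j) + (beta1 + b1_j) * rate_ij + eps_ij with
    b0_j ~ N(0, intercept_sd^2), b1_j ~ N(0, slope_sd^2), eps ~ N(0,
    residual_sd^2), and unit firing rates drawn from a truncated normal.
    Defaults emulate the silent-period cohorts: ~15-ms shortening of
    inhibition per extra pps and rates in the 8-16 pps band.
    """

    n_subjects: int = 10
    min_units: int = 4
    max_units: int = 15
    beta0_ms: float = 320.0
    beta1_ms_per_hz: float = -15.0
    intercept_sd_ms: float = 40.0
    slope_sd_ms_per_hz: float = 0.0
    residual_sd_ms: float = 18.0
    rate_mean_pps: float = 12.0
    rate_sd_pps: float = 2.0
    rate_bounds_pps: tuple[float, float] = (8.0, 16.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.intercept_sd_ms, self.slope_sd_ms_per_hz,
               self.residual_sd_ms) < 0:
            raise InvalidSpecError("variance components must be non-negative")
        if self.rate_bounds_pps[0] <= 0:
            raise InvalidSpecError("rate bounds must be positive")
        if self.min_units < 1 or self.max_units < self.min_units:
            raise InvalidSpecError("invalid units-per-subject range")


@dataclass
class ParticipantData:
    """Per-participant motor-unit observations for the duration~rate fits."""

    participant_id: str
    firing_rate_hz: np.ndarray
    inhibition_duration_ms: np.ndarray

    def __post_init__(self):
        self.firing_rate_hz = np.asarray(self.firing_rate_hz, float)
        self.inhibition_duration_ms = np.asarray(self.inhibition_duration_ms,
                                                 float)
        if self.firing_rate_hz.shape != self.inhibition_duration_ms.shape:
            raise InvalidSpecError("rate/duration arrays must align")

    @property
    def n_units(self) -> int:
        return self.firing_rate_hz.size


def hierarchical_cohort(spec: SyntheticCohortSpec,
                        ) -> tuple[list[ParticipantData], dict]:
    """Draw a cohort; returns (participants, ground-truth draws)."""
    rng = np.random.default_rng(spec.seed)
    participants = []
    truth = {"beta0": spec.beta0_ms, "beta1": spec.beta1_ms_per_hz,
             "subjects": []}
    lo, hi = spec.rate_bounds_pps
    for j in range(spec.n_subjects):
        b0 = rng.normal(0.0, spec.intercept_sd_ms)
        b1 = rng.normal(0.0, spec.slope_sd_ms_per_hz) \
            if spec.slope_sd_ms_per_hz > 0 else 0.0
        n_units = int(rng.integers(spec.min_units, spec.max_units + 1))
        rates = rng.normal(spec.rate_mean_pps, spec.rate_sd_pps, n_units)
        rates = np.clip(rates, lo, hi)
        eps = rng.normal(0.0, spec.residual_sd_ms, n_units)
        durations = (spec.beta0_ms + b0
                     + (spec.beta1_ms_per_hz + b1) * rates + eps)
        pid = f"p{j + 1:02d}"
        participants.append(ParticipantData(pid, rates, durations))
        truth["subjects"].append(
            {"participant_id": pid, "intercept_dev": float(b0),
             "slope_dev": float(b1), "n_units": n_units})
    return participants, truth


# ---------------------------------------------------------------------------

def biphasic_muap(duration_ms: float = 8.0, sample_rate_hz: float = 2000.0,
                  amplitude: float = 1.0, phase_ms: float = 3.0) -> np.ndarray:
    """Hann-windowed biphasic MUAP template (one cycle of a sine)."""
    n = max(4, int(round(duration_ms * sample_rate_hz / 1000.0)))
    t = np.arange(n) / n
    return amplitude * np.sin(2 * np.pi * t * duration_ms / (2 * phase_ms)) \
        * np.hanning(n)


def synthesize_hdsemg(trains: list[SpikeTrain], muap_bank: list[np.ndarray],
                      n_channels: int = 8, noise_sd: float = 0.02,
                      seed: int = 0, sample_rate_hz: float = 2000.0,
                      lead_ms: float = 0.0) -> np.ndarray:
    """Composite EMG: sum over units of (template convolved with impulses).

    Each unit's template is scaled per channel by a smooth spatial weight;
    `lead_ms` shifts templates earlier than the discharge times (MUAP onset
    precedes the decomposition-aligned firing instant).  Returns an array of
    shape (n_channels, n_samples).
    """
    if not trains:
        raise InvalidSpecError("need at least one spike train")
    min_isi = min((np.diff(tr.discharge_times_s).min()
                   for tr in trains if tr.n_spikes > 1), default=np.inf)
    max_len = max(len(m) for m in muap_bank) / sample_rate_hz
    if max_len > min_isi:
        raise InvalidSpecError("MUAP templates longer than the minimum ISI "
                               "(template/rate aliasing)")
    rng = np.random.default_rng(seed)
    duration = max(tr.duration_s for tr in trains)
    n_samples = int(round(duration * sample_rate_hz)) + 1
    emg = np.zeros((n_channels, n_samples))
    for u, tr in enumerate(trains):
        muap = muap_bank[u % len(muap_bank)]
        centre = (u + 0.5) / len(trains) * n_channels
        weights = np.exp(-0.5 * ((np.arange(n_channels) - centre) / 2.0) ** 2)
        weights /= weights.max()  # best channel carries the template exactly
        impulses = np.zeros(n_samples)
        for ts in tr.discharge_times_s:
            k = int(round((ts - lead_ms / 1000.0) * sample_rate_hz))
            if 0 <= k < n_samples:
                impulses[k] = 1.0
        contrib = np.convolve(impulses, muap)[:n_samples]
        emg += weights[:, None] * contrib[None, :]
    if noise_sd > 0:
        emg += rng.normal(0.0, noise_sd, emg.shape)
    return emg
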