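"""Stimulus-locked inhibition metrics from motor-unit spike trains.

The detector follows the PSTH/PSF + CUSUM error-box method: discharge times
are locked to stimulus onsets in 1-ms bins over a -200..+400 ms window; the
PSTH (firing counts) dates the inhibition onset, while the PSF (instantaneous
discharge rates at their latencies) dates its end, because firing resumes
below the baseline rate before recovering and only the rate-based trace
captures that late phase.  Both traces are summarised by a CUSUM of
deviations from the prestimulus (-200..-30 ms) mean, held constant within
+/-20 ms of the stimulus where artefacts could corrupt discharge
identification; a trough is accepted only when its amplitude exceeds the
maximum prestimulus CUSUM variation (the "error box").

The onset/end inflexion points, marked by eye in classical practice, are
picked here by a deterministic rule (see `DetectorConfig`), whose parameters
are carried in every estimate's metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .model import InvalidSpecError
from .protocol import SpikeTrain, StimulusTimes, ProtocolSpec, trapezoidal_drive

__all__ = [
    "AnalysisWindow", "DetectorConfig", "PeristimulusHistogram", "CusumTrace",
    "ErrorBox", "InhibitionEstimate", "TooFewSpikesError",
    "clean_discharges", "discharge_stats", "peristimulus_histograms",
    "cusum_with_errorbox", "detect_inhibition", "prestimulus_rate",
    "recruitment_threshold", "analyze_train",
]

ISI_COV_RETENTION_LIMIT = 0.3


class TooFewSpikesError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisWindow:
    """Peristimulus window and binning (ms relative to stimulus onset)."""

    start_ms: float = -200.0
    end_ms: float = 400.0
    bin_ms: float = 1.0
    baseline_start_ms: float = -200.0
    baseline_end_ms: float = -30.0
    blank_half_width_ms: float = 20.0

    def __post_init__(self):
        if self.end_ms <= self.start_ms:
            raise InvalidSpecError("window end must exceed start")
        if not (self.start_ms <= self.baseline_start_ms
                < self.baseline_end_ms <= 0):
            raise InvalidSpecError("baseline window must be prestimulus")

    @property
    def n_bins(self) -> int:
        return int(round((self.end_ms - self.start_ms) / self.bin_ms))

    @property
    def edges_ms(self) -> np.ndarray:
        return self.start_ms + np.arange(self.n_bins + 1) * self.bin_ms

    def bin_of(self, latency_ms: float) -> int:
        # half-open binning [k, k+1); latency 0 = stimulus onset sample; the
        # epsilon absorbs float round-off in (time - onset) differences
        return int(math.floor((latency_ms - self.start_ms) / self.bin_ms
                              + 1e-9))

    @property
    def baseline_slice(self) -> slice:
        return slice(self.bin_of(self.baseline_start_ms),
                     self.bin_of(self.baseline_end_ms))

    @property
    def blank_slice(self) -> slice:
        lo = max(0, self.bin_of(-self.blank_half_width_ms))
        hi = min(self.n_bins, self.bin_of(self.blank_half_width_ms))
        return slice(lo, hi)


@dataclass(frozen=True)
class DetectorConfig:
    """Deterministic surrogate for manual inflexion marking.

    Onset: first post-blanking bin where the CUSUM falls below (value at the
    end of blanking - error box) and stays below for `onset_run_ms`,
    back-tracked to the first bin of the local decline.  End: a trough
    narrower than the slope window ends at its minimum (the trough peak,
    e.g. when a synchronised rebound follows); a wider trough ends at the
    first bin whose `end_slope_ms` forward slope exceeds
    -`end_slope_tol_frac` x error box and keeps doing so for `end_run_ms`,
    i.e. the elbow where the decline flattens to within baseline
    variability.  All windows are in milliseconds so the rule is invariant
    to the bin width.
    """

    onset_run_ms: float = 5.0
    end_slope_ms: float = 40.0
    end_run_ms: float = 10.0
    end_slope_tol_frac: float = 0.5

    def bins(self, bin_ms: float) -> tuple[int, int, int]:
        to_bins = lambda ms: max(1, int(round(ms / bin_ms)))
        return (to_bins(self.onset_run_ms), to_bins(self.end_slope_ms),
                to_bins(self.end_run_ms))


@dataclass
class PeristimulusHistogram:
    """PSTH (counts) or PSF (rate samples, pps) on a 1-ms peristimulus grid."""

    kind: str  # "psth" | "psf"
    window: AnalysisWindow
    counts: np.ndarray | None = None          # PSTH: ints per bin
    samples: list | None = None               # PSF: list of arrays per bin

    def bin_means(self) -> tuple[np.ndarray, np.ndarray]:
        """(per-bin mean value, occupancy mask); PSTH bins are always occupied."""
        if self.kind == "psth":
            return self.counts.astype(float), np.ones(self.window.n_bins, bool)
        means = np.zeros(self.window.n_bins)
        occ = np.zeros(self.window.n_bins, bool)
        for k, s in enumerate(self.samples):
            if len(s):
                means[k] = float(np.mean(s))
                occ[k] = True
        return means, occ


@dataclass
class CusumTrace:
    values: np.ndarray
    window: AnalysisWindow

    @property
    def blanked_interval_ms(self) -> tuple[float, float]:
        return (-self.window.blank_half_width_ms,
                self.window.blank_half_width_ms)


@dataclass(frozen=True)
class ErrorBox:
    """Maximum CUSUM variation over the prestimulus baseline window."""

    max_variation: float

    def __post_init__(self):
        if self.max_variation < 0:
            raise InvalidSpecError("error box must be non-negative")


@dataclass
class InhibitionEstimate:
    detected: bool
    onset_ms: float | None = None   # from the PSTH-CUSUM trough start
    end_ms: float | None = None     # from the PSF-CUSUM trough end
    psth_amplitude: float | None = None
    psf_amplitude: float | None = None
    firing_rate_hz: float | None = None  # prestimulus mean instantaneous rate
    detector: dict = field(default_factory=lambda: asdict(DetectorConfig()))

    @property
    def duration_ms(self) -> float | None:
        if not self.detected:
            return None
        return self.end_ms - self.onset_ms


# ---------------------------------------------------------------------------

def _instantaneous_rates(times_s: np.ndarray) -> np.ndarray:
    """Rate of each discharge = reciprocal of its preceding ISI (pps);
    the first discharge carries no rate."""
    return 1.0 / np.diff(times_s)


def clean_discharges(train: SpikeTrain) -> SpikeTrain:
    """Remove outlier discharges from decomposition-style spike trains.

    A discharge is dropped when its instantaneous rate exceeds the median
    rate + 2.5 x SD, or falls below 50% of the median rate (single pass over
    the original rates).
    """
    t = np.asarray(train.discharge_times_s)
    if t.size < 3:
        raise TooFewSpikesError("need at least 3 discharges to clean")
    rates = _instantaneous_rates(t)
    med = float(np.median(rates))
    sd = float(np.std(rates))
    bad = (rates > med + 2.5 * sd) | (rates < 0.5 * med)
    keep = np.concatenate(([True], ~bad))
    return SpikeTrain(train.unit_id, tuple(t[keep]), train.duration_s,
                      train.sample_rate_hz)


def discharge_stats(train: SpikeTrain) -> tuple[float, float, bool]:
    """(mean rate Hz, ISI CoV, retained flag); retention requires CoV < 0.3."""
    t = np.asarray(train.discharge_times_s)
    if t.size < 11:
        raise TooFewSpikesError("need at least 10 inter-spike intervals")
    isi = np.diff(t)
    mean_rate = (t.size - 1) / (t[-1] - t[0])
    cov = float(np.std(isi) / np.mean(isi))
    return float(mean_rate), cov, cov < ISI_COV_RETENTION_LIMIT


def peristimulus_histograms(train: SpikeTrain, stims: StimulusTimes,
                            window: AnalysisWindow | None = None,
                            rate_train: SpikeTrain | None = None,
                            ) -> tuple[PeristimulusHistogram, PeristimulusHistogram]:
    """Build the PSTH and PSF of a (cleaned) train around the stimuli.

    When `rate_train` is given (normally the un-cleaned train), each retained
    discharge's instantaneous rate is taken with respect to its true
    preceding discharge in that sequence, so that outlier removal deletes a
    rate sample instead of fabricating an artificially long interval.
    """
    window = window or AnalysisWindow()
    if len(stims) < 10:
        raise InvalidSpecError("need at least 10 stimuli")
    t = np.asarray(train.discharge_times_s)
    if t.size < 2:
        raise TooFewSpikesError("train too sparse for peristimulus analysis")

    overlap = any(onset + window.start_ms / 1000.0 < train.duration_s
                  and onset + window.end_ms / 1000.0 > 0
                  for onset in stims.onsets_s)
    if not overlap:
        raise InvalidSpecError("stimulus windows do not overlap the spike train")

    ref = np.asarray((rate_train or train).discharge_times_s)
    pos = np.searchsorted(ref, t)
    rate_of = np.full(t.size, np.nan)
    has_prev = pos > 0
    rate_of[has_prev] = 1.0 / (t[has_prev] - ref[pos[has_prev] - 1])

    counts = np.zeros(window.n_bins, dtype=int)
    samples: list[list[float]] = [[] for _ in range(window.n_bins)]
    for onset in stims.onsets_s:
        lat_ms = (t - onset) * 1000.0
        sel = np.nonzero((lat_ms >= window.start_ms)
                         & (lat_ms < window.end_ms))[0]
        for idx in sel:
            k = window.bin_of(lat_ms[idx])
            if not 0 <= k < window.n_bins:
                continue  # right-edge round-off
            counts[k] += 1
            if np.isfinite(rate_of[idx]):
                samples[k].append(float(rate_of[idx]))
    psth = PeristimulusHistogram("psth", window, counts=counts)
    psf = PeristimulusHistogram("psf", window,
                                samples=[np.asarray(s) for s in samples])
    return psth, psf


def cusum_with_errorbox(hist: PeristimulusHistogram,
                        ) -> tuple[CusumTrace, ErrorBox]:
    """CUSUM of deviations from the prestimulus baseline mean.

    PSF bins keep their samples: the increment of an occupied bin is its
    per-bin sample mean minus the baseline mean; empty bins contribute
    nothing.  The trace is not updated across the +/-20 ms blanked interval.
    The error box is the max-min CUSUM excursion over the baseline window.
    """
    w = hist.window
    means, occ = hist.bin_means()
    base = w.baseline_slice
    base_occ = occ[base]
    if not np.any(base_occ):
        raise InvalidSpecError("empty baseline window")
    baseline_mean = float(np.mean(means[base][base_occ]))

    increments = np.where(occ, means - baseline_mean, 0.0)
    blank = w.blank_slice
    increments[blank] = 0.0
    values = np.cumsum(increments)
    trace = CusumTrace(values, w)
    base_vals = values[base]
    box = ErrorBox(float(base_vals.max() - base_vals.min()))
    return trace, box


def _find_trough(cusum: CusumTrace, box: ErrorBox, cfg: DetectorConfig):
    """Locate a post-stimulus trough; returns (onset_idx, end_idx, amplitude)
    or None.  Indices are bin indices; amplitude is CUSUM drop onset->min."""
    w = cusum.window
    v = cusum.values
    onset_run, end_slope, end_run = cfg.bins(w.bin_ms)
    blank_end = w.blank_slice.stop
    ref = v[blank_end - 1] if blank_end > 0 else 0.0
    threshold = ref - box.max_variation

    run = 0
    trigger = None
    for k in range(blank_end, w.n_bins):
        if v[k] < threshold:
            run += 1
            if run >= onset_run:
                trigger = k - onset_run + 1
                break
        else:
            run = 0
    if trigger is None:
        return None

    # back-track to the local maximum preceding the decline; the trough
    # starts at the first declining bin after it
    j = trigger
    while j > blank_end and v[j - 1] > v[j]:
        j -= 1
    onset_idx = min(j + 1, trigger)

    # end: "last deflection point or peak of the trough".  The trough's
    # sub-threshold extent decides which: a narrow trough (shorter than the
    # slope window, e.g. followed by a synchronised rebound) ends at its
    # minimum; a wide trough ends at the elbow where the sustained forward
    # slope flattens to within the tolerance.
    below = v < threshold
    k_first = trigger
    k_re = w.n_bins
    for k in range(k_first + 1, w.n_bins):
        if not below[k]:
            k_re = k
            break

    if k_re - k_first < end_slope:  # narrow trough
        end_idx = onset_idx + int(np.argmin(v[onset_idx:k_re]))
    else:
        slope_tol = cfg.end_slope_tol_frac * box.max_variation
        end_idx = None
        horizon = w.n_bins - end_slope
        for k in range(k_first, horizon):
            if v[k] >= threshold:
                continue
            good = True
            for j in range(k, min(k + end_run, horizon)):
                if v[j + end_slope] - v[j] < -slope_tol:
                    good = False
                    break
            if good:
                end_idx = k
                break
        if end_idx is None:
            end_idx = onset_idx + int(np.argmin(v[onset_idx:]))

    amplitude = float(v[onset_idx] - v[end_idx])
    return onset_idx, end_idx, amplitude


def detect_inhibition(psth_cusum: CusumTrace, psth_box: ErrorBox,
                      psf_cusum: CusumTrace, psf_box: ErrorBox,
                      prestim_rate_hz: float | None = None,
                      config: DetectorConfig | None = None,
                      ) -> InhibitionEstimate:
    """Combine PSTH-trough onset with PSF-trough end into one estimate.

    The response is genuine only when both traces contain a trough whose
    inflexion-to-inflexion amplitude exceeds that trace's own error box;
    absence of inhibition is a valid (undetected) result.
    """
    cfg = config or DetectorConfig()
    w = psth_cusum.window
    t_psth = _find_trough(psth_cusum, psth_box, cfg)
    t_psf = _find_trough(psf_cusum, psf_box, cfg)
    if t_psth is None or t_psf is None:
        return InhibitionEstimate(False, firing_rate_hz=prestim_rate_hz,
                                  detector=asdict(cfg))
    onset_idx, _, psth_amp = t_psth
    _, end_idx, psf_amp = t_psf
    onset_ms = float(w.edges_ms[onset_idx])
    end_ms = float(w.edges_ms[end_idx])
    if (psth_amp <= psth_box.max_variation or psf_amp <= psf_box.max_variation
            or end_ms <= onset_ms):
        return InhibitionEstimate(False, firing_rate_hz=prestim_rate_hz,
                                  detector=asdict(cfg))
    return InhibitionEstimate(True, onset_ms=onset_ms, end_ms=end_ms,
                              psth_amplitude=psth_amp, psf_amplitude=psf_amp,
                              firing_rate_hz=prestim_rate_hz,
                              detector=asdict(cfg))


def prestimulus_rate(psf: PeristimulusHistogram) -> float | None:
    """Mean instantaneous rate over the baseline window (same window as the
    error box); None when no baseline discharges carry a rate."""
    base = psf.window.baseline_slice
    chunks = [np.asarray(s) for s in psf.samples[base] if len(s)]
    if not chunks:
        return None
    return float(np.concatenate(chunks).mean())


def recruitment_threshold(train: SpikeTrain, spec: ProtocolSpec) -> float:
    """Common-drive value (a.u.) at the unit's first discharge during the
    ramp; errors if the unit never fires."""
    if not train.discharge_times_s:
        raise TooFewSpikesError(f"unit {train.unit_id} silent for entire record")
    return float(trapezoidal_drive(train.discharge_times_s[0], spec))


def analyze_train(train: SpikeTrain, stims: StimulusTimes,
                  window: AnalysisWindow | None = None,
                  config: DetectorConfig | None = None,
                  clean: bool = True) -> InhibitionEstimate:
    """Full per-unit pipeline: outlier removal, PSTH/PSF, CUSUM, detection."""
    raw = train
    if clean:
        train = clean_discharges(train)
    psth, psf = peristimulus_histograms(train, stims, window, rate_train=raw)
    psth_cusum, psth_box = cusum_with_errorbox(psth)
    psf_cusum, psf_box = cusum_with_errorbox(psf)
    return detect_inhibition(psth_cusum, psth_box, psf_cusum, psf_box,
                             prestimulus_rate(psf), config)


def plot_panels(psth: PeristimulusHistogram, psf: PeristimulusHistogram,
                estimate: InhibitionEstimate | None = None, path=None):
    """Optional PSTH/PSF panel figure with overlaid CUSUM traces.

    Requires matplotlib (the `plot` extra); returns the figure, and writes
    it to `path` (PNG/SVG by extension) when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w = psth.window
    centers = w.edges_ms[:-1] + w.bin_ms / 2.0
    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 6))

    axes[0].bar(centers, psth.counts, width=w.bin_ms, color="0.7")
    cus, _ = cusum_with_errorbox(psth)
    ax0 = axes[0].twinx()
    ax0.plot(centers, cus.values, color="tab:blue", lw=1.2)
    axes[0].set_ylabel("MU firings per bin")
    ax0.set_ylabel("PSTH-CUSUM", color="tab:blue")

    for k, samples in enumerate(psf.samples):
        if len(samples):
            axes[1].plot([centers[k]] * len(samples), samples, ".",
                         ms=2, color="0.6")
    cus, _ = cusum_with_errorbox(psf)
    ax1 = axes[1].twinx()
    ax1.plot(centers, cus.values, color="tab:blue", lw=1.2)
    axes[1].set_ylabel("instantaneous rate (pps)")
    axes[1].set_xlabel("time from stimulus (ms)")
    ax1.set_ylabel("PSF-CUSUM", color="tab:blue")

    if estimate is not None and estimate.detected:
        for ax in axes:
            ax.axvline(estimate.onset_ms, color="tab:red", ls="--", lw=1)
            ax.axvline(estimate.end_ms, color="tab:red", ls=":", lw=1)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
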