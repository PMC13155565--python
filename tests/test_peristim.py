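"""Outlier cleaning, PSTH/PSF construction, CUSUM and detection."""

import numpy as np
import pytest

from mnpool.peristim import (AnalysisWindow, DetectorConfig, TooFewSpikesError,
                             analyze_train, clean_discharges,
                             cusum_with_errorbox, detect_inhibition,
                             discharge_stats, peristimulus_histograms,
                             prestimulus_rate, recruitment_threshold,
                             PeristimulusHistogram)
from mnpool.protocol import ProtocolSpec, SpikeTrain, StimulusTimes


def _train(times, duration=None):
    times = tuple(np.round(np.asarray(times, float), 6))
    dur = duration if duration is not None else float(times[-1]) + 1.0
    return SpikeTrain("u1", times, dur, 2000.0)


class TestCleanDischarges:
    def test_regular_train_unchanged(self):
        tr = _train(np.arange(1, 21) * 0.1)
        out = clean_discharges(tr)
        assert out.discharge_times_s == tr.discharge_times_s

    def test_doublet_second_spike_removed(self):
        times = list(np.arange(1, 21) * 0.1)
        times.append(1.01)  # 10-ms ISI -> 100 pps
        tr = _train(sorted(times))
        out = clean_discharges(tr)
        assert 1.01 not in out.discharge_times_s
        assert out.n_spikes == tr.n_spikes - 1

    def test_post_gap_discharge_removed(self):
        # regular 10 pps with one 250-ms gap: the post-gap discharge sits at
        # 4 pps < 50% of the 10-pps median
        times = list(np.arange(0.1, 2.01, 0.1))
        times += list(np.arange(2.25, 4.0, 0.1))
        tr = _train(times)
        out = clean_discharges(tr)
        assert pytest.approx(2.25) not in out.discharge_times_s

    def test_too_few_spikes(self):
        with pytest.raises(TooFewSpikesError):
            clean_discharges(_train([0.1, 0.2]))


class TestDischargeStats:
    def test_regular_train_cov_zero(self):
        rate, cov, retained = discharge_stats(_train(np.arange(1, 31) * 0.1))
        assert rate == pytest.approx(10.0)
        assert cov == pytest.approx(0.0, abs=1e-9)
        assert retained

    def test_alternating_isi_rejected(self):
        # ISIs alternating 50/150 ms: CoV = 0.5
        t = [0.0]
        for k in range(30):
            t.append(t[-1] + (0.05 if k % 2 == 0 else 0.15))
        rate, cov, retained = discharge_stats(_train(t))
        assert cov == pytest.approx(0.5, abs=0.01)
        assert not retained

    def test_gamma_train_estimate_near_truth(self):
        from mnpool.synth import renewal_inhibited_train
        stims = StimulusTimes(())
        tr = renewal_inhibited_train(12.0, 0.2, 100.0, stims, None, seed=1)
        rate, cov, retained = discharge_stats(tr)
        assert cov == pytest.approx(0.2, abs=0.05)
        assert retained


class TestHistograms:
    STIMS = StimulusTimes(tuple(np.arange(1, 101) * 1.0))

    def test_single_latency_concentrates_one_bin(self):
        times = [s + 0.010 for s in self.STIMS.onsets_s]
        tr = _train(times, duration=self.STIMS.onsets_s[-1] + 1.0)
        psth, psf = peristimulus_histograms(tr, self.STIMS)
        k = psth.window.bin_of(10.0)
        assert psth.counts[k] == 100
        assert psth.counts.sum() == 100

    def test_requires_ten_stimuli(self):
        tr = _train(np.arange(1, 50) * 0.085)
        with pytest.raises(ValueError):
            peristimulus_histograms(tr, StimulusTimes((1.0, 2.0)))

    def test_psf_collects_instantaneous_rates(self):
        tr = _train(np.arange(0.1, 99.0, 0.1))
        psth, psf = peristimulus_histograms(tr, self.STIMS)
        rate = prestimulus_rate(psf)
        assert rate == pytest.approx(10.0, rel=0.01)


class TestCusum:
    def test_constant_histogram_is_flat_with_zero_box(self):
        w = AnalysisWindow()
        hist = PeristimulusHistogram("psth", w,
                                     counts=np.full(w.n_bins, 3, dtype=int))
        trace, box = cusum_with_errorbox(hist)
        np.testing.assert_allclose(trace.values, 0.0, atol=1e-9)
        assert box.max_variation == 0.0

    def test_dip_produces_linear_ramp(self):
        w = AnalysisWindow()
        counts = np.full(w.n_bins, 4, dtype=int)
        k0 = w.bin_of(50.0)
        depth = 3
        counts[k0:k0 + 50] -= depth
        hist = PeristimulusHistogram("psth", w, counts=counts)
        trace, box = cusum_with_errorbox(hist)
        # flat before the dip, linear decline of 50*depth across it
        assert trace.values[k0 - 1] == pytest.approx(0.0, abs=1e-9)
        assert trace.values[k0 + 49] == pytest.approx(-50 * depth, rel=1e-9)
        mid = trace.values[k0 + 24]
        assert mid == pytest.approx(-25 * depth, rel=1e-9)

    def test_blanked_interval_not_updated(self):
        rng = np.random.default_rng(0)
        w = AnalysisWindow()
        counts = rng.poisson(3, w.n_bins)
        hist = PeristimulusHistogram("psth", w, counts=counts)
        trace, _ = cusum_with_errorbox(hist)
        blank = w.blank_slice
        vals = trace.values[blank.start - 1: blank.stop]
        assert np.allclose(vals, vals[0])

    def test_partial_sum_identity(self):
        rng = np.random.default_rng(1)
        w = AnalysisWindow()
        counts = rng.poisson(2, w.n_bins)
        hist = PeristimulusHistogram("psth", w, counts=counts)
        trace, _ = cusum_with_errorbox(hist)
        base = w.baseline_slice
        baseline_mean = counts[base].mean()
        mask = np.ones(w.n_bins, bool)
        mask[w.blank_slice] = False
        expected = np.sum(counts[mask] - baseline_mean)
        assert trace.values[-1] == pytest.approx(expected, rel=1e-9)

    def test_empty_baseline_raises(self):
        w = AnalysisWindow()
        hist = PeristimulusHistogram("psf", w,
                                     samples=[np.array([])] * w.n_bins)
        with pytest.raises(ValueError):
            cusum_with_errorbox(hist)


class TestRecruitmentThreshold:
    SPEC = ProtocolSpec(ramp_up_s=2.0, plateau_s=10.0, ramp_down_s=2.0,
                        exc_amplitude=0.2)

    def test_ramp_midpoint_readout(self):
        tr = _train([1.0, 1.1, 1.2], duration=14.0)
        assert recruitment_threshold(tr, self.SPEC) == pytest.approx(0.1)

    def test_silent_unit_raises(self):
        tr = SpikeTrain("u1", (), 14.0, 2000.0)
        with pytest.raises(TooFewSpikesError):
            recruitment_threshold(tr, self.SPEC)

    def test_thresholds_increase_with_size(self):
        from mnpool.model import build_pool, default_pool_spec
        from mnpool.protocol import run_realization
        pool = build_pool(default_pool_spec(8))
        spec = ProtocolSpec(ramp_up_s=2.0, plateau_s=5.0, ramp_down_s=1.0,
                            inh_amplitude_A=0.0, noise_sd=0.0)
        trains, _, _ = run_realization(pool, spec)
        thr = [recruitment_threshold(tr, spec) for tr in trains]
        assert all(a <= b + 1e-9 for a, b in zip(thr, thr[1:]))


class TestDetection:
    def test_modulation_free_train_not_detected(self):
        from mnpool.synth import renewal_inhibited_train
        stims = StimulusTimes(tuple(np.arange(1, 301) * 1.8))
        tr = renewal_inhibited_train(12.0, 0.15, 545.0, stims, None, seed=7)
        est = analyze_train(tr, stims)
        assert not est.detected
        assert est.duration_ms is None

    def test_imposed_silence_recovered(self):
        from mnpool.synth import GroundTruthInhibition, renewal_inhibited_train
        stims = StimulusTimes(tuple(np.arange(1, 301) * 1.8))
        truth = GroundTruthInhibition(onset_ms=30.0, silent_ms=50.0,
                                      recovery_ms=0.0)
        tr = renewal_inhibited_train(12.0, 0.15, 545.0, stims, truth, seed=8)
        est = analyze_train(tr, stims)
        assert est.detected
        assert est.onset_ms == pytest.approx(30.0, abs=3.0)
        assert est.end_ms >= 80.0
        assert est.duration_ms >= 50.0
        assert est.psth_amplitude > 0
        assert est.psf_amplitude > 0

    def test_detector_parameters_carried_in_estimate(self):
        from mnpool.synth import renewal_inhibited_train
        stims = StimulusTimes(tuple(np.arange(1, 51) * 1.8))
        tr = renewal_inhibited_train(12.0, 0.15, 95.0, stims, None, seed=9)
        cfg = DetectorConfig(onset_run_ms=7.0)
        est = analyze_train(tr, stims, config=cfg)
        assert est.detector["onset_run_ms"] == 7.0


class TestPsfVersusPsthEnd:
    def test_psf_end_extends_beyond_psth_end_on_graded_troughs(self):
        """The PSF-CUSUM keeps falling while firing resumes below baseline,
        so the (PSTH onset, PSF end) duration is at least the PSTH-only
        duration on graded-depth fixtures."""
        from mnpool.peristim import (_find_trough, cusum_with_errorbox)
        from mnpool.synth import GroundTruthInhibition, renewal_inhibited_train
        cfg = DetectorConfig()
        stims = StimulusTimes(tuple(np.arange(1, 301) * 1.8))
        for seed in range(4):
            truth = GroundTruthInhibition(onset_ms=30.0, silent_ms=40.0,
                                          depth=0.5, recovery_ms=0.0)
            raw = renewal_inhibited_train(12.0, 0.15, 545.0, stims, truth,
                                          seed=seed)
            tr = clean_discharges(raw)
            psth, psf = peristimulus_histograms(tr, stims, rate_train=raw)
            ct, bt = cusum_with_errorbox(psth)
            cf, bf = cusum_with_errorbox(psf)
            t_psth = _find_trough(ct, bt, cfg)
            t_psf = _find_trough(cf, bf, cfg)
            assert t_psth is not None and t_psf is not None
            w = psth.window
            psf_dur = w.edges_ms[t_psf[1]] - w.edges_ms[t_psth[0]]
            psth_dur = w.edges_ms[t_psth[1]] - w.edges_ms[t_psth[0]]
            assert psf_dur >= psth_dur
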