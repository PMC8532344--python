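"""Evoked-potential pipeline: epoching geometry, baseline correction,
averaging statistics, pointwise group comparison, component detection
accuracy, and stimulus-locked firing probability."""

import logging

import numpy as np
import pytest

from pcsense import evoked, synthgen
from pcsense.core import (ContinuousTrace, DataError, EpochSet,
                          ParameterError, SpikeTrain)


def _epochs(n_trials=10, value=0.0, fs=25_000.0, noise=None, seed=0):
    n_samp = int(0.070 * fs)
    data = np.full((n_trials, n_samp), value)
    if noise is not None:
        data = data + np.random.default_rng(seed).normal(0, noise, data.shape)
    times_ms = (np.arange(n_samp) - int(0.020 * fs)) / fs * 1000.0
    return EpochSet(data, times_ms, fs)


class TestSegment:
    def test_shape_at_25khz(self):
        fs = 25_000.0
        trace = ContinuousTrace(np.zeros(int(12 * fs)), fs)
        stim = 0.1 + 0.1 * np.arange(100)
        epochs = evoked.segment(trace, stim)
        assert epochs.data.shape == (100, 1750)
        assert epochs.times_ms[0] == -20.0
        assert epochs.times_ms[-1] < 50.0

    def test_truncated_window_dropped(self, caplog):
        fs = 25_000.0
        trace = ContinuousTrace(np.zeros(int(fs)), fs)
        with caplog.at_level(logging.WARNING):
            epochs = evoked.segment(trace, np.array([0.010, 0.5]))
        assert epochs.n_trials == 1
        assert "dropped" in caplog.text

    def test_empty_stimuli(self):
        trace = ContinuousTrace(np.zeros(1000), 25_000.0)
        epochs = evoked.segment(trace, np.empty(0))
        assert epochs.n_trials == 0


class TestBaselineCorrect:
    def test_constant_epoch_becomes_zero(self):
        epochs = _epochs(value=5.0)
        out = evoked.baseline_correct(epochs)
        assert np.max(np.abs(out.data)) < 1e-12

    def test_prestim_mean_zero(self):
        epochs = _epochs(noise=3.0)
        out = evoked.baseline_correct(epochs)
        pre = out.data[:, out.pre_mask]
        assert np.max(np.abs(pre.mean(axis=1))) < 1e-12

    def test_idempotent(self):
        epochs = _epochs(noise=3.0)
        once = evoked.baseline_correct(epochs)
        twice = evoked.baseline_correct(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_commutes_with_constant_offset(self):
        # segment + baseline_correct is invariant to adding any constant
        fs = 25_000.0
        rng = np.random.default_rng(1)
        raw = rng.normal(0, 5, int(3 * fs))
        stim = np.array([0.5, 1.2, 2.0])
        a = evoked.baseline_correct(evoked.segment(ContinuousTrace(raw, fs), stim))
        b = evoked.baseline_correct(
            evoked.segment(ContinuousTrace(raw + 123.4, fs), stim))
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)


class TestAverageSep:
    def test_identical_epochs(self):
        epochs = _epochs(n_trials=7, value=2.5)
        mean, sem = evoked.average_sep(epochs)
        assert np.all(mean == 2.5)
        assert np.all(sem == 0.0)

    def test_single_epoch_sem_undefined(self):
        epochs = _epochs(n_trials=1, value=1.0)
        mean, sem = evoked.average_sep(epochs)
        assert np.all(mean == 1.0)
        assert np.all(np.isnan(sem))

    def test_residual_scales_with_sqrt_n(self):
        # mean-vs-template residual RMS halves per 4x trials (CLT)
        tpl = synthgen.SEPTemplate(noise_sd=10.0, n_trials=160,
                                   inter_stim_s=0.1, jitter_s=0.0)
        trace, stim = synthgen.gen_sep_session(tpl, seed=2)
        clean, _ = synthgen.gen_sep_session(
            synthgen.SEPTemplate(noise_sd=0.0, n_trials=160, inter_stim_s=0.1,
                                 jitter_s=0.0), seed=2)
        noisy_ep = evoked.segment(trace, stim)
        clean_ep = evoked.segment(clean, stim)
        template = clean_ep.data[0]
        rms = []
        for n in (10, 40, 160):
            sub = noisy_ep.data[:n].mean(axis=0)
            rms.append(np.sqrt(np.mean((sub - template) ** 2)))
        assert rms[0] / rms[1] == pytest.approx(2.0, rel=0.35)
        assert rms[1] / rms[2] == pytest.approx(2.0, rel=0.35)

    def test_empty_raises(self):
        with pytest.raises(DataError):
            evoked.average_sep(_epochs(n_trials=0))


class TestCompareSeps:
    def _animal_means(self, template, n_animals, seed0):
        means = []
        for s in range(n_animals):
            trace, stim = synthgen.gen_sep_session(template, seed=seed0 + s)
            ep = evoked.baseline_correct(evoked.segment(trace, stim))
            means.append(evoked.average_sep(ep)[0])
        return means

    def test_null_fraction_near_alpha(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (6, 2000))
        b = rng.normal(0, 1, (9, 2000))
        times = np.arange(2000) * 0.04 - 20.0
        p, _ = evoked.compare_seps(a, b, times)
        assert 0.02 < np.mean(p < 0.05) < 0.09

    def test_missing_component_span_detected(self):
        wt = synthgen.SEPTemplate(noise_sd=2.0, n_trials=10, inter_stim_s=0.1,
                                  jitter_s=0.0)
        ko = synthgen.SEPTemplate(
            components=((3.94, -80.0, 1.5),),  # late component removed
            noise_sd=2.0, n_trials=10, inter_stim_s=0.1, jitter_s=0.0)
        means_a = self._animal_means(wt, 5, 10)
        means_b = self._animal_means(ko, 5, 40)
        times = evoked.segment(
            synthgen.gen_sep_session(wt, seed=99)[0],
            synthgen.gen_sep_session(wt, seed=99)[1]).times_ms
        _, spans = evoked.compare_seps(means_a, means_b, times)
        covers = [s for s in spans if s[0] <= 12.87 <= s[1]]
        assert covers, f"no span covers the removed 12.87-ms component: {spans}"

    def test_identical_groups_no_significance(self):
        base = np.tile(np.sin(np.linspace(0, 3, 500)), (3, 1))
        times = np.linspace(-20, 49.9, 500)
        p, spans = evoked.compare_seps(base, base, times)
        assert np.all(p == 1.0)
        assert spans == []

    def test_too_few_animals(self):
        with pytest.raises(ParameterError):
            evoked.compare_seps([np.zeros(10)], [np.zeros(10)] * 3,
                                np.arange(10, dtype=float))


class TestDetectComponents:
    def _session_components(self, template, seed=0):
        trace, stim = synthgen.gen_sep_session(template, seed=seed)
        ep = evoked.baseline_correct(evoked.segment(trace, stim))
        mean, _ = evoked.average_sep(ep)
        noise = float(ep.data[:, ep.pre_mask].std())
        return evoked.detect_components(mean, ep.times_ms, noise)

    def test_noiseless_wt_template(self):
        tpl = synthgen.wt_sep_template(noise_sd=0.0, n_trials=5,
                                       inter_stim_s=0.1, jitter_s=0.0)
        comps = self._session_components(tpl)
        lats = [c.latency_ms for c in comps]
        assert len(lats) == 2
        assert abs(lats[0] - 3.94) <= 0.04 + 1e-9   # one sample at 25 kHz
        assert abs(lats[1] - 12.87) <= 0.04 + 1e-9

    def test_noiseless_ko_template(self):
        tpl = synthgen.ko_sep_template(noise_sd=0.0, n_trials=5,
                                       inter_stim_s=0.1, jitter_s=0.0)
        comps = self._session_components(tpl)
        lats = [c.latency_ms for c in comps]
        assert len(lats) == 2
        assert abs(lats[0] - 4.10) <= 0.04 + 1e-9
        assert abs(lats[1] - 6.46) <= 0.04 + 1e-9

    def test_pure_noise_empty(self):
        tpl = synthgen.SEPTemplate(components=(), noise_sd=5.0, n_trials=30,
                                   inter_stim_s=0.1, jitter_s=0.0)
        comps = self._session_components(tpl, seed=5)
        assert comps == []

    @pytest.mark.parametrize("lat", [2.0, 7.5, 19.0, 33.3, 48.0])
    def test_single_component_latency_error_one_sample(self, lat):
        tpl = synthgen.SEPTemplate(components=((lat, -80.0, 1.5),),
                                   noise_sd=0.0, n_trials=3,
                                   inter_stim_s=0.15, jitter_s=0.0)
        comps = self._session_components(tpl)
        assert len(comps) == 1
        assert abs(comps[0].latency_ms - lat) <= 0.04 + 1e-9


class TestComputePsth:
    def test_deterministic_cs_bin(self):
        stim = 0.5 + np.arange(20) * 0.5
        cs = SpikeTrain(stim + 0.0135, 11.0, "CS")
        psth = evoked.compute_psth([cs], stim)
        centers = psth.bin_centers_ms
        assert psth.probs[0, np.flatnonzero(centers == 13.5)[0]] == 1.0
        assert psth.probs[0].sum() == 1.0  # nothing else fires

    def test_poisson_occupancy(self):
        train = synthgen.gen_spike_train(50.0, 1.0, 600.0, seed=4)
        stim = 1.0 + np.arange(500) * 1.0
        psth = evoked.compute_psth([train], stim)
        expected = 1.0 - np.exp(-0.05)
        assert abs(psth.probs.mean() - expected) < 0.01

    def test_zero_stimuli_raises(self):
        train = SpikeTrain(np.array([1.0]), 2.0)
        with pytest.raises(ParameterError):
            evoked.compute_psth([train], np.empty(0))

    def test_merged_superadditive(self):
        # occupancy of SS+CS merged >= elementwise max of separate PSTHs
        rec = synthgen.gen_pc_recording(synthgen.PCParams(duration=100.0), seed=6)
        stim = 2.0 + np.arange(90) * 1.0
        ss = evoked.compute_psth([rec.ss], stim).probs[0]
        cs = evoked.compute_psth([rec.cs], stim).probs[0]
        merged_times = np.sort(np.concatenate([rec.ss.times, rec.cs.times]))
        merged = evoked.compute_psth(
            [SpikeTrain(merged_times, 100.0)], stim).probs[0]
        assert np.all(merged >= np.maximum(ss, cs) - 1e-12)


class TestComparePsth:
    def _group_psth(self, latency_ms, n_neurons, seed0, cs_prob=0.8):
        trains = []
        stim = None
        for s in range(n_neurons):
            tpl = synthgen.EvokedCSTemplate(
                cs_latency_ms=latency_ms, cs_latency_sd_ms=0.5, cs_prob=cs_prob,
                baseline=synthgen.PCParams(cs_rate=0.5))
            ses = synthgen.gen_evoked_spikes(tpl, 40, seed=seed0 + s,
                                             inter_stim_s=0.5, jitter_s=0.0)
            trains.append(ses.cs)
            stim = ses.stim_times
        return evoked.compute_psth(trains, stim, label="CS")

    def test_duplicated_neurons_f_between_zero(self):
        psth = self._group_psth(13.0, 3, 100)
        res = evoked.compare_psth(psth, psth)
        assert res["anova"].f_between == pytest.approx(0.0, abs=1e-12)

    def test_latency_shift_detected(self):
        a = self._group_psth(13.0, 8, 200)
        b = self._group_psth(6.5, 8, 300)
        res = evoked.compare_psth(a, b)
        assert res["anova"].p_interaction < 0.001
        sig_bins = res["bin_centers_ms"][res["reject"]]
        assert np.any(np.abs(sig_bins - 13.0) <= 2.0)
        assert np.any(np.abs(sig_bins - 6.5) <= 2.0)

    def test_mismatched_bins_rejected(self):
        a = self._group_psth(13.0, 2, 400)
        b = evoked.PSTH(a.bin_edges_ms[:-1], a.probs[:, :-1])
        with pytest.raises(ParameterError):
            evoked.compare_psth(a, b)
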