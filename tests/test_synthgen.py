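"""Generator contracts: renewal statistics, pause enforcement, template
placement, membrane physics and tree geometry, plus seeded reproducibility."""

import numpy as np
import pytest
from scipy import stats as sps

from pcsense import evoked, morphology, synthgen
from pcsense.core import ParameterError


class TestGenSpikeTrain:
    def test_regular_limit(self):
        st = synthgen.gen_spike_train(50, 0.01, 1.0, seed=0)
        assert 40 <= st.n_spikes <= 60
        isis = st.isis
        assert isis.std() / isis.mean() < 0.05

    def test_sample_cv_matches_request(self):
        st = synthgen.gen_spike_train(50, 0.5, 200.0, seed=1)
        isis = st.isis
        assert abs(isis.std() / isis.mean() - 0.5) < 0.05

    def test_poisson_count_band(self):
        # cv=1 gamma renewal is a Poisson process; 99% band around 100
        lo, hi = sps.poisson.ppf([0.005, 0.995], 100)
        st = synthgen.gen_spike_train(1.0, 1.0, 100.0, seed=2)
        assert lo <= st.n_spikes <= hi

    def test_times_strictly_increasing_in_range(self):
        st = synthgen.gen_spike_train(80, 0.7, 50.0, seed=3)
        assert np.all(np.diff(st.times) > 0)
        assert st.times[0] >= 0 and st.times[-1] < 50.0

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (50, 0, 1), (50, 1, 0)])
    def test_parameter_errors(self, bad):
        with pytest.raises(ParameterError):
            synthgen.gen_spike_train(*bad, seed=0)

    def test_cv_converges_long_duration(self):
        # long-run convergence of the sample CV to the requested value
        st = synthgen.gen_spike_train(50, 0.5, 500.0, seed=4)
        isis = st.isis
        assert abs(isis.std() / isis.mean() - 0.5) < 0.03

    def test_seeded_reproducibility(self):
        a = synthgen.gen_spike_train(50, 0.5, 10.0, seed=7)
        b = synthgen.gen_spike_train(50, 0.5, 10.0, seed=7)
        np.testing.assert_array_equal(a.times, b.times)


class TestGenPCRecording:
    def test_cs_rate_zero_gives_ss_only(self):
        rec = synthgen.gen_pc_recording(synthgen.PCParams(cs_rate=0.0), seed=0)
        assert rec.cs.n_spikes == 0
        assert rec.ss.n_spikes > 0

    def test_pause_enforced_by_construction(self):
        rec = synthgen.gen_pc_recording(
            synthgen.PCParams(cs_rate=1.0, cs_pause=0.015, duration=100.0), seed=1)
        for cs in rec.cs.times:
            after = rec.ss.times[(rec.ss.times > cs)]
            if after.size:
                assert after[0] - cs > 0.015

    def test_deletion_expectation(self):
        # expected SS loss rate ~ cs_rate * cs_pause * ss_rate
        params = synthgen.PCParams(ss_rate=60, cs_rate=1.0, cs_pause=0.015,
                                   duration=100.0)
        deficits = []
        for seed in range(20):
            rec = synthgen.gen_pc_recording(params, seed=seed)
            deficits.append(params.ss_rate - rec.ss.rate)
        expected = params.cs_rate * params.cs_pause * params.ss_rate  # 0.9 Hz
        assert abs(np.mean(deficits) - expected) < 0.25

    def test_ground_truth_retained(self):
        rec = synthgen.gen_pc_recording(synthgen.PCParams(duration=50.0), seed=2)
        assert rec.truth["n_ss_deleted"] == \
            rec.truth["ss_times_raw"].size - rec.ss.n_spikes
        np.testing.assert_array_equal(rec.truth["cs_times"], rec.cs.times)


class TestGenSepSession:
    def test_noiseless_minimum_at_component_latency(self, fast_sep_kwargs):
        tpl = synthgen.SEPTemplate(components=((10.0, -100.0, 1.0),),
                                   noise_sd=0.0, n_trials=20, **fast_sep_kwargs)
        trace, stim = synthgen.gen_sep_session(tpl, seed=0)
        for s in stim:
            lo = int((s - 0.005) * tpl.fs)
            hi = int((s + 0.030) * tpl.fs)
            tmin = np.argmin(trace.data[lo:hi]) + lo
            assert abs(tmin / tpl.fs - (s + 0.010)) <= 1.0 / tpl.fs

    def test_noiseless_average_recovers_template(self):
        # with stimuli on the sample grid (no jitter) every noise-free epoch
        # is identical, and the average matches the analytic template
        tpl = synthgen.wt_sep_template(noise_sd=0.0, n_trials=8,
                                       inter_stim_s=0.2, jitter_s=0.0)
        trace, stim = synthgen.gen_sep_session(tpl, seed=1)
        epochs = evoked.segment(trace, stim)
        mean, _ = evoked.average_sep(epochs)
        assert np.max(np.abs(mean - epochs.data[0])) < 1e-9
        sigma = 1.5 / (2 * np.sqrt(2 * np.log(2)))
        analytic = sum(-80.0 * np.exp(-0.5 * ((epochs.times_ms - lat) / sigma) ** 2)
                       for lat in (3.94, 12.87))
        # generator truncates each bump at 5 sigma -> sub-1e-3 uV tails
        assert np.max(np.abs(mean - analytic)) < 1e-3

    def test_zero_trials(self):
        tpl = synthgen.SEPTemplate(n_trials=0, noise_sd=1.0)
        trace, stim = synthgen.gen_sep_session(tpl, seed=2)
        assert stim.size == 0
        assert trace.n_samples > 0

    def test_latency_outside_window_rejected(self):
        with pytest.raises(ParameterError):
            synthgen.SEPTemplate(components=((55.0, -80.0, 1.5),))


class TestGenEvokedSpikes:
    def test_deterministic_latency(self):
        tpl = synthgen.EvokedCSTemplate(cs_latency_ms=13.0, cs_latency_sd_ms=0.0,
                                        cs_prob=1.0,
                                        baseline=synthgen.PCParams(cs_rate=0.0))
        ses = synthgen.gen_evoked_spikes(tpl, 20, seed=0, inter_stim_s=0.5,
                                         jitter_s=0.0)
        for s in ses.stim_times:
            assert np.any(np.abs(ses.cs.times - (s + 0.013)) < 1e-9)

    def test_prob_zero_no_locking(self):
        tpl = synthgen.EvokedCSTemplate(cs_prob=0.0)
        ses = synthgen.gen_evoked_spikes(tpl, 50, seed=1, inter_stim_s=0.5,
                                         jitter_s=0.0)
        assert ses.truth["evoked_cs_times"].size == 0

    def test_binomial_fraction(self):
        tpl = synthgen.EvokedCSTemplate(cs_latency_ms=13.0, cs_latency_sd_ms=0.5,
                                        cs_prob=0.5,
                                        baseline=synthgen.PCParams(cs_rate=0.0))
        ses = synthgen.gen_evoked_spikes(tpl, 200, seed=2, inter_stim_s=0.5,
                                         jitter_s=0.0)
        hit = 0
        for s in ses.stim_times:
            win = (ses.cs.times > s + 0.013 - 3 * 0.0005) & \
                  (ses.cs.times < s + 0.013 + 3 * 0.0005)
            hit += int(win.any())
        frac = hit / 200
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 200)


class TestGenPatchSweeps:
    def test_subthreshold_step_no_aps(self):
        cell = synthgen.make_cell(600.0)
        proto = synthgen.StepProtocol(steps_pA=(300.0,))
        sweeps = synthgen.gen_patch_sweeps(cell, proto)
        assert np.max(sweeps.sweeps[0].vm) < cell.v_thresh + 1e-6

    def test_ohmic_deflection(self):
        # -100 pA into 100 MOhm deflects -10 mV at steady state
        cell = synthgen.PatchCellParams(r_in=100.0, c_m=200.0)
        proto = synthgen.StepProtocol(steps_pA=(-100.0,))
        sw = synthgen.gen_patch_sweeps(cell, proto).sweeps[0]
        i0 = int((sw.onset_s + sw.dur_s) * sw.fs) - 10
        assert abs((sw.vm[i0] - cell.v_rest) - (-10.0)) < 0.05

    def test_first_firing_step_quantized(self):
        cell = synthgen.make_cell(200.0)
        proto = synthgen.StepProtocol(steps_pA=(75.0, 150.0, 225.0, 300.0))
        sweeps = synthgen.gen_patch_sweeps(cell, proto)
        fired = [sw.step_pA for sw in sweeps if np.max(sw.vm) > 0]
        assert fired[0] == 225.0

    def test_rheobase_identity(self):
        # ground-truth rheobase equals (v_thresh - v_rest)/r_in
        cell = synthgen.make_cell(412.0)
        assert abs(cell.rheobase_pA - 412.0) < 1e-9

    def test_seeded_noise_reproducible(self):
        cell = synthgen.make_cell(300.0)
        proto = synthgen.StepProtocol(steps_pA=(150.0, 375.0))
        a = synthgen.gen_patch_sweeps(cell, proto, seed=5, noise_sd_mV=0.3)
        b = synthgen.gen_patch_sweeps(cell, proto, seed=5, noise_sd_mV=0.3)
        np.testing.assert_array_equal(a.sweeps[1].vm, b.sweeps[1].vm)


class TestGenMorphology:
    def test_unbranched_sholl_all_one(self):
        params = synthgen.TreeParams(apical_extent=80.0, branch_prob=0.0)
        m, _ = synthgen.gen_morphology(params, seed=0)
        profile = morphology.sholl(m, step=5.0)
        assert np.all(profile.intersections == 1)
        assert profile.radii_um[-1] <= 80.0

    def test_farthest_node_is_extent(self):
        params = synthgen.TreeParams(apical_extent=80.0, branch_prob=0.3)
        m, _ = synthgen.gen_morphology(params, seed=1)
        assert abs(morphology.apical_length(m) - 80.0) <= params.segment_len

    def test_spine_poisson_mean(self):
        params = synthgen.TreeParams(spine_density=2.3)
        counts = [len(synthgen.gen_morphology(params, seed=s)[1])
                  for s in range(200)]
        mean = np.mean(counts)
        # Poisson(23): SE of the mean over 200 seeds ~ sqrt(23/200) ~ 0.34
        assert abs(mean - 23.0) < 4 * np.sqrt(23.0 / 200)

    def test_seeded_reproducibility(self):
        params = synthgen.TreeParams()
        m1, s1 = synthgen.gen_morphology(params, seed=9)
        m2, s2 = synthgen.gen_morphology(params, seed=9)
        np.testing.assert_array_equal(m1.xyz, m2.xyz)
        np.testing.assert_array_equal(s1["arc_pos_um"], s2["arc_pos_um"])
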