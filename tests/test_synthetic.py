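from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from neuroexhaust import synth
from neuroexhaust.ccfeatures import detect_aps, extract_features
from neuroexhaust.trace_io import ClampMode, build_step_protocol


def _single_step_cc(level, step_s=2.0, sr=20_000.0):
    return build_step_protocol(level, level, 5.0, step_duration=step_s,
                               pre_duration=0.25, post_duration=0.25,
                               sampling_rate=sr)


class TestCurrentClampSim:
    def test_zero_injection_settles_at_rest_without_spikes(self):
        rec = synth.simulate_current_clamp(
            synth.ARCHETYPES["T3-control"], _single_step_cc(0.0), seed=0)
        v = rec.sweeps[0]
        assert rec.metadata["truth"]["spike_counts"] == [0]
        # equilibrium: the whole sweep stays within 1 mV of its final value
        assert np.ptp(v) < 1.0
        assert -70.0 < v[-1] < -60.0

    def test_rho_zero_never_spikes(self, cc_protocol):
        rec = synth.simulate_current_clamp(
            replace(synth.ARCHETYPES["T3-control"], rho=0.0),
            cc_protocol, seed=0)
        assert all(c == 0 for c in rec.metadata["truth"]["spike_counts"])

    def test_control_fires_trains_and_truth_matches_detection(self, control_cc):
        counts = control_cc.metadata["truth"]["spike_counts"]
        assert counts[-1] >= 5  # +60 pA step
        detected = [len(detect_aps(s, control_cc.sampling_rate))
                    for s in control_cc.sweeps]
        assert detected == counts

    def test_control_spike_count_monotone_in_current(self, control_cc):
        counts = control_cc.metadata["truth"]["spike_counts"]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_deterministic_given_seed(self):
        proto = _single_step_cc(30.0, step_s=0.5)
        a = synth.simulate_current_clamp(synth.ARCHETYPES["T3-control"],
                                         proto, seed=9)
        b = synth.simulate_current_clamp(synth.ARCHETYPES["T3-control"],
                                         proto, seed=9)
        np.testing.assert_array_equal(a.sweeps[0], b.sweeps[0])

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            synth.simulate_current_clamp(synth.ARCHETYPES["T3-control"],
                                         _single_step_cc(0.0), dt_ms=0.1)

    def test_conductance_free_membrane_integrates_linearly(self):
        # with every conductance zero, V ramps at exactly I/C_m
        p = synth.NeuronParams(g_na=0.0, g_k=0.0, g_l=0.0, rho=0.0,
                               c_m=30.0)
        proto = _single_step_cc(3.0, step_s=0.5)
        rec = synth.simulate_current_clamp(p, proto, seed=0)
        v = rec.sweeps[0]
        sr = rec.sampling_rate
        i0 = int(proto.step_onset * sr)
        i1 = int(proto.step_offset * sr)
        t = (np.arange(i1 - i0)) / sr * 1000.0  # ms into step
        expected = v[i0] + 3.0 / 30.0 * t       # pA/pF = mV/ms
        np.testing.assert_allclose(v[i0:i1], expected, atol=1e-6)


class TestVoltageClampSim:
    def test_step_to_sodium_reversal_gives_no_sodium_current(self):
        # with only the Na conductance, clamping at E_Na yields zero current
        p = synth.NeuronParams(g_k=0.0, g_l=0.0)
        proto = build_step_protocol(55.0, 55.0, 5.0, step_duration=0.2,
                                    pre_duration=0.05, post_duration=0.05,
                                    mode=ClampMode.VOLTAGE_CLAMP,
                                    holding_level=-80.0)
        rec = synth.simulate_voltage_clamp(p, proto)
        sr = rec.sampling_rate
        step = rec.sweeps[0][int(0.05 * sr):int(0.25 * sr)]
        assert np.max(np.abs(step)) < 1e-9

    def test_rho_zero_gives_zero_peak_inward(self):
        rec = synth.simulate_voltage_clamp(
            replace(synth.ARCHETYPES["T3-control"], rho=0.0))
        peaks = rec.metadata["truth"]["peak_inward_pa"]
        assert all(abs(p) < 1.0 for p in peaks)

    def test_peak_inward_proportional_to_rho(self):
        proto = synth.default_vc_protocol()
        a = synth.simulate_voltage_clamp(synth.NeuronParams(rho=1.0), proto)
        b = synth.simulate_voltage_clamp(synth.NeuronParams(rho=0.5), proto)
        ratio = (min(a.metadata["truth"]["peak_inward_pa"])
                 / min(b.metadata["truth"]["peak_inward_pa"]))
        assert ratio == pytest.approx(2.0, rel=0.02)


class TestEPSCSim:
    def test_zero_rate_gives_pure_noise_and_empty_truth(self):
        plan = synth.EPSCPlan(duration_s=5.0, rate_hz=0.0,
                              noise_sigma_pa=2.0, seed=3)
        rec, truth = synth.simulate_epsc_trace(plan)
        assert len(truth) == 0
        tr = rec.sweeps[0]
        assert abs(tr.mean()) < 0.2
        assert tr.std() == pytest.approx(2.0, rel=0.1)

    def test_event_count_follows_poisson_law(self):
        # low sampling rate keeps this cheap; the count is what matters
        counts = []
        for seed in range(100):
            plan = synth.EPSCPlan(duration_s=120.0, rate_hz=1.0,
                                  noise_sigma_pa=0.0, sampling_rate=2000.0,
                                  seed=seed)
            _, truth = synth.simulate_epsc_trace(plan)
            counts.append(len(truth))
        mean = np.mean(counts)
        # mean of 100 Poisson(120) draws: SE ~ 1.1
        assert mean == pytest.approx(120.0, abs=4.0)
        assert np.var(counts) == pytest.approx(120.0, rel=0.5)

    def test_noiseless_event_peak_matches_amplitude(self):
        plan = synth.EPSCPlan(duration_s=4.0, rate_hz=0.5, amp_sigma_ln=1e-9,
                              amp_mean_pa=50.0, noise_sigma_pa=0.0, seed=8)
        rec, truth = synth.simulate_epsc_trace(plan)
        assert len(truth) >= 1
        if len(truth) == 1:  # no overlap: minimum is exactly -amplitude
            assert rec.sweeps[0].min() == pytest.approx(-50.0, rel=1e-3)
        assert rec.sweeps[0].min() <= -50.0 * 0.999

    def test_trace_is_deterministic(self):
        plan = synth.EPSCPlan(duration_s=2.0, seed=4)
        a, ta = synth.simulate_epsc_trace(plan)
        b, tb = synth.simulate_epsc_trace(plan)
        np.testing.assert_array_equal(a.sweeps[0], b.sweeps[0])
        pd.testing.assert_frame_equal(ta, tb)


class TestCohort:
    def test_counts_and_labels(self, small_cohort):
        recs, truth = small_cohort
        assert len(recs) == 12
        assert truth.label.value_counts().to_dict() == {
            "T1": 4, "T2": 4, "T3-control": 4}

    def test_same_seed_reproduces(self):
        plan = synth.standard_cohort_plan({"T1": 2}, seed=3)
        proto = _single_step_cc(60.0, step_s=0.5)
        a, _ = synth.generate_cohort(plan, proto)
        b, _ = synth.generate_cohort(plan, proto)
        np.testing.assert_array_equal(a[0].sweeps[0], b[0].sweeps[0])

    def test_t1_archetype_never_fires(self, small_cohort):
        recs, truth = small_cohort
        for rec, label in zip(recs, truth.label):
            if label == "T1":
                assert sum(rec.metadata["truth"]["spike_counts"]) == 0

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            synth.CohortPlan(archetypes=(), seed=0)


class TestAttenuationMechanism:
    def test_slower_recovery_and_lower_rho_worsen_attenuation(self,
                                                              cc_protocol):
        # 3-point grids in the amplitude-sensitive regime
        base = replace(synth.ARCHETYPES["T3-control"], rho=0.5)
        tol = 5e-3  # sampling-grid jitter on peak amplitudes
        att_tau = []
        for tau in (1000.0, 2000.0, 4000.0):
            rec = synth.simulate_current_clamp(replace(base, tau_s=tau),
                                               cc_protocol, seed=2)
            att_tau.append(extract_features(rec)["attenuation_ratio"])
        assert all(b <= a + tol for a, b in zip(att_tau, att_tau[1:]))
        att_rho = []
        for rho in (1.0, 0.7, 0.5):
            rec = synth.simulate_current_clamp(
                replace(synth.ARCHETYPES["T3-control"], rho=rho),
                cc_protocol, seed=2)
            att_rho.append(extract_features(rec)["attenuation_ratio"])
        assert all(b <= a + tol for a, b in zip(att_rho, att_rho[1:]))


class TestMIDPanel:
    def test_symmetric_split_gives_equal_citrate_isotopologues(self):
        plan = synth.TracingPlan(f_red=0.5, dilution=0.0, n_replicates=1)
        table, truth = synth.generate_mid_panel(plan)
        cit = table[table.metabolite == "citrate"].set_index("isotopologue")
        assert cit.loc[5, "fraction"] == cit.loc[4, "fraction"]

    def test_full_dilution_is_unlabelled(self):
        plan = synth.TracingPlan(f_red=0.5, dilution=1.0, n_replicates=1)
        table, _ = synth.generate_mid_panel(plan)
        m0 = table[table.isotopologue == 0]
        assert np.allclose(m0.fraction, 1.0)
        assert np.allclose(table[table.isotopologue > 0].fraction, 0.0)

    def test_single_turn_split_arithmetic(self):
        # f_red = 0.6 with half dilution: malate M+3 = 0.30, M+4 = 0.20
        mid = synth.single_turn_mid("malate", f_red=0.6, dilution=0.5)
        assert mid[3] == pytest.approx(0.30)
        assert mid[4] == pytest.approx(0.20)
        assert mid[0] == pytest.approx(0.50)

    @pytest.mark.parametrize("noise", [0.0, 0.02])
    def test_fractions_sum_to_one(self, noise):
        plan = synth.TracingPlan(f_red=0.3, dilution=0.2, n_replicates=4,
                                 noise_sigma=noise, seed=7)
        table, _ = synth.generate_mid_panel(plan)
        sums = table.groupby(["sample", "metabolite"]).fraction.sum()
        np.testing.assert_allclose(sums.values, 1.0, atol=1e-9)
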