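import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fepsp.contributions import slice_contributions
from fepsp.features import extract_features
from fepsp.io import TraceMeta
from fepsp.protocol import ProtocolSpec
from fepsp.synth import (CalibrationError, CalibrationTargets, PRESETS,
                         SynthParams, biexp_kernel, biexp_peak_time,
                         calibrate_preset, cohort_spec, gating_envelope,
                         get_preset, io_curve_calibrate, noiseless_response,
                         pipeline_measurements, simulate_cohort,
                         simulate_slice_recording, simulate_sweep)

from conftest import noiseless


class TestBiexpKernel:
    def test_zero_at_origin_and_unit_peak(self):
        assert biexp_kernel(0.0, 0.5, 2.0) == 0.0
        t_star = biexp_peak_time(0.5, 2.0)
        assert biexp_kernel(t_star, 0.5, 2.0) == pytest.approx(1.0)

    def test_peak_location_closed_form(self):
        # tau 0.5/2 ms -> stationary point at 0.924 ms, cross-checked by a
        # fine-grid argmax of the kernel itself
        t_star = biexp_peak_time(0.5, 2.0)
        assert t_star == pytest.approx(0.924, abs=5e-4)
        grid = np.arange(0, 10, 1e-4)
        assert grid[np.argmax(biexp_kernel(grid, 0.5, 2.0))] == \
            pytest.approx(t_star, abs=1e-3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(tau_rise=st.floats(0.05, 10.0),
           ratio=st.floats(1.1, 50.0))
    def test_normalisation_any_taus(self, tau_rise, ratio):
        tau_decay = tau_rise * ratio
        t_star = biexp_peak_time(tau_rise, tau_decay)
        assert biexp_kernel(t_star, tau_rise, tau_decay) == pytest.approx(1.0)
        grid = np.linspace(0, 20 * tau_decay, 2000)
        assert np.max(biexp_kernel(grid, tau_rise, tau_decay)) <= 1.0 + 1e-9

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            biexp_kernel(1.0, 2.0, 2.0)


class TestGatingEnvelope:
    def test_inactive_is_identity(self):
        t = np.linspace(-5, 100, 200)
        np.testing.assert_array_equal(
            gating_envelope(t, 3.0, 1.0, 0.2, active=False), np.ones_like(t))

    def test_midpoint_and_floor(self):
        assert gating_envelope(3.0, 3.0, 1.0, 0.0) == pytest.approx(0.5)
        assert gating_envelope(3.0, 3.0, 1.0, 0.2) == pytest.approx(0.6)
        assert gating_envelope(1e3, 3.0, 1.0, 0.2) == pytest.approx(0.2)

    def test_monotone_non_increasing(self):
        t = np.linspace(-10, 120, 5000)
        g = gating_envelope(t, 3.0, 2.0, 0.1)
        assert np.all(np.diff(g) <= 1e-12)
        assert np.all((g >= 0.1 - 1e-12) & (g <= 1.0 + 1e-12))

    def test_ten_ninety_width(self):
        lo, hi = 0.0, 0.3
        span = gating_envelope(np.linspace(0, 10, 100001), 5.0, 2.0, 0.0)
        t = np.linspace(0, 10, 100001)
        t10 = t[np.argmax(span <= 0.9)]
        t90 = t[np.argmax(span <= 0.1)]
        assert t90 - t10 == pytest.approx(2.0, rel=1e-3)


class TestSimulateSweep:
    def test_blockade_equivalence(self, control_params):
        # with NMDA receptors blocked the NMDA amplitude is irrelevant
        a = simulate_sweep(control_params, "gaba_nmda_block")
        b = simulate_sweep(replace(control_params, a_nmda_mV=0.0), "gaba_block")
        np.testing.assert_allclose(a.voltage_mV, b.voltage_mV, atol=1e-12)

    def test_baseline_is_gated_gaba_block(self, control_params):
        p0 = replace(control_params, gate_floor=0.0, gate_width_ms=1e-6,
                     gate_time_ms=1e9)
        a = simulate_sweep(p0, "baseline")
        b = simulate_sweep(p0, "gaba_block")
        np.testing.assert_allclose(a.voltage_mV, b.voltage_mV, atol=1e-9)

    def test_silent_components_give_flat_trace(self, control_params):
        p = replace(control_params, a_fast_mV=0.0, a_nmda_mV=0.0)
        tr = simulate_sweep(p, "baseline")
        np.testing.assert_array_equal(tr.voltage_mV, 0.0)

    def test_control_preset_peak(self, control_params, protocol):
        fs = extract_features(noiseless_response(control_params, "baseline"),
                              protocol)
        assert fs.peak_amplitude_mV == pytest.approx(-0.7, rel=0.02)
        assert fs.latency_to_peak_ms == pytest.approx(2.0, abs=0.1)

    def test_unknown_condition(self, control_params):
        with pytest.raises(ValueError):
            simulate_sweep(control_params, "washout")


class TestSliceRecording:
    def test_epoch_sweep_counts_and_times(self, control_params, protocol):
        sweeps = simulate_slice_recording(control_params, protocol, rng=0)
        by_cond = {}
        for s in sweeps:
            by_cond.setdefault(s.meta.condition, []).append(s)
        assert len(by_cond["baseline"]) == 60      # 20 min / 20 s
        assert len(by_cond["gaba_block"]) == 60
        assert len(by_cond["gaba_nmda_block"]) == 30
        times = [s.meta.sweep_time_s for s in sweeps]
        assert times == sorted(times)
        assert times[1] - times[0] == pytest.approx(20.0)

    def test_same_seed_identical(self, protocol):
        p = get_preset("control")
        a = simulate_slice_recording(p, protocol, rng=42)
        b = simulate_slice_recording(p, protocol, rng=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.voltage_mV, y.voltage_mV)

    def test_slice_scaling_constant_across_epochs(self, protocol):
        # with sweep noise and trial jitter off, the per-slice component
        # scaling must make peak ratios identical across epochs
        p = replace(get_preset("control"), noise_sd_mV=0.0, trial_cv=0.0)
        sweeps = simulate_slice_recording(p, protocol, rng=3)
        blocked = [s for s in sweeps if s.meta.condition == "gaba_block"]
        peaks = [s.voltage_mV.min() for s in blocked]
        assert np.ptp(peaks) < 1e-12


class TestCohort:
    def test_manifest_shape_and_determinism(self, tmp_path):
        spec = cohort_spec("control", n_slices=2, seed=7)
        m1, t1 = simulate_cohort(spec)
        m2, t2 = simulate_cohort(spec)
        assert len(m1.slices) == 2
        for sid in t1:
            for a, b in zip(t1[sid], t2[sid]):
                np.testing.assert_array_equal(a.voltage_mV, b.voltage_mV)

    def test_cohort_mean_contribution_recovers_preset(self, short_protocol):
        # slice-jittered but sweep-noise-free cohorts recover the preset's
        # generating contribution within Monte-Carlo sampling error
        p = replace(get_preset("AMC-32wk-left"), noise_sd_mV=0.0, trial_cv=0.0)
        spec = replace(cohort_spec("AMC-32wk-left", n_slices=60, seed=5),
                       params=p)
        _, traces = simulate_cohort(spec, short_protocol)
        vals = [slice_contributions(sw, short_protocol).nmda_pct
                for sw in traces.values()]
        sem = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(57.0, abs=3.5 * sem + 0.3)


class TestCalibratePreset:
    def test_control_targets_closed(self):
        m = pipeline_measurements(get_preset("control"))
        t = PRESETS["control"].targets
        assert m["peak_mV"] == pytest.approx(t.peak_mV, rel=0.02)
        assert m["latency_ms"] == pytest.approx(t.latency_ms, abs=0.05)
        assert m["duration_baseline_ms"] == pytest.approx(
            t.duration_baseline_ms, rel=0.02)
        assert m["duration_gaba_block_ms"] == pytest.approx(
            t.duration_gaba_block_ms, rel=0.02)
        assert m["gaba_pct"] == pytest.approx(t.gaba_pct, abs=0.5)
        assert m["nmda_pct"] == pytest.approx(t.nmda_pct, abs=0.5)

    @pytest.mark.parametrize("name", sorted(PRESETS))
    def test_all_presets_recover_generating_contributions(self, name):
        # pipeline-estimated GABA% and NMDA% on a noiseless slice equal the
        # calibration targets within 2% relative error
        m = pipeline_measurements(noiseless(get_preset(name)))
        t = PRESETS[name].targets
        assert m["gaba_pct"] == pytest.approx(t.gaba_pct, rel=0.02)
        assert m["nmda_pct"] == pytest.approx(t.nmda_pct, rel=0.02)

    def test_zero_nmda_target(self, control_params):
        # with no NMDA component the gate alone fixes the GABA share, so a
        # feasible target set is the measured output of a fast-only slice
        m = pipeline_measurements(replace(control_params, a_nmda_mV=0.0))
        p = calibrate_preset(CalibrationTargets(
            peak_mV=m["peak_mV"], latency_ms=m["latency_ms"],
            duration_baseline_ms=m["duration_baseline_ms"],
            duration_gaba_block_ms=m["duration_gaba_block_ms"],
            gaba_pct=m["gaba_pct"], nmda_pct=0.0))
        assert p.a_nmda_mV == 0.0
        m2 = pipeline_measurements(p)
        assert m2["gaba_pct"] == pytest.approx(m["gaba_pct"], abs=0.5)

    def test_gaba_target_matches_brute_force_integration(self, control_params):
        # independent trapezoid oracle on a dense grid of the generative
        # formulas, windowed from each trace's own peak to stimulus+100 ms
        from fepsp.synth import mean_waveform
        t = np.arange(0, 120, 0.001)

        def auc(condition):
            v = mean_waveform(control_params, condition, t)
            i0 = np.argmin(v)
            i1 = np.searchsorted(t, 100.0)
            return np.trapezoid(-v[i0:i1], t[i0:i1])

        gaba = 100.0 * (auc("gaba_block") - auc("baseline")) / auc("gaba_block")
        assert gaba == pytest.approx(85.0, abs=0.6)

    def test_inconsistent_targets_rejected(self):
        with pytest.raises(ValueError):
            CalibrationTargets(-0.7, 2.0, 96.0, 4.1, 85.0, 63.0)
        with pytest.raises(ValueError):
            CalibrationTargets(-0.7, 2.0, 4.1, 96.0, 120.0, 63.0)


class TestIOCurve:
    def test_definitional_75_percent(self, control_params):
        grid = np.linspace(0.0, 3.0, 61)
        i75 = io_curve_calibrate(control_params, grid)
        # response at the returned intensity is 75% of the plateau
        from scipy.special import expit
        drive = expit((i75 - 1.0) / 0.15)
        assert drive == pytest.approx(0.75, rel=1e-3)

    def test_scale_invariance(self, control_params):
        grid = np.linspace(0.0, 3.0, 61)
        a = io_curve_calibrate(control_params, grid)
        doubled = replace(control_params,
                          a_fast_mV=2 * control_params.a_fast_mV,
                          a_nmda_mV=2 * control_params.a_nmda_mV)
        b = io_curve_calibrate(doubled, grid)
        assert a == pytest.approx(b, abs=1e-9)

    def test_non_saturating_grid_rejected(self, control_params):
        with pytest.raises(CalibrationError, match="saturation"):
            io_curve_calibrate(control_params, np.linspace(0.0, 1.0, 11))
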