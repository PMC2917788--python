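import numpy as np
import pytest
from scipy import integrate

from fepsp.features import (QC_NO_RESPONSE, average_sweeps, estimate_baseline,
                            extract_features, measure_auc, measure_duration,
                            measure_peak)
from fepsp.io import Trace, TraceMeta
from fepsp.synth import (biexp_kernel, biexp_peak_time, mean_waveform,
                         noiseless_response)

from conftest import flat_trace


def trace_from(v, dt=0.1, stim=10.0):
    return Trace(voltage_mV=np.asarray(v, float), sampling_interval_ms=dt,
                 stimulus_time_ms=stim, meta=TraceMeta("t"))


class TestAverageSweeps:
    def test_idempotent_on_identical_sweeps(self):
        tr = flat_trace(value=-0.3)
        avg = average_sweeps([tr, tr, tr])
        np.testing.assert_array_equal(avg.voltage_mV, tr.voltage_mV)

    def test_pointwise_mean_of_last_window(self):
        sweeps = [flat_trace(value=v) for v in (9.0, 1.0, 2.0, 3.0)]
        avg = average_sweeps(sweeps, window=3)  # drops the first sweep
        np.testing.assert_allclose(avg.voltage_mV, 2.0)

    def test_noise_variance_scales_inversely_with_window(self):
        rng = np.random.default_rng(1)
        ratios = []
        for _ in range(300):
            sweeps = [trace_from(rng.standard_normal(200), stim=10.0)
                      for _ in range(3)]
            avg = average_sweeps(sweeps)
            ratios.append(np.var(avg.voltage_mV))
        assert np.mean(ratios) == pytest.approx(1.0 / 3.0, rel=0.1)

    def test_mismatched_time_bases_rejected(self):
        a, b = flat_trace(n=1300), flat_trace(n=1400)
        with pytest.raises(ValueError, match="time base"):
            average_sweeps([a, b, a], window=3)

    def test_too_few_sweeps_rejected(self):
        with pytest.raises(ValueError):
            average_sweeps([flat_trace()], window=3)


class TestBaseline:
    def test_flat_and_offset(self):
        assert estimate_baseline(flat_trace()) == (0.0, 0.0)
        assert estimate_baseline(flat_trace(value=0.1)) == \
            pytest.approx((0.1, 0.0))

    def test_noise_sd_recovered(self):
        rng = np.random.default_rng(2)
        v = np.zeros(1300)
        v[:100] = rng.standard_normal(100) * 0.02
        _, sd = estimate_baseline(trace_from(v))
        assert sd == pytest.approx(0.02, rel=0.2)

    def test_insufficient_prestimulus_rejected(self):
        with pytest.raises(ValueError, match="5 ms"):
            estimate_baseline(flat_trace(stim=2.0))


class TestPeak:
    def test_flat_trace_flagged_no_response(self):
        res = measure_peak(flat_trace(), 0.0, 0.0)
        assert res.amplitude_mV == 0.0
        assert res.latency_ms == 0.5  # window start
        assert QC_NO_RESPONSE in res.qc

    def test_pure_fast_kernel_latency(self):
        # closed-form kernel peak at 0.924 ms lands on the nearest sample
        t = np.arange(1300) * 0.1 - 10.0
        v = -0.7 * biexp_kernel(t, 0.5, 2.0)
        res = measure_peak(trace_from(v), 0.0, 0.0)
        t_star = biexp_peak_time(0.5, 2.0)
        assert abs(res.latency_ms - t_star) <= 0.05
        assert res.amplitude_mV == pytest.approx(-0.7, rel=0.01)

    def test_earliest_tie_wins(self):
        v = np.zeros(1300)
        v[115] = v[125] = -1.0
        res = measure_peak(trace_from(v), 0.0, 0.0)
        assert res.latency_ms == pytest.approx(1.5)

    def test_window_outside_record_rejected(self):
        with pytest.raises(ValueError):
            measure_peak(flat_trace(n=120), 0.0, 0.0,
                         search_window_ms=(0.5, 10.0))


class TestDuration:
    def test_flat_trace_zero(self):
        dur, qc = measure_duration(flat_trace(), 0.0, 0.0, 0.0, 0.5)
        assert dur == 0.0 and QC_NO_RESPONSE in qc

    def test_square_pulse_width(self):
        v = np.zeros(1300)
        v[100:200] = -1.0  # 10 ms pulse starting at the stimulus
        dur, qc = measure_duration(trace_from(v), 0.0, 0.0, -1.0, 5.0)
        assert dur == pytest.approx(10.0, abs=0.1)
        assert qc == ()

    def test_control_preset_baseline_duration(self, control_params, protocol):
        fs = extract_features(noiseless_response(control_params, "baseline"),
                              protocol)
        assert fs.duration_ms == pytest.approx(4.1, rel=0.05)


class TestAUC:
    def test_flat_trace_zero(self):
        assert measure_auc(flat_trace(), 0.0, 10.0) == 0.0

    def test_triangle_analytic_area(self):
        # -1 mV at the peak decaying linearly to 0 over 10 ms -> 5 mV*ms
        v = np.zeros(1300)
        v[100:201] = -1.0 + np.arange(101) / 100.0
        auc = measure_auc(trace_from(v), 0.0, peak_time_ms=10.0)
        assert auc == pytest.approx(5.0, rel=1e-3)

    def test_matches_adaptive_quadrature(self, control_params):
        # independent oracle: scipy adaptive quadrature of the generative
        # formula over the same window
        tr = noiseless_response(control_params, "gaba_block")
        base, _ = estimate_baseline(tr)
        res = measure_peak(tr, base, 0.0)
        peak_t = tr.stimulus_time_ms + res.latency_ms
        auc = measure_auc(tr, base, peak_t)
        ref, _ = integrate.quad(
            lambda t: -mean_waveform(control_params, "gaba_block",
                                     t - tr.stimulus_time_ms),
            peak_t, tr.stimulus_time_ms + 100.0, limit=300)
        assert auc == pytest.approx(ref, rel=1e-3)

    def test_additive_over_subintervals(self, control_params):
        tr = noiseless_response(control_params, "gaba_block")
        total = measure_auc(tr, 0.0, 12.0, start_ms=12.0, end_ms=110.0)
        a = measure_auc(tr, 0.0, 12.0, start_ms=12.0, end_ms=50.0)
        b = measure_auc(tr, 0.0, 12.0, start_ms=50.0, end_ms=110.0)
        assert a + b == pytest.approx(total, rel=1e-12)

    def test_baseline_offset_invariance(self, control_params):
        tr = noiseless_response(control_params, "gaba_block")
        shifted = trace_from(tr.voltage_mV + 0.25)
        assert measure_auc(shifted, 0.25, 12.0) == \
            pytest.approx(measure_auc(tr, 0.0, 12.0), rel=1e-9)

    def test_record_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            measure_auc(flat_trace(n=500), 0.0, 12.0)


class TestHomogeneity:
    @pytest.mark.parametrize("c", [0.5, 2.0, 7.0])
    def test_amplitude_and_auc_scale_linearly(self, control_params, c, protocol):
        from dataclasses import replace
        scaled = replace(control_params, a_fast_mV=c * control_params.a_fast_mV,
                         a_nmda_mV=c * control_params.a_nmda_mV)
        f0 = extract_features(noiseless_response(control_params, "baseline"),
                              protocol)
        f1 = extract_features(noiseless_response(scaled, "baseline"), protocol)
        assert f1.peak_amplitude_mV == pytest.approx(c * f0.peak_amplitude_mV)
        assert f1.auc_mV_ms == pytest.approx(c * f0.auc_mV_ms)
        assert f1.latency_to_peak_ms == f0.latency_to_peak_ms
        assert f1.duration_ms == f0.duration_ms
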