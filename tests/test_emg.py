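"""EMG processing chain: resampling, filtering, QC, normalisation, patterns."""

import numpy as np
import pytest
from scipy import signal as sps

from gymlanding import emg
from gymlanding.errors import InsufficientDataError, NormalisationError


def _sine(freq, rate, duration=4.0, amp=1.0):
    t = np.arange(int(duration * rate)) / rate
    return t, amp * np.sin(2 * np.pi * freq * t)


class TestResample:
    @pytest.mark.parametrize("native", [1926.0, 1111.0])
    def test_sinusoid_matches_analytic_reference(self, native):
        _, x = _sine(5.0, native)
        y = emg.resample_to_1000hz(x, native)
        t_out = np.arange(len(y)) / 1000.0
        ref = np.sin(2 * np.pi * 5.0 * t_out)
        core = slice(100, len(y) - 100)  # edges excluded: FIR transient
        assert np.abs(y[core] - ref[core]).max() < 1e-3

    def test_constant_preserved(self):
        y = emg.resample_to_1000hz(np.full(5000, 2.5), 1926.0)
        assert np.abs(y - 2.5).max() < 1e-6

    def test_pulse_peak_relocated_within_1ms(self):
        native = 1111.0
        t = np.arange(int(4 * native)) / native
        x = np.exp(-0.5 * ((t - 2.0) / 0.005) ** 2)  # 5-ms Gaussian pulse at 2 s
        y = emg.resample_to_1000hz(x, native)
        peak_t = np.argmax(y) / 1000.0
        assert abs(peak_t - 2.0) <= 0.001

    def test_too_short_signal_rejected(self):
        with pytest.raises(InsufficientDataError):
            emg.resample_to_1000hz(np.zeros(5), 1926.0)

    def test_unusual_rate_warns(self):
        with pytest.warns(UserWarning):
            emg.resample_to_1000hz(np.zeros(100), 500.0)


def _direct_form_filtfilt(b, a, x):
    """Independent oracle: hand-coded direct-form I difference equation,
    applied forward then backward (no padding; evaluate mid-signal only)."""

    def run(sig):
        y = np.zeros_like(sig)
        for n in range(len(sig)):
            acc = 0.0
            for k in range(len(b)):
                if n - k >= 0:
                    acc += b[k] * sig[n - k]
            for k in range(1, len(a)):
                if n - k >= 0:
                    acc -= a[k] * y[n - k]
            y[n] = acc / a[0]
        return y

    return run(run(x)[::-1])[::-1]


class TestBandpass:
    def test_dc_rejected(self):
        y = emg.bandpass_30_350(np.full(4000, 3.0))
        assert np.abs(y[500:-500]).max() < 1e-6 * 3.0

    def test_passband_amplitude_preserved(self):
        _, x = _sine(100.0, 1000.0)
        y = emg.bandpass_30_350(x)
        amp = np.abs(y[1000:3000]).max()
        assert 0.95 <= amp <= 1.05

    def test_stopband_matches_direct_form_oracle(self):
        """10 Hz steady-state attenuation agrees with an independently coded
        direct-form implementation of the same 4th-order design."""
        _, x = _sine(10.0, 1000.0)
        y = emg.bandpass_30_350(x)
        b, a = sps.butter(4, [30.0, 350.0], btype="bandpass", fs=1000.0)
        ref = _direct_form_filtfilt(b, a, x)
        core = slice(1500, 2500)
        assert np.abs(y[core] - ref[core]).max() < 1e-6

    def test_zero_phase_on_symmetric_pulse(self):
        t = np.arange(4000) / 1000.0
        x = np.exp(-0.5 * ((t - 2.0) / 0.01) ** 2)
        y = emg.bandpass_30_350(x)
        assert abs(int(np.argmax(np.abs(y))) - int(np.argmax(x))) <= 1

    def test_short_signal_rejected(self):
        with pytest.raises(InsufficientDataError):
            emg.bandpass_30_350(np.zeros(50))


class TestRectify:
    def test_matches_absolute_value(self):
        assert np.array_equal(emg.rectify(np.array([-1.0, 2.0, -3.0])), [1.0, 2.0, 3.0])
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        assert np.array_equal(emg.rectify(x), np.abs(x))
        assert np.array_equal(emg.rectify(np.zeros(10)), np.zeros(10))


class TestQC:
    def test_amplitude_over_3mv_excluded(self):
        rng = np.random.default_rng(1)
        x = 0.2 * rng.normal(size=5000)
        x[2500] = 3.5
        verdict = emg.qc_check(x)
        assert not verdict.keep and verdict.reason == "amplitude_over_3mV"

    def test_clean_burst_kept(self):
        rng = np.random.default_rng(2)
        t = np.arange(5000) / 1000.0
        x = rng.normal(size=5000) * (0.05 + 0.5 * np.exp(-((t - 2.5) ** 2) / 0.01))
        verdict = emg.qc_check(x)
        assert verdict.keep and verdict.reason == "ok"

    def test_flatline_excluded(self):
        rng = np.random.default_rng(3)
        x = 0.1 * rng.normal(size=5000)
        x[1000:1300] = 0.05
        verdict = emg.qc_check(x)
        assert not verdict.keep and verdict.reason == "artifact_flatline"

    def test_saturation_excluded(self):
        rng = np.random.default_rng(4)
        x = 0.1 * rng.normal(size=5000)
        x[2000:2080] = 2.9  # clipped near the extremum but below 3 mV
        x[2000:2080] += 1e-5 * rng.normal(size=80)  # not bit-identical
        verdict = emg.qc_check(x)
        assert not verdict.keep and verdict.reason == "artifact_saturation"


class TestNormalisation:
    def test_divisor_is_brute_force_max_over_as_windows(self):
        rng = np.random.default_rng(5)
        traces = {f"t{i}": np.abs(rng.normal(size=4000)) for i in range(3)}
        contacts = {f"t{i}": 2.0 for i in range(3)}
        divisor = emg.as_max_divisor(traces, contacts, "S01", "m")
        expected = max(
            traces[k][int(2.0 * 1000) - 300: int(2.0 * 1000) + 300].max() for k in traces
        )
        assert divisor == expected

    def test_normalised_as_max_is_one(self):
        rng = np.random.default_rng(6)
        traces = {"a": np.abs(rng.normal(size=4000)), "b": np.abs(rng.normal(size=4000))}
        contacts = {"a": 2.0, "b": 2.0}
        divisor = emg.as_max_divisor(traces, contacts, "S01", "m")
        peak = max((traces[k] / divisor)[1700:2300].max() for k in traces)
        assert peak == pytest.approx(1.0, abs=1e-12)

    def test_constant_half_scales_by_two(self):
        traces = {"a": np.full(4000, 0.5)}
        divisor = emg.as_max_divisor(traces, {"a": 2.0}, "S01", "m")
        assert divisor == 0.5
        assert np.all(traces["a"] / divisor == 1.0)

    def test_missing_as_trial_raises(self):
        with pytest.raises(NormalisationError, match="S07.*vastus"):
            emg.as_max_divisor({}, {}, "S07", "vastus_medialis")

    def test_scale_equivariance(self):
        """Scaling all of a participant's raw signals by c > 0 leaves the
        normalised patterns unchanged."""
        rng = np.random.default_rng(7)
        raw = rng.normal(size=8000) * 0.3
        contact = 2.0

        def patterns(scale):
            proc = emg.process_raw(scale * raw, 1926.0)
            div = emg.as_max_divisor({"t": proc}, {"t": contact}, "S", "m")
            return emg.extract_pattern(proc / div, contact).nodes

        assert np.allclose(patterns(1.0), patterns(7.3), rtol=1e-10)


class TestPattern:
    def test_constant_unit_signal_gives_20ms_nodes(self):
        pattern = emg.extract_pattern(np.ones(3000), 1.5)
        assert pattern.nodes.shape == (30,)
        assert np.allclose(pattern.nodes, 0.020)

    def test_ramp_matches_per_window_summation_oracle(self):
        x = np.linspace(0.0, 1.0, 4000)
        pattern = emg.extract_pattern(x, 2.0)
        start = 2000 - 300
        expected = np.array([x[start + 20 * j: start + 20 * (j + 1)].sum() / 1000.0
                             for j in range(30)])
        assert np.abs(pattern.nodes - expected).max() < 1e-12

    def test_insufficient_coverage_raises(self):
        with pytest.raises(InsufficientDataError, match="cover"):
            emg.extract_pattern(np.ones(400), 0.1)

    def test_normalise_before_integration_matters(self):
        """Dividing the signal by the AS max is not the same as dividing the
        integrated pattern by the pattern maximum: the operation order is fixed."""
        rng = np.random.default_rng(8)
        proc = np.abs(rng.normal(size=4000))
        contact = 2.0
        div = emg.as_max_divisor({"t": proc}, {"t": contact}, "S", "m")
        correct = emg.extract_pattern(proc / div, contact).nodes
        swapped = emg.extract_pattern(proc, contact).nodes
        swapped = swapped / swapped.max()
        assert not np.allclose(correct, swapped, rtol=1e-3)
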