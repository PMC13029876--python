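"""Sensor simulation, filtering and calibration metrology."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drfkit.errors import ConfigError, FitError, TraceError
from drfkit.metrology import (
    CalibrationRun,
    ForceTrace,
    SensorErrorModel,
    UncertaintyBudget,
    UncertaintyComponent,
    fit_linearity,
    gum_expanded_uncertainty,
    hysteresis_error,
    lowpass_filter,
    repeatability,
    simulate_sensor_trace,
    zero_drift,
)


class TestForceTrace:
    def test_rejects_non_uniform_sampling(self):
        t = np.array([0.0, 0.01, 0.03, 0.04])
        with pytest.raises(TraceError):
            ForceTrace(t, np.zeros(4), 100.0)

    def test_rejects_two_channels(self):
        t = np.arange(10) / 100
        with pytest.raises(TraceError):
            ForceTrace(t, np.zeros((10, 2)), 100.0)

    def test_channel_sum(self):
        t = np.arange(10) / 100
        tr = ForceTrace(t, np.ones((10, 3)), 100.0)
        assert tr.channel_sum() == pytest.approx(np.full(10, 3.0))


class TestSimulator:
    def test_zero_error_model_is_exact(self):
        tr = simulate_sensor_trace(lambda t: 100.0, SensorErrorModel(0, 0, 0), 10.0, 100.0)
        assert np.all(tr.values == 100.0)

    def test_noise_sd_matches_parameter(self):
        model = SensorErrorModel(noise_sd=0.25, drift_rate=0, hysteresis_fraction=0, seed=1)
        tr = simulate_sensor_trace(lambda t: 0.0, model, 60.0, 100.0)
        assert tr.values.std() == pytest.approx(0.25, rel=0.10)

    def test_drift_reaches_rate_after_one_hour(self):
        model = SensorErrorModel(noise_sd=0, drift_rate=0.2, hysteresis_fraction=0)
        tr = simulate_sensor_trace(lambda t: 100.0, model, 3600.0, 10.0)
        assert tr.values[-1] - tr.values[0] == pytest.approx(0.2, rel=1e-3)

    def test_fixed_seed_bit_identical(self):
        model = SensorErrorModel(seed=7)
        a = simulate_sensor_trace(lambda t: 50.0, model, 5.0, 100.0)
        b = simulate_sensor_trace(lambda t: 50.0, model, 5.0, 100.0)
        assert np.array_equal(a.values, b.values)

    def test_hysteresis_loop_direction(self):
        # triangular load cycle: unloading branch reads above loading
        model = SensorErrorModel(0.0, 0.0, hysteresis_fraction=0.001, full_scale=500.0)
        half = 10.0

        def cycle(t):
            return np.where(t < half, 20.0 * t, 20.0 * (2 * half - t))

        tr = simulate_sensor_trace(cycle, model, 2 * half, 100.0)
        i_up = 500  # 100 N on the way up
        i_down = 1500  # 100 N on the way down
        assert tr.values[i_down] > tr.values[i_up]


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        t = np.arange(1000) / 100
        tr = ForceTrace(t, np.full(1000, 100.0), 100.0)
        out = lowpass_filter(tr)
        assert out.values == pytest.approx(np.full(1000, 100.0), abs=1e-9)
        assert out.filtered

    def test_attenuation_at_ten_times_cutoff(self):
        # Butterworth magnitude: |H| = 1/sqrt(1+(f/fc)^(2n)); 10x, n=4 -> >= 60 dB
        rate, cutoff = 1000.0, 5.0
        t = np.arange(int(20 * rate)) / rate
        tr = ForceTrace(t, np.sin(2 * np.pi * 10 * cutoff * t), rate)
        out = lowpass_filter(tr, cutoff=cutoff, order=4)
        mid = out.values[int(5 * rate) : int(15 * rate)]
        attenuation_db = -20 * np.log10(max(np.abs(mid).max(), 1e-300))
        assert attenuation_db >= 4 * 20 - 3

    def test_filtered_rms_below_noise_floor(self):
        model = SensorErrorModel(noise_sd=0.25, drift_rate=0, hysteresis_fraction=0, seed=42)
        tr = simulate_sensor_trace(lambda t: 0.0, model, 60.0, 100.0)
        out = lowpass_filter(tr)
        assert np.sqrt(np.mean(out.values**2)) <= 0.15
        assert np.sqrt(np.mean(out.values**2)) <= np.sqrt(np.mean(tr.values**2))

    def test_cutoff_above_nyquist_rejected(self):
        t = np.arange(100) / 100
        tr = ForceTrace(t, np.zeros(100), 100.0)
        with pytest.raises(ConfigError):
            lowpass_filter(tr, cutoff=50.0)


class TestLadderMetrics:
    @staticmethod
    def _ideal_run(scale=1.0, n_repeats=2):
        loads = np.arange(0.0, 201.0, 20.0)
        up = np.tile(scale * loads, (n_repeats, 1))
        return CalibrationRun(loads, up, loads[::-1], up[:, ::-1])

    def test_ideal_sensor_perfect_linearity(self):
        slope, intercept, r2 = fit_linearity(self._ideal_run())
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_r_squared_scale_invariant(self):
        slope, _, r2 = fit_linearity(self._ideal_run(scale=2.0))
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_degenerate_single_level_rejected(self):
        run = CalibrationRun(np.full(3, 100.0), np.full((1, 3), 100.0))
        with pytest.raises(FitError):
            fit_linearity(run)

    def test_offset_invariance_except_intercept(self):
        loads = np.arange(0.0, 201.0, 20.0)
        base = CalibrationRun(loads, np.tile(loads, (2, 1)))
        shifted = CalibrationRun(loads + 5.0, np.tile(loads + 5.0, (2, 1)))
        s1, i1, r1 = fit_linearity(base)
        s2, i2, r2 = fit_linearity(shifted)
        assert (s1, r1) == pytest.approx((s2, r2))

    def test_hysteresis_zero_for_identical_branches(self):
        assert hysteresis_error(self._ideal_run(), 500.0) == 0.0

    def test_hysteresis_direct_arithmetic(self):
        loads = np.arange(0.0, 201.0, 20.0)
        up = np.tile(loads, (1, 1)).astype(float)
        down = up.copy()
        down[0, 5] += 0.2  # 0.2 N branch gap at one level
        run = CalibrationRun(loads, up, loads[::-1], down[:, ::-1])
        assert hysteresis_error(run, 500.0) == pytest.approx(0.04)

    def test_missing_unloading_branch_rejected(self):
        run = CalibrationRun(np.arange(0.0, 201.0, 20.0), np.tile(np.arange(0.0, 201.0, 20.0), (1, 1)))
        with pytest.raises(ValueError, match="unloading"):
            hysteresis_error(run, 500.0)

    def test_repeatability_half_range(self):
        loads = np.array([0.0, 100.0, 200.0])
        up = np.array([[0.0, 99.6, 200.0], [0.0, 100.4, 200.0]])
        run = CalibrationRun(loads, up)
        assert repeatability(run) == pytest.approx(0.4)

    def test_repeatability_needs_repeats(self):
        run = CalibrationRun(np.array([0.0, 100.0, 200.0]), np.zeros((1, 3)))
        with pytest.raises(ValueError):
            repeatability(run)


class TestZeroDrift:
    def test_constant_trace_zero(self):
        t = np.arange(36000) / 10
        assert zero_drift(ForceTrace(t, np.full(36000, 100.0), 10.0)) == 0.0

    def test_linear_ramp_window_mean_offset(self):
        # 0.2 N over 1 h; 60 s window means sit 3540 s apart -> 0.19667 N
        rate, n = 10.0, 36000
        t = np.arange(n) / rate
        values = 100.0 + 0.2 * t / 3600.0
        expected = 0.2 * (t[-600:].mean() - t[:600].mean()) / 3600.0
        assert zero_drift(ForceTrace(t, values, rate)) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.197, abs=0.001)

    def test_short_trace_rejected(self):
        t = np.arange(600) / 10
        with pytest.raises(TraceError):
            zero_drift(ForceTrace(t, np.zeros(600), 10.0))


class TestGum:
    def test_single_normal_component(self):
        b = UncertaintyBudget((UncertaintyComponent("noise", 0.15, "normal"),))
        assert gum_expanded_uncertainty(b, k=2.0) == pytest.approx(0.30)

    def test_rectangular_root_sum_square(self):
        b = UncertaintyBudget(
            (
                UncertaintyComponent("noise", 0.15),
                UncertaintyComponent("drift", 0.2),
                UncertaintyComponent("hysteresis", 0.2),
            )
        )
        # 2*sqrt((0.15^2 + 0.2^2 + 0.2^2)/3) = 0.3697 N
        assert gum_expanded_uncertainty(b, k=2.0) == pytest.approx(0.3697, abs=5e-4)

    def test_empty_budget_rejected_and_zero_component_ok(self):
        with pytest.raises(ConfigError):
            UncertaintyBudget(())
        b = UncertaintyBudget((UncertaintyComponent("null", 0.0),))
        assert gum_expanded_uncertainty(b) == 0.0

    def test_unknown_distribution_rejected(self):
        c = UncertaintyComponent("odd", 0.1, "cauchy")
        with pytest.raises(ConfigError):
            c.standard_uncertainty()

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        mags=st.lists(st.floats(0.0, 10.0), min_size=1, max_size=5),
        k=st.floats(0.5, 4.0),
        bump=st.floats(0.0, 1.0),
    )
    def test_linear_in_k_and_monotone_in_magnitudes(self, mags, k, bump):
        b1 = UncertaintyBudget(tuple(UncertaintyComponent(f"c{i}", m) for i, m in enumerate(mags)))
        bigger = [m + bump for m in mags]
        b2 = UncertaintyBudget(tuple(UncertaintyComponent(f"c{i}", m) for i, m in enumerate(bigger)))
        u1 = gum_expanded_uncertainty(b1, k=1.0)
        assert gum_expanded_uncertainty(b1, k=k) == pytest.approx(k * u1, rel=1e-12)
        assert gum_expanded_uncertainty(b2, k=k) >= gum_expanded_uncertainty(b1, k=k)
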