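"""Hydrodynamic metric operations: RF, ΔP, Q_RMS, EOA, Reynolds."""

import numpy as np
import pytest

from valvekit import hydrodynamics as hy
from valvekit import synthetic as syn
from valvekit.errors import DataError, DomainError


def make_waveform(q, p_vent=None, p_ao=None, dt=0.001, cycle_period=None):
    q = np.asarray(q, dtype=float)
    n = q.size
    return hy.PressureFlowWaveform(
        time=np.arange(n) * dt,
        p_vent=np.zeros(n) if p_vent is None else np.asarray(p_vent, float),
        p_ao=np.zeros(n) if p_ao is None else np.asarray(p_ao, float),
        q=q,
        cycle_period=cycle_period if cycle_period is not None else n * dt,
    )


def half_sine_cycle(amplitude=100.0, n_sys=300, n_total=857):
    q = np.zeros(n_total)
    q[:n_sys] = amplitude * np.sin(np.pi * np.arange(n_sys) / n_sys)
    return q


class TestEnsembleAverage:
    def test_identical_cycles_average_to_one_cycle(self):
        cycle = half_sine_cycle()
        w = make_waveform(np.tile(cycle, 10), cycle_period=0.857)
        avg = hy.ensemble_average(w, n_cycles=10)
        assert np.allclose(avg.q, cycle)
        assert avg.q.size == 857

    def test_single_cycle_identity(self):
        cycle = half_sine_cycle()
        w = make_waveform(cycle, cycle_period=0.857)
        avg = hy.ensemble_average(w, n_cycles=1)
        assert np.allclose(avg.q, cycle)

    def test_too_few_cycles_reports_counts(self):
        w = make_waveform(np.tile(half_sine_cycle(), 3), cycle_period=0.857)
        with pytest.raises(DataError, match="3"):
            hy.ensemble_average(w, n_cycles=10)

    def test_noise_reduced_by_sqrt_n_cycles(self, rng):
        """Per-sample noise sd after 10-cycle averaging is ~ sigma/sqrt(10)."""
        sigma, n_rep, spc = 1.0, 1000, 60
        cycle = np.full(spc, 50.0)
        outs = np.empty((n_rep, spc))
        for i in range(n_rep):
            q = np.tile(cycle, 10) + rng.normal(0, sigma, spc * 10)
            w = make_waveform(q, cycle_period=spc * 0.001)
            outs[i] = hy.ensemble_average(w, n_cycles=10).q
        sd = outs.std(axis=0).mean()
        assert sd == pytest.approx(sigma / np.sqrt(10), rel=0.10)


class TestForwardFlowDetection:
    def test_half_sine_window_is_systolic_support(self):
        w = make_waveform(half_sine_cycle(n_sys=300))
        i0, i1 = hy.detect_forward_flow(w).forward_flow_windows[0]
        assert i0 <= 1 and abs((i1 - i0) - 300) <= 2

    def test_all_positive_flow_spans_cycle(self):
        w = make_waveform(np.full(500, 80.0))
        i0, i1 = hy.detect_forward_flow(w).forward_flow_windows[0]
        assert (i0, i1) == (0, 500)

    def test_generator_systolic_fraction_recovered(self, noiseless_waveform):
        w, truth = noiseless_waveform
        avg = hy.ensemble_average(w)
        i0, i1 = hy.detect_forward_flow(avg).forward_flow_windows[0]
        expected = truth["systole_duration_s"] / avg.dt
        assert abs((i1 - i0) - expected) <= 2

    def test_no_positive_flow_raises(self):
        with pytest.raises(DataError):
            hy.detect_forward_flow(make_waveform(-np.ones(100)))


class TestDeltaP:
    def test_constant_differential(self):
        q = half_sine_cycle()
        w = make_waveform(q, p_vent=np.full(q.size, 108.0), p_ao=np.full(q.size, 100.0))
        seg = hy.detect_forward_flow(w)
        assert hy.compute_delta_p(w, seg) == pytest.approx(8.0)

    def test_half_sine_differential_mean(self):
        """Mean of a half-sine of peak A over its support is 2A/pi."""
        n = 857
        q = half_sine_cycle(n_sys=300, n_total=n)
        dp = np.zeros(n)
        dp[:300] = 12.0 * np.sin(np.pi * np.arange(300) / 300)
        w = make_waveform(q, p_vent=dp, p_ao=np.zeros(n))
        seg = hy.detect_forward_flow(w)
        assert hy.compute_delta_p(w, seg) == pytest.approx(2 * 12.0 / np.pi, rel=0.01)

    def test_peak_mode(self):
        n = 857
        q = half_sine_cycle(n_total=n)
        dp = np.zeros(n)
        dp[:300] = 12.0 * np.sin(np.pi * np.arange(300) / 300)
        w = make_waveform(q, p_vent=dp)
        seg = hy.detect_forward_flow(w)
        assert hy.compute_delta_p(w, seg, mode="peak") == pytest.approx(12.0, rel=0.01)

    def test_empty_window_raises(self):
        w = make_waveform(half_sine_cycle())
        seg = hy.CycleSegmentation(cycle_bounds=[(0, 857)], forward_flow_windows=[(5, 5)])
        with pytest.raises(DataError):
            hy.compute_delta_p(w, seg)


class TestQrms:
    def test_constant_flow(self):
        w = make_waveform(np.full(400, 100.0))
        seg = hy.detect_forward_flow(w)
        assert hy.compute_qrms(w, seg) == pytest.approx(100.0)

    def test_half_sine_rms_is_amplitude_over_sqrt2(self):
        w = make_waveform(half_sine_cycle(amplitude=180.0))
        seg = hy.detect_forward_flow(w)
        assert hy.compute_qrms(w, seg) == pytest.approx(180.0 / np.sqrt(2), rel=0.01)

    def test_homogeneity_in_flow_scale(self):
        q = half_sine_cycle()
        w1, w3 = make_waveform(q), make_waveform(3 * q)
        s1, s3 = hy.detect_forward_flow(w1), hy.detect_forward_flow(w3)
        assert hy.compute_qrms(w3, s3) == pytest.approx(3 * hy.compute_qrms(w1, s1))


class TestRegurgitantFraction:
    def test_no_negative_flow_gives_zero(self):
        w = make_waveform(half_sine_cycle())
        assert hy.compute_rf(w, hy.detect_forward_flow(w)) == 0.0

    def test_square_wave_volume_ratio(self):
        # forward 100 mL (1 s at 100 mL/s), retrograde 10 mL (1 s at 10 mL/s)
        q = np.concatenate([np.full(1000, 100.0), np.full(1000, -10.0)])
        w = make_waveform(q)
        rf = hy.compute_rf(w, hy.detect_forward_flow(w))
        assert rf == pytest.approx(10.0, abs=0.2)

    def test_scale_invariance(self):
        q = np.concatenate([np.full(1000, 100.0), np.full(1000, -10.0)])
        w1, w2 = make_waveform(q), make_waveform(2 * q)
        rf1 = hy.compute_rf(w1, hy.detect_forward_flow(w1))
        rf2 = hy.compute_rf(w2, hy.detect_forward_flow(w2))
        assert rf1 == pytest.approx(rf2)

    def test_zero_forward_volume_raises(self):
        w = make_waveform(np.concatenate([np.zeros(50), -np.ones(50)]))
        seg = hy.CycleSegmentation(cycle_bounds=[(0, 100)], forward_flow_windows=[(0, 50)])
        with pytest.raises(DataError):
            hy.compute_rf(w, seg)


class TestEOA:
    def test_sqrt_pressure_law(self):
        e1 = hy.compute_eoa(100.0, 4.0)
        e2 = hy.compute_eoa(100.0, 16.0)
        assert e2 == pytest.approx(e1 / 2)

    def test_monotone_in_qrms_and_delta_p(self):
        assert hy.compute_eoa(120.0, 6.0) > hy.compute_eoa(100.0, 6.0)
        assert hy.compute_eoa(100.0, 8.0) < hy.compute_eoa(100.0, 6.0)

    def test_nonpositive_delta_p_rejected(self):
        with pytest.raises(DomainError):
            hy.compute_eoa(100.0, 0.0)


class TestReynolds:
    def test_definition_hand_check(self):
        # 1007 * 1.0 * 0.026 / 1.07e-3 = 24469.2
        assert hy.compute_reynolds(1.0, 0.026) == pytest.approx(24469.16, rel=1e-4)

    def test_zero_velocity(self):
        assert hy.compute_reynolds(0.0, 0.026) == 0.0

    def test_linearity_in_velocity(self):
        assert hy.compute_reynolds(2.0, 0.026) == pytest.approx(
            2 * hy.compute_reynolds(1.0, 0.026)
        )

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(DomainError):
            hy.compute_reynolds(1.0, 0.0)


class TestPipeline:
    def test_noiseless_generator_truths_recovered(self, noiseless_waveform):
        w, truth = noiseless_waveform
        m = hy.analyze_waveform(w)
        assert m.rf == pytest.approx(truth["rf_percent"], abs=0.5)
        assert m.delta_p == pytest.approx(truth["delta_p_mean_mmhg"], rel=0.02)
        assert m.q_rms == pytest.approx(truth["q_rms_mls"], rel=0.02)

    def test_idempotent_on_averaged_cycle(self, noiseless_waveform):
        w, _ = noiseless_waveform
        avg = hy.ensemble_average(w)
        again = hy.ensemble_average(avg, n_cycles=1)
        assert np.allclose(avg.q, again.q)

    def test_rf_invariant_under_time_rescaling(self, noiseless_waveform):
        w, _ = noiseless_waveform
        avg = hy.ensemble_average(w)
        stretched = hy.PressureFlowWaveform(
            time=avg.time * 2, p_vent=avg.p_vent, p_ao=avg.p_ao, q=avg.q,
            cycle_period=avg.cycle_period * 2,
        )
        rf1 = hy.compute_rf(avg, hy.detect_forward_flow(avg))
        rf2 = hy.compute_rf(stretched, hy.detect_forward_flow(stretched))
        assert rf1 == pytest.approx(rf2)
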