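"""Filtering, differentiation and the rigid-body CG transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imgdecouple.errors import (
    AlignmentError,
    InvalidFilterSpecError,
    SignalLengthError,
)
from imgdecouple.signals import (
    ChannelSignal,
    FilterSpec,
    butterworth_phaseless,
    five_point_derivative,
    process_event,
    resultant,
    transform_to_cg,
)
from imgdecouple.simulate import ImpactScenario, simulate_coupled_event

from conftest import FS, tone


def _butter_mag(freq, cutoff, order):
    """Analytic Butterworth magnitude response (one pass)."""
    return 1.0 / np.sqrt(1.0 + (freq / cutoff) ** (2 * order))


class TestButterworthPhaseless:
    def test_dc_passes_unchanged(self):
        sig = ChannelSignal(np.full(200, 3.7), FS, 0)
        out = butterworth_phaseless(sig, FilterSpec(175.0))
        assert np.allclose(out.samples, 3.7, atol=1e-9)
        assert len(out) == len(sig) and out.trigger_index == sig.trigger_index

    @pytest.mark.parametrize("freq, cutoff", [(1000.0, 175.0), (10.0, 175.0)])
    def test_matches_analytic_magnitude(self, freq, cutoff):
        # two passes of an order-2 section -> squared magnitude response
        n = 3200
        t = np.arange(n) / FS
        sig = ChannelSignal(np.sin(2 * np.pi * freq * t), FS, 0)
        out = butterworth_phaseless(sig, FilterSpec(cutoff))
        core = slice(n // 4, 3 * n // 4)  # avoid edge transients
        gain = np.sqrt(np.mean(out.samples[core] ** 2) /
                       np.mean(sig.samples[core] ** 2))
        expected = _butter_mag(freq, cutoff, 2) ** 2
        if freq > cutoff:
            assert gain < 0.01
        else:
            assert gain == pytest.approx(expected, abs=0.01)
            assert gain == pytest.approx(1.0, abs=0.01)

    def test_zero_phase_lag_on_narrowband(self):
        t = np.arange(1600) / FS
        x = np.sin(2 * np.pi * 50.0 * t) * np.hanning(1600)
        sig = ChannelSignal(x, FS, 0)
        out = butterworth_phaseless(sig, FilterSpec(175.0))
        xc = np.correlate(out.samples, sig.samples, mode="full")
        assert np.argmax(xc) == len(x) - 1  # peak at lag 0

    def test_cutoff_at_nyquist_rejected(self):
        sig = tone(10.0)
        with pytest.raises(InvalidFilterSpecError):
            butterworth_phaseless(sig, FilterSpec(FS / 2))

    def test_too_short_signal_rejected(self):
        sig = ChannelSignal(np.zeros(8), FS, 0)
        with pytest.raises(SignalLengthError):
            butterworth_phaseless(sig, FilterSpec(175.0))


class TestFivePointDerivative:
    def test_constant_gives_zero(self):
        out = five_point_derivative(ChannelSignal(np.full(50, 2.5), FS, 0))
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_linear_ramp_gives_slope(self):
        m = -4.2
        t = np.arange(50) / FS
        out = five_point_derivative(ChannelSignal(m * t, FS, 0))
        assert np.allclose(out.samples[2:-2], m, rtol=1e-9)

    def test_exact_on_quartic(self):
        # the stencil's truncation error involves the 5th derivative,
        # identically zero for t**4
        t = np.arange(100) / FS + 0.01
        out = five_point_derivative(ChannelSignal(t ** 4, FS, 0))
        expected = 4 * t ** 3
        rel = np.abs(out.samples[2:-2] - expected[2:-2]) / np.abs(expected[2:-2])
        assert rel.max() < 1e-9

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 2 ** 16))
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        f, g = rng.normal(size=30), rng.normal(size=30)
        df = five_point_derivative(ChannelSignal(f, FS, 0)).samples
        dg = five_point_derivative(ChannelSignal(g, FS, 0)).samples
        dsum = five_point_derivative(ChannelSignal(a * f + b * g, FS, 0)).samples
        assert np.allclose(dsum, a * df + b * dg, atol=1e-12 * FS * 12)

    def test_too_short_rejected(self):
        with pytest.raises((SignalLengthError, ValueError)):
            five_point_derivative(ChannelSignal(np.zeros(4), FS, 0))


class TestTransformToCg:
    def test_zero_lever_arm_is_identity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 3))
        w = rng.normal(size=(20, 3))
        al = rng.normal(size=(20, 3))
        out = transform_to_cg(a, w, al, np.zeros(3))
        assert np.allclose(out, a)

    def test_no_rotation_is_identity(self):
        a = np.random.default_rng(1).normal(size=(20, 3))
        z = np.zeros((20, 3))
        out = transform_to_cg(a, z, z, np.array([0.1, 0.2, 0.3]))
        assert np.allclose(out, a)

    def test_centripetal_hand_case(self):
        # pure spin about z at 10 rad/s, sensor 0.1 m along x:
        # w x (w x r) = -w^2 r -> (-10, 0, 0) m/s^2
        out = transform_to_cg(np.zeros((1, 3)), np.array([[0, 0, 10.0]]),
                              np.zeros((1, 3)), np.array([0.1, 0, 0]))
        assert np.allclose(out, [[-10.0, 0.0, 0.0]], atol=1e-12)

    def test_agrees_with_cross_product_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(1000, 3))
        w = rng.normal(size=(1000, 3)) * 30
        al = rng.normal(size=(1000, 3)) * 3000
        r = rng.normal(size=3) * 0.1
        out = transform_to_cg(a, w, al, r)
        for i in range(1000):
            expected = (a[i] + np.cross(w[i], np.cross(w[i], r))
                        + np.cross(al[i], r))
            assert np.max(np.abs(out[i] - expected)) < 1e-10

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            transform_to_cg(np.zeros((5, 3)), np.zeros((4, 3)),
                            np.zeros((5, 3)), np.zeros(3))


class TestResultant:
    def test_pythagorean_and_zero(self):
        x = ChannelSignal([3, 0, 1, 0, 0], FS, 0)
        y = ChannelSignal([4, 0, 1, 0, 0], FS, 0)
        z = ChannelSignal([0, 0, 1, 0, 0], FS, 0)
        out = resultant(x, y, z)
        assert out.samples[0] == pytest.approx(5.0)
        assert out.samples[1] == 0.0
        assert out.samples[2] == pytest.approx(np.sqrt(3))

    def test_bounds_components(self, coupled_event):
        _, truth = coupled_event
        res = truth.resultant_lin.samples
        for c in truth.lin_acc_cg:
            assert np.all(res >= np.abs(c.samples) - 1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            resultant(ChannelSignal(np.zeros(6), FS, 0),
                      ChannelSignal(np.zeros(5), FS, 0),
                      ChannelSignal(np.zeros(6), FS, 0))


class TestProcessEvent:
    def test_recovers_ground_truth_peak(self, coupled_event):
        record, truth = coupled_event
        kin = process_event(record)
        peak = np.max(kin.resultant_lin.samples)
        truth_peak = np.max(truth.resultant_lin.samples)
        assert peak == pytest.approx(truth_peak, rel=0.03)

    def test_constant_rate_gyro_zero_angular_acceleration(self, quiet_cfg):
        record, _ = simulate_coupled_event(
            ImpactScenario(peak_lin_g=40.0), quiet_cfg, seed=0)
        # overwrite gyro with constant rate
        const = tuple(c.with_samples(np.full(len(c), 2.0)) for c in record.gyro)
        from dataclasses import replace
        rec = replace(record, gyro=const, lever_arm_r=np.zeros(3))
        kin = process_event(rec)
        for c in kin.ang_acc:
            assert np.allclose(c.samples[10:-10], 0.0, atol=1e-6)

    def test_deterministic(self, coupled_event):
        record, _ = coupled_event
        k1 = process_event(record)
        k2 = process_event(record)
        assert np.array_equal(k1.resultant_lin.samples, k2.resultant_lin.samples)
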