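"""MODWT multiresolution salvaging: decomposition, selection, reconstruction."""

from dataclasses import replace

import numpy as np
import pytest

from imgdecouple.errors import SignalLengthError
from imgdecouple.evaluate import percent_error, post_trigger_peak
from imgdecouple.salvage import (
    LEVEL_NAMES,
    NOMINAL_BANDS,
    SalvageConfig,
    modwt_mra,
    reconstruct,
    salvage_event,
    section_relative_energy,
    select_levels_angular,
    select_levels_linear,
)
from imgdecouple.signals import ChannelSignal, process_event

from conftest import FS, tone


def _burst(freq, start_ms, stop_ms, n=161, ti=32, amp=1.0):
    t = (np.arange(n) - ti) / FS
    x = np.where((t >= start_ms * 1e-3) & (t <= stop_ms * 1e-3),
                 amp * np.sin(2 * np.pi * freq * t), 0.0)
    return ChannelSignal(x, FS, ti)


class TestModwtMra:
    @pytest.mark.parametrize("seed", range(5))
    def test_perfect_reconstruction(self, seed):
        x = np.random.default_rng(seed).normal(size=160)
        sig = ChannelSignal(x, FS, 32)
        d = modwt_mra(sig)
        total = sum(d.components.values())
        assert np.max(np.abs(total - x)) < 1e-8 * np.max(np.abs(x))

    @pytest.mark.parametrize("freq, level", [(1200.0, "D1"), (300.0, "D3"),
                                             (20.0, "A")])
    def test_band_localization(self, freq, level):
        d = modwt_mra(tone(freq))
        frac = d.component_energy(level) / d.total_energy()
        lo, hi = NOMINAL_BANDS[level]
        assert lo <= freq <= hi
        assert frac >= 0.80

    def test_too_short_signal_rejected(self):
        with pytest.raises(SignalLengthError):
            modwt_mra(ChannelSignal(np.zeros(16), FS, 0))


class TestSectionEnergy:
    def test_impulse_in_one_section(self):
        x = np.zeros(161)
        x[80] = 3.0  # (80-32)/3200 = 15 ms -> 10-20 ms section
        prof = section_relative_energy(x, ChannelSignal(x, FS, 32))
        assert prof.energy_at(10.0) == pytest.approx(1.0)
        assert prof.energy_at(0.0) == 0.0

    def test_energies_sum_to_one(self):
        x = np.random.default_rng(0).normal(size=161)
        prof = section_relative_energy(x, ChannelSignal(x, FS, 32))
        assert prof.relative_energies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_level_splits_evenly(self):
        sig = ChannelSignal(np.zeros(161), FS, 32)
        x = np.zeros(161)
        x[32:128] = 2.0  # constant over exactly 0-30 ms
        prof = section_relative_energy(x, sig)
        for start in (0.0, 10.0, 20.0):
            assert prof.energy_at(start) == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=161)
        sig = ChannelSignal(x, FS, 32)
        prof = section_relative_energy(x, sig)
        t_ms = sig.time_ms
        total = np.sum(x ** 2)
        for start in (-10.0, 0.0, 10.0, 20.0, 30.0):
            mask = (t_ms >= start) & (t_ms < start + 10.0)
            assert prof.energy_at(start) == \
                pytest.approx(np.sum(x[mask] ** 2) / total, abs=1e-12)

    def test_zero_level_undefined(self):
        prof = section_relative_energy(np.zeros(161),
                                       ChannelSignal(np.zeros(161), FS, 32))
        assert not prof.defined


class TestLevelSelection:
    def test_clean_half_sine_keeps_d3_to_d5(self, coupled_event):
        record, _ = coupled_event
        # strongest linear channel carries the pulse
        d = modwt_mra(record.lin[0])
        kept, rejected = select_levels_linear(d)
        assert {"D3", "D4", "D5"} <= set(kept)
        assert set(rejected) == {"D1", "D2"}

    def test_late_burst_rejects_matching_band(self):
        base = _burst(80.0, 0.0, 8.0, amp=5.0)  # primary low-freq energy
        late = _burst(300.0, 22.0, 30.0, amp=2.0)
        d = modwt_mra(base.with_samples(base.samples + late.samples))
        kept, rejected = select_levels_linear(d)
        assert rejected.get("D3") == "late_energy"

    def test_d1_d2_never_kept(self):
        for seed in range(3):
            x = np.random.default_rng(seed).normal(size=161)
            kept, rejected = select_levels_linear(modwt_mra(ChannelSignal(x, FS, 32)))
            assert "D1" not in kept and "D2" not in kept
            kept_a, rejected_a = select_levels_angular(modwt_mra(ChannelSignal(x, FS, 32)))
            assert "D1" not in kept_a and "D2" not in kept_a

    def test_angular_d3_always_rejected(self, coupled_event):
        record, _ = coupled_event
        for g in record.gyro:
            kept, rejected = select_levels_angular(modwt_mra(g))
            assert "D3" not in kept
            assert "D3" in rejected

    def test_angular_d4_outright_rejection(self):
        # 150 Hz tone puts nearly all energy in D4 -> far above the 10% gate
        kept, rejected = select_levels_angular(modwt_mra(tone(150.0)))
        assert rejected.get("D4") == "outright_energy"

    def test_smooth_angular_pulse_keeps_d4_d5(self, coupled_event):
        record, _ = coupled_event
        # gyro channels carry a smooth raised-cosine pulse peaking 10-20 ms
        idx = int(np.argmax([np.max(np.abs(g.samples)) for g in record.gyro]))
        kept, _ = select_levels_angular(modwt_mra(record.gyro[idx]))
        assert {"D4", "D5"} <= set(kept)

    def test_selection_monotone_in_artifact_amplitude(self):
        base = _burst(80.0, 0.0, 8.0, amp=5.0)
        rejected_before = None
        for amp in (0.5, 1.0, 2.0, 4.0, 8.0):
            late = _burst(250.0, 20.0, 30.0, amp=amp)
            d = modwt_mra(base.with_samples(base.samples + late.samples))
            _, rejected = select_levels_linear(d)
            now = set(rejected)
            if rejected_before is not None:
                assert rejected_before <= now
            rejected_before = now


class TestReconstruct:
    def test_all_kept_reproduces_input(self):
        x = np.random.default_rng(1).normal(size=161)
        sig = ChannelSignal(x, FS, 32)
        d = modwt_mra(sig)
        out = reconstruct(d, list(LEVEL_NAMES))
        assert np.max(np.abs(out.samples - x)) < 1e-8 * np.max(np.abs(x))

    def test_pre_trigger_always_preserved(self):
        x = np.random.default_rng(2).normal(size=161)
        sig = ChannelSignal(x, FS, 32)
        d = modwt_mra(sig)
        out = reconstruct(d, ["A"])  # reject every detail
        assert np.allclose(out.samples[:32], x[:32], atol=1e-8)

    def test_rejection_reduces_artifact_peak(self):
        base = _burst(80.0, 0.0, 8.0, amp=5.0)
        late = _burst(250.0, 20.0, 30.0, amp=12.0)
        noisy = base.with_samples(base.samples + late.samples)
        d = modwt_mra(noisy)
        kept, _ = select_levels_linear(d)
        out = reconstruct(d, kept)
        assert np.max(out.samples[32:]) < np.max(noisy.samples[32:])

    def test_energy_non_increase(self):
        for seed in range(3):
            x = np.random.default_rng(seed).normal(size=161)
            sig = ChannelSignal(x, FS, 32)
            d = modwt_mra(sig)
            kept, _ = select_levels_linear(d)
            out = reconstruct(d, kept)
            pre_energy = np.sum(x[:32] ** 2)
            assert np.sum(out.samples ** 2) <= np.sum(x ** 2) + pre_energy + 1e-9


class TestSalvageEvent:
    def test_decoupled_error_shrinks(self, coupled_event, decoupled_twin,
                                     trained_model):
        _, truth = coupled_event
        rec_d, _ = decoupled_twin
        truth_peak = post_trigger_peak(truth.resultant_lin)
        raw_peak = post_trigger_peak(process_event(rec_d).resultant_lin)
        res = salvage_event(rec_d, trained_model)
        salv_peak = post_trigger_peak(
            process_event(res.salvaged_record).resultant_lin)
        assert abs(percent_error(salv_peak, truth_peak)) < \
            abs(percent_error(raw_peak, truth_peak))
        assert salv_peak < raw_peak  # peaks shrink
        assert res.reclassified_as is not None

    def test_coupled_event_nearly_unchanged(self, coupled_event):
        record, _ = coupled_event
        raw_peak = post_trigger_peak(process_event(record).resultant_lin)
        res = salvage_event(record)
        salv_peak = post_trigger_peak(
            process_event(res.salvaged_record).resultant_lin)
        assert abs(percent_error(salv_peak, raw_peak)) < 10.0

    def test_idempotent_on_clean_signal(self, coupled_event):
        record, _ = coupled_event
        first = salvage_event(record)
        second = salvage_event(first.salvaged_record)
        for name in first.kept_levels:
            assert set(first.kept_levels[name]) <= set(second.kept_levels[name])
        a = post_trigger_peak(process_event(first.salvaged_record).resultant_lin)
        b = post_trigger_peak(process_event(second.salvaged_record).resultant_lin)
        assert b == pytest.approx(a, rel=0.05)

    def test_pervasive_artifact_unsalvageable(self, coupled_event,
                                              trained_model):
        # the section-energy rule only catches artifacts whose energy is
        # concentrated late: a stationary in-band tone spanning the whole
        # window has uniform section energies (levels kept), and a late
        # bump below 50 Hz hides in the always-kept approximation — the
        # salvaged event therefore still looks decoupled
        record, truth = coupled_event
        t = record.lin[2].time_s
        peak_lin = np.max(truth.resultant_lin.samples)
        peak_ang = np.max(truth.resultant_ang_vel.samples)
        tone150 = np.sin(2 * np.pi * 150.0 * t)
        rel = t - 0.025
        bump = np.where(rel >= 0, np.exp(-np.maximum(rel, 0) / 0.015)
                        * np.sin(2 * np.pi * 40.0 * rel), 0.0)
        lin = list(record.lin)
        gyro = list(record.gyro)
        lin[2] = lin[2].with_samples(
            lin[2].samples + 2.0 * peak_lin * tone150 + 4.0 * peak_lin * bump)
        for i in (0, 1):
            gyro[i] = gyro[i].with_samples(
                gyro[i].samples + peak_ang * tone150 + 2.0 * peak_ang * bump)
        wrecked = replace(record, lin=tuple(lin), gyro=tuple(gyro),
                          label="decoupled")
        res = salvage_event(wrecked, trained_model)
        assert res.reclassified_as == "decoupled"
        assert res.salvage_success is False
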