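"""Passive geometric model of tail and nose oscillation."""

import numpy as np
import pytest

from locogait.coordination import feature_phase, phase_vs_cadence_delay
from locogait.passive import (HindPawDrive, PassiveModelConfig,
                              default_lever_arms, simulate_hind_paws,
                              simulate_passive, tail_angle)


def _zero_delay_config(**kw):
    return PassiveModelConfig(tail_base_delay_s=0.0, nose_delay_s=0.0,
                              delay_slope_ms=0.0, delay_intercept_ms=0.0, **kw)


def _sine_drive(cadence, amplitude=20.0, duration=3.0, dt=1 / 400.0,
                t0=-1.0):
    t = np.arange(t0, duration, dt)
    diff = amplitude * np.sin(2 * np.pi * cadence * t)
    return HindPawDrive(t=t, x_left=np.zeros_like(t), x_right=diff,
                        stride_duration_s=1.0 / cadence, cadence_hz=cadence)


class TestHindPawSimulation:
    def test_swing_slope_and_stance_flat(self):
        d = simulate_hind_paws(50.0, 0.1, 0.15, 0.0, 1.0, 1 / 400.0)
        v = np.diff(d.x_left) * 400.0
        assert set(np.round(np.unique(v), 6)) <= {0.0, 500.0}
        # swing slope = stride length / swing duration = 0.5 m/s
        assert np.max(v) == pytest.approx(500.0)

    def test_phase_half_shifts_second_paw(self):
        d = simulate_hind_paws(50.0, 0.1, 0.1, 0.5, 1.0, 1 / 400.0, t0_s=-0.5)
        n_half = int(0.1 * 400)       # half a 0.2 s stride
        sel = slice(n_half, len(d.t))
        np.testing.assert_allclose(d.x_right[sel],
                                   d.x_left[:len(d.t) - n_half], atol=1e-9)

    def test_mean_forward_speed(self):
        d = simulate_hind_paws(60.0, 0.1, 0.1, 0.0, 10.0, 1 / 400.0)
        speed = (d.x_left[-1] - d.x_left[0]) / (d.t[-1] - d.t[0])
        assert speed == pytest.approx(60.0 / 0.2, rel=0.01)

    def test_dt_longer_than_swing_raises(self):
        with pytest.raises(ValueError):
            simulate_hind_paws(50.0, 0.001, 0.1, 0.0, 1.0, 0.01)


class TestTailAngle:
    def test_level_paws_angle_zero(self):
        assert tail_angle(5.0, 5.0, 25.0) == 0.0

    def test_offset_equal_to_width_gives_45_degrees(self):
        assert tail_angle(0.0, 25.0, 25.0) == pytest.approx(np.pi / 4)

    def test_wider_base_strictly_smaller_angle(self):
        widths = np.array([15.0, 20.0, 25.0, 30.0, 40.0])
        angles = [abs(tail_angle(0.0, 10.0, w)) for w in widths]
        assert np.all(np.diff(angles) < 0)


class TestSimulatePassive:
    def test_aligned_paws_zero_lateral_positions(self):
        config = _zero_delay_config()
        t = np.arange(-0.5, 1.0, 1 / 400.0)
        drive = HindPawDrive(t=t, x_left=np.full_like(t, 7.0),
                             x_right=np.full_like(t, 7.0),
                             stride_duration_s=0.25, cadence_hz=4.0)
        out = simulate_passive(config, drive)
        np.testing.assert_allclose(out["tail"], 0.0)
        np.testing.assert_allclose(out["nose"], 0.0)

    def test_zero_delay_nose_antiphase_to_tail_base(self):
        config = _zero_delay_config()
        out = simulate_passive(config, _sine_drive(4.0))
        tail_base = out["tail"][:, 0] / config.lever_arms_mm[0]
        nose = out["nose"] / config.nose_lever_mm
        np.testing.assert_allclose(nose, -tail_base, atol=1e-9)

    def test_sine_bound_on_amplitudes(self):
        config = PassiveModelConfig()
        out = simulate_passive(config, _sine_drive(4.0, amplitude=60.0))
        finite = np.isfinite(out["tail"])
        assert np.all(np.abs(out["tail"][finite])
                      <= config.lever_arms_mm[None, :].repeat(
                          out["tail"].shape[0], 0)[finite] + 1e-9)
        assert np.nanmax(np.abs(out["nose"])) <= config.nose_lever_mm + 1e-9

    def test_amplitude_monotone_decreasing_in_base_width(self):
        amps = []
        for w in (15.0, 25.0, 35.0, 50.0):
            config = _zero_delay_config(base_width_mm=w)
            out = simulate_passive(config, _sine_drive(4.0))
            amps.append(np.nanmax(np.abs(out["tail"][:, -1])))
        assert np.all(np.diff(amps) < 0)

    def test_delay_schedule_accumulates_from_base(self):
        config = PassiveModelConfig()
        d = config.segment_delays_s()
        assert d[0] == pytest.approx(0.031)
        # increment between base and segment 2: (-0.23*1 + 3.97) ms
        assert d[1] - d[0] == pytest.approx(3.74e-3)
        assert np.all(np.diff(d) >= 0)
        # increments shrink along the tail
        assert np.all(np.diff(np.diff(d)) < 0)

    def test_insufficient_history_flagged_missing(self):
        config = PassiveModelConfig(nose_delay_s=0.5)
        out = simulate_passive(config, _sine_drive(4.0, t0=-0.1))
        assert np.isnan(out["nose"][0])


class TestTimeLockedSignature:
    def test_segment_phase_slope_equals_total_delay(self):
        """Cross-module check: the coordination module's phase estimator,
        applied to passive-model output, recovers each segment's delay as
        the slope of phase against cadence."""
        config = PassiveModelConfig()
        delays = config.segment_delays_s()
        for seg in (0, 7, 14):
            cads, phases = [], []
            for cadence in (2.0, 3.0, 4.0, 5.0):
                n = int(400 / cadence)
                drive = _sine_drive(cadence, dt=1 / 400.0)
                out = simulate_passive(config, drive)
                ok = np.isfinite(out["tail"][:, seg])
                sig = out["tail"][ok, seg][:4 * n]
                ref = np.interp(out["t"][ok], drive.t,
                                drive.difference())[:4 * n]
                # fold onto one cycle
                one_sig = sig[:n]
                one_ref = ref[:n]
                phases.append(feature_phase(one_sig, one_ref))
                cads.append(cadence)
            fit = phase_vs_cadence_delay(np.array(cads), np.array(phases))
            assert fit["delay_s"] == pytest.approx(delays[seg], abs=0.004)

    def test_zero_delay_model_is_phase_locked(self):
        config = _zero_delay_config()
        cads, phases = [], []
        for cadence in (2.0, 4.0, 6.0):
            n = int(400 / cadence)
            drive = _sine_drive(cadence)
            out = simulate_passive(config, drive)
            sig = out["tail"][:n, 0]
            ref = np.interp(out["t"], drive.t, drive.difference())[:n]
            phases.append(feature_phase(sig, ref))
            cads.append(cadence)
        fit = phase_vs_cadence_delay(np.array(cads), np.array(phases))
        assert fit["delay_s"] == pytest.approx(0.0, abs=0.003)


class TestConfigValidation:
    def test_non_increasing_lever_arms_raise(self):
        with pytest.raises(ValueError):
            PassiveModelConfig(lever_arms_mm=np.array([10.0, 9.0, 11.0]))

    def test_negative_delay_raises(self):
        with pytest.raises(ValueError):
            PassiveModelConfig(tail_base_delay_s=-0.01)

    def test_default_lever_arms_increase(self):
        arms = default_lever_arms()
        assert len(arms) == 15 and np.all(np.diff(arms) > 0)
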