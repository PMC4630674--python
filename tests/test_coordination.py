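"""Interlimb and whole-body coordination metrics."""

import numpy as np
import pytest

from locogait.coordination import (circular_mean, coefficient_of_variation,
                                   correlation_matrix, double_support,
                                   feature_phase, paw_distance,
                                   phase_vs_cadence_delay, stance_phase,
                                   support_fractions, unwrap_phases)

T = 0.25    # reference stride duration, s


def _trot_intervals(duty, phase_map=None, k_range=(-3, 10)):
    """Stance intervals (touchdown, liftoff) for an ideal trot."""
    phase_map = phase_map or {"FR": 0.0, "HL": 0.0, "FL": 0.5, "HR": 0.5}
    return {p: [((k + ph) * T, (k + ph + duty) * T)
                for k in range(*k_range)]
            for p, ph in phase_map.items()}


class TestStancePhase:
    def test_half_cycle_touchdown(self):
        assert stance_phase(0.0, T, np.array([0.125])) == pytest.approx(0.5)

    def test_simultaneous_touchdown_is_zero(self):
        assert stance_phase(0.0, T, np.array([0.0])) == 0.0

    def test_touchdown_just_before_reference_wraps(self):
        assert stance_phase(0.0, T, np.array([-0.025])) == pytest.approx(0.9)

    def test_no_touchdown_in_window_is_missing(self):
        assert np.isnan(stance_phase(0.0, T, np.array([10.0])))


class TestSupportFractions:
    def _oracle(self, intervals, duty, phase_map):
        """Interval-arithmetic reference: exact event-grid computation."""
        events = sorted({e for ivs in intervals.values() for ab in ivs
                         for e in ab if 0 <= e <= T} | {0.0, T})
        fractions = {}
        for a, b in zip(events[:-1], events[1:]):
            mid = (a + b) / 2
            down = {p for p, ivs in intervals.items()
                    if any(lo <= mid < hi for lo, hi in ivs)}
            if len(down) == 2:
                cat = "two_diagonal" if down in ({"FR", "HL"}, {"FL", "HR"}) \
                    else "two_other"
            else:
                cat = {0: "zero", 1: "one", 3: "three", 4: "four"}[len(down)]
            fractions[cat] = fractions.get(cat, 0.0) + (b - a) / T
        return fractions

    @pytest.mark.parametrize("duty,expected", [
        (0.5, {"two_diagonal": 1.0}),
        (0.6, {"four": 0.2, "two_diagonal": 0.8}),
        (0.4, {"two_diagonal": 0.8, "zero": 0.2}),
    ])
    def test_ideal_trot_matches_closed_form(self, duty, expected):
        out = support_fractions(_trot_intervals(duty), 0.0, T)
        for cat, frac in expected.items():
            assert out[cat] == pytest.approx(frac, abs=0.005)
        assert sum(out.values()) == pytest.approx(1.0)

    def test_matches_interval_arithmetic_oracle_on_random_phasings(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pm = {p: float(rng.uniform(0, 1)) for p in ("FR", "FL", "HR", "HL")}
            duty = float(rng.uniform(0.3, 0.8))
            ivs = _trot_intervals(duty, pm)
            got = support_fractions(ivs, 0.0, T, n_samples=5000)
            want = self._oracle(ivs, duty, pm)
            for cat in got:
                assert got[cat] == pytest.approx(want.get(cat, 0.0), abs=0.003)

    def test_all_paws_down_is_pure_four_support(self):
        ivs = {p: [(-1.0, 10.0)] for p in ("FR", "FL", "HR", "HL")}
        out = support_fractions(ivs, 0.0, T)
        assert out["four"] == 1.0

    def test_missing_paw_raises(self):
        with pytest.raises(ValueError, match="missing"):
            support_fractions({"FR": [(0, 1)]}, 0.0, T)


class TestDoubleSupport:
    @pytest.mark.parametrize("duty,expected", [(0.6, 10.0), (0.5, 0.0),
                                               (0.4, -10.0)])
    def test_antiphase_identity(self, duty, expected):
        # contralateral paw at phase 0.5: lift-offs at (k + 0.5 + duty) * T
        lifts = np.array([(k + 0.5 + duty) * T for k in range(-3, 5)])
        assert double_support(0.0, T, lifts) == pytest.approx(expected)

    def test_below_back_window_is_missing(self):
        lifts = np.array([-0.3 * T, 1.2 * T])
        assert np.isnan(double_support(0.0, T, lifts))


class TestPawDistance:
    def test_identical_positions_zero(self):
        assert paw_distance((5.0, 3.0), (5.0, 3.0)) == 0.0

    def test_three_four_five(self):
        assert paw_distance((0.0, 0.0), (3.0, 4.0)) == pytest.approx(5.0)

    def test_jittered_distances_cv_matches_generative(self):
        rng = np.random.default_rng(8)
        base = np.array([20.0, 0.0])
        d = [paw_distance((0.0, 0.0), tuple(base + rng.normal(0, 1.0, 2)))
             for _ in range(4000)]
        # distance ~ |N([20,0], I)|: sd ≈ 1, mean ≈ 20 -> CV ≈ 0.05
        assert coefficient_of_variation(np.array(d)) == pytest.approx(
            0.05, rel=0.15)

    def test_missing_event_gives_nan(self):
        assert np.isnan(paw_distance((np.nan, 0.0), (1.0, 1.0)))


class TestFeaturePhase:
    def test_identical_signals_zero_phase(self):
        sig = np.sin(2 * np.pi * np.arange(100) / 100)
        assert feature_phase(sig, sig) == 0.0

    def test_negated_signal_half_phase(self):
        sig = np.sin(2 * np.pi * np.arange(100) / 100)
        assert feature_phase(-sig, sig) == pytest.approx(0.5)

    def test_imposed_delay_recovered(self):
        # 31 ms delay at 4 Hz cadence -> phase 0.124
        n, cadence, delay = 100, 4.0, 0.031
        ref = np.sin(2 * np.pi * np.arange(n) / n)
        feat = np.sin(2 * np.pi * (np.arange(n) / n - cadence * delay))
        assert feature_phase(feat, ref) == pytest.approx(0.124, abs=0.01)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        n = 200
        base = np.sin(2 * np.pi * np.arange(n) / n) \
            + 0.3 * np.sin(4 * np.pi * np.arange(n) / n)
        p0 = feature_phase(base, base)
        for shift in (10, 57, 123):
            shifted = np.roll(base, shift)
            expect = (p0 + shift / n) % 1.0
            assert feature_phase(shifted, base) == pytest.approx(expect,
                                                                 abs=1e-9)

    def test_constant_signal_is_missing(self):
        assert np.isnan(feature_phase(np.ones(100), np.sin(np.arange(100.0))))


class TestPhaseVsCadenceDelay:
    def test_exact_recovery_of_96_ms_delay(self):
        cad = np.array([2.0, 4.0, 6.0])
        phases = (cad * 0.096) % 1.0
        fit = phase_vs_cadence_delay(cad, phases)
        assert fit["delay_s"] == pytest.approx(0.096, abs=1e-12)

    def test_phase_locked_regime_zero_slope(self):
        fit = phase_vs_cadence_delay(np.array([2.0, 4.0, 6.0]),
                                     np.array([0.3, 0.3, 0.3]))
        assert fit["delay_s"] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_phase_slope_within_ten_percent(self):
        # 12 speed bins spanning the physiological cadence range; with
        # sigma = 0.02 cycles the slope's standard error is then ~3.5% of a
        # 96 ms delay, so a 10% band holds in well over 95% of runs
        ok = 0
        cad = np.arange(1.5, 7.25, 0.5)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            phases = (cad * 0.096 + rng.normal(0, 0.02, len(cad))) % 1.0
            fit = phase_vs_cadence_delay(cad, phases)
            if abs(fit["delay_s"] - 0.096) <= 0.1 * 0.096:
                ok += 1
        assert ok >= 95

    def test_unwrap_assumes_small_steps(self):
        assert unwrap_phases(np.array([0.8, 0.1, 0.3])).tolist() == \
            pytest.approx([0.8, 1.1, 1.3])

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError):
            phase_vs_cadence_delay(np.array([2.0, 4.0]), np.array([0.1, 0.2]))


class TestCorrelationMatrix:
    def test_identical_and_negated_trajectories(self):
        sig = np.sin(2 * np.pi * np.arange(100) / 100)
        mat, names = correlation_matrix({"a": sig, "b": sig, "c": -sig})
        assert mat[0, 1] == pytest.approx(1.0)
        assert mat[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(mat), 1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(12)
        trajs = {f"t{i}": rng.normal(size=100) for i in range(4)}
        mat, names = correlation_matrix(trajs)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i == j:
                    continue
                x, y = trajs[a] - trajs[a].mean(), trajs[b] - trajs[b].mean()
                want = (x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum())
                assert mat[i, j] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_entry_flagged_nan(self):
        mat, _ = correlation_matrix({"a": np.ones(100),
                                     "b": np.sin(np.arange(100.0))})
        assert np.isnan(mat[0, 1])


class TestCoefficientOfVariation:
    def test_constant_values_zero(self):
        assert coefficient_of_variation(np.array([1.0, 1.0, 1.0])) == 0.0

    def test_two_point_sample(self):
        assert coefficient_of_variation(np.array([8.0, 12.0])) == \
            pytest.approx(0.2828, abs=2e-4)

    def test_lognormal_closed_form(self):
        sigma = 0.4
        rng = np.random.default_rng(21)
        x = rng.lognormal(0.0, sigma, 10_000)
        want = np.sqrt(np.exp(sigma ** 2) - 1.0)
        assert coefficient_of_variation(x) == pytest.approx(want, rel=0.02)

    def test_zero_mean_raises(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(np.array([-1.0, 1.0]))
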