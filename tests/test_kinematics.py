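"""Signal-processing chain: triggering, filtering, CoG transform, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haekit.config import ConfigError, KinematicsConfig
from haekit.kinematics import (HAERecord, KinematicTrace, RawTrace, apply_trigger,
                               compute_paa, compute_pla, compute_rvci,
                               lowpass_filter, process_event, transform_to_cog)

FS = 3200.0


def make_raw(a, omega=None, start=0.0, noise_class=0):
    a = np.asarray(a, float)
    if omega is None:
        omega = np.zeros_like(a)
    return RawTrace(player_id="P0", fixture_id="F0", start_time=start,
                    a=a, omega=omega, noise_class=noise_class, trace_id="t")


def make_trace(a, omega=None, noise_class=0):
    a = np.asarray(a, float)
    if omega is None:
        omega = np.zeros_like(a)
    n = a.shape[1]
    return KinematicTrace(hae_id="h", player_id="P0", fixture_id="F0",
                          trigger_timestamp=0.0, t=np.arange(n) / FS,
                          a_m=a, omega=omega, noise_class=noise_class)


def half_sine(n, start, dur_s, amp, fs=FS):
    t = np.arange(n) / fs
    x = np.zeros(n)
    m = (t >= start) & (t <= start + dur_s)
    x[m] = amp * np.sin(np.pi * (t[m] - start) / dur_s)
    return x


class TestTrigger:
    def test_subthreshold_never_triggers(self, kin):
        a = np.full((3, int(FS)), 5.0)
        assert apply_trigger(make_raw(a), kin) == []

    def test_single_pulse_one_window_trigger_at_sample_32(self, kin):
        n = int(FS)  # 1 s
        a = np.zeros((3, n))
        a[0] = half_sine(n, 0.5, 0.010, 30.0)
        wins = apply_trigger(make_raw(a), kin)
        assert len(wins) == 1
        w = wins[0]
        assert w.a_m.shape == (3, 160)
        # the trigger sample (first >8 g) sits at index 32 (10 ms pre-trigger)
        k = np.flatnonzero(np.abs(a[0]) > kin.trigger_threshold)[0]
        assert np.isclose(w.a_m[0, 32], a[0, k])
        assert np.all(np.abs(w.a_m[0, :32]) <= kin.trigger_threshold)
        assert np.isclose(w.trigger_timestamp, k / FS)

    def test_rearming_two_pulses_20ms_apart_one_window(self, kin):
        n = int(FS)
        a = np.zeros((3, n))
        a[0] = half_sine(n, 0.5, 0.008, 30.0) + half_sine(n, 0.52, 0.008, 30.0)
        assert len(apply_trigger(make_raw(a), kin)) == 1

    def test_rearming_two_pulses_60ms_apart_two_windows(self, kin):
        n = int(FS)
        a = np.zeros((3, n))
        a[0] = half_sine(n, 0.5, 0.008, 30.0) + half_sine(n, 0.56, 0.008, 30.0)
        assert len(apply_trigger(make_raw(a), kin)) == 2

    def test_early_trigger_zero_padded_and_flagged(self, kin):
        n = 400
        a = np.zeros((3, n))
        a[0] = half_sine(n, 0.002, 0.010, 30.0)
        wins = apply_trigger(make_raw(a), kin)
        assert len(wins) == 1
        assert wins[0].head_padded
        assert wins[0].a_m.shape == (3, 160)

    def test_trigger_on_any_axis(self, kin):
        n = int(FS // 2)
        for axis in range(3):
            a = np.zeros((3, n))
            a[axis] = half_sine(n, 0.1, 0.010, -20.0)  # negative excursion
            assert len(apply_trigger(make_raw(a), kin)) == 1


class TestFilter:
    def test_dc_invariance(self, kin):
        a = np.full((3, 160), 7.5)
        out = lowpass_filter(make_trace(a), kin)
        assert np.allclose(out.a_m, 7.5, atol=1e-6)

    def test_800hz_attenuation(self, kin):
        t = np.arange(1600) / FS
        a = np.zeros((3, 1600))
        a[0] = np.sin(2 * np.pi * 800.0 * t)
        out = lowpass_filter(make_trace(a), kin)
        mid = out.a_m[0, 400:1200]
        # squared 2-pole Butterworth magnitude at 4x cutoff: 1/(1+4^4)
        predicted = 1.0 / (1.0 + (800.0 / 200.0) ** 4)
        measured = np.abs(mid).max()
        assert measured < 0.03
        assert abs(measured - predicted) < 0.03

    @pytest.mark.parametrize("noise_class,cutoff", [(0, 200.0), (1, 100.0), (2, 50.0)])
    def test_noise_class_cutoff_routing(self, kin, noise_class, cutoff):
        out = lowpass_filter(make_trace(np.zeros((3, 160)), noise_class=noise_class), kin)
        assert out.applied_cutoff == cutoff

    def test_idempotent_in_passband(self, kin):
        t = np.arange(1600) / FS
        a = np.zeros((3, 1600))
        a[0] = np.sin(2 * np.pi * 30.0 * t)  # well inside the passband
        once = lowpass_filter(make_trace(a), kin)
        twice = lowpass_filter(once, kin)
        rms = np.sqrt(np.mean((twice.a_m - once.a_m) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(once.a_m ** 2))

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            KinematicsConfig(primary_cutoff=1600.0)


class TestCogTransform:
    def test_zero_lever_arm_is_identity(self, kin, rng):
        k0 = KinematicsConfig(r_mh=(0.0, 0.0, 0.0))
        a = rng.normal(size=(3, 160))
        w = rng.normal(size=(3, 160))
        out = transform_to_cog(make_trace(a, w), k0)
        assert np.allclose(out, a, rtol=0, atol=1e-12)

    def test_tangential_term_hand_computed(self, kin):
        # constant alpha = (0,0,100) rad/s^2 from a linear omega_z ramp;
        # alpha x r_mh = (-0.9, -8.2, 0) m/s^2
        n = 160
        t = np.arange(n) / FS
        omega = np.zeros((3, n))
        omega[2] = 100.0 * t
        a = np.zeros((3, n))
        out_si = transform_to_cog(make_trace(a, omega), kin) * kin.gravity_constant
        expected = np.array([-0.9, -8.2, 0.0])
        # centripetal term grows as omega_z^2 t^2; compare at the start
        assert np.allclose(out_si[:, 0], expected, rtol=1e-12, atol=1e-9)

    def test_centripetal_term_hand_computed(self, kin):
        # constant omega = (0,0,10): omega x (omega x r) = (8.2, -0.9, 0) m/s^2
        n = 160
        omega = np.zeros((3, n))
        omega[2] = 10.0
        a = np.zeros((3, n))
        out_si = transform_to_cog(make_trace(a, omega), kin) * kin.gravity_constant
        expected = np.array([8.2, -0.9, 0.0])
        assert np.allclose(out_si[:, 80], expected, rtol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_linearity_in_sensor_acceleration(self, seed):
        kin = KinematicsConfig()
        rg = np.random.default_rng(seed)
        a1 = rg.normal(size=(3, 64))
        a2 = rg.normal(size=(3, 64))
        w = rg.normal(size=(3, 64))
        lhs = transform_to_cog(make_trace(a1 + a2, w), kin)
        rhs = transform_to_cog(make_trace(a2, w), kin)
        assert np.allclose(lhs - rhs, a1, atol=1e-10)


class TestMetrics:
    def test_pla_345(self):
        a = np.tile([[3.0], [4.0], [0.0]], (1, 160))
        assert compute_pla(a) == pytest.approx(5.0)

    def test_pla_zero(self):
        assert compute_pla(np.zeros((3, 160))) == 0.0

    def test_paa_constant_omega_zero(self, kin):
        assert compute_paa(np.full((3, 160), 5.0), kin) == pytest.approx(0.0)

    def test_paa_sine_analytic(self, kin):
        t = np.arange(800) / FS
        omega = np.zeros((3, 800))
        omega[2] = 10.0 * np.sin(2 * np.pi * 50.0 * t)
        expected = 10.0 * 2 * np.pi * 50.0
        assert compute_paa(omega, kin) == pytest.approx(expected, rel=0.01)

    def test_paa_linear_ramp(self, kin):
        t = np.arange(160) / FS
        omega = np.zeros((3, 160))
        omega[2] = 10.0 * t  # slope 10 rad/s^2 over the 50 ms window
        assert compute_paa(omega, kin) == pytest.approx(10.0, rel=1e-9)

    def test_rvci_constant_zero(self, kin):
        assert compute_rvci(np.full((3, 160), 3.0), kin) == 0.0

    def test_rvci_linear_ramp_closed_form(self, kin):
        # slope 10 rad/s^2: max delta-omega over 10 ms = 0.1 rad/s on z
        t = np.arange(160) / FS
        omega = np.zeros((3, 160))
        omega[2] = 10.0 * t
        expected = np.sqrt(1.17) * 10.0 * kin.rvci_duration
        assert compute_rvci(omega, kin) == pytest.approx(expected, rel=1e-9)

    def test_rvci_step_on_x(self, kin):
        omega = np.zeros((3, 160))
        omega[0, 80:] = 2.0
        assert compute_rvci(omega, kin) == pytest.approx(2.0, rel=1e-12)

    def test_rvci_window_longer_than_trace_rejected(self, kin):
        with pytest.raises(ConfigError):
            compute_rvci(np.zeros((3, 16)), kin)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rvci_equals_bruteforce_pair_search(self, seed):
        kin = KinematicsConfig()
        rg = np.random.default_rng(seed)
        omega = rg.normal(size=(3, 60))
        w = np.array(kin.rvci_weights)
        best = 0.0
        for i in range(60):
            for j in range(i + 1, min(i + kin.rvci_window_samples, 59) + 1):
                d = omega[:, j] - omega[:, i]
                best = max(best, float(np.sqrt((w * d * d).sum())))
        assert compute_rvci(omega, kin) == best


class TestProcessEvent:
    def test_all_zero_trace(self, kin):
        rec = process_event(make_trace(np.zeros((3, 160))), kin)
        assert rec.pla == rec.paa == rec.rvci == 0.0
        assert rec.applied_cutoff == 200.0

    def test_class1_applied_cutoff(self, kin):
        rec = process_event(make_trace(np.zeros((3, 160)), noise_class=1), kin)
        assert rec.applied_cutoff == 100.0

    def test_time_reversal_invariance(self, kin, rng):
        # PAA and RVCI depend on angular velocity only through norms of
        # differences, so they are reversal-invariant; PLA is too in the
        # absence of rotation (with rotation, the alpha x r term of the
        # CoG transform changes sign under reversal).
        t = np.arange(160) / FS
        a = np.zeros((3, 160))
        a[0] = half_sine(160, 0.02, 0.012, 25.0)
        w = np.zeros((3, 160))
        w[2] = 3.0 * np.sin(2 * np.pi * 40 * t)
        fwd = process_event(make_trace(a, w), kin)
        bwd = process_event(make_trace(a[:, ::-1].copy(), w[:, ::-1].copy()), kin)
        assert fwd.paa == pytest.approx(bwd.paa, rel=1e-6)
        assert fwd.rvci == pytest.approx(bwd.rvci, rel=1e-9)
        fwd0 = process_event(make_trace(a), kin)
        bwd0 = process_event(make_trace(a[:, ::-1].copy()), kin)
        assert fwd0.pla == pytest.approx(bwd0.pla, rel=1e-9)
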