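"""Kinematic criteria: closed forms, the exhaustive window-search oracle,
monotonicity and unit invariances."""

import numpy as np
import pytest

from headcrit import (
    CriterionConstants,
    KinematicsRecord,
    bric,
    compute_all_kinematic,
    gambit,
    hic,
    hip,
    ric,
)
from headcrit.errors import ValidationError


def make_record(t, lin=None, rot=None, vel=None, unit_lin="g", g_value=9.81):
    n = len(t)
    zeros = np.zeros((3, n))
    return KinematicsRecord("test", t, lin if lin is not None else zeros,
                            rot if rot is not None else zeros,
                            vel if vel is not None else zeros,
                            unit_lin=unit_lin, g_value=g_value)


def constant_lin_record(peak_g, duration, dt=1e-4, unit_lin="g", g_value=9.81):
    t = np.arange(0, duration + dt / 2, dt)
    lin = np.zeros((3, len(t)))
    lin[0] = peak_g if unit_lin == "g" else peak_g * g_value
    return make_record(t, lin=lin, unit_lin=unit_lin, g_value=g_value)


def windowed_max_oracle(t, v, cap):
    """Exhaustive all-window-pairs search, trapezoids accumulated stepwise.

    Independent of the production path: no prefix-integral array, plain
    Python accumulation per start index.
    """
    n = len(t)
    best = 0.0
    for i in range(n - 1):
        acc = 0.0
        for j in range(i + 1, n):
            acc += 0.5 * (v[j] + v[j - 1]) * (t[j] - t[j - 1])
            dt = t[j] - t[i]
            if dt > cap * (1 + 1e-9):
                break
            best = max(best, dt * (acc / dt) ** 2.5)
    return best


class TestHic:
    def test_zero_signal(self):
        rec = make_record(np.arange(0, 0.02, 1e-3))
        assert hic(rec).value == 0.0

    def test_constant_100g_20ms_closed_form(self):
        rec = constant_lin_record(100.0, 0.020, dt=1e-3)
        res = hic(rec)
        assert res.value == pytest.approx(1500.0, rel=1e-9)
        t1, t2 = res.window
        assert t2 - t1 == pytest.approx(0.015, abs=1e-12)

    def test_window_cap_override_gives_hic36(self):
        rec = constant_lin_record(100.0, 0.050, dt=1e-3)
        res = hic(rec, CriterionConstants(hic_window_max=0.036))
        assert res.value == pytest.approx(100.0 ** 2.5 * 0.036, rel=1e-9)

    def test_scaling_linear_channel_scales_hic_by_k_pow_2p5(self, haversine_pulse):
        rec, _ = haversine_pulse
        k = 1.7
        scaled = make_record(rec.t, lin=k * rec.lin_acc, rot=rec.rot_acc,
                             vel=rec.rot_vel, unit_lin=rec.unit_lin)
        assert hic(scaled).value == pytest.approx(k ** 2.5 * hic(rec).value,
                                                  rel=1e-12)

    def test_unit_sanity_g_vs_si_storage(self, haversine_pulse):
        rec, _ = haversine_pulse
        si = rec.with_units("m_per_s2")
        assert hic(si).value == pytest.approx(hic(rec).value, rel=1e-12)

    def test_too_short_record(self):
        with pytest.raises(ValidationError):
            hic(make_record([0.0]))


class TestRic:
    def test_zero_rotational(self):
        rec = make_record(np.arange(0, 0.05, 1e-3))
        assert ric(rec).value == 0.0

    def test_constant_1000rads2_50ms_closed_form(self):
        t = np.arange(0, 0.050 + 5e-4, 1e-3)
        rot = np.zeros((3, len(t)))
        rot[2] = 1000.0
        rec = make_record(t, rot=rot)
        assert ric(rec).value == pytest.approx(1000.0 ** 2.5 * 0.036, rel=1e-9)

    def test_short_record_evaluated_over_full_duration(self, caplog):
        t = np.arange(0, 0.020 + 5e-4, 1e-3)
        rot = np.zeros((3, len(t)))
        rot[0] = 500.0
        rec = make_record(t, rot=rot)
        import logging
        with caplog.at_level(logging.WARNING, logger="headcrit.kinematic"):
            res = ric(rec)
        assert res.value == pytest.approx(500.0 ** 2.5 * 0.020, rel=1e-9)
        assert any("full duration" in m for m in caplog.messages)


@pytest.mark.parametrize("seed", range(8))
def test_window_search_equals_exhaustive_oracle(seed):
    """hic and ric match an all-pairs window search on random pulse mixes."""
    r = np.random.default_rng(seed)
    n = int(r.integers(30, 400))
    t = np.cumsum(r.uniform(0.5e-4, 2e-4, n))
    lin = r.uniform(0, 80, (3, n)) * np.sin(
        np.pi * np.linspace(0, 1, n)) ** 2
    rot = r.uniform(0, 5000, (3, n)) * np.sin(
        np.pi * np.linspace(0, 1, n)) ** 2
    rec = make_record(t, lin=lin, rot=rot)
    a_res = np.linalg.norm(lin, axis=0)
    alpha_res = np.linalg.norm(rot, axis=0)
    assert hic(rec).value == pytest.approx(
        windowed_max_oracle(t, a_res, 0.015), rel=1e-9)
    assert ric(rec).value == pytest.approx(
        windowed_max_oracle(t, alpha_res, 0.036), rel=1e-9)


class TestGambit:
    def test_critical_linear_only(self):
        rec = constant_lin_record(350.0, 0.01)
        assert gambit(rec).value == pytest.approx(1.0, rel=1e-12)

    def test_critical_rotational_only(self):
        t = np.arange(0, 0.01, 1e-3)
        rot = np.zeros((3, len(t)))
        rot[1] = 12_000.0
        assert gambit(make_record(t, rot=rot)).value == pytest.approx(1.0, rel=1e-12)

    def test_half_critical_both_axes(self):
        t = np.arange(0, 0.01, 1e-3)
        lin = np.zeros((3, len(t)))
        lin[0] = 175.0
        rot = np.zeros((3, len(t)))
        rot[2] = 6000.0
        val = gambit(make_record(t, lin=lin, rot=rot)).value
        assert val == pytest.approx(np.sqrt(0.5), rel=1e-12)

    def test_time_shift_invariance(self, haversine_pulse):
        rec, _ = haversine_pulse
        shifted = make_record(rec.t + 0.5, lin=rec.lin_acc, rot=rec.rot_acc,
                              vel=rec.rot_vel, unit_lin=rec.unit_lin)
        assert gambit(shifted).value == gambit(rec).value

    def test_never_decreases_under_linear_scaling(self, haversine_pulse):
        rec, _ = haversine_pulse
        scaled = make_record(rec.t, lin=1.5 * rec.lin_acc, rot=rec.rot_acc,
                             vel=rec.rot_vel, unit_lin=rec.unit_lin)
        assert gambit(scaled).value >= gambit(rec).value


class TestHip:
    def test_zero_record(self):
        rec = make_record(np.arange(0, 0.1, 1e-3), unit_lin="m_per_s2")
        assert hip(rec).value == 0.0

    def test_constant_linear_channel_closed_form(self):
        # m * a * (a*T) = 4.5 * 10 * 10 * 0.1 = 45 W = 0.045 kW
        t = np.arange(0, 0.1 + 5e-4, 1e-3)
        lin = np.zeros((3, len(t)))
        lin[0] = 10.0
        rec = make_record(t, lin=lin, unit_lin="m_per_s2")
        assert hip(rec).value == pytest.approx(0.045, rel=1e-9)

    def test_constant_rotational_channel_closed_form(self):
        # I_zz * alpha * (alpha*T) = 0.022 * 100 * 100 * 1 = 220 W = 0.22 kW
        t = np.arange(0, 1.0 + 5e-4, 1e-3)
        rot = np.zeros((3, len(t)))
        rot[2] = 100.0
        rec = make_record(t, rot=rot, unit_lin="m_per_s2")
        assert hip(rec).value == pytest.approx(0.22, rel=1e-9)

    def test_never_decreases_under_linear_scaling(self, haversine_pulse):
        rec, _ = haversine_pulse
        scaled = make_record(rec.t, lin=2.0 * rec.lin_acc, rot=rec.rot_acc,
                             vel=rec.rot_vel, unit_lin=rec.unit_lin)
        assert hip(scaled).value >= hip(rec).value

    def test_signed_maximum_on_rebound(self):
        # acceleration then equal deceleration: power peaks mid-pulse, and
        # the signed convention must not pick the (negative) rebound extreme
        t = np.arange(0, 0.2 + 5e-4, 1e-3)
        lin = np.zeros((3, len(t)))
        lin[0] = np.where(t <= 0.1, 10.0, -10.0)
        rec = make_record(t, lin=lin, unit_lin="m_per_s2")
        assert hip(rec).value == pytest.approx(0.045, rel=1e-6)


class TestBric:
    def test_critical_velocity_only(self):
        t = np.arange(0, 0.01, 1e-3)
        vel = np.zeros((3, len(t)))
        vel[2] = 140.0
        assert bric(make_record(t, vel=vel)).value == pytest.approx(1.0, rel=1e-12)

    def test_critical_acceleration_only(self):
        t = np.arange(0, 0.01, 1e-3)
        rot = np.zeros((3, len(t)))
        rot[0] = 12_000.0
        assert bric(make_record(t, rot=rot)).value == pytest.approx(1.0, rel=1e-12)

    def test_half_and_half(self):
        t = np.arange(0, 0.01, 1e-3)
        rot = np.zeros((3, len(t)))
        rot[0] = 6000.0
        vel = np.zeros((3, len(t)))
        vel[1] = 70.0
        assert bric(make_record(t, rot=rot, vel=vel)).value == pytest.approx(
            1.0, rel=1e-12)

    def test_missing_rot_vel_rejected(self):
        rec = KinematicsRecord("x", np.arange(0, 0.01, 1e-3),
                               np.zeros((3, 10)), np.zeros((3, 10)))
        with pytest.raises(ValidationError, match="rotational-velocity"):
            bric(rec)


class TestComputeAll:
    def test_zero_record_all_zero(self):
        rec = make_record(np.arange(0, 0.05, 1e-3))
        results = compute_all_kinematic(rec)
        assert [r.name for r in results] == ["HIC", "GAMBIT", "BrIC", "RIC", "HIP"]
        assert all(r.value == 0.0 for r in results)

    def test_matches_individual_ops(self, haversine_pulse):
        rec, _ = haversine_pulse
        combined = {r.name: r.value for r in compute_all_kinematic(rec)}
        separate = {"HIC": hic(rec).value, "GAMBIT": gambit(rec).value,
                    "BrIC": bric(rec).value, "RIC": ric(rec).value,
                    "HIP": hip(rec).value}
        assert combined == separate
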