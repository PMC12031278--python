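"""Complementary-filter unit behavior: increments, corrections, convergence."""

import numpy as np
import pytest

from skiturn import quat
from skiturn.fusion import (ComplementaryFilter, FusionParams, YawUnobservableError,
                            gyro_increment, initialize, run_filter, tilt_correct,
                            tilt_error, yaw_correct, yaw_error)
from skiturn.io import ImuRecording
from skiturn.simulate import SimConfig, simulate
from conftest import assert_same_rotation


def _static_recording(mount=None, duration=10.0, fs=50.0, sigma_acc=0.0,
                      gyro_bias=(0, 0, 0), sigma_gyr=0.0, seed=0):
    cfg = SimConfig(duration=duration, fs=fs, roll_amp=0, pitch_amp=0,
                    side_accel_amp=0, forward_accel_amp=0, mount_q=mount,
                    sigma_acc=sigma_acc, sigma_gyr=sigma_gyr, sigma_mag=0.0,
                    gyro_bias=gyro_bias, seed=seed)
    return simulate(cfg)


def test_gyro_increment_cases():
    np.testing.assert_allclose(gyro_increment((0, 0, 0), 0.02), quat.IDENTITY)
    q = gyro_increment((np.pi / 2 / 0.02, 0, 0), 0.02)
    assert_same_rotation(q, quat.from_axis_angle(np.pi / 2, (1, 0, 0)), tol=1e-12)


def test_gyro_increment_constant_rate_composition(rng):
    """n constant-rate increments compose to one axis-angle rotation."""
    omega = rng.standard_normal(3)
    dt, n = 0.02, 137
    q = quat.IDENTITY.copy()
    for _ in range(n):
        q = quat.multiply(q, gyro_increment(omega, dt))
    w = np.linalg.norm(omega)
    assert_same_rotation(q, quat.from_axis_angle(n * dt * w, omega / w), tol=1e-9)


@pytest.mark.parametrize(
    "v, phi, axis",
    [
        ((0, 1, 0), 0.0, (0, 0, 0)),
        ((1, 0, 0), np.pi / 2, (0, 0, 1)),
        ((0, 0, 1), np.pi / 2, (-1, 0, 0)),
    ],
)
def test_tilt_error_closed_forms(v, phi, axis):
    got_phi, got_axis = tilt_error(np.array([0.0, *v]))
    assert got_phi == pytest.approx(phi, abs=1e-12)
    np.testing.assert_allclose(got_axis, axis, atol=1e-12)


def test_tilt_error_dropout():
    with pytest.raises(ValueError):
        tilt_error(np.zeros(4))


def test_tilt_correct_cases(rng):
    q = quat.random_unit(rng)
    np.testing.assert_allclose(tilt_correct(q, 0.0, (0, 0, 1), 0.98), q)
    np.testing.assert_allclose(tilt_correct(q, 0.5, (0, 0, 1), 1.0), q, atol=1e-12)
    got = tilt_correct(quat.IDENTITY, np.pi / 2, (0, 0, 1), 0.98)
    assert_same_rotation(got, quat.from_axis_angle(0.01 * np.pi, (0, 0, 1)), tol=1e-12)


def test_tilt_correct_reduces_misalignment():
    """One corrected step pulls the measured up direction toward world up."""
    q = quat.from_axis_angle(0.3, (0, 0, 1))       # tilted attitude
    a_world = quat.rotate_vector(q, (0, 9.81, 0))
    phi, axis = tilt_error(np.array([0.0, *a_world]))
    q2 = tilt_correct(q, phi, axis, alpha_c=0.9)
    a2 = quat.rotate_vector(q2, (0, 9.81, 0))
    assert np.arccos(a2[1] / 9.81) < np.arccos(a_world[1] / 9.81)


def test_yaw_error_cases():
    m = np.array([5.0, -2.0, 3.0])
    assert yaw_error(quat.IDENTITY, quat.IDENTITY, m, m) == pytest.approx(0.0)
    # rotated fields (1,0,0) vs (0,0,1): headings pi/2 and 0
    assert yaw_error(quat.IDENTITY, quat.IDENTITY, (1, 0, 0), (0, 0, 1)) == pytest.approx(np.pi / 2)
    # wrap-around: theta=-3, theta_ref=3 -> 2*pi - 6, not -6
    m_cur = (np.sin(-3.0), 0.0, np.cos(-3.0))
    m_ref = (np.sin(3.0), 0.0, np.cos(3.0))
    d = yaw_error(quat.IDENTITY, quat.IDENTITY, m_cur, m_ref)
    assert d == pytest.approx(2 * np.pi - 6, abs=1e-9)


def test_yaw_error_unobservable():
    with pytest.raises(YawUnobservableError):
        yaw_error(quat.IDENTITY, quat.IDENTITY, (0, 1, 0), (1, 0, 0))
    with pytest.raises(YawUnobservableError):
        yaw_error(quat.IDENTITY, quat.IDENTITY, (1, 0, 0), (0, 1, 0))


def test_yaw_correct_cases(rng):
    q = quat.random_unit(rng)
    np.testing.assert_allclose(yaw_correct(q, 0.0, 0.98), q)
    np.testing.assert_allclose(yaw_correct(q, 1.0, 1.0), q)
    got = yaw_correct(quat.IDENTITY, np.pi, 0.98)
    assert_same_rotation(got, quat.from_axis_angle(0.02 * np.pi, (0, 1, 0)), tol=1e-12)


def test_initialize_static_poses():
    rec, _ = _static_recording()
    st = initialize(rec, FusionParams())
    assert_same_rotation(st.q, quat.IDENTITY, tol=1e-9)

    # sensor lying on its side: mean accel (9.81, 0, 0) must map onto up
    n = 100
    rec2 = ImuRecording(t=np.arange(n) / 50.0,
                        acc=np.tile([9.81, 0.0, 0.0], (n, 1)),
                        gyr=np.zeros((n, 3)), fs=50.0)
    st2 = initialize(rec2, FusionParams(use_mag=False))
    np.testing.assert_allclose(quat.rotate_vector(st2.q, (9.81, 0, 0)), (0, 9.81, 0), atol=1e-6)


def test_initialize_random_poses_monte_carlo(rng):
    """100 random static poses, accel noise 0.05 m/s2, 0.5 s window:
    initial up-alignment error below 1 degree."""
    for _ in range(100):
        mount = quat.random_unit(rng)
        u_sensor = quat.to_rotation_matrix(mount).T @ np.array([0, 1.0, 0])
        n = 25
        acc = 9.81 * u_sensor + rng.normal(0, 0.05, (n, 3))
        rec = ImuRecording(t=np.arange(n) / 50.0, acc=acc, gyr=np.zeros((n, 3)), fs=50.0)
        st = initialize(rec, FusionParams(use_mag=False, init_window_s=0.5))
        up = quat.rotate_vector(st.q, u_sensor)
        assert np.degrees(np.arccos(np.clip(up[1], -1, 1))) < 1.0


def test_run_filter_static_recovers_gravity():
    for mount in (None, "random"):
        rec, _ = _static_recording(mount=mount, seed=11)
        w = run_filter(rec, FusionParams())
        np.testing.assert_allclose(w.accel.mean(axis=0), (0, 9.81, 0), atol=1e-6)


def test_run_filter_preserves_norms_and_unit_quaternions():
    rec, _ = _static_recording(mount="random", sigma_acc=0.3, sigma_gyr=0.05, seed=5)
    w = run_filter(rec, FusionParams())
    np.testing.assert_allclose(np.linalg.norm(w.q_series, axis=1), 1.0, atol=1e-6)
    np.testing.assert_allclose(np.linalg.norm(w.accel, axis=1),
                               np.linalg.norm(rec.acc, axis=1), atol=1e-9)


def test_gyro_bias_drift_bounded_by_tilt_correction():
    """0.01 rad/s per-axis bias: complementary gain keeps the up estimate
    within 2 degrees while pure integration drifts past 10 degrees."""
    rec, truth = _static_recording(mount="random", duration=30.0, sigma_acc=0.05,
                                   gyro_bias=(0.01, 0.01, 0.01), sigma_gyr=0.0, seed=21)
    u_sensor = quat.to_rotation_matrix(truth.mount_q).T @ np.array([0, 1.0, 0])

    def up_err_deg(world):
        u = quat.rotation_matrices(world.q_series) @ u_sensor
        return np.degrees(np.arccos(np.clip(u[:, 1], -1, 1)))

    corrected = run_filter(rec, FusionParams(alpha_c=0.98, alpha_y=0.98))
    assert up_err_deg(corrected)[5 * 50:].max() < 2.0
    dead = run_filter(rec, FusionParams(alpha_c=1.0, alpha_y=1.0, use_mag=False))
    assert up_err_deg(dead)[-1] > 10.0


def test_gain_one_reproduces_dead_reckoning():
    """alpha_c = alpha_y = 1 is exactly gyro-only integration."""
    rec, _ = _static_recording(mount="random", sigma_gyr=0.1, sigma_acc=0.2, seed=9)
    w = run_filter(rec, FusionParams(alpha_c=1.0, alpha_y=1.0, use_mag=True))
    params = FusionParams(use_mag=False)
    q = initialize(rec, params).q
    for k in range(rec.n_samples):
        q = quat.normalize(quat.multiply(q, gyro_increment(rec.gyr[k], 1 / rec.fs)))
        assert quat.rotation_angle_between(q, w.q_series[k]) < 1e-9


def test_fast_loop_matches_reference_composition():
    """The scalar inner loop is the exact composition of the public
    increment/correction operations (including the convergent yaw sign)."""
    rec, _ = _static_recording(mount="random", duration=3.0, sigma_acc=0.2,
                               sigma_gyr=0.05, gyro_bias=(0.01, 0, -0.02), seed=3)
    params = FusionParams(alpha_c=0.97, alpha_y=0.96, use_mag=True)
    w = run_filter(rec, params)

    state = initialize(rec, params)
    q = state.q
    for k in range(rec.n_samples):
        q = quat.normalize(quat.multiply(q, gyro_increment(rec.gyr[k], 1 / rec.fs)))
        a_w = quat.rotate_vector(q, rec.acc[k])
        if np.linalg.norm(a_w) > 1e-9:
            phi, axis = tilt_error(np.array([0.0, *a_w]))
            q = tilt_correct(q, phi, axis, params.alpha_c, params.eps_axis)
        try:
            d = yaw_error(q, state.q_ref, rec.mag[k], state.m_ref, params.eps_axis)
            q = yaw_correct(q, -d, params.alpha_y)
        except YawUnobservableError:
            pass
        assert quat.rotation_angle_between(q, w.q_series[k]) < 1e-9
        np.testing.assert_allclose(quat.rotate_vector(q, rec.acc[k]), w.accel[k], atol=1e-9)


def test_yaw_stability_with_and_without_magnetometer():
    """Vertical gyro-bias component: heading bounded with the magnetometer,
    growing without it."""
    rec, truth = _static_recording(duration=60.0, gyro_bias=(0, 0.01, 0),
                                   sigma_acc=0.05, seed=13)

    def heading_deg(world):
        q_err = quat.multiply(world.q_series[-1], quat.inverse(truth.world_q[-1]))
        v = quat.rotate_vector(quat.normalize(q_err), (0, 0, 1.0))
        return abs(np.degrees(np.arctan2(v[0], v[2])))

    with_mag = run_filter(rec, FusionParams(use_mag=True))
    without = run_filter(rec, FusionParams(use_mag=False))
    assert heading_deg(with_mag) < 5.0
    drift = heading_deg(without)
    assert drift > 20.0                       # ~0.01 rad/s * 60 s = 34 deg
    # half the time, roughly half the drift (linear growth in the bias)
    rec2, truth2 = _static_recording(duration=30.0, gyro_bias=(0, 0.01, 0),
                                     sigma_acc=0.05, seed=13)
    truth = truth2
    half = heading_deg(run_filter(rec2, FusionParams(use_mag=False)))
    assert 0.3 < half / drift < 0.7


def test_complementary_filter_estimator():
    rec, _ = _static_recording(mount="random", sigma_acc=0.05, seed=4)
    X = np.hstack([rec.acc, rec.gyr, rec.mag])
    est = ComplementaryFilter(fs=50.0).fit(X)
    world = est.transform(X)
    assert world.shape == (len(X), 3)
    np.testing.assert_allclose(world[-100:].mean(axis=0), (0, 9.81, 0), atol=0.05)
    assert est.quaternions_.shape == (len(X), 4)
    assert est.get_params()["alpha_c"] == 0.98
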