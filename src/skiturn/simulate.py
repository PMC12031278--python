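"""Synthetic skier-IMU generator with known ground truth.

The generator emulates the body-frame inertial signature of linked ski
turns rather than a full point-mass descent model:

* body roll oscillates at the turn cadence about the forward axis
  (inclination into each turn), co-phased with a lateral specific
  force at the same cadence;
* a smaller flexion-driven pitch oscillation at twice the cadence
  about the side axis, paired with a fore–aft specific-force term at
  the same doubled frequency (each turn cycle contains two
  flexion–extension/speed-change phases);
* gravity as a constant +g specific force along world up;
* a fixed arbitrary sensor-mounting rotation (optionally drifting
  slowly, emulating a phone moving in a pocket);
* gyroscope bias and white noise, accelerometer and magnetometer white
  noise, and a constant world magnetic field with a nonzero horizontal
  component (so yaw is observable).

A 1-s static lead-in precedes the motion so the fusion initializer has
rest data.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import quat
from .io import ImuRecording, segment as make_segments

__all__ = ["SimConfig", "SimTruth", "simulate", "random_mount"]


@dataclass
class SimConfig:
    """Study conditions for one simulated run.

    Defaults describe a recreational short/medium-radius descent at a
    0.5 Hz turn cadence: ±20° roll, 2 m/s² peak lateral acceleration
    (signal-to-noise 5 against the 0.4 m/s² accelerometer noise),
    ±8.6° flexion pitch with a 0.5 m/s² fore–aft term, an uncalibrated
    MEMS-grade gyro bias of 0.01 rad/s per axis, and a magnetic field
    with a dominant horizontal component (units arbitrary).
    """

    duration: float = 60.0          # seconds of motion (lead-in extra)
    fs: float = 50.0                # Hz
    turn_freq: float = 0.5          # Hz, cadence of roll / lateral force
    roll_amp: float = 0.35          # rad, peak inclination
    pitch_amp: float = 0.15         # rad, flexion pitch at 2x cadence
    side_accel_amp: float = 2.0     # m/s², peak lateral specific force
    forward_accel_amp: float = 0.5  # m/s², fore-aft term at 2x cadence
    mount_q: object = None          # None=identity, "random", or (4,) quaternion
    gyro_bias: tuple = (0.01, 0.01, 0.01)   # rad/s, sensor frame
    sigma_acc: float = 0.4          # m/s²
    sigma_gyr: float = 0.02         # rad/s
    sigma_mag: float = 0.5          # field units
    B_world: tuple = (20.0, -40.0, 10.0)    # nonzero horizontal part
    g: float = 9.81                 # m/s²
    lead_in_s: float = 1.0          # static rest prepended for initialization
    side_axis: str = "x"            # world axis carrying the lateral force
    mount_drift_dps: float = 0.0    # deg/s slow mounting drift (stress option)
    seed: int = 0

    def validate(self) -> None:
        if self.fs < 10.0 * self.turn_freq:
            raise ValueError("fs must be at least 10x the turn frequency")
        if self.duration * self.turn_freq < 1.0:
            raise ValueError("duration must cover at least one turn cycle")
        if self.side_axis not in ("x", "z"):
            raise ValueError("side_axis must be 'x' or 'z'")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated recording."""

    side_truth: np.ndarray        # world-frame lateral specific force series
    roll_truth: np.ndarray        # rad
    extrema_times: np.ndarray     # seconds, true turning points
    n_turns_true: int
    mount_q: np.ndarray
    world_q: np.ndarray           # (n, 4) true sensor-to-world attitude
    side_axis_label: str          # "X" or "Z" in the simulator world frame
    fs: float

    def turns_per_segment(self, seg_seconds: float = 12.0) -> np.ndarray:
        n = len(self.side_truth)
        segs = make_segments(n, self.fs, seg_seconds)
        idx = np.round(self.extrema_times * self.fs).astype(int)
        return np.array([int(np.sum((idx >= s.start) & (idx < s.stop))) for s in segs])


def random_mount(seed: int) -> np.ndarray:
    """Reproducible uniformly distributed unit quaternion."""
    return quat.random_unit(np.random.default_rng(seed))


def _axis_quat(angle: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """(n, 4) quaternions for rotations about one fixed unit axis."""
    half = 0.5 * angle
    q = np.empty((len(angle), 4))
    q[:, 0] = np.cos(half)
    q[:, 1:] = np.sin(half)[:, None] * axis[None, :]
    return q


def simulate(cfg: SimConfig) -> tuple[ImuRecording, SimTruth]:
    """Generate one synthetic recording plus its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    if isinstance(cfg.mount_q, str) and cfg.mount_q == "random":
        mount0 = quat.random_unit(rng)
    elif cfg.mount_q is None:
        mount0 = quat.IDENTITY.copy()
    else:
        mount0 = quat.normalize(np.asarray(cfg.mount_q, dtype=float))

    up = np.array([0.0, 1.0, 0.0])
    if cfg.side_axis == "x":
        s_axis, f_axis, label = np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]), "X"
    else:
        s_axis, f_axis, label = np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]), "Z"

    total = cfg.duration + cfg.lead_in_s
    n = int(round(total * cfg.fs))
    t = np.arange(n) / cfg.fs
    tau = t - cfg.lead_in_s
    moving = tau >= 0.0
    tau_m = np.where(moving, tau, 0.0)

    w1 = 2.0 * np.pi * cfg.turn_freq
    w2 = 2.0 * w1
    roll = np.where(moving, cfg.roll_amp * np.sin(w1 * tau_m), 0.0)
    droll = np.where(moving, cfg.roll_amp * w1 * np.cos(w1 * tau_m), 0.0)
    pitch = np.where(moving, cfg.pitch_amp * np.sin(w2 * tau_m), 0.0)
    dpitch = np.where(moving, cfg.pitch_amp * w2 * np.cos(w2 * tau_m), 0.0)
    side_f = np.where(moving, cfg.side_accel_amp * np.sin(w1 * tau_m), 0.0)
    fwd_f = np.where(moving, cfg.forward_accel_amp * np.sin(w2 * tau_m), 0.0)

    q_roll = _axis_quat(roll, f_axis)
    q_pitch = _axis_quat(pitch, s_axis)
    q_body = quat.multiply(q_roll, q_pitch)

    # mounting rotation, optionally drifting about a fixed random body axis
    if cfg.mount_drift_dps:
        rate = np.deg2rad(cfg.mount_drift_dps)
        d_axis = rng.standard_normal(3)
        d_axis /= np.linalg.norm(d_axis)
        q_drift = _axis_quat(rate * tau_m, d_axis)
        mount = quat.multiply(q_drift, mount0[None, :])
    else:
        mount = np.broadcast_to(mount0, (n, 4))
    q_s = quat.multiply(q_body, mount)

    # world-frame specific force and magnetic field, expressed in the sensor frame
    f_w = cfg.g * up[None, :] + side_f[:, None] * s_axis[None, :] + fwd_f[:, None] * f_axis[None, :]
    R_s = quat.rotation_matrices(q_s)
    acc = np.einsum("nji,nj->ni", R_s, f_w)
    mag = np.einsum("nji,nj->ni", R_s, np.broadcast_to(np.asarray(cfg.B_world, float), (n, 3)))

    # body angular velocity: roll about the fixed world/body forward axis applied
    # after pitch, so its axis must be pulled back through the pitch rotation
    R_p = quat.rotation_matrices(q_pitch)
    omega_body = (np.einsum("nji,j->ni", R_p, f_axis) * droll[:, None]
                  + s_axis[None, :] * dpitch[:, None])
    R_m = quat.rotation_matrices(np.ascontiguousarray(mount))
    gyr = np.einsum("nji,nj->ni", R_m, omega_body)
    if cfg.mount_drift_dps:
        R_m0 = quat.to_rotation_matrix(mount0)
        gyr = gyr + (R_m0.T @ (rate * d_axis))[None, :] * moving[:, None]

    acc = acc + cfg.sigma_acc * rng.standard_normal((n, 3))
    gyr = gyr + np.asarray(cfg.gyro_bias, float)[None, :] + cfg.sigma_gyr * rng.standard_normal((n, 3))
    mag = mag + cfg.sigma_mag * rng.standard_normal((n, 3))

    rec = ImuRecording(t=t, acc=acc, gyr=gyr, mag=mag, fs=cfg.fs,
                       meta=f"simulated skier fs={cfg.fs} f_turn={cfg.turn_freq}")

    if cfg.side_accel_amp == 0.0 and cfg.roll_amp == 0.0:
        k = np.arange(0)                      # no turning motion, no turns
    else:
        k = np.arange(int(np.floor(2.0 * cfg.turn_freq * cfg.duration + 0.5)))
    extrema_times = cfg.lead_in_s + (2.0 * k + 1.0) / (4.0 * cfg.turn_freq)
    truth = SimTruth(side_truth=side_f, roll_truth=roll, extrema_times=extrema_times,
                     n_turns_true=int(len(extrema_times)), mount_q=mount0,
                     world_q=q_s, side_axis_label=label, fs=cfg.fs)
    return rec, truth
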