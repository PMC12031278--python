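"""Streaming quaternion complementary filter.

The filter tracks the sensor-to-world rotation ``q(t)`` (world frame:
Y up against gravity, X and Z horizontal) by

1. integrating each gyroscope sample into a small axis-angle increment
   and accumulating it onto ``q``;
2. rotating the raw accelerometer sample into the world frame and
   nudging ``q`` so the measured specific-force direction re-aligns
   with world up — by the fraction ``(1 − αc)`` of the misalignment
   angle per step (tilt correction);
3. optionally comparing the horizontal heading of the rotated
   magnetometer sample against the heading of the reference reading
   taken at the start of the recording, and nudging ``q`` about world
   Y by ``(1 − αy)`` of the heading difference (yaw correction).

With gains ``αc = αy = 1`` the filter degenerates to pure gyro
dead-reckoning.  Sign convention: a resting accelerometer outputs the
*specific force* +g along its up direction, so a converged static
filter emits world acceleration ``(0, +g, 0)``.

A note on the yaw update sign: with heading measured as
``θ = atan2(m′x, m′z)``, pre-multiplying ``q`` by a rotation of ``+ψ``
about world Y shifts ``θ`` by ``+ψ``.  The convergent update therefore
rotates by ``−(1 − αy)·(θ − θref)``; :func:`run_filter` passes the
negated heading difference to :func:`yaw_correct`, whose own angle
argument is applied literally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import quat
from .io import ImuRecording

logger = logging.getLogger(__name__)

__all__ = [
    "FusionParams",
    "FusionState",
    "WorldAccel",
    "YawUnobservableError",
    "gyro_increment",
    "tilt_error",
    "tilt_correct",
    "yaw_error",
    "yaw_correct",
    "initialize",
    "run_filter",
    "ComplementaryFilter",
]


class YawUnobservableError(ValueError):
    """Raised when the rotated magnetic field has no horizontal component."""


@dataclass
class FusionParams:
    """Complementary-filter gains and initialization settings.

    alpha_c, alpha_y : float in [0, 1]
        Tilt / yaw complementary gains; 1 disables the correction.
        Defaults 0.98 at 50 Hz give a ~1 s correction time constant.
    use_mag : bool
        Enable the magnetometer yaw correction.
    init_window_s : float
        Seconds of initial data averaged to set the starting attitude
        and the magnetometer heading reference.
    eps_axis : float
        Threshold below which a correction axis (or the horizontal
        magnetic projection, relative to the field norm) is treated as
        degenerate and the correction is skipped.
    """

    alpha_c: float = 0.98
    alpha_y: float = 0.98
    use_mag: bool = True
    init_window_s: float = 1.0
    eps_axis: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_c <= 1.0 and 0.0 <= self.alpha_y <= 1.0):
            raise ValueError("complementary gains must lie in [0, 1]")


@dataclass
class FusionState:
    """Filter state: current attitude plus the heading reference."""

    q: np.ndarray
    q_ref: np.ndarray
    m_ref: np.ndarray | None
    t_last: float = 0.0


@dataclass
class WorldAccel:
    """World-frame acceleration series with per-sample attitude."""

    t: np.ndarray
    accel: np.ndarray          # (n, 3), Y is up
    q_series: np.ndarray       # (n, 4) scalar-first unit quaternions
    n_yaw_skipped: int = 0


def gyro_increment(omega, dt: float) -> np.ndarray:
    """Axis-angle quaternion for one gyroscope sample over ``dt`` seconds.

    Returns identity for a (near-)zero rate — the removable singularity
    of the axis-angle construction.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    omega = np.asarray(omega, dtype=float)
    w = float(np.linalg.norm(omega))
    if w < 1e-12:
        return quat.IDENTITY.copy()
    return quat.from_axis_angle(dt * w, omega / w)


def tilt_error(q_acc_up) -> tuple[float, np.ndarray]:
    """Misalignment angle and correction axis from the rotated accel sample.

    ``q_acc_up`` is the pure (vector) quaternion of the accelerometer
    reading after rotation to the world frame.  With ``v`` its
    normalized vector part, the axis is ``v × ŷ = (−vz, 0, vx)`` and
    the angle ``arccos(vy)``.
    """
    v = np.asarray(q_acc_up, dtype=float)[1:]
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ValueError("accelerometer dropout: zero vector part")
    v = v / n
    phi = float(np.arccos(np.clip(v[1], -1.0, 1.0)))
    return phi, np.array([-v[2], 0.0, v[0]])


def tilt_correct(q_omega, phi: float, n, alpha_c: float, eps_axis: float = 1e-6) -> np.ndarray:
    """Blend a fraction ``(1 − αc)`` of the tilt misalignment into ``q``.

    Degenerate axis (already aligned, or anti-aligned) or zero angle
    leaves ``q`` unchanged.
    """
    n = np.asarray(n, dtype=float)
    nn = float(np.linalg.norm(n))
    if nn < eps_axis or phi <= 0.0:
        return np.asarray(q_omega, dtype=float)
    corr = quat.from_axis_angle((1.0 - alpha_c) * phi, n / nn)
    return quat.normalize(quat.multiply(corr, q_omega))


def yaw_error(q, q_ref, m, m_ref, eps_axis: float = 1e-6) -> float:
    """Heading difference (radians, wrapped to (−π, π]) between the
    current rotated magnetometer sample and the rotated reference.

    Raises :class:`YawUnobservableError` when either rotated field is
    (near-)vertical, i.e. its horizontal projection is below
    ``eps_axis`` relative to the field norm.
    """
    m = np.asarray(m, dtype=float)
    m_ref = np.asarray(m_ref, dtype=float)
    if np.linalg.norm(m) < 1e-12 or np.linalg.norm(m_ref) < 1e-12:
        raise ValueError("magnetometer reading is zero")
    mp = quat.rotate_vector(q, m)
    mpr = quat.rotate_vector(q_ref, m_ref)
    for vec in (mp, mpr):
        if math.hypot(vec[0], vec[2]) < eps_axis * np.linalg.norm(vec):
            raise YawUnobservableError("rotated magnetic field has no horizontal component")
    d = math.atan2(mp[0], mp[2]) - math.atan2(mpr[0], mpr[2])
    # wrap to (−π, π]
    d = -((-d + math.pi) % (2.0 * math.pi) - math.pi)
    return d


def yaw_correct(q_c, d_theta: float, alpha_y: float) -> np.ndarray:
    """Rotate ``q`` by ``(1 − αy)·d_theta`` about world Y (applied literally).

    The filter passes the *negated* heading error so the estimate
    converges; see the module docstring.
    """
    if d_theta == 0.0 or alpha_y == 1.0:
        return np.asarray(q_c, dtype=float)
    corr = quat.from_axis_angle((1.0 - alpha_y) * d_theta, (0.0, 1.0, 0.0))
    return quat.normalize(quat.multiply(corr, q_c))


def _tilt_aligning_quaternion(a_mean: np.ndarray) -> np.ndarray:
    """Yaw-free rotation taking the mean accel direction onto world up."""
    norm = float(np.linalg.norm(a_mean))
    if norm < 1e-9:
        raise ValueError("near-zero mean accelerometer vector; cannot initialize attitude")
    v = a_mean / norm
    # rotation axis v × ŷ = (−vz, 0, vx); rotating v about it by the
    # separation angle lands v on ŷ.
    axis = np.array([-v[2], 0.0, v[0]])
    ang = float(np.arccos(np.clip(v[1], -1.0, 1.0)))
    an = float(np.linalg.norm(axis))
    if an < 1e-12:
        if v[1] > 0:
            return quat.IDENTITY.copy()
        return quat.from_axis_angle(math.pi, (1.0, 0.0, 0.0))  # upside down
    return quat.from_axis_angle(ang, axis / an)


def initialize(rec: ImuRecording, params: FusionParams) -> FusionState:
    """Attitude and heading reference from the first ``init_window_s`` seconds.

    The starting quaternion is the tilt-only rotation mapping the mean
    accelerometer vector onto world up (its yaw is zero by
    construction); the magnetometer reference is the mean field over
    the same window.
    """
    if rec.fs is None:
        raise ValueError("initialize expects a resampled uniform recording")
    n0 = max(1, int(round(params.init_window_s * rec.fs)))
    if n0 > rec.n_samples:
        raise ValueError("recording shorter than the initialization window")
    q0 = _tilt_aligning_quaternion(rec.acc[:n0].mean(axis=0))
    m_ref = None
    if params.use_mag:
        if rec.mag is None:
            raise ValueError("use_mag=True but the recording has no magnetometer stream")
        m_ref = rec.mag[:n0].mean(axis=0)
    return FusionState(q=q0, q_ref=q0.copy(), m_ref=m_ref, t_last=float(rec.t[0]))


def run_filter(rec: ImuRecording, params: FusionParams | None = None) -> WorldAccel:
    """Run the complementary filter over a uniform recording.

    Per sample: accumulate the gyro increment, apply the tilt
    correction, optionally the yaw correction, renormalize, and emit
    the raw acceleration rotated by the final attitude of the step.
    Yaw-unobservable steps skip the magnetometer correction (counted in
    ``n_yaw_skipped``).

    The inner loop is written in scalar arithmetic for speed; it is the
    exact sample-by-sample composition of :func:`gyro_increment`,
    :func:`tilt_correct` and :func:`yaw_correct` (asserted by tests
    against the quaternion-module route).
    """
    params = params or FusionParams()
    if rec.fs is None:
        raise ValueError("run_filter expects a resampled uniform recording")
    if params.use_mag and rec.mag is None:
        logger.warning("no magnetometer stream: yaw correction disabled")
        params = replace(params, use_mag=False)
    state = initialize(rec, params)
    dt = 1.0 / rec.fs
    n = rec.n_samples

    qw, qx, qy, qz = (float(c) for c in state.q)
    use_mag = params.use_mag and rec.mag is not None
    one_m_ac = 1.0 - params.alpha_c
    one_m_ay = 1.0 - params.alpha_y
    eps = params.eps_axis

    theta_ref = 0.0
    if use_mag:
        mref_w = quat.rotate_vector(state.q_ref, state.m_ref)
        h = math.hypot(mref_w[0], mref_w[2])
        if h < eps * np.linalg.norm(mref_w):
            logger.warning("reference magnetic field vertical: yaw correction disabled")
            use_mag = False
        else:
            theta_ref = math.atan2(mref_w[0], mref_w[2])

    acc = np.ascontiguousarray(rec.acc, dtype=float)
    gyr = np.ascontiguousarray(rec.gyr, dtype=float)
    mag = np.ascontiguousarray(rec.mag, dtype=float) if use_mag else None

    out = np.empty((n, 3))
    qs = np.empty((n, 4))
    n_skip = 0
    sin, cos, sqrt, acos, atan2 = math.sin, math.cos, math.sqrt, math.acos, math.atan2

    for k in range(n):
        wx, wy, wz = gyr[k, 0], gyr[k, 1], gyr[k, 2]
        om = sqrt(wx * wx + wy * wy + wz * wz)
        if om > 1e-12:
            half = 0.5 * dt * om
            s = sin(half) / om
            dw, dx, dy, dz = cos(half), wx * s, wy * s, wz * s
            # q ← q ∗ dq (body-frame increment post-multiplies)
            qw, qx, qy, qz = (
                qw * dw - qx * dx - qy * dy - qz * dz,
                qw * dx + qx * dw + qy * dz - qz * dy,
                qw * dy - qx * dz + qy * dw + qz * dx,
                qw * dz + qx * dy - qy * dx + qz * dw,
            )
            nrm = sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
            qw, qx, qy, qz = qw / nrm, qx / nrm, qy / nrm, qz / nrm

        ax, ay, az = acc[k, 0], acc[k, 1], acc[k, 2]
        # rotate accel into the world frame: a_w = R(q) a
        tx = 2.0 * (qy * az - qz * ay)
        ty = 2.0 * (qz * ax - qx * az)
        tz = 2.0 * (qx * ay - qy * ax)
        awx = ax + qw * tx + (qy * tz - qz * ty)
        awy = ay + qw * ty + (qz * tx - qx * tz)
        awz = az + qw * tz + (qx * ty - qy * tx)

        na = sqrt(awx * awx + awy * awy + awz * awz)
        if na > 1e-9:
            vx, vy, vz = awx / na, awy / na, awz / na
            c = vy
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            phi = acos(c)
            nx, nz = -vz, vx
            nn = sqrt(nx * nx + nz * nz)
            if nn > eps and phi > 0.0:
                half = 0.5 * one_m_ac * phi
                s = sin(half) / nn
                cw, cx, cz = cos(half), nx * s, nz * s
                # q ← corr ∗ q (world-frame correction pre-multiplies)
                qw, qx, qy, qz = (
                    cw * qw - cx * qx - cz * qz,
                    cw * qx + cx * qw + 0.0 - cz * qy,
                    cw * qy - cx * qz + 0.0 + cz * qx,
                    cw * qz + cx * qy - 0.0 + cz * qw,
                )
                nrm = sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
                qw, qx, qy, qz = qw / nrm, qx / nrm, qy / nrm, qz / nrm

        if use_mag:
            mx, my, mz = mag[k, 0], mag[k, 1], mag[k, 2]
            tx = 2.0 * (qy * mz - qz * my)
            ty = 2.0 * (qz * mx - qx * mz)
            tz = 2.0 * (qx * my - qy * mx)
            mwx = mx + qw * tx + (qy * tz - qz * ty)
            mwy = my + qw * ty + (qz * tx - qx * tz)
            mwz = mz + qw * tz + (qx * ty - qy * tx)
            h = sqrt(mwx * mwx + mwz * mwz)
            if h < eps * sqrt(mwx * mwx + mwy * mwy + mwz * mwz):
                n_skip += 1
            else:
                d = atan2(mwx, mwz) - theta_ref
                d = -((-d + math.pi) % (2.0 * math.pi) - math.pi)
                half = -0.5 * one_m_ay * d          # negated error: convergent update
                cw, cy = cos(half), sin(half)
                qw, qx, qy, qz = (
                    cw * qw - cy * qy,
                    cw * qx + cy * qz,
                    cw * qy + cy * qw,
                    cw * qz - cy * qx,
                )
                nrm = sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
                qw, qx, qy, qz = qw / nrm, qx / nrm, qy / nrm, qz / nrm

        # emit raw accel rotated by the final attitude of this step
        tx = 2.0 * (qy * az - qz * ay)
        ty = 2.0 * (qz * ax - qx * az)
        tz = 2.0 * (qx * ay - qy * ax)
        out[k, 0] = ax + qw * tx + (qy * tz - qz * ty)
        out[k, 1] = ay + qw * ty + (qz * tx - qx * tz)
        out[k, 2] = az + qw * tz + (qx * ty - qy * tx)
        qs[k, 0], qs[k, 1], qs[k, 2], qs[k, 3] = qw, qx, qy, qz

    if n_skip:
        logger.info("yaw correction skipped on %d unobservable step(s)", n_skip)
    return WorldAccel(t=rec.t.copy(), accel=out, q_series=qs, n_yaw_skipped=n_skip)


class ComplementaryFilter(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`run_filter`.

    Input ``X`` is an ``(n, 9)`` array of columns
    ``[ax, ay, az, gx, gy, gz, mx, my, mz]`` (or ``(n, 6)`` without a
    magnetometer) sampled uniformly at ``fs``.  ``fit`` computes the
    initial attitude and heading reference from the first
    ``init_window_s`` seconds; ``transform`` returns the ``(n, 3)``
    world-frame acceleration (Y up).  The per-sample attitudes of the
    last transform are available as ``quaternions_``.
    """

    def __init__(self, fs: float = 50.0, alpha_c: float = 0.98, alpha_y: float = 0.98,
                 use_mag: bool = True, init_window_s: float = 1.0, eps_axis: float = 1e-6):
        self.fs = fs
        self.alpha_c = alpha_c
        self.alpha_y = alpha_y
        self.use_mag = use_mag
        self.init_window_s = init_window_s
        self.eps_axis = eps_axis

    def _params(self) -> FusionParams:
        return FusionParams(alpha_c=self.alpha_c, alpha_y=self.alpha_y,
                            use_mag=self.use_mag and self._has_mag,
                            init_window_s=self.init_window_s, eps_axis=self.eps_axis)

    def _recording(self, X: np.ndarray) -> ImuRecording:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] not in (6, 9):
            raise ValueError("X must be (n, 9) [acc|gyr|mag] or (n, 6) [acc|gyr]")
        self._has_mag = X.shape[1] == 9
        t = np.arange(X.shape[0]) / self.fs
        mag = X[:, 6:9] if self._has_mag else None
        return ImuRecording(t=t, acc=X[:, 0:3], gyr=X[:, 3:6], mag=mag, fs=self.fs)

    def fit(self, X, y=None):
        rec = self._recording(X)
        state = initialize(rec, self._params())
        self.q0_ = state.q
        self.m_ref_ = state.m_ref
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "q0_"):
            raise ValueError("ComplementaryFilter is not fitted yet")
        rec = self._recording(X)
        world = run_filter(rec, self._params())
        self.quaternions_ = world.q_series
        self.n_yaw_skipped_ = world.n_yaw_skipped
        return world.accel
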