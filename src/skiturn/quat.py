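"""Rotation-quaternion algebra used throughout the package.

Conventions
-----------
* Scalar-first component order ``(w, x, y, z)``.
* Right-handed frames, angles in radians.
* Quaternions act as *active* rotations via the sandwich product
  ``q v q⁻¹``; for a unit quaternion this rotates ``v`` by the encoded
  angle about the encoded axis (right-hand rule).
* ``q`` and ``-q`` encode the same rotation; comparisons between
  rotations must therefore go through :func:`rotation_angle_between`
  or the rotation matrix, never component-wise.

All functions accept plain sequences or ndarrays.  Batched variants used
by the simulator operate on arrays of shape ``(n, 4)`` / ``(n, 3)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IDENTITY",
    "from_axis_angle",
    "multiply",
    "conjugate",
    "inverse",
    "normalize",
    "rotate_vector",
    "to_rotation_matrix",
    "rotation_matrices",
    "random_unit",
    "rotation_angle_between",
]

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

_UNIT_TOL = 1e-6


def from_axis_angle(theta: float, axis) -> np.ndarray:
    """Unit quaternion for a rotation of ``theta`` radians about ``axis``.

    The axis is normalized internally; a zero axis is only legal for
    ``theta == 0`` (identity), otherwise the rotation axis is undefined.
    """
    axis = np.asarray(axis, dtype=float)
    norm = float(np.linalg.norm(axis))
    if norm < 1e-12:
        if theta == 0.0 or abs(float(theta)) < 1e-15:
            return IDENTITY.copy()
        raise ValueError("rotation axis is zero while theta != 0: axis undefined")
    half = 0.5 * float(theta)
    s = np.sin(half) / norm
    return np.array([np.cos(half), axis[0] * s, axis[1] * s, axis[2] * s])


def multiply(q1, q2) -> np.ndarray:
    """Hamilton product ``q1 * q2`` (supports broadcasting over (n, 4))."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def conjugate(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def inverse(q) -> np.ndarray:
    """General quaternion inverse ``q* / ||q||²`` (conjugate for unit q)."""
    q = np.asarray(q, dtype=float)
    n2 = np.sum(q * q, axis=-1, keepdims=True)
    if np.any(n2 < 1e-24):
        raise ValueError("cannot invert a zero quaternion")
    return conjugate(q) / n2


def normalize(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def rotate_vector(q, v) -> np.ndarray:
    """Rotate vector ``v`` by unit quaternion ``q`` (sandwich product).

    ``q`` must be unit within 1e-6; callers holding unnormalized state
    must normalize first.  Preserves the vector norm to rounding error.
    """
    q = np.asarray(q, dtype=float)
    if abs(float(np.dot(q, q)) - 1.0) > 2 * _UNIT_TOL:
        raise ValueError("rotate_vector requires a unit quaternion; normalize first")
    v = np.asarray(v, dtype=float)
    w, qv = q[0], q[1:]
    # q v q⁻¹ expanded: v + 2 w (qv × v) + 2 qv × (qv × v)
    t = 2.0 * np.cross(qv, v)
    return v + w * t + np.cross(qv, t)


def to_rotation_matrix(q) -> np.ndarray:
    """3×3 rotation matrix equivalent of unit quaternion ``q``."""
    w, x, y, z = np.asarray(q, dtype=float)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotation_matrices(q: np.ndarray) -> np.ndarray:
    """Vectorized :func:`to_rotation_matrix` for an (n, 4) array."""
    q = np.asarray(q, dtype=float)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    m = np.empty((q.shape[0], 3, 3))
    m[:, 0, 0] = 1 - 2 * (y * y + z * z)
    m[:, 0, 1] = 2 * (x * y - w * z)
    m[:, 0, 2] = 2 * (x * z + w * y)
    m[:, 1, 0] = 2 * (x * y + w * z)
    m[:, 1, 1] = 1 - 2 * (x * x + z * z)
    m[:, 1, 2] = 2 * (y * z - w * x)
    m[:, 2, 0] = 2 * (x * z - w * y)
    m[:, 2, 1] = 2 * (y * z + w * x)
    m[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def random_unit(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Uniformly distributed unit quaternion(s) (normalized 4-Gaussian)."""
    size = (4,) if n is None else (n, 4)
    q = rng.standard_normal(size)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def rotation_angle_between(q1, q2) -> float:
    """Geodesic angle (radians) between the rotations encoded by q1, q2.

    Invariant under the q ↔ −q sign ambiguity.  Computed from the
    chordal distance (accurate for near-identical rotations, where the
    arccos of the dot product loses half the working precision).
    """
    a = normalize(q1)
    b = normalize(q2)
    d = min(float(np.linalg.norm(a - b)), float(np.linalg.norm(a + b)))
    return 4.0 * float(np.arcsin(min(1.0, 0.5 * d)))
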