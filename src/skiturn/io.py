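"""Reading, writing, resampling and segmenting IMU recordings.

Canonical on-disk format: a comma-delimited text file with a header row
and columns ``time,ax,ay,az,gx,gy,gz,mx,my,mz`` — time in seconds,
accelerometer in m/s², gyroscope in rad/s, magnetometer in any
calibrated unit (only the field direction is used downstream).  Exports
from other devices are adapted by a small column-mapping schema that
also declares the gyroscope unit (``rad/s`` or ``deg/s``) and the time
unit (``s``, ``ms``, ``ns``).

Multi-rate sources (e.g. a phone sampling inertial channels at 500 Hz
and the compass at 100 Hz) are supported by leaving magnetometer cells
empty/NaN on rows without a compass sample; :func:`resample` then
interpolates every stream onto one uniform grid (50 Hz by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ImuRecording",
    "Segment",
    "DEFAULT_SCHEMA",
    "read_recording",
    "write_recording",
    "resample",
    "segment",
]

#: Default column mapping / unit declaration for the canonical format.
DEFAULT_SCHEMA = {
    "time": "time",
    "ax": "ax", "ay": "ay", "az": "az",
    "gx": "gx", "gy": "gy", "gz": "gz",
    "mx": "mx", "my": "my", "mz": "mz",
    "gyro_unit": "rad/s",
    "time_unit": "s",
}

_TIME_SCALE = {"s": 1.0, "ms": 1e-3, "ns": 1e-9}


@dataclass
class ImuRecording:
    """Synchronized tri-axial accelerometer / gyroscope / magnetometer streams.

    ``t`` is the accelerometer/gyroscope time base in seconds (strictly
    increasing).  ``mag_t`` is ``None`` when the magnetometer shares
    ``t``; otherwise it carries the magnetometer's own timestamps (the
    multi-rate case before resampling).  ``fs`` is set only once the
    recording is uniform.
    """

    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    mag: np.ndarray | None = None
    mag_t: np.ndarray | None = None
    fs: float | None = None
    meta: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        if self.mag_t is not None:
            self.mag_t = np.asarray(self.mag_t, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class Segment:
    """Half-open sample-index range ``[start, stop)`` of fixed duration."""

    start: int
    stop: int
    duration: float

    def __len__(self) -> int:
        return self.stop - self.start


def _collapse_duplicate_times(t: np.ndarray, values: np.ndarray):
    """Average rows sharing an identical timestamp."""
    uniq, inv, counts = np.unique(t, return_inverse=True, return_counts=True)
    if len(uniq) == len(t):
        return t, values
    out = np.zeros((len(uniq), values.shape[1]))
    np.add.at(out, inv, values)
    return uniq, out / counts[:, None]


def read_recording(path, schema: dict | None = None, meta: str = "") -> ImuRecording:
    """Read a delimited-text IMU export into canonical units.

    Gyroscope values declared in deg/s are converted to rad/s and
    timestamps to seconds from the first sample.  Rows with non-finite
    time or inertial values are dropped (count logged); rows with
    missing magnetometer cells merely leave that row out of the
    magnetometer stream.  Duplicate timestamps are collapsed by
    averaging.

    Raises
    ------
    ValueError
        On a missing mandatory column, fewer than 2 usable rows, or a
        non-monotonic time base after de-duplication.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)

    mandatory = ["time", "ax", "ay", "az", "gx", "gy", "gz"]
    for key in mandatory:
        if schema[key] not in df.columns:
            raise ValueError(f"schema error: column {schema[key]!r} (field {key!r}) missing")

    t = df[schema["time"]].to_numpy(dtype=float)
    acc = df[[schema["ax"], schema["ay"], schema["az"]]].to_numpy(dtype=float)
    gyr = df[[schema["gx"], schema["gy"], schema["gz"]]].to_numpy(dtype=float)

    try:
        t = t * _TIME_SCALE[schema["time_unit"]]
    except KeyError:
        raise ValueError(f"schema error: unknown time unit {schema['time_unit']!r}")
    if schema["gyro_unit"] == "deg/s":
        gyr = np.deg2rad(gyr)
    elif schema["gyro_unit"] != "rad/s":
        raise ValueError(f"schema error: unknown gyro unit {schema['gyro_unit']!r}")

    mag_cols = [schema["mx"], schema["my"], schema["mz"]]
    has_mag = all(c in df.columns for c in mag_cols)
    mag_all = df[mag_cols].to_numpy(dtype=float) if has_mag else None

    good = np.isfinite(t) & np.isfinite(acc).all(axis=1) & np.isfinite(gyr).all(axis=1)
    n_dropped = int((~good).sum())
    if n_dropped:
        logger.info("dropped %d row(s) with non-finite time/inertial values", n_dropped)
    t, acc, gyr = t[good], acc[good], gyr[good]
    if len(t) < 2:
        raise ValueError("recording has fewer than 2 usable rows")

    t = t - t[0]
    t, inert = _collapse_duplicate_times(t, np.hstack([acc, gyr]))
    acc, gyr = inert[:, :3], inert[:, 3:]
    if np.any(np.diff(t) <= 0):
        raise ValueError("time base not strictly increasing after de-duplication")

    mag = mag_t = None
    if has_mag:
        mrows = good & np.isfinite(mag_all).all(axis=1)
        t_raw = df[schema["time"]].to_numpy(dtype=float) * _TIME_SCALE[schema["time_unit"]]
        # magnetometer stays on the same clock origin as the inertial streams
        tm = t_raw[mrows] - t_raw[good][0]
        mvals = mag_all[mrows]
        if len(tm) >= 2:
            mag_t_u, mag = _collapse_duplicate_times(tm, mvals)
            if np.array_equal(mag_t_u, t):
                mag_t = None
            else:
                mag_t = mag_t_u

    return ImuRecording(t=t, acc=acc, gyr=gyr, mag=mag, mag_t=mag_t, meta=meta)


def write_recording(rec: ImuRecording, path) -> None:
    """Write a uniform recording in the canonical CSV format."""
    if rec.mag_t is not None:
        raise ValueError("write_recording expects a synchronized (resampled) recording")
    cols = {"time": rec.t,
            "ax": rec.acc[:, 0], "ay": rec.acc[:, 1], "az": rec.acc[:, 2],
            "gx": rec.gyr[:, 0], "gy": rec.gyr[:, 1], "gz": rec.gyr[:, 2]}
    if rec.mag is not None:
        cols.update({"mx": rec.mag[:, 0], "my": rec.mag[:, 1], "mz": rec.mag[:, 2]})
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def resample(rec: ImuRecording, fs_target: float = 50.0) -> ImuRecording:
    """Linearly interpolate all streams onto a uniform grid at ``fs_target``.

    The grid starts at the first timestamp common to every stream and
    ends at the last; streams with disjoint time ranges are an error.
    """
    if fs_target <= 0:
        raise ValueError("fs_target must be positive")
    t0, t1 = rec.t[0], rec.t[-1]
    if rec.mag is not None and rec.mag_t is not None:
        t0 = max(t0, rec.mag_t[0])
        t1 = min(t1, rec.mag_t[-1])
        if t1 <= t0:
            raise ValueError("inertial and magnetometer streams cover disjoint time ranges")
    if (t1 - t0) < 2.0 / fs_target:
        raise ValueError("recording shorter than two samples at the target rate")

    n = int(np.floor((t1 - t0) * fs_target)) + 1
    grid = t0 + np.arange(n) / fs_target

    def interp(ts, vals):
        return np.column_stack([np.interp(grid, ts, vals[:, i]) for i in range(vals.shape[1])])

    acc = interp(rec.t, rec.acc)
    gyr = interp(rec.t, rec.gyr)
    mag = None
    if rec.mag is not None:
        mag = interp(rec.t if rec.mag_t is None else rec.mag_t, rec.mag)
    return ImuRecording(t=grid - grid[0], acc=acc, gyr=gyr, mag=mag,
                        mag_t=None, fs=float(fs_target), meta=rec.meta)


def segment(n_samples: int, fs: float, seg_seconds: float = 12.0) -> list[Segment]:
    """Consecutive non-overlapping fixed-duration segments; remainder dropped.

    Returns an empty list (with a warning) when the recording is shorter
    than one segment.
    """
    seg_len = int(round(seg_seconds * fs))
    n_seg = n_samples // seg_len
    if n_seg == 0:
        logger.warning("recording shorter than one %.3g s segment; no segments", seg_seconds)
        return []
    return [Segment(i * seg_len, (i + 1) * seg_len, seg_seconds) for i in range(n_seg)]
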