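"""World-frame kinematics from a waist-worn inertial measurement unit.

The screening task records a child's trunk motion with a belt-worn IMU
(3-axis accelerometer + 3-axis rate gyroscope).  This module turns those
raw device-frame signals into six world-referenced kinematic channels:

====== ======================================================= =========
symbol meaning                                                 units
====== ======================================================= =========
ah     horizontal acceleration magnitude                       m/s^2
av     vertical acceleration, gravity removed                  m/s^2
omegah horizontal angular-velocity magnitude                   deg/s
omegav vertical (about-the-up-axis) angular-velocity component deg/s
alpha  tilt of the device axis from vertical                   deg
gamma  unsigned heading change from the initial heading        deg
====== ======================================================= =========

The processing chain is: down-sample to 100 Hz, low-pass filter
(4th-order Butterworth, 20 Hz cutoff, zero-phase by default), estimate
device orientation with a complementary filter (gyro strapdown
integration corrected toward the accelerometer gravity direction), then
resolve acceleration and angular velocity in a world frame whose z axis
points vertically up.

The complementary filter carries no magnetometer, so heading is obtained
purely by integrating the vertical angular rate; slow gyro drift is
accepted over the ~90 s task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

#: standard gravity, m/s^2
G = 9.80665

#: channel names in the canonical extraction order
CHANNEL_ORDER = ("ah", "av", "omegah", "omegav", "alpha", "gamma")


class KinematicsError(ValueError):
    """Raised for invalid recordings or incompatible inputs."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ImuRecording:
    """Raw (or preprocessed) IMU time series.

    Parameters
    ----------
    time:
        Sample times in seconds, strictly increasing.
    accel:
        (n, 3) specific force in ``accel_units`` ("g" or "m/s2").
    gyro:
        (n, 3) angular velocity, deg/s.
    sample_rate_hz:
        Nominal sampling rate.
    """

    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    sample_rate_hz: float
    accel_units: str = "g"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        n = self.time.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise KinematicsError(
                f"channel length mismatch: time {n}, accel {self.accel.shape},"
                f" gyro {self.gyro.shape}"
            )
        if self.sample_rate_hz <= 0:
            raise KinematicsError("sample_rate_hz must be positive")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise KinematicsError("timestamps must be strictly increasing")
        if self.accel_units not in ("g", "m/s2"):
            raise KinematicsError(f"unknown accel_units {self.accel_units!r}")

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0])

    def accel_ms2(self) -> np.ndarray:
        """Specific force in m/s^2 regardless of the stored units."""
        if self.accel_units == "g":
            return self.accel * G
        return self.accel

    def accel_g(self) -> np.ndarray:
        if self.accel_units == "g":
            return self.accel
        return self.accel / G


@dataclass
class OrientationSeries:
    """Per-sample unit quaternions mapping the device frame to the world
    frame (world z up).  Quaternions are stored scalar-last (x, y, z, w)."""

    quat: np.ndarray

    def __post_init__(self) -> None:
        self.quat = np.asarray(self.quat, dtype=float)
        if self.quat.ndim != 2 or self.quat.shape[1] != 4:
            raise KinematicsError("quaternion array must have shape (n, 4)")
        norms = np.linalg.norm(self.quat, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise KinematicsError("orientation quaternions must have unit norm")

    def __len__(self) -> int:
        return self.quat.shape[0]

    def as_rotation(self) -> Rotation:
        return Rotation.from_quat(self.quat)


@dataclass
class KinematicChannels:
    """The six derived kinematic series on a common time base."""

    time: np.ndarray
    rate_hz: float
    ah: np.ndarray
    av: np.ndarray
    omegah: np.ndarray
    omegav: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in CHANNEL_ORDER:
            if len(getattr(self, name)) != n:
                raise KinematicsError(f"channel {name} length != time length")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNEL_ORDER:
            raise KeyError(name)
        return getattr(self, name)

    def slice(self, i0: int, i1: int) -> "KinematicChannels":
        return KinematicChannels(
            time=self.time[i0:i1],
            rate_hz=self.rate_hz,
            **{name: getattr(self, name)[i0:i1] for name in CHANNEL_ORDER},
        )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    raw: ImuRecording,
    target_rate: float = 100.0,
    cutoff: float = 20.0,
    order: int = 4,
    zero_phase: bool = True,
) -> ImuRecording:
    """Down-sample to ``target_rate`` and low-pass filter all six axes.

    Decimation is by integer stride (the subsequent 20 Hz low-pass acts
    as the anti-alias stage), then each axis passes through an
    ``order``-th order Butterworth IIR filter with the given cutoff.
    ``zero_phase`` applies the filter forward and backward (doubling the
    attenuation, zero group delay — the default for event-locked
    segmentation); set it False for a causal single pass.

    Raises
    ------
    KinematicsError
        If the recording is shorter than 1 s, the timestamps are not
        strictly increasing, the input rate is below ``target_rate``
        (no upsampling), or the decimation factor is non-integer.
    """
    if raw.duration_s < 1.0:
        raise KinematicsError(
            f"recording too short for filtering ({raw.duration_s:.3f} s < 1 s)"
        )
    if raw.sample_rate_hz < target_rate - 1e-9:
        raise KinematicsError(
            f"input rate {raw.sample_rate_hz} Hz below target {target_rate} Hz;"
            " upsampling is not supported"
        )
    factor_f = raw.sample_rate_hz / target_rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-6:
        raise KinematicsError(
            f"rate ratio {factor_f:.4f} is not an integer decimation factor"
        )

    time = raw.time[::factor]
    accel = raw.accel[::factor]
    gyro = raw.gyro[::factor]

    if cutoff >= target_rate / 2:
        raise KinematicsError("cutoff must be below the target Nyquist rate")
    sos = signal.butter(order, cutoff, btype="low", fs=target_rate, output="sos")
    if zero_phase:
        accel = signal.sosfiltfilt(sos, accel, axis=0)
        gyro = signal.sosfiltfilt(sos, gyro, axis=0)
    else:
        accel = signal.sosfilt(sos, accel, axis=0)
        gyro = signal.sosfilt(sos, gyro, axis=0)

    return ImuRecording(
        time=time,
        accel=accel,
        gyro=gyro,
        sample_rate_hz=target_rate,
        accel_units=raw.accel_units,
    )


# ---------------------------------------------------------------------------
# complementary-filter orientation estimation
# ---------------------------------------------------------------------------

def _quat_mul(a, b):
    ax, ay, az, aw = a
    bx, by, bz, bw = b
    return (
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
        aw * bw - ax * bx - ay * by - az * bz,
    )


def _quat_normalize(q):
    x, y, z, w = q
    n = math.sqrt(x * x + y * y + z * z + w * w)
    return (x / n, y / n, z / n, w / n)


def _quat_rotate(q, v):
    """Rotate 3-vector v by quaternion q (device -> world)."""
    x, y, z, w = q
    vx, vy, vz = v
    # t = 2 q_vec x v
    tx = 2.0 * (y * vz - z * vy)
    ty = 2.0 * (z * vx - x * vz)
    tz = 2.0 * (x * vy - y * vx)
    return (
        vx + w * tx + (y * tz - z * ty),
        vy + w * ty + (z * tx - x * tz),
        vz + w * tz + (x * ty - y * tx),
    )


def _quat_from_axis_angle(axis, angle):
    s = math.sin(angle / 2.0)
    return (axis[0] * s, axis[1] * s, axis[2] * s, math.cos(angle / 2.0))


def _tilt_quat_from_accel(a) -> tuple:
    """Minimal (yaw-free) rotation taking the measured gravity direction
    in the device frame onto the world up axis."""
    norm = math.sqrt(a[0] ** 2 + a[1] ** 2 + a[2] ** 2)
    if norm == 0.0:
        return (0.0, 0.0, 0.0, 1.0)
    ux, uy, uz = a[0] / norm, a[1] / norm, a[2] / norm
    # axis = u x ez = (uy, -ux, 0); angle between u and ez
    s = math.hypot(ux, uy)
    angle = math.atan2(s, uz)
    if s < 1e-12:
        if uz > 0:
            return (0.0, 0.0, 0.0, 1.0)
        return (1.0, 0.0, 0.0, 0.0)  # upside down: flip about x
    return _quat_from_axis_angle((uy / s, -ux / s, 0.0), angle)


def estimate_orientation(
    rec: ImuRecording,
    accel_weight: float = 0.02,
    init_window_s: float = 0.5,
    freefall_threshold_g: float = 0.05,
) -> OrientationSeries:
    """Complementary-filter orientation from a preprocessed recording.

    Each step integrates the gyroscope (strapdown, body-frame rates) and
    then rotates the estimate a fraction ``accel_weight`` of the way
    toward agreement with the accelerometer-implied gravity direction.
    The correction axis is horizontal, so it fixes inclination only;
    heading evolves exclusively by gyro integration.  With the default
    weight (0.02/sample at 100 Hz) the tilt correction has a ~0.5 s time
    constant.  Samples whose specific-force norm falls below
    ``freefall_threshold_g`` (near free fall) skip the correction.

    Initial orientation is taken from the mean accelerometer vector over
    the first ``init_window_s`` seconds (tilt), with zero initial yaw.
    """
    if not 0.0 < accel_weight < 1.0:
        raise KinematicsError("accel_weight must lie in (0, 1)")
    n = rec.n_samples
    if n == 0:
        raise KinematicsError("empty recording")

    accel_g = rec.accel_g()
    t = rec.time.tolist()
    al = accel_g.tolist()
    gl = np.radians(rec.gyro).tolist()

    n_init = max(1, int(round(init_window_s * rec.sample_rate_hz)))
    q = _tilt_quat_from_accel(accel_g[:n_init].mean(axis=0))

    thr2 = freefall_threshold_g * freefall_threshold_g
    out = np.empty((n, 4), dtype=float)
    out[0] = q
    for k in range(1, n):
        dt = t[k] - t[k - 1]
        wx, wy, wz = gl[k]
        # gyro strapdown step (body-frame rate, right multiplication)
        angle = math.sqrt(wx * wx + wy * wy + wz * wz) * dt
        if angle > 0.0:
            half = angle / 2.0
            s = math.sin(half) / (angle / dt)
            dq = (wx * s, wy * s, wz * s, math.cos(half))
            q = _quat_mul(q, dq)
        # accelerometer tilt correction (world-frame, horizontal axis)
        ax, ay, az = al[k]
        norm2 = ax * ax + ay * ay + az * az
        if norm2 > thr2:
            gx, gy, gz = _quat_rotate(q, (ax, ay, az))
            gn = math.sqrt(gx * gx + gy * gy + gz * gz)
            gx, gy, gz = gx / gn, gy / gn, gz / gn
            s = math.hypot(gx, gy)
            if s > 1e-12:
                err = math.atan2(s, gz)
                corr = _quat_from_axis_angle(
                    (gy / s, -gx / s, 0.0), err * accel_weight
                )
                q = _quat_mul(corr, q)
        q = _quat_normalize(q)
        out[k] = q
    return OrientationSeries(out)


# ---------------------------------------------------------------------------
# channel derivation
# ---------------------------------------------------------------------------

def _yaw_angle(rot: Rotation) -> np.ndarray:
    """Heading (rotation about world z) of each sample, radians, signed."""
    # Intrinsic z-y-x decomposition: first angle is the heading.
    return rot.as_euler("ZYX")[:, 0]


def derive_channels(rec: ImuRecording, orient: OrientationSeries) -> KinematicChannels:
    """Resolve acceleration/angular velocity in the world frame and build
    the six kinematic channels.

    ``av`` is world-vertical specific force minus 1 g (≈0 at rest).
    ``gamma`` is the unwrapped heading, referenced to zero at the first
    sample and reported as an absolute deviation (so a 180° turn in
    either direction reads 180°).
    """
    if len(orient) != rec.n_samples:
        raise KinematicsError(
            f"orientation length {len(orient)} != recording length {rec.n_samples}"
        )
    rot = orient.as_rotation()

    a_world = rot.apply(rec.accel_ms2())
    w_world = rot.apply(rec.gyro)  # deg/s

    ah = np.hypot(a_world[:, 0], a_world[:, 1])
    av = a_world[:, 2] - G
    omegah = np.hypot(w_world[:, 0], w_world[:, 1])
    omegav = w_world[:, 2]

    up_world = rot.apply(np.array([0.0, 0.0, 1.0]))
    alpha = np.degrees(np.arccos(np.clip(up_world[:, 2], -1.0, 1.0)))

    yaw = np.unwrap(_yaw_angle(rot))
    gamma = np.degrees(np.abs(yaw - yaw[0]))

    return KinematicChannels(
        time=rec.time,
        rate_hz=rec.sample_rate_hz,
        ah=ah,
        av=av,
        omegah=omegah,
        omegav=omegav,
        alpha=alpha,
        gamma=gamma,
    )


def process_recording(
    raw: ImuRecording,
    target_rate: float = 100.0,
    cutoff: float = 20.0,
    order: int = 4,
    zero_phase: bool = True,
    accel_weight: float = 0.02,
) -> KinematicChannels:
    """Full front end: preprocess → orientation → six channels."""
    rec = preprocess(raw, target_rate=target_rate, cutoff=cutoff, order=order,
                     zero_phase=zero_phase)
    orient = estimate_orientation(rec, accel_weight=accel_weight)
    return derive_channels(rec, orient)
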