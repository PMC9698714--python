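"""Neutral-pose calibration: sensor frame -> gravity-free anatomical frame.

A trunk-worn IMU is strapped near L5 with an arbitrary (small) tilt relative
to the body.  The subject stands still for a few seconds before walking; the
mean specific force in that window is the gravity vector expressed in the
sensor frame.  The minimal rotation taking that vector onto +z corrects the
tilt.  The remaining degree of freedom — the heading (rotation about the
vertical) that makes +x point along the direction of travel — is resolved
either from the orientation quaternions when the recording carries them, or
from the walking data itself: the horizontal oscillatory velocity is
band-passed around the step frequency, where essentially all power belongs
to the anterior-posterior (AP) component, and its principal direction is
taken as AP.

Axis convention of the calibrated output: x = AP (direction of travel),
y = ML (leftward positive), z = VT (up positive).  Oscillatory energies are
quadratic in the velocity components, so the axis *signs* never affect any
reported metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .errors import CalibrationError, DegenerateInputError

GRAVITY_RANGE = (9.5, 10.1)  # plausible |g| for a valid static pose, m/s^2
STATIC_STD_MAX = 0.2         # m/s^2 per axis; above this the window is not static


@dataclass(frozen=True)
class CalibrationPose:
    """Rotation from sensor frame to the anatomical (AP, ML, VT) frame."""

    rotation: np.ndarray          # 3x3, orthonormal, det +1
    gravity_mag: float            # m/s^2
    neutral_window: tuple[float, float]
    heading_source: str = "none"  # "quaternion" | "ap-excursion" | "none"
    heading_yaw_rad: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise DegenerateInputError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise DegenerateInputError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise DegenerateInputError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 deg: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + 2.0 * K @ K
    K = np.array([[0, -v[2], v[1]],
                  [v[2], 0, -v[0]],
                  [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * (1.0 / (1.0 + c))


def _rot_z(yaw: float) -> np.ndarray:
    c, s = np.cos(yaw), np.sin(yaw)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) -> rotation matrix (sensor -> earth)."""
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _heading_from_quaternions(quats: np.ndarray, tilt_rot: np.ndarray) -> float:
    """Residual yaw between the fused orientation and the tilt-only rotation."""
    q = np.mean(quats, axis=0)
    R_q = _quat_to_matrix(q)                 # sensor -> fused earth frame
    residual = R_q @ tilt_rot.T              # what tilt-only correction missed
    return float(np.arctan2(residual[1, 0], residual[0, 0]))


def _heading_from_ap_excursion(accel_level: np.ndarray, fs: float) -> float:
    """Heading from the principal direction of step-frequency horizontal velocity.

    `accel_level` is tilt-corrected, gravity-removed acceleration.  The ML
    velocity oscillates at the stride frequency and the AP velocity at the
    step frequency (twice the stride frequency), so after narrow band-passing
    around the step frequency the dominant horizontal direction is AP even
    when broadband AP and ML variances happen to tie.
    """
    n = accel_level.shape[0]
    if n < int(8 * fs):  # need several strides of walking data
        return 0.0
    nyq = fs / 2.0
    sos = _sig.butter(2, [0.3 / nyq, min(15.0, 0.9 * nyq) / nyq], btype="bandpass",
                      output="sos")
    filt = _sig.sosfiltfilt(sos, accel_level, axis=0)
    vel = np.cumsum((filt[1:] + filt[:-1]) / 2.0, axis=0) / fs
    vel = _sig.sosfiltfilt(_sig.butter(2, 0.3 / nyq, btype="highpass", output="sos"),
                           vel, axis=0)
    # step frequency from the vertical velocity spectrum (1-4 Hz band)
    f, pxx = _sig.periodogram(vel[:, 2], fs=fs)
    band = (f >= 1.0) & (f <= 4.0)
    if not band.any() or pxx[band].max() <= 0:
        return 0.0
    f_step = float(f[band][np.argmax(pxx[band])])
    lo, hi = 0.75 * f_step, 1.25 * f_step
    if hi >= nyq:
        return 0.0
    sos_nb = _sig.butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    horiz = _sig.sosfiltfilt(sos_nb, vel[:, :2], axis=0)
    cov = np.cov(horiz.T)
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, np.argmax(evals)]
    if u[0] < 0:  # travel-direction sign is unobservable; fix a convention
        u = -u
    return float(np.arctan2(u[1], u[0]))


def estimate_neutral_pose(recording, window: tuple[float, float] = (0.0, 3.0), *,
                          heading: str = "auto",
                          gravity_override: float | None = None) -> CalibrationPose:
    """Build the calibration rotation from a quasi-static neutral-pose window.

    Parameters
    ----------
    recording : ImuRecording
        Raw sensor-frame recording (gravity included).
    window : (start_s, end_s)
        Time span of the neutral standing pose, in the recording's time base.
    heading : {"auto", "quaternion", "ap-excursion", "none"}
        How to resolve the rotation about the vertical.  "auto" prefers the
        quaternion stream when present, else falls back to the walking-data
        principal-direction pass; "none" leaves the heading unresolved
        (tilt-only correction).
    gravity_override : float, optional
        Use this gravity magnitude instead of validating the measured one.

    Raises
    ------
    CalibrationError
        Window shorter than 1 s, not quasi-static, or implausible |g|.
    DegenerateInputError
        Zero-norm mean acceleration in the window.
    """
    t = recording.timestamps
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < max(2, int(1.0 * recording.nominal_rate)):
        raise CalibrationError("neutral-pose window must contain >= 1 s of data")
    static = recording.accel_sensor[mask]
    if np.any(static.std(axis=0) > STATIC_STD_MAX):
        raise CalibrationError(
            "neutral-pose window is not quasi-static "
            f"(per-axis std {static.std(axis=0)} m/s^2, limit {STATIC_STD_MAX})")
    m = static.mean(axis=0)
    g = float(np.linalg.norm(m))
    if g < 1e-9:
        raise DegenerateInputError("zero-norm mean acceleration in static window")
    if gravity_override is not None:
        g_mag = float(gravity_override)
    else:
        if not (GRAVITY_RANGE[0] <= g <= GRAVITY_RANGE[1]):
            raise CalibrationError(
                f"static gravity magnitude {g:.3f} m/s^2 outside {GRAVITY_RANGE}")
        g_mag = g

    tilt_rot = _rotation_between(m, np.array([0.0, 0.0, 1.0]))

    yaw = 0.0
    source = "none"
    if heading not in ("auto", "quaternion", "ap-excursion", "none"):
        raise CalibrationError(f"unknown heading source {heading!r}")
    if heading in ("auto", "quaternion") and recording.quaternions is not None:
        yaw = _heading_from_quaternions(recording.quaternions[mask], tilt_rot)
        source = "quaternion"
    elif heading in ("auto", "ap-excursion"):
        walk = t > window[1]
        if walk.sum() > int(8 * recording.nominal_rate):
            level = recording.accel_sensor[walk] @ tilt_rot.T
            level = level - np.array([0.0, 0.0, g_mag])
            yaw = _heading_from_ap_excursion(level, recording.nominal_rate)
            source = "ap-excursion"

    rotation = _rot_z(-yaw) @ tilt_rot
    return CalibrationPose(rotation=rotation, gravity_mag=g_mag,
                           neutral_window=(float(window[0]), float(window[1])),
                           heading_source=source, heading_yaw_rad=float(yaw))


def apply_calibration(recording, pose: CalibrationPose) -> np.ndarray:
    """Rotate sensor-frame acceleration into (AP, ML, VT) and remove gravity.

    Returns an (N, 3) array of linear acceleration in m/s^2.  Gravity is
    subtracted as the constant vector (0, 0, gravity_mag) in the levelled
    frame; residual low-frequency error from this approximation is absorbed
    by the downstream 0.3 Hz high-pass.
    """
    rotated = recording.accel_sensor @ pose.rotation.T
    rotated[:, 2] -= pose.gravity_mag
    return rotated
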