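"""Parametric gait simulator: synthetic trunk-IMU recordings with exact ground truth.

The kinematic model is the minimal description of BCOM motion during steady
walking: constant forward translation plus one sinusoid per axis.  The ML
oscillation completes one cycle per stride (the BCOM sways toward each
stance foot once), while the VT and AP oscillations complete one cycle per
step (every footfall lifts the BCOM and modulates the forward speed), i.e.
at twice the ML frequency — the 2:1 ratio that produces the bow-tie
frontal-plane trajectory.  With τ the time since walking began and S the
stride period:

    ml(τ) = (d_ml/2)·sin(2πτ/S + φ_ml)
    vt(τ) = (d_vt/2)·sin(4πτ/S + φ_vt)
    ap(τ) = v̄·τ + (d_ap/2)·sin(4πτ/S + φ_ap)

Acceleration is the analytic second derivative, expressed in a tilted sensor
frame with gravity, white noise and a linear bias ramp added — exactly the
nuisances the calibration and 0.3 Hz high-pass stages exist to remove.
Because the kinematics are pure sinusoids every tested quantity has a closed
form; per axis with period P and peak-to-peak d:

    OE = ((d/2)·(2π/P))² / 4       (= ½ · mean v², velocity amplitude²/4)

A 3 s standing lead-in precedes the walk, emulating the neutral-pose
protocol the calibration stage expects.  The forward speed starts abruptly
at the walk boundary; the corresponding acceleration impulse is deliberately
omitted from the sampled series (it lies entirely below the 0.3 Hz analysis
band) so that walk_distance = v̄·duration stays exact for walkway-mode
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .errors import ParameterError
from .imu_io import ImuRecording, WalkMetadata

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth kinematic parameters for a synthetic recording."""

    v_bar: float = 1.3                # forward speed, m/s
    stride_period: float = 1.1        # s (two steps)
    d_pp: dict = field(default_factory=lambda: {"ap": 0.02, "ml": 0.02, "vt": 0.03})
    phases: dict = field(default_factory=lambda: {"ap": 0.0, "ml": 0.0, "vt": 0.0})
    tilt_roll_deg: float = 0.0        # about the AP axis
    tilt_pitch_deg: float = 0.0       # about the ML axis
    noise_sigma: float = 0.05         # white accelerometer noise, m/s^2
    drift_rate: float = 0.001         # linear bias ramp, m/s^2 per s, each axis
    duration: float = 30.0            # walking time, s
    rate: float = 100.0               # Hz
    seed: int = 1
    static_lead: float = 3.0          # neutral standing pose before the walk, s
    static_tail: float = 3.0          # standing after the walk, s (keeps the
                                      # walk clear of the filter's array-edge
                                      # transient, as in a real recording)
    include_quaternions: bool = False
    preset: str | None = None

    def __post_init__(self) -> None:
        if self.v_bar < 0 or self.stride_period <= 0:
            raise ParameterError("v_bar must be >= 0 and stride_period > 0")
        if any(v < 0 for v in self.d_pp.values()):
            raise ParameterError("peak-to-peak displacements must be >= 0")
        if self.rate < 50:
            raise ParameterError("sampling rate must be >= 50 Hz")

    @property
    def step_period(self) -> float:
        return self.stride_period / 2.0

    def axis_period(self, axis: str) -> float:
        """Period of the oscillation on an axis: stride for ML, step for VT/AP."""
        return self.stride_period if axis == "ml" else self.step_period


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form truth for everything the pipeline estimates."""

    v_bar: float
    step_period: float
    stride_period: float
    d_pp: dict
    oe: dict              # per-axis oscillatory energy, m²/s²
    toe: float
    ke0: float
    oep: float
    ep_pct: dict
    periods: dict         # per-axis dominant period, s
    step_events: np.ndarray  # times of VT-acceleration peaks, recording time base
    walk_start: float
    walk_end: float

    def as_dict(self) -> dict:
        d = asdict(self)
        d["step_events"] = [float(x) for x in self.step_events]
        return d


def closed_form_oe(config: SimulationConfig) -> dict[str, float]:
    """Exact per-axis oscillatory energy of the sinusoidal model."""
    out = {}
    for axis in ("ap", "ml", "vt"):
        amp_v = (config.d_pp[axis] / 2.0) * (2.0 * np.pi / config.axis_period(axis))
        out[axis] = amp_v ** 2 / 4.0
    return out


def _rot_xyz(roll_rad: float, pitch_rad: float) -> np.ndarray:
    """Sensor -> earth rotation: pitch about ML (y) after roll about AP (x)."""
    cr, sr = np.cos(roll_rad), np.sin(roll_rad)
    cp, sp = np.cos(pitch_rad), np.sin(pitch_rad)
    rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    return ry @ rx


def _matrix_to_quat(R: np.ndarray) -> np.ndarray:
    w = np.sqrt(max(0.0, 1.0 + R[0, 0] + R[1, 1] + R[2, 2])) / 2.0
    if w < 1e-8:  # not reachable for small tilts, kept for safety
        raise ParameterError("tilt too large for quaternion shortcut")
    x = (R[2, 1] - R[1, 2]) / (4 * w)
    y = (R[0, 2] - R[2, 0]) / (4 * w)
    z = (R[1, 0] - R[0, 1]) / (4 * w)
    return np.array([w, x, y, z])


def _vt_accel_peak_times(config: SimulationConfig) -> np.ndarray:
    """Maxima of the analytic VT acceleration within the walk, one per step."""
    S, phi = config.stride_period, config.phases["vt"]
    omega = 4.0 * np.pi / S
    # accel = -(d/2)ω² sin(ωτ+φ): maxima where sin(ωτ+φ) = −1
    k = np.arange(0, int(np.ceil(config.duration / config.step_period)) + 2)
    tau = (-np.pi / 2.0 - phi + 2.0 * np.pi * k) / omega
    tau = tau[(tau > 0) & (tau < config.duration)]
    return config.static_lead + tau


def simulate_gait(config: SimulationConfig) -> tuple[ImuRecording, GroundTruth]:
    """Synthesise a trunk-IMU recording and its exact ground truth.

    The recording is static for ``static_lead`` seconds, then walks for
    ``duration`` seconds.  Same config + same seed is bit-identical.
    """
    n = int(round((config.static_lead + config.duration + config.static_tail)
                  * config.rate))
    t = np.arange(n) / config.rate
    tau = t - config.static_lead
    walking = (tau >= 0.0) & (tau <= config.duration)
    tau_w = np.where(walking, tau, 0.0)

    accel_earth = np.zeros((n, 3))
    for i, axis in enumerate(("ap", "ml", "vt")):
        amp = config.d_pp[axis] / 2.0
        omega = 2.0 * np.pi / config.axis_period(axis)
        phi = config.phases[axis]
        accel_earth[:, i] = np.where(
            walking, -amp * omega ** 2 * np.sin(omega * tau_w + phi), 0.0)

    R = _rot_xyz(np.deg2rad(config.tilt_roll_deg), np.deg2rad(config.tilt_pitch_deg))
    specific = accel_earth + np.array([0.0, 0.0, GRAVITY])
    accel_sensor = specific @ R  # == (R.T @ specific.T).T

    rng = np.random.default_rng(config.seed)
    accel_sensor = accel_sensor + rng.normal(0.0, config.noise_sigma, (n, 3))
    accel_sensor = accel_sensor + config.drift_rate * t[:, None]

    quats = None
    if config.include_quaternions:
        quats = np.tile(_matrix_to_quat(R), (n, 1))

    metadata = WalkMetadata(
        subject_id=config.preset or "synthetic",
        walk_distance_m=config.v_bar * config.duration,
        treadmill_speed_mps=config.v_bar)
    recording = ImuRecording(timestamps=t, accel_sensor=accel_sensor,
                             nominal_rate=config.rate, quaternions=quats,
                             metadata=metadata)

    oe = closed_form_oe(config)
    toe = sum(oe.values())
    ke0 = 0.5 * config.v_bar ** 2
    truth = GroundTruth(
        v_bar=config.v_bar, step_period=config.step_period,
        stride_period=config.stride_period, d_pp=dict(config.d_pp), oe=oe,
        toe=toe, ke0=ke0, oep=toe / ke0 if ke0 > 0 else 0.0,
        ep_pct={ax: (100.0 * oe[ax] / toe if toe > 0 else 0.0) for ax in oe},
        periods={"ap": config.step_period, "ml": config.stride_period,
                 "vt": config.step_period},
        step_events=_vt_accel_peak_times(config),
        walk_start=config.static_lead,
        walk_end=config.static_lead + config.duration)
    return recording, truth


_PRESETS = {
    # comfortable overground gait; EP lands inside the healthy region
    "normal": {},
    # lateral sway doubled -> MLE share quadruples
    "wide_stance": {"d_pp": {"ap": 0.02, "ml": 0.04, "vt": 0.03}},
    # vertical bounce doubled -> OEP roughly triples
    "bouncy": {"d_pp": {"ap": 0.02, "ml": 0.02, "vt": 0.06}},
    # flattened vertical lift and a quicker, shorter stride
    "shuffle": {"d_pp": {"ap": 0.02, "ml": 0.02, "vt": 0.015},
                "stride_period": 1.0},
}


def preset_config(name: str, **overrides) -> SimulationConfig:
    """Named gait presets: normal | wide_stance | bouncy | shuffle.

    All share v̄ = 1.3 m/s, 30 s at 100 Hz, noise σ = 0.05 m/s², drift
    0.001 m/s³, seed 1; only the amplitudes (and for shuffle the stride
    period) differ, in the qualitative directions the gait names imply.
    """
    if name not in _PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return SimulationConfig(preset=name, **kwargs)


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.as_dict(), fh, indent=2)
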