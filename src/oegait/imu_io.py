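"""On-disk artifacts: delimited IMU recordings, YAML config, JSON reports.

Vendors export trunk-IMU logs as delimited text with wildly varying column
names, so the reader takes an explicit column mapping (time + three
acceleration axes, optional orientation quaternion) instead of assuming a
dialect.  Timestamps are validated and, when jitter exceeds 5% of the
nominal sample interval, the series is resampled onto a uniform grid by
linear interpolation — adequate far below the 15 Hz analysis cut-off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .energetics import EnergySummary
from .errors import DataError, FormatError, InsufficientDataError

MIN_DURATION_S = 3.0
JITTER_TOLERANCE = 0.05  # resample when any interval deviates more than this


@dataclass
class WalkMetadata:
    subject_id: str | None = None
    walk_distance_m: float | None = None
    treadmill_speed_mps: float | None = None
    body_mass_kg: float | None = None


@dataclass
class ColumnMap:
    """Mapping from on-disk column names to the recording's fields."""

    time: str = "t"
    ax: str = "ax"
    ay: str = "ay"
    az: str = "az"
    quat: tuple[str, str, str, str] | None = None  # (qw, qx, qy, qz)
    delimiter: str = ","


@dataclass
class ImuRecording:
    """Raw sensor-frame acceleration time series (gravity included)."""

    timestamps: np.ndarray          # s, strictly increasing
    accel_sensor: np.ndarray        # (N, 3), m/s^2, sensor frame
    nominal_rate: float             # Hz
    quaternions: np.ndarray | None = None  # (N, 4) unit (w, x, y, z)
    metadata: WalkMetadata = field(default_factory=WalkMetadata)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel_sensor = np.asarray(self.accel_sensor, dtype=float)
        t = self.timestamps
        if t.ndim != 1 or self.accel_sensor.shape != (t.size, 3):
            raise FormatError("need 1-D timestamps and (N, 3) acceleration")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if t[-1] - t[0] < MIN_DURATION_S:
            raise InsufficientDataError(
                f"recording shorter than {MIN_DURATION_S} s")
        if not np.all(np.isfinite(self.accel_sensor)):
            raise DataError("acceleration contains non-finite values")
        med_dt = float(np.median(np.diff(t)))
        if abs(med_dt - 1.0 / self.nominal_rate) > 0.2 / self.nominal_rate:
            raise DataError(
                f"median sampling interval {med_dt:.4f} s inconsistent with "
                f"nominal rate {self.nominal_rate} Hz")
        if self.quaternions is not None:
            self.quaternions = np.asarray(self.quaternions, dtype=float)
            if self.quaternions.shape != (t.size, 4):
                raise FormatError("quaternions must be (N, 4)")
            norms = np.linalg.norm(self.quaternions, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-3):
                raise DataError("quaternions must have unit norm within 1e-3")

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.size)


def _resample_uniform(rec: ImuRecording) -> ImuRecording:
    t = rec.timestamps
    dt = 1.0 / rec.nominal_rate
    grid = t[0] + np.arange(int(np.floor((t[-1] - t[0]) / dt)) + 1) * dt
    accel = np.column_stack([np.interp(grid, t, rec.accel_sensor[:, i])
                             for i in range(3)])
    quats = None
    if rec.quaternions is not None:
        quats = np.column_stack([np.interp(grid, t, rec.quaternions[:, i])
                                 for i in range(4)])
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    return ImuRecording(timestamps=grid, accel_sensor=accel,
                        nominal_rate=rec.nominal_rate, quaternions=quats,
                        metadata=rec.metadata)


def read_imu_recording(path, format_spec: ColumnMap | None = None, *,
                       nominal_rate: float = 100.0,
                       metadata: WalkMetadata | None = None) -> ImuRecording:
    """Read a delimited-text IMU recording and validate it.

    Irregular timestamps (any interval off by more than 5% of the nominal
    sample interval) are resampled to the nominal rate by linear
    interpolation.
    """
    spec = format_spec or ColumnMap()
    try:
        df = pd.read_csv(path, sep=spec.delimiter)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed text
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    needed = [spec.time, spec.ax, spec.ay, spec.az]
    if spec.quat is not None:
        needed += list(spec.quat)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns {missing} in {path}")

    t = df[spec.time].to_numpy(dtype=float)
    accel = df[[spec.ax, spec.ay, spec.az]].to_numpy(dtype=float)
    quats = None
    if spec.quat is not None:
        quats = df[list(spec.quat)].to_numpy(dtype=float)
    elif {"qw", "qx", "qy", "qz"}.issubset(df.columns):
        quats = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)

    rec = ImuRecording(timestamps=t, accel_sensor=accel,
                       nominal_rate=nominal_rate, quaternions=quats,
                       metadata=metadata or WalkMetadata())
    dt_nom = 1.0 / nominal_rate
    if np.any(np.abs(np.diff(t) - dt_nom) > JITTER_TOLERANCE * dt_nom):
        rec = _resample_uniform(rec)
    return rec


def write_imu_recording(rec: ImuRecording, path) -> None:
    """Write the recording as CSV (t, ax, ay, az[, qw, qx, qy, qz])."""
    data = {"t": rec.timestamps,
            "ax": rec.accel_sensor[:, 0],
            "ay": rec.accel_sensor[:, 1],
            "az": rec.accel_sensor[:, 2]}
    if rec.quaternions is not None:
        for i, name in enumerate(("qw", "qx", "qy", "qz")):
            data[name] = rec.quaternions[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


@dataclass
class SegmentResult:
    """Per-segment analysis output."""

    summary: EnergySummary
    step_period_s: float
    v_bar_ap_mps: float
    d_pp_m: dict                  # {"ap": ..., "ml": ..., "vt": ...}
    n_steps: int
    n_strides: int
    start_s: float
    end_s: float
    dominant_periods_s: dict | None = None
    ep_region: str | None = None

    def as_dict(self) -> dict:
        d = self.summary.as_dict()
        d.update({
            "step_period_s": self.step_period_s,
            "v_bar_ap_mps": self.v_bar_ap_mps,
            "d_pp_m": dict(self.d_pp_m),
            "n_steps": self.n_steps,
            "n_strides": self.n_strides,
            "start_s": self.start_s,
            "end_s": self.end_s,
            "dominant_periods_s": self.dominant_periods_s,
            "ep_region": self.ep_region,
        })
        return d


@dataclass
class AnalysisReport:
    """Full analysis output: per-segment results, combined summary, provenance."""

    segments: list[SegmentResult]
    combined: dict                # pooled metrics across segments
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        for seg in self.segments:
            s = seg.summary
            if s.ep_defined:
                total = s.ep_ap_pct + s.ep_ml_pct + s.ep_vt_pct
                if abs(total - 100.0) > 1e-9 * 100.0:
                    raise DataError(
                        f"EP percentages sum to {total!r}, expected 100")

    def as_dict(self) -> dict:
        return {"segments": [s.as_dict() for s in self.segments],
                "combined": dict(self.combined),
                "provenance": dict(self.provenance)}


def write_analysis_report(report: AnalysisReport, path) -> None:
    """Write the report as JSON; floats round-trip exactly (repr precision)."""
    report.validate()
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)


def read_analysis_report(path) -> dict:
    """Read a report back as a plain dict (numeric fields bit-exact)."""
    with open(path) as fh:
        return json.load(fh)
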