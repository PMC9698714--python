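"""End-to-end analysis: recording -> calibrate -> filter -> integrate -> segment -> energies.

This is the orchestration layer behind the ``oegait analyze`` command; every
step is an ordinary library call so the pipeline stays scriptable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import __version__
from .calibration import apply_calibration, estimate_neutral_pose
from .energetics import classify_ep_region, compute_energies
from .errors import InsufficientDataError
from .imu_io import AnalysisReport, ImuRecording, SegmentResult
from .preprocessing import (bandpass_accel, integrate_to_displacement,
                            integrate_to_velocity)
from .segmentation import detect_steps, dominant_periods, select_steady_state

log = logging.getLogger("oegait")


@dataclass
class RunConfig:
    """Everything `analyze` needs beyond the recording itself."""

    calibration_window: tuple[float, float] = (0.0, 3.0)
    heading: str = "auto"                  # quaternion | ap-excursion | auto | none
    gravity_override: float | None = None
    cut_on: float = 0.3                    # Hz
    cut_off: float | None = 15.0           # Hz; None disables the low-pass
    filter_order: int = 4
    forward_speed_source: str = "walkway"  # treadmill | walkway | lowfreq
    peak_prominence: float = 0.5           # m/s^2
    min_separation: float = 0.25           # s
    turn_policy: str = "none"              # none | time | auto
    turn_time: float | None = None
    trim_steps: int = 2
    min_strides: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.calibration_window, list):
            cfg.calibration_window = tuple(cfg.calibration_window)
        return cfg

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _pooled_metrics(results: list[SegmentResult]) -> dict:
    """Duration-weighted pooling across segments (= time average over their union)."""
    w = np.array([r.end_s - r.start_s for r in results])
    w = w / w.sum()

    def wmean(vals):
        return float(np.dot(w, vals))

    ke0 = wmean([r.summary.ke0 for r in results])
    ape = wmean([r.summary.ape for r in results])
    mle = wmean([r.summary.mle for r in results])
    vte = wmean([r.summary.vte for r in results])
    toe = ape + mle + vte
    out = {"ke0": ke0, "ape": ape, "mle": mle, "vte": vte, "toe": toe,
           "oep": toe / ke0 if ke0 > 0 else 0.0,
           "step_period_s": wmean([r.step_period_s for r in results]),
           "v_bar_ap_mps": wmean([r.v_bar_ap_mps for r in results])}
    if toe > 0:
        out.update(ep_ap_pct=100.0 * ape / toe, ep_ml_pct=100.0 * mle / toe,
                   ep_vt_pct=100.0 * vte / toe)
    return out


def analyze_recording(recording: ImuRecording, config: RunConfig | None = None, *,
                      input_path: str | None = None) -> AnalysisReport:
    """Run the full single-IMU gait-efficiency analysis on one recording."""
    cfg = config or RunConfig()
    fs = recording.nominal_rate
    t = recording.timestamps

    pose = estimate_neutral_pose(recording, cfg.calibration_window,
                                 heading=cfg.heading,
                                 gravity_override=cfg.gravity_override)
    log.info("calibration: |g|=%.3f m/s^2, heading=%s (yaw %.2f deg)",
             pose.gravity_mag, pose.heading_source,
             np.rad2deg(pose.heading_yaw_rad))
    accel_anat = apply_calibration(recording, pose)
    accel_filt = bandpass_accel(accel_anat, fs, cfg.cut_on, cfg.cut_off,
                                cfg.filter_order)

    events = detect_steps(accel_filt[:, 2], fs, prominence=cfg.peak_prominence,
                          min_separation=cfg.min_separation)
    log.info("detected %d step events (mean step period %.3f s)",
             events.size, float(np.mean(np.diff(events))))

    # provisional oscillatory velocity for the turn detector
    vel_prov = integrate_to_velocity(accel_filt, t, forward_speed_source="treadmill",
                                     metadata=_ZeroSpeed(), cut_on=cfg.cut_on,
                                     order=cfg.filter_order)
    segments = select_steady_state((float(t[0]), float(t[-1])), events,
                                   cfg.turn_policy, turn_time=cfg.turn_time,
                                   ap_velocity=vel_prov.v_ap, t=t, rate=fs,
                                   trim_steps=cfg.trim_steps,
                                   min_strides=cfg.min_strides)

    results: list[SegmentResult] = []
    for seg in segments:
        log.info("segment %.2f-%.2f s: %d steps, %d strides",
                 seg.start_s, seg.end_s, seg.n_steps, seg.n_periods)
        vel = integrate_to_velocity(
            accel_filt, t, forward_speed_source=cfg.forward_speed_source,
            metadata=recording.metadata, step_events=seg.bout_events,
            accel_unfiltered=accel_anat, centring=seg.sample_slice(t),
            cut_on=cfg.cut_on, order=cfg.filter_order)
        log.info("v_bar_ap=%.3f m/s (source=%s)", vel.v_bar_ap,
                 cfg.forward_speed_source)
        summary = compute_energies(vel, seg)
        disp = integrate_to_displacement(vel, seg, cut_on=cfg.cut_on,
                                         order=cfg.filter_order)
        periods = None
        if seg.n_periods >= 8:
            try:
                periods = dominant_periods(vel, seg)
            except InsufficientDataError:
                periods = None
        region = classify_ep_region(summary)[0] if summary.ep_defined else None
        results.append(SegmentResult(
            summary=summary, step_period_s=seg.step_period,
            v_bar_ap_mps=vel.v_bar_ap, d_pp_m=disp.d_pp, n_steps=seg.n_steps,
            n_strides=seg.n_periods, start_s=seg.start_s, end_s=seg.end_s,
            dominant_periods_s=periods, ep_region=region))

    provenance = {"input_file": input_path, "config_hash": cfg.digest(),
                  "software_version": __version__,
                  "subject_id": recording.metadata.subject_id}
    return AnalysisReport(segments=results, combined=_pooled_metrics(results),
                          provenance=provenance)


class _ZeroSpeed:
    """Stand-in metadata for the provisional (oscillation-only) pass."""

    treadmill_speed_mps = 0.0
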