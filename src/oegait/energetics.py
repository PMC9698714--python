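"""Oscillatory kinetic energy metrics of BCOM motion.

During steady walking the BCOM velocity decomposes into a constant forward
speed v̄_ap plus zero-mean oscillations on the three anatomical axes.  The
time-averaged kinetic energy per unit mass then splits exactly:

    Ēk = KE0 + (APE + MLE + VTE),        KE0 = ½ v̄_ap²

where each oscillatory energy (OE) is the time average of ½ v_axis(t)² over
an integer number of strides (the v̄·v_ap cross term vanishes on such a
window).  Two derived metrics summarise gait efficiency and form:

* OEP (overhead energy percentage) = TOE / KE0 — the fraction of forward
  kinetic energy spent on maintaining the oscillatory gait form.  Healthy
  adults at comfortable speed sit around a few percent.
* EP percentages — the share of the total OE on each axis, drawn on the EP
  graph as a point (x = MLE%, y = APE%) with diagonal iso-VTE% contours
  x + y = 100 − VTE%.

All energies here are per unit body mass (m²/s², i.e. J/kg); OEP and the EP
percentages are therefore independent of body mass by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientGaitError, ParameterError, UndefinedRatioError
from .preprocessing import AXES, DisplacementSignal, VelocitySignal
from .segmentation import GaitSegment

#: Healthy-region bounds on the EP graph (strict inequalities).
EP_REGION_BOUNDS = {"vte_pct_min": 40.0, "mle_pct_max": 35.0, "ape_pct_max": 50.0}


@dataclass(frozen=True)
class EnergySummary:
    """Per-unit-mass energy decomposition of one steady-state gait segment."""

    ke0: float        # ½ v̄_ap², m²/s²
    ape: float        # AP oscillatory energy
    mle: float        # ML oscillatory energy
    vte: float        # VT oscillatory energy
    toe: float        # APE + MLE + VTE
    ek_bar: float     # total average kinetic energy, computed independently
    oep: float        # TOE / KE0, dimensionless fraction
    ep_ap_pct: float  # 100 · APE / TOE
    ep_ml_pct: float
    ep_vt_pct: float
    ep_defined: bool = True  # False iff TOE == 0 (EP shares meaningless, set to 0)

    def __post_init__(self) -> None:
        if min(self.ape, self.mle, self.vte) < 0:
            raise ParameterError("oscillatory energies must be non-negative")
        if self.ep_defined:
            s = self.ep_ap_pct + self.ep_ml_pct + self.ep_vt_pct
            if abs(s - 100.0) > 1e-9 * 100.0:
                raise ParameterError(f"EP percentages sum to {s!r}, expected 100")

    @property
    def oep_pct(self) -> float:
        return 100.0 * self.oep

    def as_dict(self) -> dict[str, float]:
        return {"ke0": self.ke0, "ape": self.ape, "mle": self.mle,
                "vte": self.vte, "toe": self.toe, "ek_bar": self.ek_bar,
                "oep": self.oep, "ep_ap_pct": self.ep_ap_pct,
                "ep_ml_pct": self.ep_ml_pct, "ep_vt_pct": self.ep_vt_pct}


def compute_energies(vel: VelocitySignal, segment: GaitSegment) -> EnergySummary:
    """Energy decomposition over a steady-state, integer-stride window.

    Each OE is the plain sample mean of ½ v_axis² over the segment's samples
    (for periodic signals over complete periods this matches the continuous
    time average to O(dt²) and keeps OE == ½·variance exact).  Ēk is computed
    independently from the full velocity vector including v̄_ap, so the
    decomposition identity Ēk = KE0 + TOE is a genuine cross-check, not a
    restatement.
    """
    sl = segment.sample_slice(vel.t)
    comps = {ax: vel.component(ax)[sl] for ax in AXES}
    n = comps["ap"].size
    if n < 4:
        raise InsufficientGaitError("segment contains too few samples")
    # re-centre on the integer-stride window so the cross term cancels exactly
    comps = {ax: c - c.mean() for ax, c in comps.items()}

    oe = {ax: float(np.sum(c * c)) / (2.0 * n) for ax, c in comps.items()}
    ke0 = 0.5 * vel.v_bar_ap ** 2
    toe = oe["ap"] + oe["ml"] + oe["vt"]

    full = np.column_stack([vel.v_bar_ap + comps["ap"], comps["ml"], comps["vt"]])
    ek_bar = float(np.sum(full * full)) / (2.0 * n)

    if ke0 == 0.0 and toe > 0.0:
        raise UndefinedRatioError("v̄_ap is zero with nonzero TOE: OEP undefined")
    oep = toe / ke0 if ke0 > 0 else 0.0
    if toe == 0.0:
        # no oscillatory motion at all: OEP is 0, EP shares are flagged undefined
        return EnergySummary(ke0=ke0, ape=0.0, mle=0.0, vte=0.0, toe=0.0,
                             ek_bar=ek_bar, oep=0.0, ep_ap_pct=0.0,
                             ep_ml_pct=0.0, ep_vt_pct=0.0, ep_defined=False)
    return EnergySummary(
        ke0=ke0, ape=oe["ap"], mle=oe["ml"], vte=oe["vt"], toe=toe,
        ek_bar=ek_bar, oep=oep,
        ep_ap_pct=100.0 * oe["ap"] / toe,
        ep_ml_pct=100.0 * oe["ml"] / toe,
        ep_vt_pct=100.0 * oe["vt"] / toe)


def oep_scaling(d_ref: float, oep_ref: float, oep_target: float) -> float:
    """Scale a BCOM peak-to-peak displacement between OEP levels.

    At fixed forward speed and step period, OEP is proportional to the
    square of the peak-to-peak BCOM displacement, so
    ``d_target = d_ref · sqrt(oep_target / oep_ref)``.
    """
    if min(d_ref, oep_ref, oep_target) <= 0:
        raise ParameterError("oep_scaling inputs must all be positive")
    return d_ref * float(np.sqrt(oep_target / oep_ref))


def oscillatory_velocity_estimate(d_pp: float, step_period: float) -> float:
    """Approximate mean oscillatory speed for a peak-to-peak excursion d_pp.

    The BCOM travels the excursion out and back once per step, hence
    ``~2·d_pp / T``.  For a sinusoid this round-trip rule is exact: the mean
    |velocity| is (d_pp/2)·(2π/T)·(2/π) = 2·d_pp/T (the peak is π·d_pp/T).
    """
    if d_pp < 0 or step_period <= 0:
        raise ParameterError("d_pp must be >= 0 and step_period > 0")
    return 2.0 * d_pp / step_period


@dataclass
class StrideTrajectory:
    """BCOM displacement folded onto a single stride (phase-averaged)."""

    time: np.ndarray  # seconds within one stride, [0, stride_period)
    ml: np.ndarray    # metres
    vt: np.ndarray
    ap: np.ndarray    # oscillatory AP component only


def trajectory_frontal_plane(disp: DisplacementSignal, segment: GaitSegment,
                             n_points: int = 200) -> StrideTrajectory:
    """Fold the displacement onto one stride and average across strides.

    Stride boundaries come from the segment's step events (every second
    step).  The healthy pattern in the frontal (ML, VT) plane is the bow-tie:
    the VT axis completes two cycles per ML cycle, so the parametric curve
    self-intersects.
    """
    if segment.n_periods < 4:
        raise InsufficientGaitError("trajectory fold needs >= 4 strides")
    phase = np.arange(n_points) / n_points
    bounds = segment.stride_boundaries()
    folded = {ax: [] for ax in AXES}
    for a, b in zip(bounds[:-1], bounds[1:]):
        grid = a + phase * (b - a)
        for ax in AXES:
            folded[ax].append(np.interp(grid, disp.t, disp.component(ax)))
    mean = {ax: np.mean(folded[ax], axis=0) for ax in AXES}
    mean = {ax: v - v.mean() for ax, v in mean.items()}  # zero-mean over the stride
    return StrideTrajectory(time=phase * segment.stride_period,
                            ml=mean["ml"], vt=mean["vt"], ap=mean["ap"])


def ep_graph_coordinates(summary: EnergySummary):
    """EP-graph point (x = MLE%, y = APE%) and its iso-VTE% contour level.

    Every point lies on exactly one iso-VTE% diagonal, x + y = 100 − VTE%.
    Returns ``(point, vte_level)``.
    """
    if summary.toe <= 0:
        raise UndefinedRatioError("EP-graph point undefined for TOE == 0")
    point = (summary.ep_ml_pct, summary.ep_ap_pct)
    return point, 100.0 - point[0] - point[1]


def iso_vte_contour(level: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Endpoints of the iso-VTE% contour x + y = 100 − level in the first quadrant."""
    if not 0.0 <= level <= 100.0:
        raise ParameterError("iso-VTE% level must be in [0, 100]")
    c = 100.0 - level
    return (0.0, c), (c, 0.0)


def classify_ep_region(summary: EnergySummary) -> tuple[str, list[str]]:
    """Healthy-region test on the EP graph.

    Typical gait satisfies (strictly) VTE% > 40, MLE% < 35 and APE% < 50;
    otherwise the gait is labelled atypical and the violated bounds are
    listed.  Boundary values count as violations (strict inequalities).
    """
    if not summary.ep_defined:
        raise UndefinedRatioError("EP region undefined for TOE == 0")
    violated: list[str] = []
    if not summary.ep_vt_pct > EP_REGION_BOUNDS["vte_pct_min"]:
        violated.append("VTE% <= 40")
    if not summary.ep_ml_pct < EP_REGION_BOUNDS["mle_pct_max"]:
        violated.append("MLE% >= 35")
    if not summary.ep_ap_pct < EP_REGION_BOUNDS["ape_pct_max"]:
        violated.append("APE% >= 50")
    return ("typical" if not violated else "atypical", violated)
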