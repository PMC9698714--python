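"""Figures: the EP graph and the frontal-plane BCOM trajectory."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .energetics import EP_REGION_BOUNDS, StrideTrajectory, iso_vte_contour


def plot_ep_graph(points, labels=None, ax=None, show_region=True):
    """EP graph: x = MLE%, y = APE%, dotted diagonal iso-VTE% contours.

    ``points`` is a sequence of (mle_pct, ape_pct) pairs.  Any point's
    VTE% is readable as 100 − x − y from the contour it sits on.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for level in range(0, 100, 10):
        (x0, y0), (x1, y1) = iso_vte_contour(level)
        ax.plot([x0, x1], [y0, y1], ls=":", lw=0.8, color="0.6", zorder=1)
        ax.annotate(f"{level}%", xy=((x1 + 2), 1), fontsize=7, color="0.5")
    if show_region:
        # healthy region: VTE% > 40, MLE% < 35, APE% < 50
        mle_max = EP_REGION_BOUNDS["mle_pct_max"]
        ape_max = EP_REGION_BOUNDS["ape_pct_max"]
        vte_min = EP_REGION_BOUNDS["vte_pct_min"]
        xs = np.linspace(0, mle_max, 50)
        ys = np.minimum(ape_max, 100 - vte_min - xs)
        ax.fill_between(xs, 0, ys, where=ys > 0, alpha=0.12, color="tab:green",
                        label="typical region")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ax.scatter(pts[:, 0], pts[:, 1], zorder=3, color="tab:blue")
    if labels is not None:
        for (x, y), lab in zip(pts, labels):
            ax.annotate(str(lab), xy=(x, y), xytext=(3, 3),
                        textcoords="offset points", fontsize=8)
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.set_xlabel("MLE (%)")
    ax.set_ylabel("APE (%)")
    ax.set_title("Energy partition")
    ax.set_aspect("equal")
    return ax


def plot_frontal_trajectory(traj: StrideTrajectory, ax=None):
    """Stride-averaged BCOM path in the frontal (ML, VT) plane, in cm."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ml = np.append(traj.ml, traj.ml[0]) * 100.0
    vt = np.append(traj.vt, traj.vt[0]) * 100.0
    ax.plot(ml, vt, lw=1.5)
    ax.set_xlabel("ML displacement (cm)")
    ax.set_ylabel("VT displacement (cm)")
    ax.set_title("BCOM frontal-plane trajectory (one stride)")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_aspect("equal")
    return ax
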