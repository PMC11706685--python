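"""Figure-style outputs: posture plots, CI-coloured plots, circular histograms."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402


def posture_plot(centerlines, ax=None, color="tab:green", alpha=0.7):
    """Overlay root centerlines with every basal point at (0, 0)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for cl in centerlines:
        pts = cl.points - cl.points[0]
        ax.plot(pts[:, 0], pts[:, 1], color=color, alpha=alpha, lw=0.8)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    return ax


def ci_colored_plot(centerlines, profiles, ax=None, vmax=50.0, cmap="viridis"):
    """Posture plot coloured by the smoothed CI (shared colour scale).

    ``vmax`` defaults to the 50 1/cm threshold so rare sharp bends
    saturate the scale.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    norm = plt.Normalize(vmin=0.0, vmax=vmax)
    mappable = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    for cl, pr in zip(centerlines, profiles):
        pts = cl.points - cl.points[0]
        kappa = pr.kappa
        segs = np.stack([pts[:-1], pts[1:]], axis=1)
        from matplotlib.collections import LineCollection

        lc = LineCollection(segs, cmap=cmap, norm=norm, lw=1.0)
        lc.set_array(0.5 * (kappa[:-1] + kappa[1:]))
        ax.add_collection(lc)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    plt.colorbar(mappable, ax=ax, label="CI (cm$^{-1}$)")
    return ax


def circular_histogram(summary, ax=None, color="tab:blue"):
    """Polar histogram of tip angles in fixed-width classes.

    0 deg is horizontal (to the right) and +90 deg points straight down,
    matching the tip-angle sign convention.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4), subplot_kw={"projection": "polar"})
    edges = np.radians(summary.class_edges)
    widths = np.diff(edges)
    # +angle toward gravity (down): flip so downward appears at the bottom
    ax.set_theta_zero_location("E")
    ax.set_theta_direction(-1)
    ax.bar(
        edges[:-1] + widths / 2,
        summary.histogram,
        width=widths,
        color=color,
        alpha=0.8,
        edgecolor="black",
        lw=0.5,
    )
    ax.set_title(
        f"{summary.group}: {summary.mean_deg:.1f} ± {summary.sd_deg:.1f}° (n={summary.n})",
        fontsize=9,
    )
    return ax
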