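"""Root-tip bending angles for gravistimulation assays.

The tip angle is measured between the horizontal plane and the root-tip
direction: 0 deg is horizontal, +90 deg is parallel to gravity
(straight down).  The tip direction is the secant from the centerline
point a fixed arc length before the tip (the tip window, default
0.05 cm) to the tip itself -- a reproducible surrogate for the manual
angle tool.  Summaries use 20 deg classes anchored at 0 deg and
arithmetic mean +/- sample SD, which is appropriate while angles stay
far from the +/-180 deg wrap; a circular-statistics option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, TooShortError
from .geometry import ResampledCenterline
from .indices import perp
from .traces import DEFAULT_GRAVITY

DEFAULT_TIP_WINDOW_CM = 0.05
DEFAULT_CLASS_WIDTH_DEG = 20.0


@dataclass
class TipAngleResult:
    root_id: str
    group: str
    angle_deg: float
    tip_window_cm: float


@dataclass
class AngleSummary:
    group: str
    n: int
    mean_deg: float
    sd_deg: float
    class_edges: np.ndarray
    histogram: np.ndarray  # counts per class over (-180, 180]


def _normalize_deg(a: float) -> float:
    """Map to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    if a == -180.0:
        a = 180.0
    return a


def tip_angle(
    centerline: ResampledCenterline,
    gravity_direction: np.ndarray = DEFAULT_GRAVITY,
    tip_window_cm: float = DEFAULT_TIP_WINDOW_CM,
) -> TipAngleResult:
    """Signed tip angle to the horizontal, positive toward gravity."""
    if tip_window_cm <= 0:
        raise ParameterError("tip_window_cm must be positive")
    L = centerline.total_length_L
    if L <= tip_window_cm:
        raise TooShortError(
            f"root {centerline.root_id!r}: length {L:.4f} cm <= tip window "
            f"{tip_window_cm} cm"
        )
    g = np.asarray(gravity_direction, dtype=float)
    arc = centerline.arc_pos
    target = L - tip_window_cm
    anchor = np.array(
        [np.interp(target, arc, centerline.points[:, 0]),
         np.interp(target, arc, centerline.points[:, 1])]
    )
    d = centerline.tip - anchor
    angle = float(np.degrees(np.arctan2(d @ g, d @ perp(g))))
    return TipAngleResult(
        root_id=centerline.root_id,
        group=centerline.group,
        angle_deg=_normalize_deg(angle),
        tip_window_cm=tip_window_cm,
    )


def bin_angles(
    results: list[TipAngleResult],
    class_width_deg: float = DEFAULT_CLASS_WIDTH_DEG,
    circular: bool = False,
) -> dict[str, AngleSummary]:
    """Per-group angle summary with fixed-width classes over (-180, 180].

    Classes are half-open ``[k*w, (k+1)*w)`` anchored at 0 deg; +180 deg
    falls in the last class.  ``circular=True`` switches the mean/SD to
    circular statistics.
    """
    if class_width_deg <= 0 or 360.0 % class_width_deg != 0:
        raise ParameterError("class_width_deg must divide 360")
    if not results:
        raise ParameterError("no tip-angle results to summarize")
    w = class_width_deg
    edges = np.arange(-180.0, 180.0 + w / 2, w)
    by_group: dict[str, list[float]] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r.angle_deg)
    out: dict[str, AngleSummary] = {}
    for group, angles in by_group.items():
        a = np.asarray(angles, dtype=float)
        idx = np.floor_divide(a, w).astype(int) + int(180 / w)
        idx = np.clip(idx, 0, len(edges) - 2)  # +180 deg into the last class
        hist = np.bincount(idx, minlength=len(edges) - 1)
        if circular:
            from scipy.stats import circmean, circstd

            mean = float(circmean(a, high=180.0, low=-180.0))
            sd = float(circstd(a, high=180.0, low=-180.0)) if a.size > 1 else float("nan")
        else:
            mean = float(a.mean())
            sd = float(a.std(ddof=1)) if a.size > 1 else float("nan")
        out[group] = AngleSummary(
            group=group,
            n=int(a.size),
            mean_deg=mean,
            sd_deg=sd,
            class_edges=edges,
            histogram=hist,
        )
    return out
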