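"""Per-root posture indices and curvature-index summaries.

Base-to-tip indices follow the growth-index conventions: with basal
point B, tip T and primary root length L,

* ``Ly`` -- displacement along gravity (positive = downward),
* ``Lx`` -- displacement along the horizontal (perpendicular to
  gravity, rightward positive),
* ``Lc`` -- Euclidean base-to-tip distance,
* ``VGI = Ly / L``, ``HGI = Lx / L``, ``SI = Lc / L``.

A perfectly straight root has SI = 1; SI = sqrt(HGI^2 + VGI^2) holds by
construction.  CI summaries per root are the 1%-trimmed mean (0.5%
lowest and highest values removed), the maximum, the count of dots above
a threshold (default 50 1/cm) and plain means within arc-length
compartments from the basal point (default 0.0-0.5, 0.5-1.0, >=1.0 cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, RootPostureError
from .geometry import CurvatureProfile, ResampledCenterline
from .traces import DEFAULT_GRAVITY

DEFAULT_CI_THRESHOLD = 50.0
DEFAULT_BREAKS = (0.5, 1.0)
DEFAULT_TRIM_FRACTION = 0.005


def perp(gravity_direction: np.ndarray) -> np.ndarray:
    """Horizontal unit vector; for gravity (0, -1) this is (1, 0)."""
    g = np.asarray(gravity_direction, dtype=float)
    return np.array([-g[1], g[0]])


@dataclass
class RootIndices:
    """Per-root summary row."""

    root_id: str
    group: str
    L: float
    Lx: float
    Ly: float
    Lc: float
    HGI: float
    VGI: float
    SI: float
    ci_mean: float = np.nan
    ci_max: float = np.nan
    n_exceed: int = 0
    compartment_means: dict = field(default_factory=dict)
    tip_angle_deg: float = np.nan

    def to_dict(self) -> dict:
        d = {
            "root_id": self.root_id,
            "group": self.group,
            "L": self.L,
            "Lx": self.Lx,
            "Ly": self.Ly,
            "Lc": self.Lc,
            "HGI": self.HGI,
            "VGI": self.VGI,
            "SI": self.SI,
            "ci_mean": self.ci_mean,
            "ci_max": self.ci_max,
            "n_exceed": self.n_exceed,
        }
        d.update(self.compartment_means)
        d["tip_angle_deg"] = self.tip_angle_deg
        return d


def base_tip_indices(
    centerline: ResampledCenterline,
    gravity_direction: np.ndarray = DEFAULT_GRAVITY,
) -> dict:
    """L, Lx, Ly, Lc and the ratios HGI, VGI, SI for one root."""
    g = np.asarray(gravity_direction, dtype=float)
    if abs(np.linalg.norm(g) - 1.0) > 1e-9:
        raise ParameterError("gravity_direction must have unit norm")
    L = centerline.total_length_L
    if L <= 0:
        raise RootPostureError(f"root {centerline.root_id!r}: zero length")
    d = centerline.tip - centerline.base
    Ly = float(d @ g)
    Lx = float(d @ perp(g))
    Lc = float(np.hypot(Lx, Ly))
    return {
        "L": L,
        "Lx": Lx,
        "Ly": Ly,
        "Lc": Lc,
        "HGI": Lx / L,
        "VGI": Ly / L,
        "SI": Lc / L,
    }


def trimmed_mean_ci(
    profile: CurvatureProfile,
    trim_fraction_each_side: float = DEFAULT_TRIM_FRACTION,
) -> float:
    """1%-trimmed mean CI: drop floor(n*frac) lowest and highest values.

    With fewer than ``1/frac`` valid dots the trim count floors to zero
    and this is the plain mean.
    """
    if not 0 <= trim_fraction_each_side < 0.5:
        raise ParameterError("trim_fraction_each_side must be in [0, 0.5)")
    vals = profile.valid_values()
    if vals.size == 0:
        raise RootPostureError(f"root {profile.root_id!r}: no valid CI values")
    k = int(np.floor(vals.size * trim_fraction_each_side))
    vals = np.sort(vals)
    if k > 0:
        vals = vals[k:-k]
    return float(vals.mean())


def count_exceed(
    profile: CurvatureProfile, threshold: float = DEFAULT_CI_THRESHOLD
) -> int:
    """Number of valid dots with CI strictly above the threshold."""
    return int((profile.valid_values() > threshold).sum())


def compartment_means(
    profile: CurvatureProfile,
    breaks: tuple[float, ...] = DEFAULT_BREAKS,
) -> dict[str, float]:
    """Plain mean CI in half-open arc-length bins from the basal point.

    Default bins [0, 0.5), [0.5, 1.0), [1.0, inf) cm.  Bins with no
    valid dots are reported as NaN (missing), not zero.
    """
    breaks = tuple(float(b) for b in breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])) or any(
        b <= 0 for b in breaks
    ):
        raise ParameterError("breaks must be positive and strictly increasing")
    edges = (0.0,) + breaks + (np.inf,)
    mask = (
        np.ones(profile.n_points, dtype=bool)
        if profile.valid_mask is None
        else profile.valid_mask
    )
    arc = profile.arc_pos
    kappa = profile.kappa
    out: dict[str, float] = {}
    for lo, hi in zip(edges, edges[1:]):
        sel = mask & (arc >= lo) & (arc < hi)
        label = f"ci_{lo:g}_{'inf' if np.isinf(hi) else f'{hi:g}'}"
        out[label] = float(kappa[sel].mean()) if sel.any() else float("nan")
    return out


def summarize_profile(
    centerline: ResampledCenterline,
    profile: CurvatureProfile,
    gravity_direction: np.ndarray = DEFAULT_GRAVITY,
    threshold: float = DEFAULT_CI_THRESHOLD,
    breaks: tuple[float, ...] = DEFAULT_BREAKS,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    tip_angle_deg: float = np.nan,
) -> RootIndices:
    """Assemble the full RootIndices row for one root."""
    bt = base_tip_indices(centerline, gravity_direction)
    vals = profile.valid_values()
    return RootIndices(
        root_id=centerline.root_id,
        group=centerline.group,
        ci_mean=trimmed_mean_ci(profile, trim_fraction),
        ci_max=float(vals.max()),
        n_exceed=count_exceed(profile, threshold),
        compartment_means=compartment_means(profile, breaks),
        tip_angle_deg=tip_angle_deg,
        **bt,
    )


def ci_distance_smoother(
    profiles: list[CurvatureProfile],
    family: str = "lowess",
    frac: float = 0.3,
    grid_n: int = 200,
) -> dict[str, pd.DataFrame]:
    """Smoothed CI-versus-distance curve per group.

    Pools the valid (arc_pos, CI) dots of every profile in a group and
    fits a local-regression smoother (LOWESS by default), evaluated on a
    uniform grid over the group's arc-length range.  A spline family
    (penalized regression on binned means) is available as
    ``family="spline"``.  Returns one DataFrame per group with columns
    ``arc_pos`` and ``ci``, plus the smoother family in ``df.attrs``.
    """
    if family not in ("lowess", "spline"):
        raise ParameterError("smoother family must be 'lowess' or 'spline'")
    by_group: dict[str, list[CurvatureProfile]] = {}
    for p in profiles:
        by_group.setdefault(p.group, []).append(p)
    out: dict[str, pd.DataFrame] = {}
    for group, plist in by_group.items():
        xs = np.concatenate(
            [p.arc_pos[p.valid_mask] if p.valid_mask is not None else p.arc_pos for p in plist]
        )
        ys = np.concatenate([p.valid_values() for p in plist])
        if xs.size == 0:
            import logging

            logging.getLogger(__name__).warning(
                "group %r has no valid CI dots; skipped", group
            )
            continue
        grid = np.linspace(xs.min(), xs.max(), grid_n)
        if family == "lowess":
            import statsmodels.api as sm

            fitted = sm.nonparametric.lowess(
                ys, xs, frac=frac, xvals=grid, return_sorted=False
            )
        else:
            from scipy.interpolate import make_smoothing_spline

            order = np.argsort(xs, kind="stable")
            xs_s, ys_s = xs[order], ys[order]
            # collapse duplicate abscissae (pooled profiles share arc grids)
            ux, inv = np.unique(np.round(xs_s, 9), return_inverse=True)
            sums = np.bincount(inv, weights=ys_s)
            cnts = np.bincount(inv)
            spl = make_smoothing_spline(ux, sums / cnts, lam=None)
            fitted = spl(grid)
        df = pd.DataFrame({"arc_pos": grid, "ci": fitted})
        df.attrs["smoother"] = family
        df.attrs["frac"] = frac
        out[group] = df
    return out
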