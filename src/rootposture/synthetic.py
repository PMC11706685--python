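"""Synthetic root centerlines with analytic ground truth.

Roots are grown along gravity with a lateral sinusoidal displacement
``x(t) = A sin(2 pi t / lambda)`` (optionally plus a second, shorter
wave), giving closed-form curvature ``kappa = |x''| / (1 + x'^2)^{3/2}``
and arc length by high-precision quadrature.  Archetypes encode the
phenotype contrast between large gradual waving and small sharp kinking;
an optional terminal bend (circular arc to a prescribed tip angle
followed by a short straight tip) supports gravitropism assays.

A digitizer model emulates manual marking of 100-450 dots along the
root: dots approximately uniform in arc length with a small spacing
jitter, plus isotropic Gaussian positional noise.  All randomness is
seeded; the same seed reproduces the same trace exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson, quad

from .errors import ParameterError
from .traces import RootTrace, TraceCollection

#: default positional click-noise SD, cm (~2 px at a typical scan resolution)
DEFAULT_JITTER_SD_CM = 0.002
#: default number of digitized dots per root (within the 100-450 range)
DEFAULT_N_POINTS = 250
#: bend radius of the optional terminal arc, cm
TIP_BEND_RADIUS_CM = 0.05
#: straight tip segment after the terminal arc, cm
TIP_STRAIGHT_CM = 0.1


@dataclass
class PhenotypeArchetype:
    """Parametric description of a synthetic root shape."""

    name: str
    amplitude_cm: float
    wavelength_cm: float
    length_cm: float
    amplitude2_cm: float = 0.0
    wavelength2_cm: float = 1.0
    tip_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude_cm < 0 or self.amplitude2_cm < 0:
            raise ParameterError("amplitude must be >= 0")
        if self.wavelength_cm <= 0 or self.wavelength2_cm <= 0:
            raise ParameterError("wavelength must be > 0")
        if self.length_cm <= 0:
            raise ParameterError("length must be > 0")

    def scaled(self, amplitude_factor: float) -> "PhenotypeArchetype":
        """Copy with both wave amplitudes multiplied by a factor."""
        return PhenotypeArchetype(
            name=self.name,
            amplitude_cm=self.amplitude_cm * amplitude_factor,
            wavelength_cm=self.wavelength_cm,
            length_cm=self.length_cm,
            amplitude2_cm=self.amplitude2_cm * amplitude_factor,
            wavelength2_cm=self.wavelength2_cm,
            tip_angle_deg=self.tip_angle_deg,
        )


def straight(length_cm: float = 2.0) -> PhenotypeArchetype:
    return PhenotypeArchetype("straight", 0.0, 1.0, length_cm)


def gradual_wave(
    amplitude_cm: float = 0.05, wavelength_cm: float = 0.5, length_cm: float = 2.0
) -> PhenotypeArchetype:
    """Large, gradual curves (peak kappa ~ 7.9 1/cm at defaults)."""
    return PhenotypeArchetype("gradual_wave", amplitude_cm, wavelength_cm, length_cm)


def sharp_wave(
    amplitude_cm: float = 0.02, wavelength_cm: float = 0.15, length_cm: float = 1.5
) -> PhenotypeArchetype:
    """Small, sharp curves (peak kappa ~ 35 1/cm at defaults)."""
    return PhenotypeArchetype("sharp_wave", amplitude_cm, wavelength_cm, length_cm)


def mixed(length_cm: float = 2.0) -> PhenotypeArchetype:
    """Gradual wave with a superimposed short sharp component."""
    return PhenotypeArchetype(
        "mixed", 0.05, 0.5, length_cm, amplitude2_cm=0.015, wavelength2_cm=0.15
    )


ARCHETYPES = {
    "straight": straight,
    "gradual_wave": gradual_wave,
    "sharp_wave": sharp_wave,
    "mixed": mixed,
}


@dataclass
class DigitizerModel:
    """Surrogate for manual dot marking along the root."""

    n_points: int = DEFAULT_N_POINTS
    jitter_sd_cm: float = DEFAULT_JITTER_SD_CM
    spacing_jitter_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ParameterError("n_points must be >= 3")
        if self.jitter_sd_cm < 0:
            raise ParameterError("jitter_sd_cm must be >= 0")
        if not 0 <= self.spacing_jitter_frac < 0.5:
            raise ParameterError("spacing_jitter_frac must be in [0, 0.5)")


@dataclass
class DenseCurve:
    """Densely sampled analytic centerline with ground truth attached."""

    points: np.ndarray
    arc_pos: np.ndarray
    kappa: np.ndarray
    truth: dict = field(default_factory=dict)

    @property
    def total_length(self) -> float:
        return float(self.arc_pos[-1])


def _wave_funcs(arch: PhenotypeArchetype):
    c1 = 2 * np.pi / arch.wavelength_cm
    c2 = 2 * np.pi / arch.wavelength2_cm
    A1, A2 = arch.amplitude_cm, arch.amplitude2_cm

    def x(t):
        return A1 * np.sin(c1 * t) + A2 * np.sin(c2 * t)

    def xp(t):
        return A1 * c1 * np.cos(c1 * t) + A2 * c2 * np.cos(c2 * t)

    def xpp(t):
        return -A1 * c1**2 * np.sin(c1 * t) - A2 * c2**2 * np.sin(c2 * t)

    def speed(t):
        return np.sqrt(1.0 + xp(t) ** 2)

    def kappa(t):
        return np.abs(xpp(t)) / (1.0 + xp(t) ** 2) ** 1.5

    return x, xp, xpp, speed, kappa


def make_curve(
    archetype: PhenotypeArchetype, points_per_cm: int = 10000
) -> DenseCurve:
    """Dense analytic centerline for an archetype, base at the origin.

    The wavy body is sampled at ``points_per_cm`` dots per axial cm with
    closed-form coordinates and curvature; its arc length comes from
    quadrature of the analytic speed.  If a terminal tip angle is
    requested, a circular arc (radius 0.05 cm) turns the tangent to that
    angle and a 0.1 cm straight tip follows, both with exact geometry.
    """
    x, xp, xpp, speed, kap = _wave_funcs(archetype)
    T = archetype.length_cm
    n = int(points_per_cm * T) + 1
    t = np.linspace(0.0, T, n)
    pts = np.column_stack([x(t), -t])
    kappas = kap(t)
    arc = cumulative_simpson(speed(t), x=t, initial=0.0)
    L_body, _ = quad(speed, 0.0, T, limit=500)
    arc = arc * (L_body / arc[-1])  # pin to the quadrature value

    segments = [(pts, arc, kappas)]
    L_total = L_body
    tip_dir = np.array([xp(T), -1.0])
    tip_dir = tip_dir / np.linalg.norm(tip_dir)

    if archetype.tip_angle_deg is not None:
        # angle convention: 0 = horizontal, +90 = straight down (y-up frame)
        theta_cur = np.arctan2(-tip_dir[1], tip_dir[0])  # angle below horizon
        theta_tgt = np.radians(archetype.tip_angle_deg)
        r = TIP_BEND_RADIUS_CM
        dth = theta_tgt - theta_cur
        m = max(int(abs(dth) * r * points_per_cm), 8)
        phis = np.linspace(0.0, dth, m + 1)[1:]
        thetas = theta_cur + phis
        start = pts[-1]
        sgn = 1.0 if dth >= 0 else -1.0
        # exact circular arc: dp/dtheta = r*sgn*(cos theta, -sin theta)
        arc_pts = start + r * sgn * np.column_stack(
            [
                np.sin(thetas) - np.sin(theta_cur),
                np.cos(thetas) - np.cos(theta_cur),
            ]
        )
        arc_len = arc[-1] + np.abs(phis) * r
        seg_kappa = np.full(m, 1.0 / r)
        segments.append((arc_pts, arc_len, seg_kappa))
        L_total += abs(dth) * r
        tip_dir = np.array([np.cos(theta_tgt), -np.sin(theta_tgt)])
        # straight tip
        s_straight = np.linspace(0.0, TIP_STRAIGHT_CM, max(int(TIP_STRAIGHT_CM * points_per_cm), 4) + 1)[1:]
        straight_pts = arc_pts[-1] + np.outer(s_straight, tip_dir)
        segments.append(
            (straight_pts, arc_len[-1] + s_straight, np.zeros(s_straight.size))
        )
        L_total += TIP_STRAIGHT_CM

    pts_all = np.vstack([s[0] for s in segments])
    arc_all = np.concatenate([s[1] for s in segments])
    kap_all = np.concatenate([s[2] for s in segments])

    d = pts_all[-1] - pts_all[0]
    Lx, Ly = float(d[0]), float(-d[1])  # Ly positive downward
    Lc = float(np.hypot(Lx, Ly))
    num, _ = quad(lambda u: kap(u) * speed(u), 0.0, T, limit=800)
    kappa_ds = num  # integral of kappa over arc length, wavy body
    if archetype.tip_angle_deg is not None:
        kappa_ds += abs(dth)  # arc contributes |delta theta| exactly
    truth = {
        "L": L_total,
        "Lx": Lx,
        "Ly": Ly,
        "Lc": Lc,
        "SI": Lc / L_total,
        "HGI": Lx / L_total,
        "VGI": Ly / L_total,
        "mean_abs_kappa": kappa_ds / L_total,
        "max_kappa": float(kap_all.max()),
        "tip_angle_deg": float(np.degrees(np.arctan2(-tip_dir[1], tip_dir[0]))),
        "archetype": archetype.name,
    }
    return DenseCurve(points=pts_all, arc_pos=arc_all, kappa=kap_all, truth=truth)


def digitize(
    curve: DenseCurve,
    model: DigitizerModel,
    root_id: str = "synthetic",
    group: str = "",
) -> RootTrace:
    """Emulate manual dot marking of a dense curve.

    Dots are placed approximately uniformly in arc length with a uniform
    spacing jitter (endpoints pinned), then displaced by isotropic
    Gaussian noise of SD ``jitter_sd_cm``.  Deterministic for a fixed
    model seed.
    """
    n = model.n_points
    if n > curve.arc_pos.size:
        raise ParameterError(
            f"n_points={n} exceeds the dense curve resolution {curve.arc_pos.size}"
        )
    rng = np.random.default_rng(model.seed)
    L = curve.total_length
    targets = np.linspace(0.0, L, n)
    if model.spacing_jitter_frac > 0:
        step = L / (n - 1)
        targets = targets + rng.uniform(
            -model.spacing_jitter_frac * step, model.spacing_jitter_frac * step, n
        )
        targets = np.sort(np.clip(targets, 0.0, L))
        targets[0], targets[-1] = 0.0, L
    pts = np.column_stack(
        [
            np.interp(targets, curve.arc_pos, curve.points[:, 0]),
            np.interp(targets, curve.arc_pos, curve.points[:, 1]),
        ]
    )
    if model.jitter_sd_cm > 0:
        pts = pts + rng.normal(0.0, model.jitter_sd_cm, pts.shape)
    # collapse any coincidental duplicates introduced by jitter
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 0.0])
    return RootTrace(root_id=root_id, points=pts[keep], group=group)


def make_cohort(
    archetypes: dict[str, PhenotypeArchetype],
    n_per_group: int,
    model: DigitizerModel | None = None,
    seed: int = 0,
    amplitude_cv: float = 0.1,
    matched_factors: bool = False,
) -> tuple[TraceCollection, pd.DataFrame]:
    """Labelled multi-group collection plus per-root ground truth.

    Each root's wave amplitude is multiplied by a lognormal factor of
    coefficient of variation ``amplitude_cv`` to create within-group
    spread.  With ``matched_factors=True`` the same factor sequence is
    used in every group (a matched design: groups then have identical
    per-root analytic SI whenever their archetypes share the slope
    profile).  Returns the trace collection and a truth table with
    analytic L, SI, mean and max curvature per root.
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    if not archetypes:
        raise ParameterError("need at least one group archetype")
    model = model if model is not None else DigitizerModel()
    ss = np.random.SeedSequence(seed)
    factor_seed, *group_seeds = ss.spawn(len(archetypes) + 1)
    factor_rng = np.random.default_rng(factor_seed)
    shared = (
        np.exp(factor_rng.normal(0.0, amplitude_cv, n_per_group))
        if amplitude_cv > 0
        else np.ones(n_per_group)
    )
    traces: list[RootTrace] = []
    rows: list[dict] = []
    for (group, arch), gseed in zip(archetypes.items(), group_seeds):
        grng = np.random.default_rng(gseed)
        if matched_factors or amplitude_cv == 0:
            factors = shared
        else:
            factors = np.exp(grng.normal(0.0, amplitude_cv, n_per_group))
        child_seeds = gseed.spawn(n_per_group)
        for i in range(n_per_group):
            curve = make_curve(arch.scaled(float(factors[i])))
            dig_seed = int(child_seeds[i].generate_state(1)[0] % (2**31))
            m = DigitizerModel(
                n_points=model.n_points,
                jitter_sd_cm=model.jitter_sd_cm,
                spacing_jitter_frac=model.spacing_jitter_frac,
                seed=dig_seed,
            )
            rid = f"{group}_{i:03d}"
            traces.append(digitize(curve, m, root_id=rid, group=group))
            rows.append({"root_id": rid, "group": group, **curve.truth})
    coll = TraceCollection(
        traces=traces,
        provenance={"generator": "rootposture.synthetic", "seed": seed},
    )
    return coll, pd.DataFrame(rows)


def contrast_cohorts(
    n_per_group: int = 30,
    model: DigitizerModel | None = None,
    seed: int = 0,
    amplitude_cv: float = 0.1,
) -> tuple[TraceCollection, pd.DataFrame]:
    """Two cohorts with equal analytic SI but 4x different mean curvature.

    Both groups are sinusoids with the same slope amplitude
    ``2 pi A / lambda`` over an integer number of periods, so their
    analytic SI is identical root-for-root (matched amplitude factors),
    while the sharp group's wavelength is 4x shorter, scaling curvature
    by 4.  The gradual group's peak curvature stays well below the
    50 1/cm threshold and the sharp group's peaks exceed it.
    """
    grad = PhenotypeArchetype("gradual", 0.1, 0.5, 2.0)
    sharp = PhenotypeArchetype("sharp", 0.025, 0.125, 2.0)
    return make_cohort(
        {"gradual": grad, "sharp": sharp},
        n_per_group=n_per_group,
        model=model,
        seed=seed,
        amplitude_cv=amplitude_cv,
        matched_factors=True,
    )
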