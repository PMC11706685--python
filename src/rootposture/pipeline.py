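"""Batch measurement: traces in, per-root indices and profiles out.

Roots that fail a precondition (too short to trim, degenerate) are
reported and skipped, never silently dropped; the skip count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import RunConfig
from .errors import RootPostureError
from .geometry import (
    CurvatureProfile,
    ResampledCenterline,
    compute_curvature,
    resample_spline,
)
from .gravitropism import tip_angle
from .indices import RootIndices, summarize_profile
from .traces import TraceCollection

logger = logging.getLogger(__name__)


@dataclass
class MeasureResult:
    indices: list[RootIndices]
    centerlines: list[ResampledCenterline]
    profiles: list[CurvatureProfile]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame([ri.to_dict() for ri in self.indices])

    def profiles_frame(self) -> pd.DataFrame:
        return pd.concat([p.to_frame() for p in self.profiles], ignore_index=True)


def measure_collection(
    collection: TraceCollection, config: RunConfig | None = None
) -> MeasureResult:
    """Run the full measurement pipeline over a trace collection."""
    cfg = config if config is not None else RunConfig()
    gravity = cfg.gravity_vec
    out = MeasureResult(indices=[], centerlines=[], profiles=[])
    for trace in collection:
        try:
            _, profile = compute_curvature(
                trace,
                density=cfg.density,
                half_window_cm=cfg.half_window_cm,
                n_trim=cfg.n_trim,
                smoothing=cfg.smoothing,
                tau=cfg.tau,
                denominator=cfg.curvature_denominator,
            )
            # length/posture geometry from the lighter discrepancy fit
            centerline = resample_spline(
                trace,
                density=cfg.density,
                smoothing=cfg.smoothing,
                tau=cfg.tau_geometry,
            )
            try:
                angle = tip_angle(centerline, gravity, cfg.tip_window_cm).angle_deg
            except RootPostureError:
                angle = float("nan")
            ri = summarize_profile(
                centerline,
                profile,
                gravity_direction=gravity,
                threshold=cfg.threshold,
                breaks=cfg.breaks,
                trim_fraction=cfg.trim_fraction,
                tip_angle_deg=angle,
            )
        except RootPostureError as exc:
            logger.warning("skipping root %s: %s", trace.root_id, exc)
            out.skipped.append((trace.root_id, str(exc)))
            continue
        out.indices.append(ri)
        out.centerlines.append(centerline)
        out.profiles.append(profile)
    if out.skipped:
        logger.warning("skipped %d of %d roots", len(out.skipped), len(collection))
    return out
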