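"""Run configuration shared by the CLI subcommands.

Defaults are the protocol values used throughout the package: 1,000
dots per cm resampling density, 0.005 cm moving-average half window,
20-dot end trim, 50 1/cm CI threshold, compartment breaks at 0.5 and
1.0 cm, 0.5% trim per side for the mean CI, 0.05 cm tip window, 20 deg
angle classes and alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    density: float = 1000.0
    half_window_cm: float = 0.005
    n_trim: int = 20
    threshold: float = 50.0
    breaks: tuple[float, ...] = (0.5, 1.0)
    trim_fraction: float = 0.005
    tip_window_cm: float = 0.05
    class_width_deg: float = 20.0
    alpha: float = 0.05
    gravity: tuple[float, float] = (0.0, -1.0)
    scale_cm_per_unit: float = 1.0
    seed: int = 0
    smoothing: str | float = "auto"
    tau: float = 1.5
    tau_geometry: float = 1.0
    curvature_denominator: str = "mean_chord"
    smoother_family: str = "lowess"
    smoother_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ParameterError("density must be positive")
        if self.half_window_cm < 0:
            raise ParameterError("half_window_cm must be non-negative")
        if self.n_trim < 0:
            raise ParameterError("n_trim must be non-negative")
        if not 0 <= self.trim_fraction < 0.5:
            raise ParameterError("trim_fraction must be in [0, 0.5)")
        if self.tip_window_cm <= 0:
            raise ParameterError("tip_window_cm must be positive")
        if self.class_width_deg <= 0 or 360.0 % self.class_width_deg != 0:
            raise ParameterError("class_width_deg must divide 360")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        g = np.asarray(self.gravity, dtype=float)
        if abs(np.linalg.norm(g) - 1.0) > 1e-9:
            raise ParameterError("gravity must be a unit vector")
        self.breaks = tuple(float(b) for b in self.breaks)
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ParameterError("breaks must be strictly increasing")
        if self.scale_cm_per_unit <= 0:
            raise ParameterError("scale_cm_per_unit must be positive")
        if self.curvature_denominator not in ("mean_chord", "endpoint_chord"):
            raise ParameterError("invalid curvature_denominator")

    @property
    def gravity_vec(self) -> np.ndarray:
        return np.asarray(self.gravity, dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("breaks", "gravity"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)
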