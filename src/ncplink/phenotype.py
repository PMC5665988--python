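"""Culture-based utilities: specific growth rates and diatom biovolumes.

Growth rates come from log-linear regression of in-vivo chlorophyll a
fluorescence during exponential phase; biovolumes use the standard
geometric models (cylinder for centric diatoms, elliptic prism for
pennates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GrowthSeries",
    "specific_growth_rate",
    "biovolume_cylinder",
    "biovolume_elliptic_prism",
    "log10_volume_ratio",
]

TREATMENTS = ("+FeSL", "-FeSL", "+FeLL", "-FeLL")


@dataclass
class GrowthSeries:
    """Fluorescence time course for one isolate x treatment x replicate."""

    times: np.ndarray          # days
    fluorescence: np.ndarray   # relative units, > 0
    isolate: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.size != self.fluorescence.size or self.times.size < 3:
            raise ValueError("need >= 3 matched (time, fluorescence) points")
        if np.any(self.fluorescence <= 0):
            raise ValueError("fluorescence must be strictly positive")


def specific_growth_rate(series: GrowthSeries) -> tuple[float, float]:
    """Slope of ln(fluorescence) vs time, in day-1, with its standard error."""
    if np.ptp(series.times) < 2.0:
        raise ValueError("time points must span at least 2 days")
    res = stats.linregress(series.times, np.log(series.fluorescence))
    return float(res.slope), float(res.stderr)


def biovolume_cylinder(diameter: float, height: float) -> float:
    """Cylinder volume pi (d/2)^2 h, um^3 — centric diatom model."""
    if diameter <= 0 or height <= 0:
        raise ValueError("dimensions must be positive")
    return math.pi * (diameter / 2.0) ** 2 * height


def biovolume_elliptic_prism(apical_length: float, transapical_width: float,
                             pervalvar_height: float) -> float:
    """Elliptic prism volume (pi/4) AL TW PH, um^3 — pennate diatom model."""
    if min(apical_length, transapical_width, pervalvar_height) <= 0:
        raise ValueError("dimensions must be positive")
    return math.pi / 4.0 * apical_length * transapical_width * pervalvar_height


def log10_volume_ratio(volume_a: float, volume_b: float) -> float:
    """Order-of-magnitude size contrast between two isolates."""
    if volume_a <= 0 or volume_b <= 0:
        raise ValueError("volumes must be positive")
    return math.log10(volume_a / volume_b)
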