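"""β-galactosidase (Miller unit) and promoter-activity calculations.

Endpoint assays: Miller units = (1000 × OD420) / (volume_mL × OD600 ×
reaction_time_min).  Kinetic assays follow color development over time and
use the regression slope instead of a single endpoint: Miller units =
(1000 × slope) / (volume_mL × OD600).  Promoter activity is the product of
LacZ activity and the culture's maximum doubling rate, which corrects
expression level for dilution by growth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BetaGalEndpoint",
    "BetaGalKinetic",
    "PromoterActivity",
    "miller_endpoint",
    "miller_kinetic",
    "promoter_activity",
]

_VOLUME_TO_ML = {"mL": 1.0, "ml": 1.0, "uL": 1e-3, "µL": 1e-3, "ul": 1e-3}


def _volume_ml(volume: float, unit: str) -> float:
    try:
        factor = _VOLUME_TO_ML[unit]
    except KeyError:
        raise ValueError(
            f"unknown volume unit {unit!r}; tag volumes explicitly ({sorted(set(_VOLUME_TO_ML))})"
        )
    return volume * factor


@dataclass
class BetaGalEndpoint:
    """One endpoint β-Gal reading.  Volumes must carry a unit tag."""

    od420: float
    od600: float
    volume: float
    reaction_time: float  # minutes
    volume_unit: str = "mL"

    def __post_init__(self) -> None:
        if self.od600 <= 0:
            raise ValueError("od600 must be positive")
        if self.reaction_time <= 0:
            raise ValueError("reaction_time must be positive")
        self.volume_ml = _volume_ml(self.volume, self.volume_unit)
        if self.volume_ml <= 0:
            raise ValueError("volume must be positive")


@dataclass
class BetaGalKinetic:
    """A kinetic β-Gal series: OD420 followed over time (minutes)."""

    times: np.ndarray
    od420_series: np.ndarray
    od600: float
    volume: float
    volume_unit: str = "mL"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od420_series = np.asarray(self.od420_series, dtype=float)
        if self.times.size < 3 or self.times.shape != self.od420_series.shape:
            raise ValueError("need >= 3 aligned time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.od600 <= 0:
            raise ValueError("od600 must be positive")
        self.volume_ml = _volume_ml(self.volume, self.volume_unit)
        if self.volume_ml <= 0:
            raise ValueError("volume must be positive")


@dataclass
class PromoterActivity:
    miller: float
    doubling_rate: float  # doublings/hr
    activity: float       # Miller · doublings/hr


def miller_endpoint(a: BetaGalEndpoint) -> float:
    """Miller units from a single stopped reaction."""
    return 1000.0 * a.od420 / (a.volume_ml * a.od600 * a.reaction_time)


def miller_kinetic(a: BetaGalKinetic) -> float:
    """Miller units from the slope of OD420 color development over time."""
    slope = stats.linregress(a.times, a.od420_series).slope
    if slope < 0:
        warnings.warn(f"negative color-development slope ({slope:.4g}/min)")
    return 1000.0 * slope / (a.volume_ml * a.od600)


def promoter_activity(
    miller: float,
    doubling_rate: float,
    rate_unit: str = "doublings_per_hr",
) -> PromoterActivity:
    """Promoter activity = LacZ activity × maximum doubling rate.

    ``rate_unit`` accepts ``"doublings_per_hr"`` (default) or ``"per_hr"``
    (a Malthusian rate μ, converted by μ/ln 2).  The two conventions differ
    only by the constant ln 2, which cancels in all between-strain ratios.
    """
    if miller < 0 or doubling_rate < 0:
        raise ValueError("inputs must be nonnegative")
    if rate_unit == "per_hr":
        doubling_rate = doubling_rate / math.log(2)
    elif rate_unit != "doublings_per_hr":
        raise ValueError(f"unknown rate unit {rate_unit!r}")
    return PromoterActivity(
        miller=miller,
        doubling_rate=doubling_rate,
        activity=miller * doubling_rate,
    )
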