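"""Habitat classification, change accounting and density summaries.

Turns per-reach suitability P into three-class habitat maps (unsuitable /
moderately / highly suitable), stream-length tallies, present-vs-future
stable/new/lost accounting, and kernel-density curves of suitability and of
the elevation of suitable reaches.

Class boundaries follow the convention: unsuitable P < MTP, moderately
suitable MTP <= P < 0.5, highly suitable P >= 0.5.  Change percentages use
the present-suitable total as denominator for stable, lost AND new (so
stable + lost = 100% exactly); the union denominator is available via
``denominator="union"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_UNSUITABLE",
    "CLASS_MODERATE",
    "CLASS_HIGH",
    "HabitatClassMap",
    "ChangeSummary",
    "DensityConfig",
    "mtp_threshold",
    "classify_suitability",
    "suitable_length_km",
    "change_analysis",
    "gaussian_kde_curve",
    "suitability_density",
    "elevation_density",
]

CLASS_UNSUITABLE = "unsuitable"
CLASS_MODERATE = "moderate"
CLASS_HIGH = "high"
_CLASSES = (CLASS_UNSUITABLE, CLASS_MODERATE, CLASS_HIGH)


@dataclass
class HabitatClassMap:
    """Per-reach habitat class with the threshold that produced it."""

    classes: pd.Series          # reach_id -> class label
    mtp: float
    scenario: str = "present"

    def suitable_ids(self) -> pd.Index:
        return self.classes.index[self.classes.isin([CLASS_MODERATE, CLASS_HIGH])]

    def counts(self) -> dict[str, int]:
        c = self.classes.value_counts()
        return {k: int(c.get(k, 0)) for k in _CLASSES}


@dataclass
class ChangeSummary:
    stable_km: float
    lost_km: float
    new_km: float
    stable_pct: float
    lost_pct: float
    new_pct: float
    scenario_pair: str = ""
    denominator: str = "present"

    def as_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class DensityConfig:
    bandwidth: float
    grid: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 512))

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        self.grid = np.asarray(self.grid, dtype=float)


def mtp_threshold(training_suitabilities) -> float:
    """Minimum training presence: lowest P over training presences."""
    s = np.asarray(training_suitabilities, dtype=float)
    if s.size == 0:
        raise ValueError("no training suitabilities")
    return float(s.min())


def classify_suitability(
    p: pd.Series, mtp: float, scenario: str = "present"
) -> HabitatClassMap:
    """Three classes: P < mtp, mtp <= P < 0.5, P >= 0.5."""
    if not 0 < mtp < 0.5:
        raise ValueError("mtp must lie in (0, 0.5)")
    v = p.to_numpy(dtype=float)
    labels = np.where(v >= 0.5, CLASS_HIGH,
                      np.where(v >= mtp, CLASS_MODERATE, CLASS_UNSUITABLE))
    return HabitatClassMap(
        classes=pd.Series(labels, index=p.index, name="habitat_class"),
        mtp=mtp, scenario=scenario,
    )


def suitable_length_km(
    class_map: HabitatClassMap, reach_lengths_m: pd.Series
) -> dict[str, float]:
    """Summed reach length (km) per class, plus 'suitable' = moderate + high."""
    lengths = reach_lengths_m.reindex(class_map.classes.index)
    out = {}
    for cls in _CLASSES:
        sel = class_map.classes == cls
        out[cls] = float(lengths[sel].sum()) / 1000.0
    out["suitable"] = out[CLASS_MODERATE] + out[CLASS_HIGH]
    return out


def change_analysis(
    present: HabitatClassMap,
    future: HabitatClassMap,
    reach_lengths_m: pd.Series,
    denominator: str = "present",
) -> ChangeSummary:
    """Stable/new/lost suitable habitat between two periods.

    stable = suitable in both, lost = present only, new = future only.
    Percentages are relative to the present-suitable total (default) or the
    union of suitable reaches.
    """
    if not present.classes.index.equals(future.classes.index):
        raise ValueError("present and future maps cover different reaches")
    if denominator not in ("present", "union"):
        raise ValueError("denominator must be 'present' or 'union'")
    pres = set(present.suitable_ids())
    fut = set(future.suitable_ids())
    km = lambda ids: float(reach_lengths_m.loc[sorted(ids)].sum()) / 1000.0
    stable_km = km(pres & fut)
    lost_km = km(pres - fut)
    new_km = km(fut - pres)
    denom_km = km(pres) if denominator == "present" else km(pres | fut)
    pct = lambda v: 100.0 * v / denom_km if denom_km > 0 else 0.0
    return ChangeSummary(
        stable_km=stable_km, lost_km=lost_km, new_km=new_km,
        stable_pct=pct(stable_km), lost_pct=pct(lost_km), new_pct=pct(new_km),
        scenario_pair=f"{present.scenario}->{future.scenario}",
        denominator=denominator,
    )


def gaussian_kde_curve(values, config: DensityConfig) -> pd.DataFrame:
    """Fixed-bandwidth Gaussian KDE evaluated on the config grid.

    Plain kernel sum (each kernel integrates to 1), so the curve integrates
    to ~1 wherever the grid covers the mass.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values for density estimation")
    x = config.grid
    h = config.bandwidth
    z = (x[None, :] - v[:, None]) / h
    dens = np.exp(-0.5 * z ** 2).sum(axis=0) / (v.size * h * np.sqrt(2 * np.pi))
    return pd.DataFrame({"x": x, "density": dens})


def suitability_density(p: pd.Series, config: DensityConfig) -> pd.DataFrame:
    """Density of per-reach suitability values."""
    if len(p) == 0:
        raise ValueError("empty suitability map")
    return gaussian_kde_curve(p.to_numpy(dtype=float), config)


def elevation_density(
    p: pd.Series,
    elevations_m: pd.Series,
    threshold: float,
    config: DensityConfig,
) -> pd.DataFrame:
    """Density of elevations of reaches with P > threshold."""
    sel = p > threshold
    elev = elevations_m.reindex(p.index)[sel].to_numpy(dtype=float)
    if elev.size == 0:
        warnings.warn("no suitable reaches above threshold; empty density")
        return pd.DataFrame({"x": config.grid, "density": np.zeros_like(config.grid)})
    return gaussian_kde_curve(elev, config)
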