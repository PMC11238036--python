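"""Bioclimatic predictors from monthly climate.

Derives the 19 standard bioclimatic summaries (annual means, extremes,
seasonality, quarter aggregates) plus 8 "hydroclimatic" variants of the
precipitation variables (bio12h-bio19h) computed from catchment-averaged
rather than local precipitation, and assembles the per-reach predictor table
that feeds habitat modelling.

Conventions, stated because implementations differ:

* temperature seasonality (bio4) is the population standard deviation of
  monthly mean temperature x 100;
* precipitation seasonality (bio15) is 100 x sd(prcp) / (1 + bio12/12);
* quarters are all 12 wrap-around 3-month windows (Dec-Jan-Feb included),
  ties broken by the earliest window;
* hydroclimatic wettest/driest quarters are selected on the
  catchment-averaged series itself, warmest/coldest on reach-local
  temperature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .climate import MonthlyClimate
from .streams import (
    FlowGrid,
    StreamNetwork,
    delineate_catchment,
    flow_accumulate_weights,
)

__all__ = [
    "bioclim19",
    "catchment_mean",
    "hydroclim8",
    "BIOCLIM_NAMES",
    "HYDROCLIM_NAMES",
    "reach_predictor_table",
]

BIOCLIM_NAMES = [f"bio{i}" for i in range(1, 20)]
HYDROCLIM_NAMES = [f"bio{i}h" for i in range(12, 20)]


def _as_months_last(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape[-1] != 12:
        raise ValueError(f"{name} must have 12 monthly values on the last axis")
    return arr


def _quarter_stats(series: np.ndarray, how: str) -> np.ndarray:
    """All 12 wrap-around 3-month window aggregates, window axis last."""
    windows = []
    for w in range(12):
        idx = [w, (w + 1) % 12, (w + 2) % 12]
        block = series[..., idx]
        windows.append(block.sum(-1) if how == "sum" else block.mean(-1))
    return np.stack(windows, axis=-1)


def bioclim19(tmin, tmax, prcp) -> dict[str, np.ndarray]:
    """The 19 standard bioclimatic variables.

    Inputs are arrays with months on the last axis (shape ``(..., 12)``);
    outputs are arrays of the leading shape.  Scalars come back as 0-d
    arrays.
    """
    tmin = _as_months_last(tmin, "tmin")
    tmax = _as_months_last(tmax, "tmax")
    prcp = _as_months_last(prcp, "prcp")
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin in some month")
    tmean = (tmin + tmax) / 2.0

    out: dict[str, np.ndarray] = {}
    out["bio1"] = tmean.mean(-1)
    out["bio2"] = (tmax - tmin).mean(-1)
    out["bio4"] = tmean.std(-1) * 100.0  # population sd
    out["bio5"] = tmax.max(-1)
    out["bio6"] = tmin.min(-1)
    out["bio7"] = out["bio5"] - out["bio6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["bio3"] = np.where(out["bio7"] != 0,
                               out["bio2"] / out["bio7"] * 100.0, 0.0)

    q_tmean = _quarter_stats(tmean, "mean")
    q_prcp = _quarter_stats(prcp, "sum")
    wettest = q_prcp.argmax(-1)
    driest = q_prcp.argmin(-1)
    warmest = q_tmean.argmax(-1)
    coldest = q_tmean.argmin(-1)

    take = np.take_along_axis
    out["bio8"] = take(q_tmean, wettest[..., None], -1)[..., 0]
    out["bio9"] = take(q_tmean, driest[..., None], -1)[..., 0]
    out["bio10"] = take(q_tmean, warmest[..., None], -1)[..., 0]
    out["bio11"] = take(q_tmean, coldest[..., None], -1)[..., 0]

    out["bio12"] = prcp.sum(-1)
    out["bio13"] = prcp.max(-1)
    out["bio14"] = prcp.min(-1)
    out["bio15"] = 100.0 * prcp.std(-1) / (1.0 + out["bio12"] / 12.0)
    out["bio16"] = take(q_prcp, wettest[..., None], -1)[..., 0]
    out["bio17"] = take(q_prcp, driest[..., None], -1)[..., 0]
    out["bio18"] = take(q_prcp, warmest[..., None], -1)[..., 0]
    out["bio19"] = take(q_prcp, coldest[..., None], -1)[..., 0]
    return {k: out[k] for k in BIOCLIM_NAMES}


def catchment_mean(prcp_grid: np.ndarray, catchment: set[tuple[int, int]]) -> float:
    """Mean of a grid over a catchment cell set, NaN cells excluded."""
    if not catchment:
        raise ValueError("empty catchment")
    vals = np.array([prcp_grid[r, c] for r, c in catchment], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("catchment contains no valid cells")
    return float(vals.mean())


def hydroclim8(catchment_prcp, tmin, tmax) -> dict[str, np.ndarray]:
    """bio12h-bio19h from a catchment-averaged precipitation series.

    ``catchment_prcp`` has months on the last axis; temperature-dependent
    quarters (bio18h/bio19h) use the reach-local tmin/tmax series.
    """
    p = _as_months_last(catchment_prcp, "catchment_prcp")
    tmin = _as_months_last(tmin, "tmin")
    tmax = _as_months_last(tmax, "tmax")
    tmean = (tmin + tmax) / 2.0
    q_p = _quarter_stats(p, "sum")
    q_t = _quarter_stats(tmean, "mean")
    wettest = q_p.argmax(-1)
    driest = q_p.argmin(-1)
    warmest = q_t.argmax(-1)
    coldest = q_t.argmin(-1)
    take = np.take_along_axis
    out = {
        "bio12h": p.sum(-1),
        "bio13h": p.max(-1),
        "bio14h": p.min(-1),
        "bio16h": take(q_p, wettest[..., None], -1)[..., 0],
        "bio17h": take(q_p, driest[..., None], -1)[..., 0],
        "bio18h": take(q_p, warmest[..., None], -1)[..., 0],
        "bio19h": take(q_p, coldest[..., None], -1)[..., 0],
    }
    out["bio15h"] = 100.0 * p.std(-1) / (1.0 + out["bio12h"] / 12.0)
    return {k: out[k] for k in HYDROCLIM_NAMES}


def reach_predictor_table(
    network: StreamNetwork,
    climate: MonthlyClimate,
    flow: FlowGrid,
    catchments: dict[int, set[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Geophysical + bioclimatic + hydroclimatic predictors per reach.

    Climate series are read at each reach's midpoint cell.  Hydroclimatic
    precipitation is the mean over the reach catchment: by default computed
    in one topological pass (accumulated precipitation / accumulated cell
    count at the reach's most-downstream cell — equivalent to enumerating
    the catchment); pass explicit ``catchments`` to average over given cell
    sets instead.  Returns a reach_id-indexed frame — the single modelling
    input table.
    """
    if climate.shape != flow.shape:
        raise ValueError("climate and flow grids misaligned")
    if flow.accumulation is None:
        raise ValueError("flow accumulation required")
    geo = network.to_dataframe().set_index("reach_id")
    if catchments is None:
        prcp_acc = np.stack([
            flow_accumulate_weights(flow, climate.prcp[m]) for m in range(12)
        ])
    rows = {}
    for rid in sorted(network.reaches):
        reach = network.reaches[rid]
        r, c = reach.midpoint_cell
        tmin = climate.tmin[:, r, c]
        tmax = climate.tmax[:, r, c]
        prcp = climate.prcp[:, r, c]
        rec = {k: float(v) for k, v in bioclim19(tmin, tmax, prcp).items()}
        if catchments is not None:
            catch = catchments[rid]
            cp = np.array([
                catchment_mean(climate.prcp[m], catch) for m in range(12)
            ])
        else:
            dr, dc = reach.anchor_cells[-1]  # most-downstream cell of the reach
            cp = prcp_acc[:, dr, dc] / flow.accumulation[dr, dc]
        rec.update({k: float(v) for k, v in hydroclim8(cp, tmin, tmax).items()})
        mx, my = reach.midpoint
        rec["x"], rec["y"] = float(mx), float(my)
        rows[rid] = rec
    clim = pd.DataFrame.from_dict(rows, orient="index")
    clim.index.name = "reach_id"
    return geo.join(clim)
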