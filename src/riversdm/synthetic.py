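"""Synthetic landscapes with known ground truth.

Generates everything the pipeline needs without downloads: a drainable DEM,
coarse and fine monthly climate surfaces with point "station" samples, future
scenarios as parametric deltas, and presence records sampled from a known
suitability function.  Every generator is a pure function of (config, seed);
the master seed is expanded into fixed per-stage substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .climate import MonthlyClimate
from .grids import ElevationGrid, RasterGrid

__all__ = [
    "SyntheticWorldConfig",
    "TrueNiche",
    "NicheResponse",
    "ScenarioDelta",
    "make_dem",
    "make_monthly_climate",
    "apply_scenario",
    "true_suitability",
    "sample_presences",
]

# fixed substream keys so stages are independent of call order
_STAGE_KEYS = {"dem": 11, "climate": 23, "stations": 37, "presences": 53}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS[stage],))
    )


@dataclass
class SyntheticWorldConfig:
    """Parameters of a synthetic study landscape."""

    grid_rows: int = 64
    grid_cols: int = 64
    cell_size: float = 100.0                # metres
    seed: int = 0
    relief_amplitude: float = 80.0          # metres (sd of smoothed relief)
    regional_slope: float = 0.01            # dz per metre of x
    lapse_rate: float = 6.5                 # degC per km of elevation
    seasonal_temp_amplitude: float = 6.0    # degC
    annual_precip_base: float = 1200.0      # mm
    precip_orographic_factor: float = 400.0  # mm per km of elevation
    station_count: int = 15
    coarse_factor: int = 4
    sea_level_tmean: float = 15.0           # degC annual mean at elevation 0
    diurnal_half_range: float = 5.0         # degC, (tmax - tmin)/2 before noise
    temp_noise_sd: float = 0.3              # degC
    precip_noise_frac: float = 0.05         # multiplicative sd
    relief_smooth_cells: float = 8.0

    def __post_init__(self) -> None:
        if self.grid_rows < 16 or self.grid_cols < 16:
            raise ValueError("grid must be at least 16x16")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.coarse_factor < 1 or self.grid_rows % self.coarse_factor or \
                self.grid_cols % self.coarse_factor:
            raise ValueError("coarse_factor must divide grid dimensions")
        if self.station_count < 10:
            raise ValueError("need at least 10 stations")

    def to_text(self) -> str:
        return "".join(f"{k}: {v}\n" for k, v in vars(self).items())

    @classmethod
    def from_text(cls, text: str) -> "SyntheticWorldConfig":
        defaults = cls()
        kwargs = {}
        for line in text.strip().splitlines():
            k, v = (s.strip() for s in line.split(":", 1))
            kwargs[k] = type(getattr(defaults, k))(v)
        return cls(**kwargs)


@dataclass
class NicheResponse:
    predictor: str
    optimum: float
    breadth: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.breadth <= 0:
            raise ValueError("breadth must be positive")


@dataclass
class TrueNiche:
    """Known suitability surface: logistic of a quadratic penalty.

    suitability = expit(baseline - sum_k w_k ((x_k - opt_k)/breadth_k)^2)
    """

    responses: list[NicheResponse]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("niche needs at least one predictor response")


@dataclass
class ScenarioDelta:
    """Additive temperature / multiplicative precipitation climate delta."""

    delta_t: float
    precip_scale: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.precip_scale <= 0:
            raise ValueError("precip_scale must be positive")


def make_dem(config: SyntheticWorldConfig) -> ElevationGrid:
    """Regional slope plane plus Gaussian-smoothed random relief.

    Elevation increases with x at ``regional_slope``; relief is white noise
    smoothed over ~relief_smooth_cells cells and scaled to standard deviation
    ``relief_amplitude``.  The result drains to the boundary after sink
    filling.
    """
    rng = _rng(config.seed, "dem")
    rows, cols = config.grid_rows, config.grid_cols
    x = (np.arange(cols) + 0.5) * config.cell_size
    plane = config.regional_slope * np.broadcast_to(x, (rows, cols)).copy()
    if config.relief_amplitude > 0:
        noise = rng.standard_normal((rows, cols))
        relief = ndimage.gaussian_filter(noise, sigma=config.relief_smooth_cells,
                                         mode="reflect")
        sd = relief.std()
        if sd > 0:
            relief = relief / sd * config.relief_amplitude
        plane = plane + relief
    plane -= plane.min()  # keep elevations non-negative
    return ElevationGrid(values=plane, cell_size=config.cell_size)


def _block_mean(arr: np.ndarray, f: int) -> np.ndarray:
    """Aggregate the trailing two axes by f x f block means."""
    *lead, r, c = arr.shape
    return arr.reshape(*lead, r // f, f, c // f, f).mean(axis=(-3, -1))


def make_monthly_climate(
    dem: ElevationGrid, config: SyntheticWorldConfig
) -> tuple[MonthlyClimate, MonthlyClimate, pd.DataFrame]:
    """Fine monthly climate, its coarse aggregation, and station samples.

    Temperature = sea-level seasonal sinusoid (summer peak in January,
    southern hemisphere) minus lapse_rate x elevation, plus Gaussian noise;
    precipitation = winter-peaked seasonal base plus an orographic term,
    with multiplicative noise, floored at 0.  The coarse stack is the
    block-mean aggregation by coarse_factor; stations are exact fine-grid
    values at station_count distinct random cells.
    """
    rng = _rng(config.seed, "climate")
    elev = dem.values
    months = np.arange(12)
    season = np.cos(2 * np.pi * months / 12.0)  # +1 in Jan (austral summer)
    tmean_sea = config.sea_level_tmean + config.seasonal_temp_amplitude * season
    lapse = config.lapse_rate * elev / 1000.0   # degC
    tmin = (tmean_sea[:, None, None] - config.diurnal_half_range
            - lapse[None, :, :]
            + rng.normal(0.0, config.temp_noise_sd, (12,) + elev.shape))
    tmax = (tmean_sea[:, None, None] + config.diurnal_half_range
            - lapse[None, :, :]
            + rng.normal(0.0, config.temp_noise_sd, (12,) + elev.shape))
    # guard tmax > tmin (noise sd << diurnal range, so this rarely triggers)
    bad = tmax <= tmin
    if bad.any():
        mid = (tmax + tmin) / 2.0
        tmax = np.where(bad, mid + 0.1, tmax)
        tmin = np.where(bad, mid - 0.1, tmin)

    monthly_base = config.annual_precip_base / 12.0
    wet_season = 1.0 + 0.8 * np.cos(2 * np.pi * (months - 6) / 12.0)  # July peak
    oro = config.precip_orographic_factor * elev / 1000.0 / 12.0
    prcp = (monthly_base * wet_season[:, None, None] + oro[None, :, :])
    prcp = prcp * (1.0 + rng.normal(0.0, config.precip_noise_frac,
                                    (12,) + elev.shape))
    prcp = np.maximum(prcp, 0.0)

    fine = MonthlyClimate(tmin=tmin, tmax=tmax, prcp=prcp,
                          cell_size=config.cell_size, origin=dem.origin,
                          resolution="fine")
    f = config.coarse_factor
    coarse = MonthlyClimate(
        tmin=_block_mean(tmin, f), tmax=_block_mean(tmax, f),
        prcp=_block_mean(prcp, f),
        cell_size=config.cell_size * f, origin=dem.origin,
        resolution="coarse",
    )

    srng = _rng(config.seed, "stations")
    n_cells = elev.size
    flat = srng.choice(n_cells, size=config.station_count, replace=False)
    rows_idx, cols_idx = np.unravel_index(flat, elev.shape)
    grid = RasterGrid(elev, config.cell_size, dem.origin)
    records = []
    for sid, (r, c) in enumerate(zip(rows_idx, cols_idx)):
        xx, yy = grid.cell_center(int(r), int(c))
        for var, stack in (("tmin", tmin), ("tmax", tmax), ("prcp", prcp)):
            for m in range(12):
                records.append((sid, xx, yy, var, m + 1, float(stack[m, r, c])))
    stations = pd.DataFrame(
        records, columns=["station_id", "x", "y", "variable", "month", "value"]
    )
    return fine, coarse, stations


def apply_scenario(climate: MonthlyClimate, delta: ScenarioDelta) -> MonthlyClimate:
    """Shift temperatures by delta_t and scale precipitation by precip_scale."""
    return MonthlyClimate(
        tmin=climate.tmin + delta.delta_t,
        tmax=climate.tmax + delta.delta_t,
        prcp=climate.prcp * delta.precip_scale,
        cell_size=climate.cell_size,
        origin=climate.origin,
        resolution=climate.resolution,
    )


def true_suitability(predictors: pd.DataFrame, niche: TrueNiche) -> pd.Series:
    """Known suitability in [0, 1] for each row of a predictor table."""
    penalty = np.zeros(len(predictors), dtype=float)
    for resp in niche.responses:
        if resp.predictor not in predictors.columns:
            raise KeyError(f"predictor '{resp.predictor}' missing from table")
        x = predictors[resp.predictor].to_numpy(dtype=float)
        penalty += resp.weight * ((x - resp.optimum) / resp.breadth) ** 2
    s = expit(niche.baseline - penalty)
    return pd.Series(s, index=predictors.index, name="suitability")


def sample_presences(
    reach_suitability: pd.Series,
    n: int,
    seed: int,
    midpoints: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw n presence reaches, probability proportional to suitability.

    Sampling is without replacement (one record per reach, mimicking
    filtered occurrence data).  If ``midpoints`` (reach_id-indexed, columns
    x/y) is given, occurrences carry the reach midpoint coordinate.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    s = reach_suitability[reach_suitability > 0]
    if len(s) == 0:
        raise ValueError("no reach has positive suitability")
    if n > len(s):
        raise ValueError(
            f"requested {n} presences but only {len(s)} reaches have "
            "positive suitability"
        )
    rng = _rng(seed, "presences")
    ids = np.asarray(s.index)
    p = s.to_numpy(dtype=float)
    chosen = rng.choice(ids, size=n, replace=False, p=p / p.sum())
    out = pd.DataFrame({"reach_id": chosen})
    if midpoints is not None:
        out = out.join(midpoints[["x", "y"]], on="reach_id")
    return out
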