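"""Statistical climate downscaling: GWR on elevation + ordinary kriging.

Coarse monthly climate is regressed locally on coarse elevation with a
Gaussian spatial kernel (geographically weighted regression); the local
intercept/slope surfaces are interpolated to the fine grid by ordinary
kriging under an automatically fitted variogram, and the fine prediction is
``intercept + slope * fine_elevation``.  Station records, when given, apply a
kriged-residual correction so the output matches stations exactly at their
cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .climate import MonthlyClimate
from .grids import RasterGrid

__all__ = [
    "GwrFit",
    "VariogramModel",
    "gwr_fit",
    "select_bandwidth",
    "fit_variogram",
    "krige_surface",
    "krige_points",
    "kriging_weights",
    "station_correction",
    "downscale_predict",
    "downscale_surface",
    "downscale_climate",
]


@dataclass
class GwrFit:
    """Local intercept/slope per sample point from a Gaussian-kernel GWR."""

    coords: np.ndarray        # (n, 2)
    intercept: np.ndarray     # (n,)
    slope: np.ndarray         # response units per metre of elevation
    bandwidth: float          # metres
    fallback: np.ndarray      # bool: local design singular, mean used


@dataclass
class VariogramModel:
    """Semivariogram gamma(h) of a chosen family."""

    family: str               # spherical | exponential | gaussian
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self) -> None:
        if self.family not in ("spherical", "exponential", "gaussian"):
            raise ValueError(f"unknown variogram family '{self.family}'")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("variogram parameters out of range")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        n, s, r = self.nugget, self.partial_sill, self.range_
        if self.family == "spherical":
            hr = np.minimum(h / r, 1.0)
            g = s * (1.5 * hr - 0.5 * hr ** 3)
        elif self.family == "exponential":
            g = s * (1.0 - np.exp(-3.0 * h / r))
        else:
            g = s * (1.0 - np.exp(-3.0 * (h / r) ** 2))
        return np.where(h > 0, n + g, 0.0)


def _grid_coords(grid: RasterGrid) -> np.ndarray:
    gx, gy = grid.cell_centers()
    return np.column_stack([gx.ravel(), gy.ravel()])


def gwr_fit(
    response: RasterGrid, predictor_elev: RasterGrid, bandwidth: float
) -> GwrFit:
    """Locally weighted regression of response on elevation at each cell.

    Kernel weights w = exp(-0.5 (d / bandwidth)^2) over cell-centre
    distances.  Where the local elevation is effectively constant the design
    is singular; those cells fall back to the local weighted mean with zero
    slope and are flagged.
    """
    if response.shape != predictor_elev.shape:
        raise ValueError("response and predictor grids misaligned")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    coords = _grid_coords(response)
    y = response.values.ravel()
    e = predictor_elev.values.ravel()
    n = len(y)
    intercept = np.empty(n)
    slope = np.empty(n)
    fallback = np.zeros(n, dtype=bool)
    for i in range(n):
        d2 = ((coords - coords[i]) ** 2).sum(axis=1)
        w = np.exp(-0.5 * d2 / bandwidth ** 2)
        sw = w.sum()
        em = (w * e).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (e - em) ** 2).sum()
        if sxx <= 1e-10 * sw * max(1.0, em ** 2):
            intercept[i], slope[i] = ym, 0.0
            fallback[i] = True
        else:
            b = (w * (e - em) * (y - ym)).sum() / sxx
            slope[i] = b
            intercept[i] = ym - b * em
    return GwrFit(coords=coords, intercept=intercept, slope=slope,
                  bandwidth=bandwidth, fallback=fallback)


def select_bandwidth(
    response: RasterGrid,
    predictor_elev: RasterGrid,
    candidate_bandwidths: list[float],
) -> float:
    """Leave-one-out CV over candidate bandwidths; ties go to the smallest."""
    if not candidate_bandwidths:
        raise ValueError("no candidate bandwidths")
    if len(candidate_bandwidths) == 1:
        return float(candidate_bandwidths[0])
    coords = _grid_coords(response)
    y = response.values.ravel()
    e = predictor_elev.values.ravel()
    n = len(y)
    best_bw, best_score = None, np.inf
    for bw in sorted(float(b) for b in candidate_bandwidths):
        sse = 0.0
        for i in range(n):
            d2 = ((coords - coords[i]) ** 2).sum(axis=1)
            w = np.exp(-0.5 * d2 / bw ** 2)
            w[i] = 0.0
            sw = w.sum()
            if sw <= 0:
                sse = np.inf
                break
            em = (w * e).sum() / sw
            ym = (w * y).sum() / sw
            sxx = (w * (e - em) ** 2).sum()
            if sxx <= 1e-10 * sw * max(1.0, em ** 2):
                pred = ym
            else:
                b = (w * (e - em) * (y - ym)).sum() / sxx
                pred = ym + b * (e[i] - em)
            sse += (y[i] - pred) ** 2
        if sse < best_score - 1e-12:  # strict improvement; ties keep smaller bw
            best_score, best_bw = sse, bw
    return float(best_bw)


def _empirical_variogram(
    coords: np.ndarray, values: np.ndarray, n_bins: int = 12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned semivariance: (bin centres, gamma, pair counts)."""
    diff = coords[:, None, :] - coords[None, :, :]
    h = np.sqrt((diff ** 2).sum(axis=-1))
    iu = np.triu_indices(len(values), k=1)
    hp = h[iu]
    gp = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    span = coords.max(axis=0) - coords.min(axis=0)
    hmax = 0.5 * float(np.hypot(*span))
    if hmax <= 0:
        hmax = float(hp.max()) or 1.0
    edges = np.linspace(0.0, hmax, n_bins + 1)
    centres, gamma, counts = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (hp > a) & (hp <= b)
        if sel.any():
            centres.append(0.5 * (a + b))
            gamma.append(float(gp[sel].mean()))
            counts.append(int(sel.sum()))
    return np.asarray(centres), np.asarray(gamma), np.asarray(counts)


def fit_variogram(coords: np.ndarray, values: np.ndarray) -> VariogramModel:
    """Automatic variogram: best of spherical/exponential/gaussian by WLS.

    Empirical semivariance in 12 equal-width distance bins up to half the
    domain diagonal; fits weighted by pair counts.  An all-constant sample
    yields a degenerate pure-nugget model with zero sill.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 samples to fit a variogram")
    if np.ptp(values) == 0:
        span = coords.max(axis=0) - coords.min(axis=0)
        r = max(float(np.hypot(*span)) / 4.0, 1e-6)
        return VariogramModel("exponential", 0.0, 0.0, r)
    centres, gamma, counts = _empirical_variogram(coords, values)
    var = float(values.var())
    hmax = float(centres.max())
    best: tuple[float, VariogramModel] | None = None
    for family in ("spherical", "exponential", "gaussian"):
        def resid(p):
            m = VariogramModel(family, p[0], p[1], p[2])
            return np.sqrt(counts) * (m(centres) - gamma)

        x0 = np.array([0.1 * var + 1e-12, max(var, 1e-12), max(hmax / 2, 1e-6)])
        try:
            sol = least_squares(
                resid, x0,
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, 2 * hmax]),
            )
        except Exception:
            continue
        model = VariogramModel(family, float(sol.x[0]), float(sol.x[1]),
                               float(sol.x[2]))
        score = float((sol.fun ** 2).sum())
        if best is None or score < best[0]:
            best = (score, model)
    if best is None:
        return VariogramModel("exponential", 0.0, var, max(hmax / 2, 1e-6))
    return best[1]


def _dedup(coords: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "v": values})
    g = df.groupby(["x", "y"], sort=True, as_index=False)["v"].mean()
    if len(g) < len(df):
        warnings.warn("duplicate sample coordinates averaged before kriging")
    return g[["x", "y"]].to_numpy(), g["v"].to_numpy()


def _krige_system(coords: np.ndarray, variogram: VariogramModel) -> np.ndarray:
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    h = np.sqrt((diff ** 2).sum(axis=-1))
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = variogram(h)
    K[:n, n] = 1.0
    K[n, :n] = 1.0
    K[n, n] = 0.0
    return K


def kriging_weights(
    sample_coords: np.ndarray,
    variogram: VariogramModel,
    targets: np.ndarray,
) -> np.ndarray:
    """Ordinary-kriging weights, one row per target; rows sum to 1."""
    sample_coords = np.asarray(sample_coords, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(sample_coords)
    K = _krige_system(sample_coords, variogram)
    d = np.sqrt(((targets[:, None, :] - sample_coords[None, :, :]) ** 2).sum(-1))
    rhs = np.empty((n + 1, len(targets)))
    rhs[:n] = variogram(d).T
    rhs[n] = 1.0
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
    return sol[:n].T


def krige_points(
    sample_coords: np.ndarray,
    sample_values: np.ndarray,
    variogram: VariogramModel,
    targets: np.ndarray,
) -> np.ndarray:
    """Ordinary-kriging prediction at arbitrary target points."""
    sample_coords = np.asarray(sample_coords, dtype=float)
    sample_values = np.asarray(sample_values, dtype=float)
    if len(sample_coords) < 3:
        raise ValueError("need at least 3 samples to krige")
    sample_coords, sample_values = _dedup(sample_coords, sample_values)
    if variogram.nugget + variogram.partial_sill <= 0:
        # degenerate: constant field
        return np.full(len(np.atleast_2d(targets)), sample_values.mean())
    w = kriging_weights(sample_coords, variogram, targets)
    return w @ sample_values


def krige_surface(
    sample_coords: np.ndarray,
    sample_values: np.ndarray,
    variogram: VariogramModel,
    target: RasterGrid,
) -> RasterGrid:
    """Krige samples onto every cell of a target grid."""
    pts = _grid_coords(target)
    vals = krige_points(sample_coords, sample_values, variogram, pts)
    return target.like(vals.reshape(target.shape))


def downscale_predict(
    intercept_fine: RasterGrid,
    slope_fine: RasterGrid,
    fine_elev: RasterGrid,
    floor_zero: bool = False,
) -> RasterGrid:
    """fine value = intercept + slope * fine elevation (optionally >= 0)."""
    if intercept_fine.shape != fine_elev.shape or slope_fine.shape != fine_elev.shape:
        raise ValueError("coefficient and elevation grids misaligned")
    vals = intercept_fine.values + slope_fine.values * fine_elev.values
    if floor_zero:
        vals = np.maximum(vals, 0.0)
    return fine_elev.like(vals)


def downscale_surface(
    response_coarse: RasterGrid,
    elev_coarse: RasterGrid,
    elev_fine: RasterGrid,
    bandwidth: float,
    floor_zero: bool = False,
) -> RasterGrid:
    """One-variable downscaling: GWR fit, kriged coefficients, prediction."""
    fit = gwr_fit(response_coarse, elev_coarse, bandwidth)
    vg_i = fit_variogram(fit.coords, fit.intercept)
    vg_s = fit_variogram(fit.coords, fit.slope)
    intercept_fine = krige_surface(fit.coords, fit.intercept, vg_i, elev_fine)
    slope_fine = krige_surface(fit.coords, fit.slope, vg_s, elev_fine)
    return downscale_predict(intercept_fine, slope_fine, elev_fine, floor_zero)


def station_correction(
    downscaled: RasterGrid,
    stations: pd.DataFrame,
    floor_zero: bool = False,
) -> RasterGrid:
    """Add a kriged surface of station residuals.

    ``stations`` columns: x, y, value.  Stations outside the grid are dropped
    with a warning.  The corrected surface equals station values exactly at
    station cells (station coordinates snap to their cell centre).
    """
    rows = []
    for _, rec in stations.iterrows():
        try:
            r, c = downscaled.index_of(rec["x"], rec["y"])
        except IndexError:
            warnings.warn(f"station at ({rec['x']}, {rec['y']}) outside grid; dropped")
            continue
        cx, cy = downscaled.cell_center(r, c)
        rows.append((cx, cy, rec["value"] - downscaled.values[r, c]))
    if len(rows) < 3:
        raise ValueError("need at least 3 in-grid stations")
    coords = np.array([(x, y) for x, y, _ in rows])
    resid = np.array([v for _, _, v in rows])
    if np.allclose(resid, 0.0):
        return downscaled.copy()
    if len(resid) >= 10 and np.ptp(resid) > 0:
        vg = fit_variogram(coords, resid)
    else:
        span = coords.max(axis=0) - coords.min(axis=0)
        vg = VariogramModel("exponential", 0.0,
                            max(float(resid.var()), 1e-12),
                            max(float(np.hypot(*span)) / 4.0, 1e-6))
    if vg.nugget + vg.partial_sill <= 0:
        vg = VariogramModel("exponential", 0.0,
                            max(float(resid.var()), 1e-12), vg.range_)
    surf = krige_surface(coords, resid, vg, downscaled)
    vals = downscaled.values + surf.values
    if floor_zero:
        vals = np.maximum(vals, 0.0)
    return downscaled.like(vals)


def downscale_climate(
    coarse: MonthlyClimate,
    elev_coarse: RasterGrid,
    elev_fine: RasterGrid,
    bandwidth: float,
    stations: pd.DataFrame | None = None,
) -> MonthlyClimate:
    """Downscale all 36 monthly surfaces independently.

    ``stations``, if given, is the long table (station_id, x, y, variable,
    month, value).  After independent tmin/tmax downscaling any cell with
    tmax < tmin has both replaced by their midpoint +/- 0.1 degC.
    """
    out = {}
    for var, floor in (("tmin", False), ("tmax", False), ("prcp", True)):
        stack = getattr(coarse, var)
        fine_stack = np.empty((12,) + elev_fine.shape)
        for m in range(12):
            rg = RasterGrid(stack[m], coarse.cell_size, coarse.origin)
            surf = downscale_surface(rg, elev_coarse, elev_fine, bandwidth,
                                     floor_zero=floor)
            if stations is not None:
                st = stations[(stations["variable"] == var)
                              & (stations["month"] == m + 1)]
                if len(st) >= 3:
                    surf = station_correction(
                        surf,
                        st.rename(columns={})[["x", "y", "value"]],
                        floor_zero=floor,
                    )
            fine_stack[m] = surf.values
        out[var] = fine_stack
    tmin, tmax = out["tmin"], out["tmax"]
    bad = tmax < tmin
    if bad.any():
        warnings.warn(f"{int(bad.sum())} cell-months with tmax < tmin repaired")
        mid = (tmin + tmax) / 2.0
        tmin = np.where(bad, mid - 0.1, tmin)
        tmax = np.where(bad, mid + 0.1, tmax)
    return MonthlyClimate(tmin=tmin, tmax=tmax, prcp=out["prcp"],
                          cell_size=elev_fine.cell_size, origin=elev_fine.origin,
                          resolution="fine")
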