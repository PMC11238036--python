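"""Monthly climate stacks shared by the synthetic generator and downscaling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyClimate",
    "station_table_columns",
    "write_climate_csv",
    "read_climate_csv",
]

station_table_columns = ["station_id", "x", "y", "variable", "month", "value"]


@dataclass
class MonthlyClimate:
    """12-layer tmin/tmax/prcp stacks on a common grid.

    Arrays have shape (12, n_rows, n_cols); tmax >= tmin cellwise and
    precipitation is non-negative.
    """

    tmin: np.ndarray
    tmax: np.ndarray
    prcp: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    resolution: str = "fine"

    def __post_init__(self) -> None:
        for name in ("tmin", "tmax", "prcp"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 3 or arr.shape[0] != 12:
                raise ValueError(f"{name} must have shape (12, rows, cols)")
            setattr(self, name, arr)
        if self.tmin.shape != self.tmax.shape or self.tmin.shape != self.prcp.shape:
            raise ValueError("tmin/tmax/prcp shapes differ")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin at some cell/month")
        if np.any(self.prcp < 0):
            raise ValueError("negative precipitation")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tmin.shape[1:]

    def tmean(self) -> np.ndarray:
        return (self.tmin + self.tmax) / 2.0

    def at_cell(self, row: int, col: int) -> pd.DataFrame:
        """Monthly series at one cell as a (month x variable) frame."""
        return pd.DataFrame({
            "month": np.arange(1, 13),
            "tmin": self.tmin[:, row, col],
            "tmax": self.tmax[:, row, col],
            "prcp": self.prcp[:, row, col],
        })


def write_climate_csv(climate: MonthlyClimate, path) -> None:
    """Long-format CSV: month, row, col, tmin, tmax, prcp (plus grid header)."""
    nr, nc = climate.shape
    month, row, col = np.meshgrid(
        np.arange(1, 13), np.arange(nr), np.arange(nc), indexing="ij"
    )
    df = pd.DataFrame({
        "month": month.ravel(), "row": row.ravel(), "col": col.ravel(),
        "tmin": climate.tmin.ravel(), "tmax": climate.tmax.ravel(),
        "prcp": climate.prcp.ravel(),
    })
    with open(path, "w") as fh:
        fh.write(f"# cell_size={climate.cell_size} origin_x={climate.origin[0]} "
                 f"origin_y={climate.origin[1]} resolution={climate.resolution}\n")
        df.to_csv(fh, index=False)


def read_climate_csv(path) -> MonthlyClimate:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(item.split("=") for item in header)
        df = pd.read_csv(fh)
    nr = int(df["row"].max()) + 1
    nc = int(df["col"].max()) + 1
    stacks = {}
    df = df.sort_values(["month", "row", "col"])
    for var in ("tmin", "tmax", "prcp"):
        stacks[var] = df[var].to_numpy().reshape(12, nr, nc)
    return MonthlyClimate(
        cell_size=float(meta["cell_size"]),
        origin=(float(meta["origin_x"]), float(meta["origin_y"])),
        resolution=meta.get("resolution", "fine"),
        **stacks,
    )
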