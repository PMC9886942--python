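"""NetCDF / CSV persistence for pipeline intermediates.

Cubes (pixel x time) go to NetCDF3 via xarray's scipy engine; tables go
to CSV. Every writer records enough metadata (dt, start year, seed) for
a stage to be re-run from its files alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .series import PrecipSeries, ResidualSeries, VegetationSeries

ENGINE = "scipy"  # NetCDF3; no netCDF4 dependency


def write_veg_cube(path, values: np.ndarray, time: np.ndarray, pixel_ids, kind: str, seed=None):
    ds = xr.Dataset(
        {"veg": (("pixel", "time"), np.asarray(values, dtype=float))},
        coords={"pixel": np.asarray(pixel_ids, dtype=np.int32), "time": np.asarray(time)},
        attrs={"kind": kind, "time_units": "decimal_years"},
    )
    if seed is not None:
        ds.attrs["seed"] = int(seed)
    ds.to_netcdf(path, engine=ENGINE)


def read_veg_cube(path) -> list[VegetationSeries]:
    with xr.open_dataset(path, engine=ENGINE) as ds:
        kind = ds.attrs.get("kind", "generic")
        time = ds["time"].values.astype(float)
        return [
            VegetationSeries(ds["veg"].values[i], time, pixel_id=int(p), kind=kind)
            for i, p in enumerate(ds["pixel"].values)
        ]


def write_residual_cube(path, residuals: list[ResidualSeries], seed=None):
    n = max(len(r) for r in residuals)
    arr = np.full((len(residuals), n), np.nan)
    for i, r in enumerate(residuals):
        arr[i, : len(r)] = r.values
    ds = xr.Dataset(
        {"residual": (("pixel", "step"), arr)},
        coords={
            "pixel": np.asarray([r.pixel_id for r in residuals], dtype=np.int32),
            "step": np.arange(n, dtype=np.int32),
        },
        attrs={
            "dt": float(residuals[0].dt),
            "time0": float(residuals[0].time0),
            "time_units": "decimal_years",
        },
    )
    if seed is not None:
        ds.attrs["seed"] = int(seed)
    ds.to_netcdf(path, engine=ENGINE)


def read_residual_cube(path) -> list[ResidualSeries]:
    with xr.open_dataset(path, engine=ENGINE) as ds:
        dt = float(ds.attrs["dt"])
        time0 = float(ds.attrs.get("time0", 0.0))
        return [
            ResidualSeries(ds["residual"].values[i], dt=dt, pixel_id=int(p), time0=time0)
            for i, p in enumerate(ds["pixel"].values)
        ]


def write_precip_cube(path, values: np.ndarray, start_year: int, pixel_ids, seed=None):
    values = np.asarray(values, dtype=float)
    ds = xr.Dataset(
        {"precip": (("pixel", "month"), values)},
        coords={
            "pixel": np.asarray(pixel_ids, dtype=np.int32),
            "month": np.arange(values.shape[1], dtype=np.int32),
        },
        attrs={"start_year": int(start_year), "units": "mm/month"},
    )
    if seed is not None:
        ds.attrs["seed"] = int(seed)
    ds.to_netcdf(path, engine=ENGINE)


def read_precip_cube(path) -> list[PrecipSeries]:
    with xr.open_dataset(path, engine=ENGINE) as ds:
        start_year = int(ds.attrs.get("start_year", 0))
        return [
            PrecipSeries(ds["precip"].values[i], start_year=start_year, pixel_id=int(p))
            for i, p in enumerate(ds["pixel"].values)
        ]


def write_landscape(landscape, path) -> Path:
    """Write a SyntheticLandscape to a directory (cubes + truth tables)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pix = landscape.pixels["pixel_id"].to_numpy() if len(landscape.pixels) else np.array([], int)
    write_veg_cube(
        path / "veg.nc", landscape.veg, landscape.time, pix,
        kind=landscape.config.veg_kind, seed=landscape.seed,
    )
    write_precip_cube(
        path / "precip.nc", landscape.precip, landscape.config.start_year, pix,
        seed=landscape.seed,
    )
    landscape.pixels.to_csv(path / "pixels.csv", index=False)
    landscape.events_truth.to_csv(path / "events_truth.csv", index=False)
    landscape.labels.to_csv(path / "labels.csv")
    meta = {"seed": int(landscape.seed), "config": landscape.config.to_dict()}
    (path / "landscape.json").write_text(json.dumps(meta, indent=2, default=list))
    return path


def read_labels(path) -> pd.DataFrame:
    labels = pd.read_csv(path, index_col="pixel_id")
    labels.columns = [int(c) for c in labels.columns]
    return labels
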