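"""Water-availability and variability predictors.

Three per-pixel predictors summarize the water regime:

* **aridity** = PET / MAP (potential evapotranspiration over mean annual
  precipitation): > 1 denotes water deficit, > 2 roughly semi-arid;
* **Walsh-Lawler seasonality index (SI)**: normalized sum of absolute
  monthly deviations from uniform rainfall, from 0 (uniform) to 11/6
  (all precipitation in a single month);
* **normalized inter-annual variability**: standard deviation of annual
  precipitation sums divided by MAP, removing the strong linear
  dependence of the raw standard deviation on MAP itself.

The same operators applied to monthly soil-moisture series give the
mean-normalized soil-moisture variability; there is no separate code
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import PrecipSeries

__all__ = [
    "ClimateMetrics",
    "walsh_lawler_si",
    "interannual_variability",
    "aridity_index",
    "aridity_from_map_over_pet",
    "percentile_band_mask",
    "climate_metrics",
]

#: Analytic maximum of the Walsh-Lawler index (single-month concentration).
SI_MAX = 11.0 / 6.0


@dataclass(frozen=True)
class ClimateMetrics:
    """Per-pixel water predictors."""

    map_mm: float
    pet_mm: float
    aridity: float
    si: float
    interannual_norm: float


def walsh_lawler_si(precip: PrecipSeries, per_year: bool = False) -> float:
    """Walsh-Lawler seasonality index.

    ``SI = (1/R) * sum_i |m_i - R/12|`` where ``m_i`` are the long-term
    mean monthly totals and ``R`` their annual sum (climatological form,
    default). With ``per_year=True`` the index is computed for each year
    separately and averaged. Returns NaN when ``R`` is zero.
    """
    if per_year:
        years = precip.values.reshape(precip.n_years, 12)
        out = []
        for row in years:
            r = row.sum()
            out.append(np.nan if r == 0 else float(np.abs(row - r / 12.0).sum() / r))
        return float(np.nanmean(out)) if out else float("nan")
    m = precip.monthly_climatology()
    r = float(m.sum())
    if r == 0:
        return float("nan")
    return float(np.abs(m - r / 12.0).sum() / r)


def interannual_variability(precip: PrecipSeries, normalize: bool = True) -> float:
    """Std of annual precipitation sums, optionally normalized by MAP.

    Sample (n-1) standard deviation over calendar-year sums; requires at
    least 3 complete years. The normalized form is invariant under
    uniform rescaling of the series; the raw form scales linearly.
    """
    if precip.n_years < 3:
        raise ValueError("need at least 3 complete years")
    sums = precip.annual_sums()
    sd = float(np.std(sums, ddof=1))
    if not normalize:
        return sd
    map_mm = float(sums.mean())
    if map_mm == 0:
        return float("nan")
    return sd / map_mm


def aridity_index(pet_mm, map_mm):
    """Aridity = PET / MAP; values above 1 denote water deficit."""
    map_arr = np.asarray(map_mm, dtype=float)
    if np.any(map_arr <= 0):
        raise ValueError("map_mm must be positive")
    out = np.asarray(pet_mm, dtype=float) / map_arr
    return float(out) if out.ndim == 0 else out


def aridity_from_map_over_pet(map_over_pet):
    """Convert a MAP/PET-oriented index (higher = wetter) to PET/MAP."""
    arr = np.asarray(map_over_pet, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("map_over_pet must be positive")
    out = 1.0 / arr
    return float(out) if out.ndim == 0 else out


def percentile_band_mask(map_values, labels, band: tuple = (40.0, 60.0)) -> np.ndarray:
    """Keep pixels whose MAP lies in a per-class percentile band.

    Percentiles are computed independently within each land-cover class
    using inverted-CDF (type-1) percentiles, and the band is closed, so
    e.g. with distinct values 1..100 and band (40, 60) exactly the values
    40..60 are kept. A class whose MAP values are all equal keeps every
    pixel (the band degenerates onto the common value). Empty classes
    contribute an empty mask.
    """
    map_values = np.asarray(map_values, dtype=float)
    labels = np.asarray(labels)
    if map_values.shape != labels.shape:
        raise ValueError("map_values and labels must have the same shape")
    lo_p, hi_p = band
    mask = np.zeros(map_values.shape, dtype=bool)
    for cls in np.unique(labels):
        sel = labels == cls
        vals = map_values[sel]
        ok = np.isfinite(vals)
        if not ok.any():
            continue
        lo = np.percentile(vals[ok], lo_p, method="inverted_cdf")
        hi = np.percentile(vals[ok], hi_p, method="inverted_cdf")
        mask[sel] = ok & (vals >= lo) & (vals <= hi)
    return mask


def climate_metrics(precip: PrecipSeries, pet_mm: float) -> ClimateMetrics:
    """All water predictors for one pixel."""
    sums = precip.annual_sums()
    map_mm = float(sums.mean())
    return ClimateMetrics(
        map_mm=map_mm,
        pet_mm=float(pet_mm),
        aridity=aridity_index(pet_mm, map_mm),
        si=walsh_lawler_si(precip),
        interannual_norm=interannual_variability(precip),
    )
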