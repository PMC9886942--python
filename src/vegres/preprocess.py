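"""Vegetation-series preprocessing: despiking, resampling, STL residuals.

All resilience estimation downstream consumes the *residual* of a
seasonal-trend decomposition by loess (STL) — the de-seasoned and
de-trended anomalies — computed here with period 24 (one year of
bi-weekly samples), trend smoother 47 and low-pass 25. The seasonal
smoother defaults to a very stiff loess so the seasonal component is
near-periodic and does not absorb residual variance or autocorrelation,
which would bias the resilience estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from statsmodels.tsa.seasonal import STL

from .series import BIWEEKLY_DT, ResidualSeries, VegetationSeries

__all__ = [
    "despike",
    "resample_biweekly",
    "stl_residual",
    "landcover_mask",
    "IGBP_CLASSES",
    "NATURAL_CLASSES",
]

#: IGBP-style land-cover class names understood by :func:`landcover_mask`.
IGBP_CLASSES = frozenset(
    {
        "water",
        "evergreen_needleleaf_forest",
        "evergreen_broadleaf_forest",
        "deciduous_needleleaf_forest",
        "deciduous_broadleaf_forest",
        "mixed_forest",
        "closed_shrublands",
        "open_shrublands",
        "woody_savannas",
        "savannas",
        "grasslands",
        "permanent_wetlands",
        "croplands",
        "urban",
        "cropland_natural_mosaic",
        "snow_ice",
        "barren",
    }
)

#: Natural-vegetation classes retained by default (anthropogenic and
#: non-vegetated landscapes are excluded from the analysis).
NATURAL_CLASSES = frozenset(
    {
        "evergreen_needleleaf_forest",
        "evergreen_broadleaf_forest",
        "deciduous_needleleaf_forest",
        "deciduous_broadleaf_forest",
        "mixed_forest",
        "closed_shrublands",
        "open_shrublands",
        "woody_savannas",
        "savannas",
        "grasslands",
        "permanent_wetlands",
    }
)


def despike(series: VegetationSeries, window: int = 7, k: float = 4.0) -> VegetationSeries:
    """Replace spurious values (spikes) by the local running median.

    A point is flagged when it deviates from the median of its
    ``window``-sample neighbourhood by more than ``k`` scaled local MADs
    (median absolute deviations; the Hampel scaling 1.4826 makes the MAD
    a consistent estimate of a Gaussian sigma). Flagged points are
    replaced by the local median; all other points are untouched. This
    is a generic median/MAD despiking operator standing in for
    sensor-specific contamination screening (e.g. cloud contamination in
    NDVI).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    n = len(series)
    if window > n:
        raise ValueError(f"window ({window}) longer than series ({n})")

    x = series.values
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    win = sliding_window_view(xp, window)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            med = np.nanmedian(win, axis=1)
            mad = np.nanmedian(np.abs(win - med[:, None]), axis=1)

    dev = np.abs(x - med)
    # Hampel convention: 1.4826 * MAD is a consistent sigma estimate; the
    # absolute floor lets an isolated spike on a locally constant signal
    # (MAD = 0) still be caught while exact ties are never flagged
    flags = np.isfinite(x) & np.isfinite(med) & (dev > k * 1.4826 * mad + 1e-12)
    cleaned = x.copy()
    cleaned[flags] = med[flags]
    return VegetationSeries(
        cleaned, series.time.copy(), pixel_id=series.pixel_id, kind=series.kind,
        despike_flags=flags,
    )


def resample_biweekly(series: VegetationSeries) -> VegetationSeries:
    """Aggregate to the bi-weekly grid (24 samples/yr) by bin medians.

    Bins are half-open intervals of width 1/24 year anchored at the
    series' first timestamp. Each output value is the median of the
    non-missing input values falling in its bin; empty bins are missing.
    """
    t = series.time
    if t.size >= 2 and np.any(np.diff(t) <= 0):  # defensive; container validates too
        raise ValueError("timestamps must be strictly increasing")
    dt = BIWEEKLY_DT
    idx = np.floor((t - t[0]) / dt + 1e-9).astype(int)
    n_bins = int(idx[-1]) + 1
    out = np.full(n_bins, np.nan)
    for b in np.unique(idx):
        vals = series.values[idx == b]
        finite = vals[np.isfinite(vals)]
        if finite.size:
            out[b] = np.median(finite)
    new_time = t[0] + (np.arange(n_bins) + 0.5) * dt
    return VegetationSeries(out, new_time, pixel_id=series.pixel_id, kind=series.kind)


def _fill_gaps(x: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate missing runs; report positions of long gaps.

    Returns the filled array and a mask of positions belonging to gaps
    longer than ``max_gap`` (including edge extrapolations), which are
    restored to NaN in the residual after decomposition.
    """
    missing = ~np.isfinite(x)
    if not missing.any():
        return x.copy(), missing
    idx = np.arange(x.size)
    filled = x.copy()
    filled[missing] = np.interp(idx[missing], idx[~missing], x[~missing])

    long_gap = np.zeros(x.size, dtype=bool)
    run_start = None
    for i in range(x.size + 1):
        if i < x.size and missing[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            run_len = i - run_start
            if run_len > max_gap or run_start == 0 or i == x.size:
                long_gap[run_start:i] = True
            run_start = None
    return filled, long_gap


def stl_residual(
    series: VegetationSeries,
    period: int = 24,
    trend_smoother: int = 47,
    lowpass: int = 25,
    seasonal_smoother: int = 121,
    robust: bool = True,
    max_gap: int = 4,
    max_missing_frac: float = 0.2,
    return_components: bool = False,
):
    """STL decomposition residual of a vegetation series.

    Gaps up to ``max_gap`` samples are linearly interpolated before the
    decomposition (STL requires a complete series); longer gaps are also
    interpolated for the fit but restored to NaN in the returned
    residual. Series missing more than ``max_missing_frac`` of their
    points are rejected.
    """
    n = len(series)
    if n < 2 * period:
        raise ValueError(f"series length {n} shorter than two periods ({2 * period})")
    if series.missing_fraction > max_missing_frac:
        raise ValueError(
            f"missing fraction {series.missing_fraction:.2f} exceeds {max_missing_frac}"
        )

    filled, long_gap = _fill_gaps(series.values, max_gap)
    fit = STL(
        filled,
        period=period,
        seasonal=seasonal_smoother,
        trend=trend_smoother,
        low_pass=lowpass,
        robust=robust,
    ).fit()
    resid = np.asarray(fit.resid, dtype=float).copy()
    resid[long_gap] = np.nan

    dt = float(np.median(np.diff(series.time))) if n > 1 else BIWEEKLY_DT
    out = ResidualSeries(resid, dt=dt, pixel_id=series.pixel_id, time0=float(series.time[0]))
    if return_components:
        return out, {
            "seasonal": np.asarray(fit.seasonal),
            "trend": np.asarray(fit.trend),
            "filled": filled,
        }
    return out


def landcover_mask(
    labels: pd.DataFrame,
    natural_classes=NATURAL_CLASSES,
    known_classes=IGBP_CLASSES,
) -> pd.Series:
    """Pixel eligibility from per-year land-cover labels.

    ``labels`` has one row per pixel and one column per year of the
    masking period. A pixel is eligible iff its class belongs to
    ``natural_classes`` *and* is identical across all years (pixels whose
    land cover changed during the masking period are excluded).
    """
    arr = labels.to_numpy()
    seen = set(np.unique(arr.astype(str))) if arr.size else set()
    unknown = seen - set(known_classes)
    if unknown:
        raise ValueError(f"unknown land-cover class code(s): {sorted(unknown)}")
    if labels.shape[1] == 0:
        raise ValueError("labels must cover at least one year")
    stable = labels.nunique(axis=1) == 1
    natural = labels.iloc[:, 0].isin(set(natural_classes))
    eligible = stable & natural
    eligible.name = "eligible"
    return eligible
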