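"""Core time-series containers shared across the pipeline.

Time is carried as decimal years so that the canonical bi-weekly sampling
grid (24 samples per year, ``dt = 1/24`` yr) is exact and calendar-free.
Missing observations are encoded as NaN; no container interpolates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical bi-weekly sampling step in years (24 samples per year).
BIWEEKLY_DT: float = 1.0 / 24.0


def _as_1d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class VegetationSeries:
    """A single pixel's vegetation-index time series.

    Parameters
    ----------
    values
        Vegetation index (dimensionless). NaN marks missing observations.
    time
        Observation times in decimal years, strictly increasing.
    pixel_id
        Integer pixel identifier.
    kind
        ``"ndvi"`` enforces the NDVI range ``[-1, 1]``; ``"vod"`` enforces
        nonnegativity; ``"generic"`` imposes no range.
    despike_flags
        Boolean mask of points replaced by :func:`vegres.preprocess.despike`.
    """

    values: np.ndarray
    time: np.ndarray
    pixel_id: int = 0
    kind: str = "generic"
    despike_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _as_1d_float(self.values, "values")
        self.time = _as_1d_float(self.time, "time")
        if self.values.shape != self.time.shape:
            raise ValueError("values and time must have the same length")
        if self.values.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if self.kind == "ndvi" and finite.size and (finite.min() < -1 or finite.max() > 1):
            raise ValueError("NDVI-like values must lie within [-1, 1]")
        if self.kind == "vod" and finite.size and finite.min() < 0:
            raise ValueError("VOD-like values must be nonnegative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(~np.isfinite(self.values))) if len(self) else 0.0


@dataclass
class ResidualSeries:
    """De-seasoned, de-trended vegetation anomalies on a regular grid.

    This is the substrate for all resilience estimation: the anomalies are
    modelled as a linearization around a stable state, so their mean is
    (approximately) zero and ``dt`` is the sampling step in years.
    """

    values: np.ndarray
    dt: float = BIWEEKLY_DT
    pixel_id: int = 0
    time0: float = 0.0

    def __post_init__(self) -> None:
        self.values = _as_1d_float(self.values, "values")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def time(self) -> np.ndarray:
        """Sample times in decimal years."""
        return self.time0 + np.arange(self.values.size) * self.dt


@dataclass
class PrecipSeries:
    """Monthly precipitation totals (mm) covering whole calendar years."""

    values: np.ndarray
    start_year: int = 0
    pixel_id: int = 0

    def __post_init__(self) -> None:
        self.values = _as_1d_float(self.values, "values")
        if self.values.size == 0 or self.values.size % 12 != 0:
            raise ValueError("precipitation series must cover whole years (length multiple of 12)")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("precipitation totals must be nonnegative")

    @property
    def n_years(self) -> int:
        return self.values.size // 12

    def annual_sums(self) -> np.ndarray:
        """Calendar-year precipitation sums, mm/yr."""
        return self.values.reshape(self.n_years, 12).sum(axis=1)

    def monthly_climatology(self) -> np.ndarray:
        """Long-term mean total for each of the 12 months, mm."""
        return np.nanmean(self.values.reshape(self.n_years, 12), axis=0)
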