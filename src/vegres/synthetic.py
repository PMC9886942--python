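"""Synthetic landscape generator with known ground truth.

Emulates the statistical structure the resilience analysis assumes:

* per-pixel vegetation anomalies follow a stationary Ornstein-Uhlenbeck
  (OU) process ``dx = lambda*x dt + sigma dW`` with restoring rate
  ``lambda < 0``, sampled exactly as an AR(1) process;
* the observed vegetation index adds a sinusoidal seasonal cycle, a linear
  trend, and optional abrupt negative perturbations that relax back
  exponentially at a prescribed recovery rate;
* monthly precipitation has a configurable mean annual total, seasonal
  concentration, and inter-annual coefficient of variation;
* pixels are organised into land-cover classes along aridity and
  variability gradients, with the restoring rate tied monotonically to
  both so that the qualitative resilience-water relationship is encoded
  as ground truth.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal

from .series import BIWEEKLY_DT, PrecipSeries, ResidualSeries, VegetationSeries

__all__ = [
    "OUParams",
    "PerturbationTruth",
    "PrecipGenParams",
    "ClassConfig",
    "LambdaMap",
    "LandscapeConfig",
    "SyntheticLandscape",
    "gen_ou_residual",
    "gen_vegetation_series",
    "gen_precip_monthly",
    "gen_landscape",
    "default_landscape_config",
]


@dataclass(frozen=True)
class OUParams:
    """Parameters of a stationary OU simulation.

    ``lambda_true`` is the restoring rate in 1/year (strictly negative for
    stable dynamics), ``sigma`` the continuous noise amplitude in
    index-units/sqrt(year), ``dt`` the sampling step in years.
    """

    lambda_true: float
    sigma: float
    dt: float = BIWEEKLY_DT
    n_steps: int = 720
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lambda_true < 0:
            raise ValueError("lambda_true must be strictly negative for stable dynamics")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    @property
    def stationary_var(self) -> float:
        """Stationary variance ``-sigma^2 / (2*lambda)``."""
        return -self.sigma**2 / (2.0 * self.lambda_true)


@dataclass(frozen=True)
class PerturbationTruth:
    """Ground truth for one injected abrupt perturbation."""

    time_index: int
    amplitude: float  # negative index units (instantaneous drop)
    recovery_rate_true: float  # 1/year, negative for a recovering system

    def __post_init__(self) -> None:
        if not self.amplitude < 0:
            raise ValueError("perturbation amplitude must be negative (a drop)")
        if self.time_index < 0:
            raise ValueError("time_index must be nonnegative")


@dataclass(frozen=True)
class PrecipGenParams:
    """Parameters of the monthly precipitation generator."""

    map_mm: float
    month_weights: tuple = (1 / 12.0,) * 12
    interannual_cv: float = 0.2
    n_years: int = 30
    seed: int = 0
    month_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if not self.map_mm > 0:
            raise ValueError("map_mm must be positive")
        w = np.asarray(self.month_weights, dtype=float)
        if w.size != 12 or np.any(w < 0):
            raise ValueError("month_weights must be 12 nonnegative values")
        if abs(float(w.sum()) - 1.0) > 1e-8:
            raise ValueError("month_weights must sum to 1")
        if self.interannual_cv < 0 or self.month_noise_cv < 0:
            raise ValueError("coefficients of variation must be nonnegative")
        if self.n_years < 1:
            raise ValueError("n_years must be at least 1")


def gen_ou_residual(params: OUParams) -> ResidualSeries:
    """Simulate a stationary OU process sampled at step ``dt``.

    Uses the exact AR(1) transition: autoregressive coefficient
    ``phi = exp(lambda*dt)`` and innovation variance
    ``-sigma^2/(2*lambda) * (1 - phi^2)``, so that the discrete sample has
    exactly the continuous process's stationary variance and lag-1
    autocorrelation ``exp(lambda*dt)``. The initial value is drawn from
    the stationary distribution.
    """
    rng = np.random.default_rng(params.seed)
    phi = math.exp(params.lambda_true * params.dt)
    stat_var = params.stationary_var
    innov_std = math.sqrt(stat_var * (1.0 - phi * phi))

    x0 = rng.normal(0.0, math.sqrt(stat_var)) if stat_var > 0 else 0.0
    eps = rng.normal(0.0, 1.0, size=params.n_steps - 1) * innov_std
    # x[t] = phi*x[t-1] + eps[t]  ==  AR(1) filter of the innovations
    rest, _ = signal.lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    values = np.concatenate(([x0], rest))
    return ResidualSeries(values, dt=params.dt)


def perturbation_component(
    n_steps: int, dt: float, perturbations: list[PerturbationTruth]
) -> np.ndarray:
    """Deterministic anomaly contributed by injected perturbations.

    Each perturbation is an instantaneous drop of ``amplitude`` at its
    ``time_index`` followed by exponential relaxation
    ``amplitude * exp(recovery_rate_true * (t - t0))``.
    """
    comp = np.zeros(n_steps)
    t = np.arange(n_steps) * dt
    for p in perturbations:
        if p.time_index >= n_steps:
            raise ValueError(f"perturbation index {p.time_index} out of range (n={n_steps})")
        tail = t[p.time_index :] - t[p.time_index]
        comp[p.time_index :] += p.amplitude * np.exp(p.recovery_rate_true * tail)
    return comp


def gen_vegetation_series(
    ou: OUParams,
    seasonal_amplitude: float = 0.15,
    trend_slope: float = 0.0,
    perturbations: list[PerturbationTruth] | None = None,
    mean_level: float = 0.45,
    seasonal_phase: float = 0.0,
    pixel_id: int = 0,
    kind: str = "generic",
) -> tuple[VegetationSeries, dict]:
    """Compose a vegetation index series and return it with its truth.

    series = mean + sinusoidal seasonal cycle (period 1 year) + linear
    trend + OU residual + injected perturbation components. The returned
    truth dict carries every component so tests can validate the
    decomposition and recovery fitting against known values.
    """
    perturbations = list(perturbations or [])
    residual = gen_ou_residual(ou)
    t = np.arange(ou.n_steps) * ou.dt
    seasonal = seasonal_amplitude * np.sin(2 * np.pi * t + seasonal_phase)
    trend = trend_slope * t
    perturb = perturbation_component(ou.n_steps, ou.dt, perturbations)
    values = mean_level + seasonal + trend + residual.values + perturb
    series = VegetationSeries(values, t, pixel_id=pixel_id, kind=kind)
    truth = {
        "ou": ou,
        "residual": residual.values,
        "seasonal": mean_level + seasonal,
        "trend": trend,
        "perturbation_component": perturb,
        "perturbations": perturbations,
    }
    return series, truth


def gen_precip_monthly(params: PrecipGenParams) -> PrecipSeries:
    """Simulate monthly precipitation totals.

    The annual total for year ``y`` is ``map_mm`` times a unit-mean gamma
    factor with standard deviation ``interannual_cv`` (gamma keeps the
    series nonnegative without truncation). The annual total is split
    across months following ``month_weights``, with optional small
    multiplicative within-month gamma noise (``month_noise_cv``).
    """
    rng = np.random.default_rng(params.seed)
    w = np.asarray(params.month_weights, dtype=float)

    cv = params.interannual_cv
    if cv > 0:
        shape = 1.0 / cv**2
        year_factor = rng.gamma(shape, scale=1.0 / shape, size=params.n_years)
    else:
        year_factor = np.ones(params.n_years)

    monthly = params.map_mm * year_factor[:, None] * w[None, :]
    mcv = params.month_noise_cv
    if mcv > 0:
        shape = 1.0 / mcv**2
        monthly = monthly * rng.gamma(shape, scale=1.0 / shape, size=monthly.shape)
    return PrecipSeries(monthly.ravel(), pixel_id=params.seed)


# ---------------------------------------------------------------------------
# Landscape-level generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LambdaMap:
    """Monotone map from (aridity, inter-annual CV) to the restoring rate.

    ``lambda_true = clip(intercept + beta_aridity*aridity + beta_cv*cv)``
    with positive slopes, so drier and more variable pixels have lambda
    closer to zero (lower resilience) by construction.
    """

    intercept: float = -7.5
    beta_aridity: float = 1.6
    beta_cv: float = 4.0
    lo: float = -8.0
    hi: float = -0.4

    def __call__(self, aridity, cv):
        lam = self.intercept + self.beta_aridity * np.asarray(aridity) + self.beta_cv * np.asarray(cv)
        return np.clip(lam, self.lo, self.hi)


@dataclass
class ClassConfig:
    """Per-land-cover-class generator ranges (uniform sampling within)."""

    name: str
    n_pixels: int = 1000
    pet_mm: float = 1400.0
    aridity_range: tuple = (0.8, 2.8)
    cv_range: tuple = (0.1, 0.4)
    kappa_range: tuple = (0.5, 5.0)  # seasonal concentration of rainfall
    residual_std_range: tuple = (0.03, 0.06)  # stationary OU std, index units
    seasonal_amplitude_range: tuple = (0.1, 0.2)
    trend_slope_range: tuple = (-0.001, 0.001)
    inject_fraction: float = 0.35
    drop_mult: float = 8.0  # drop amplitude as multiple of residual std


@dataclass
class LandscapeConfig:
    """Full landscape generator configuration."""

    classes: list = field(default_factory=list)
    n_years: int = 30
    dt: float = BIWEEKLY_DT
    lambda_map: LambdaMap = field(default_factory=LambdaMap)
    mean_level: float = 0.45
    veg_kind: str = "ndvi"
    start_year: int = 1990

    @property
    def n_steps(self) -> int:
        return int(round(self.n_years / self.dt))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeConfig":
        d = dict(d)
        d["classes"] = [
            c if isinstance(c, ClassConfig) else ClassConfig(**_tupled(c))
            for c in d.get("classes", [])
        ]
        lm = d.get("lambda_map", LambdaMap())
        d["lambda_map"] = lm if isinstance(lm, LambdaMap) else LambdaMap(**lm)
        return cls(**d)


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def default_landscape_config() -> LandscapeConfig:
    """Demo landscape: two grass-dominated classes, ~2000 pixels, 30 yr.

    Ranges are chosen to span the water-surplus to semi-arid transition
    (aridity 0.6-3) with inter-annual precipitation CVs typical of grass
    and savanna landscapes (0.1-0.45).
    """
    return LandscapeConfig(
        classes=[
            ClassConfig(
                name="savannas",
                n_pixels=1000,
                pet_mm=1500.0,
                aridity_range=(0.6, 2.5),
                cv_range=(0.08, 0.35),
                kappa_range=(1.0, 5.0),
            ),
            ClassConfig(
                name="grasslands",
                n_pixels=1000,
                pet_mm=1300.0,
                aridity_range=(1.0, 3.0),
                cv_range=(0.12, 0.45),
                kappa_range=(0.5, 4.0),
            ),
        ]
    )


def _month_weights(kappa: float, peak_month: int) -> np.ndarray:
    """Unimodal monthly rainfall weights with concentration ``kappa``."""
    m = np.arange(12)
    w = np.exp(kappa * np.cos(2 * np.pi * (m - peak_month) / 12.0))
    return w / w.sum()


@dataclass
class SyntheticLandscape:
    """A generated pixel grid: series cubes plus a complete truth table."""

    pixels: pd.DataFrame  # one row per pixel: class, climate params, lambda_true, ...
    veg: np.ndarray  # (n_pixels, n_steps) vegetation index
    time: np.ndarray  # decimal years, length n_steps
    precip: np.ndarray  # (n_pixels, 12*n_years) monthly totals, mm
    events_truth: pd.DataFrame  # one row per injected perturbation
    labels: pd.DataFrame  # land-cover label per pixel (rows) per year (columns)
    config: LandscapeConfig
    seed: int

    @property
    def truth(self) -> pd.DataFrame:
        """Per-pixel ground-truth table (alias of ``pixels``)."""
        return self.pixels

    def vegetation_series(self, pixel_id: int) -> VegetationSeries:
        return VegetationSeries(
            self.veg[pixel_id], self.time, pixel_id=pixel_id, kind=self.config.veg_kind
        )

    def precip_series(self, pixel_id: int) -> PrecipSeries:
        return PrecipSeries(
            self.precip[pixel_id], start_year=self.config.start_year, pixel_id=pixel_id
        )

    def to_dir(self, path) -> None:
        """Write NetCDF cubes + CSV truth tables + config metadata."""
        from . import io as _io

        _io.write_landscape(self, path)


def gen_landscape(
    config: LandscapeConfig, seed: int = 0, n_pixels: int | None = None
) -> SyntheticLandscape:
    """Generate a synthetic landscape from ``config``, deterministically.

    ``n_pixels`` optionally overrides the total pixel count, distributed
    across classes proportionally to their configured counts
    (``n_pixels=0`` yields an empty landscape with an empty truth table).
    """
    if not config.classes:
        raise ValueError("landscape config must define at least one land-cover class")

    counts = [c.n_pixels for c in config.classes]
    if n_pixels is not None:
        total = sum(counts)
        if n_pixels == 0:
            counts = [0] * len(counts)
        elif total == 0:
            raise ValueError("cannot rescale classes with zero configured pixels")
        else:
            counts = [int(round(n_pixels * c / total)) for c in counts]

    n_total = sum(counts)
    n_steps = config.n_steps
    time = np.arange(n_steps) * config.dt

    ss = np.random.SeedSequence(seed)
    pixel_seeds = ss.spawn(max(n_total, 1))

    rows = []
    events = []
    veg = np.zeros((n_total, n_steps))
    precip = np.zeros((n_total, 12 * config.n_years))

    pid = 0
    for cls, n_px in zip(config.classes, counts):
        for _ in range(n_px):
            child = pixel_seeds[pid]
            rng = np.random.default_rng(child)
            sub = child.generate_state(4, dtype=np.uint32)  # derived sub-seeds

            aridity = rng.uniform(*cls.aridity_range)
            cv = rng.uniform(*cls.cv_range)
            kappa = rng.uniform(*cls.kappa_range)
            peak_month = int(rng.integers(0, 12))
            resid_std = rng.uniform(*cls.residual_std_range)
            seas_amp = rng.uniform(*cls.seasonal_amplitude_range)
            trend = rng.uniform(*cls.trend_slope_range)
            phase = rng.uniform(0, 2 * np.pi)

            lam = float(config.lambda_map(aridity, cv))
            sigma = resid_std * math.sqrt(-2.0 * lam)
            map_mm = cls.pet_mm / aridity
            weights = _month_weights(kappa, peak_month)

            perts: list[PerturbationTruth] = []
            if rng.random() < cls.inject_fraction:
                lo = int(round(3.0 / config.dt))
                hi = int(round((config.n_years - 6.0) / config.dt))
                if hi > lo:
                    perts = [
                        PerturbationTruth(
                            time_index=int(rng.integers(lo, hi)),
                            amplitude=-cls.drop_mult * resid_std,
                            recovery_rate_true=lam,
                        )
                    ]

            ou = OUParams(lam, sigma, dt=config.dt, n_steps=n_steps, seed=int(sub[0]))
            series, _ = gen_vegetation_series(
                ou,
                seasonal_amplitude=seas_amp,
                trend_slope=trend,
                perturbations=perts,
                mean_level=config.mean_level,
                seasonal_phase=phase,
                pixel_id=pid,
                kind=config.veg_kind,
            )
            veg[pid] = series.values

            pparams = PrecipGenParams(
                map_mm=map_mm,
                month_weights=tuple(weights),
                interannual_cv=cv,
                n_years=config.n_years,
                seed=int(sub[1]),
            )
            precip[pid] = gen_precip_monthly(pparams).values

            rows.append(
                {
                    "pixel_id": pid,
                    "landcover": cls.name,
                    "pet_mm": cls.pet_mm,
                    "map_mm": map_mm,
                    "aridity_true": aridity,
                    "interannual_cv_true": cv,
                    "si_true": float(np.abs(weights - 1.0 / 12.0).sum()),
                    "lambda_true": lam,
                    "sigma": sigma,
                    "residual_std_true": resid_std,
                    "seasonal_amplitude": seas_amp,
                    "trend_slope": trend,
                    "n_perturbations": len(perts),
                }
            )
            for p in perts:
                events.append(
                    {
                        "pixel_id": pid,
                        "time_index": p.time_index,
                        "amplitude": p.amplitude,
                        "recovery_rate_true": p.recovery_rate_true,
                    }
                )
            pid += 1

    pixels = pd.DataFrame(
        rows,
        columns=[
            "pixel_id", "landcover", "pet_mm", "map_mm", "aridity_true",
            "interannual_cv_true", "si_true", "lambda_true", "sigma",
            "residual_std_true", "seasonal_amplitude", "trend_slope",
            "n_perturbations",
        ],
    )
    events_truth = pd.DataFrame(
        events, columns=["pixel_id", "time_index", "amplitude", "recovery_rate_true"]
    )
    years = list(range(config.start_year, config.start_year + config.n_years))
    labels = pd.DataFrame(
        {y: pixels["landcover"].to_numpy() for y in years},
        index=pixels["pixel_id"].to_numpy() if n_total else [],
    )
    labels.index.name = "pixel_id"

    return SyntheticLandscape(
        pixels=pixels,
        veg=veg,
        time=time,
        precip=precip,
        events_truth=events_truth,
        labels=labels,
        config=config,
        seed=seed,
    )
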