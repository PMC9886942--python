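"""Theory-based resilience metrics: AC1, variance, and restoring rates.

Linearizing vegetation dynamics around a stable state gives an
Ornstein-Uhlenbeck process ``dx = lambda*x dt + sigma dW`` whose
discrete sample is an AR(1) process. Its stationary variance and lag-1
autocorrelation (AC1) relate to the restoring rate ``lambda`` via

    Var(x)  = -sigma^2 / (2*lambda)        (variance route)
    AC1     = exp(lambda * dt)             (autocorrelation route)

so ``lambda`` (1/year, negative = resilient) can be recovered by
inverting either relation. The closer ``lambda`` is to zero, the larger
AC1 and variance, and the lower the resilience. Estimates are always
computed over the full series (no sliding windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import ResidualSeries

__all__ = [
    "ResilienceEstimate",
    "estimate_ac1",
    "estimate_variance_and_noise",
    "lambda_from_ac1",
    "lambda_from_variance",
    "estimate_resilience",
]


@dataclass
class ResilienceEstimate:
    """Per-pixel resilience indicators and derived restoring rates.

    ``lambda_ac1`` and ``lambda_var`` are in 1/year; NaN entries carry an
    explanatory flag. ``noise_var`` is the innovation variance of the
    fitted AR(1) process, ``variance * (1 - ac1^2)``.
    """

    ac1: float
    variance: float
    noise_var: float
    lambda_ac1: float
    lambda_var: float
    dt: float
    n_eff: int
    flags: list = field(default_factory=list)


def _finite_pairs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = x[:-1], x[1:]
    ok = np.isfinite(a) & np.isfinite(b)
    return a[ok], b[ok]


def estimate_ac1(residual: ResidualSeries) -> float:
    """Lag-1 autocorrelation: Pearson correlation of the series with its
    one-step-lagged self over the full span, pairwise-complete.

    Returns NaN for degenerate (zero-variance or too-short) input.
    """
    a, b = _finite_pairs(residual.values)
    if a.size < 3:
        return float("nan")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def estimate_variance_and_noise(residual: ResidualSeries) -> tuple[float, float]:
    """Sample variance of the residual and AR(1) innovation variance.

    The innovation (noise) variance uses the stationary AR(1) identity
    ``noise_var = variance * (1 - ac1^2)``; for white noise it equals the
    variance. Degenerate series yield NaNs.
    """
    x = residual.values[np.isfinite(residual.values)]
    if x.size < 3:
        return float("nan"), float("nan")
    var = float(np.var(x, ddof=1))
    if var == 0:
        return float("nan"), float("nan")
    ac1 = estimate_ac1(residual)
    noise = var * (1.0 - ac1 * ac1) if np.isfinite(ac1) else float("nan")
    return var, noise


def lambda_from_ac1(ac1: float, dt: float) -> float:
    """Invert ``AC1 = exp(lambda*dt)``: ``lambda = ln(AC1)/dt``.

    Defined only on AC1 in (0, 1); AC1 >= 1 signals a non-resilient or
    unstable fit and AC1 <= 0 lies outside the OU model — both return NaN
    so callers can flag them.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(ac1) or ac1 <= 0.0 or ac1 >= 1.0:
        return float("nan")
    return float(np.log(ac1) / dt)


def lambda_from_variance(
    variance: float,
    noise_var: float | None = None,
    sigma2: float | None = None,
    dt: float | None = None,
) -> float:
    """Invert the stationary-variance relation for ``lambda``.

    With the continuous noise amplitude ``sigma2`` (= sigma^2) supplied,
    this is the exact inversion ``lambda = -sigma2 / (2*variance)``.
    Otherwise the discrete estimator ``lambda = -noise_var /
    (2*variance*dt)`` is used, with the innovation variance standing in
    for ``sigma^2 * dt``; the two agree in the small-``dt`` limit.
    """
    if not variance > 0:
        raise ValueError("variance must be positive")
    if sigma2 is not None:
        return float(-sigma2 / (2.0 * variance))
    if noise_var is None:
        raise ValueError("supply either sigma2 or noise_var")
    if dt is None or not dt > 0:
        raise ValueError("dt must be positive when using the discrete estimator")
    if not np.isfinite(noise_var) or noise_var <= 0:
        return float("nan")
    return float(-noise_var / (2.0 * variance * dt))


def estimate_resilience(residual: ResidualSeries) -> ResilienceEstimate:
    """Full set of indicators for one residual series."""
    flags: list[str] = []
    a, b = _finite_pairs(residual.values)
    n_eff = int(a.size)

    ac1 = estimate_ac1(residual)
    var, noise = estimate_variance_and_noise(residual)
    if not np.isfinite(ac1):
        flags.append("ac1_undefined")
    elif ac1 >= 1.0:
        flags.append("nonstationary")
    elif ac1 <= 0.0:
        flags.append("ac1_out_of_model")

    lam_ac1 = lambda_from_ac1(ac1, residual.dt) if np.isfinite(ac1) else float("nan")
    lam_var = (
        lambda_from_variance(var, noise_var=noise, dt=residual.dt)
        if np.isfinite(var) and var > 0
        else float("nan")
    )
    if not np.isfinite(var):
        flags.append("variance_undefined")
    return ResilienceEstimate(
        ac1=ac1,
        variance=var,
        noise_var=noise,
        lambda_ac1=lam_ac1,
        lambda_var=lam_var,
        dt=residual.dt,
        n_eff=n_eff,
        flags=flags,
    )
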