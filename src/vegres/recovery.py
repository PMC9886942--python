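"""Empirical resilience: abrupt-perturbation detection and recovery fitting.

Detection follows a three-filter chain on the residual series:

1. local slopes from an 18-sample (9-month) moving OLS window; connected
   runs of slopes steeper than the 99th percentile of the pixel's own
   negative-slope magnitudes form candidate perturbation regions, with
   the largest-magnitude slope in each region labelling the disturbance;
2. candidates are validated by requiring a genuine downward shift (the
   post-transition window mean must drop below the pre-transition mean)
   and a significant two-sample Kolmogorov-Smirnov test between the
   pre- and post-transition windows;
3. from the post-transition minimum, five years of residuals are fitted
   with an exponential ``x(t) = x0 * exp(r*t)`` and fits with a poor
   coefficient of determination are discarded.

The fitted exponent ``r`` (1/year) is the empirical recovery rate:
negative ``r`` means the system relaxes back at rate ``|r|``; positive
``r`` means the perturbation is amplified (non-resilient state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .series import ResidualSeries

__all__ = [
    "Perturbation",
    "RecoveryFit",
    "rolling_slopes",
    "detect_perturbations",
    "validate_perturbation",
    "fit_recovery",
    "find_recovery_events",
]

SLOPE_WINDOW_DEFAULT = 18  # samples (9 months at bi-weekly sampling)


@dataclass
class Perturbation:
    """One candidate abrupt perturbation.

    ``region`` is the half-open interval of contiguous above-threshold
    slope indices; ``footprint`` is the corresponding half-open interval
    of residual sample indices touched by those slope windows.
    """

    region: tuple
    peak_index: int  # slope-series index of the steepest slope
    peak_sample: int  # residual-series index of the window centre at the peak
    slope_at_peak: float  # index-units per year
    window: int = SLOPE_WINDOW_DEFAULT
    ks_p: float = float("nan")
    drop_ok: bool | None = None
    retained: bool | None = None
    min_index: int | None = None
    reason: str | None = None

    @property
    def footprint(self) -> tuple:
        return (self.region[0], self.region[1] - 1 + self.window)


@dataclass
class RecoveryFit:
    """Exponential recovery fit ``x(t) = x0 * exp(r*t)`` after one event."""

    x0: float
    r: float  # 1/year
    r2: float
    window: tuple  # half-open residual-index interval used for the fit
    accepted: bool
    reason: str | None = None
    perturbation: Perturbation | None = None


def rolling_slopes(residual: ResidualSeries, window: int = SLOPE_WINDOW_DEFAULT) -> np.ndarray:
    """OLS slope (index-units/year) of the residual over each moving window.

    Slopes are assigned to window centres; the result has length
    ``n - window + 1``. Windows containing any missing sample get NaN.
    """
    x = residual.values
    n = x.size
    if window > n:
        raise ValueError(f"window ({window}) longer than series ({n})")
    if window < 2:
        raise ValueError("window must be at least 2")
    t = np.arange(window) * residual.dt
    w = (t - t.mean()) / np.sum((t - t.mean()) ** 2)
    # correlate == dot product of w with each window
    slopes = np.correlate(np.nan_to_num(x, nan=0.0), w, mode="valid")
    bad = np.correlate((~np.isfinite(x)).astype(float), np.ones(window), mode="valid") > 0
    slopes = np.where(bad, np.nan, slopes)
    return slopes


def detect_perturbations(
    slopes: np.ndarray,
    percentile: float = 99.0,
    window: int = SLOPE_WINDOW_DEFAULT,
) -> list[Perturbation]:
    """Threshold negative slopes at a per-pixel percentile of their magnitude.

    The threshold is the ``percentile``-th percentile of the magnitudes
    of the *negative* slopes in this series (only drops are of interest
    downstream). Contiguous runs of slopes at or beyond the threshold
    form regions; the steepest slope in each region (earliest index on
    ties) labels the disturbance.
    """
    slopes = np.asarray(slopes, dtype=float)
    finite = slopes[np.isfinite(slopes)]
    if finite.size == 0 or np.ptp(finite) == 0:
        warnings.warn("degenerate slope series: no perturbations detectable", stacklevel=2)
        return []
    neg = -finite[finite < 0]
    if neg.size == 0:
        return []
    threshold = float(np.percentile(neg, percentile))
    above = np.isfinite(slopes) & (slopes <= -threshold)
    if not above.any():
        return []

    half = (window - 1) // 2
    out: list[Perturbation] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        seg = slopes[start:stop]
        peak = start + int(np.nanargmin(seg))  # steepest (most negative); earliest on ties
        out.append(
            Perturbation(
                region=(int(start), int(stop)),
                peak_index=int(peak),
                peak_sample=int(peak + half),
                slope_at_peak=float(slopes[peak]),
                window=window,
            )
        )
    return out


def validate_perturbation(
    residual: ResidualSeries,
    p: Perturbation,
    pre_win: int = 24,
    post_win: int = 24,
    alpha: float = 0.05,
    min_fraction: float = 0.5,
) -> Perturbation:
    """Apply the drop and Kolmogorov-Smirnov filters to one candidate.

    Windows of ``pre_win``/``post_win`` samples immediately before and
    after the transition footprint (the footprint itself excluded) are
    compared: the candidate is retained iff the post-window mean lies
    below the pre-window mean *and* a two-sample KS test rejects equality
    of the two windows at level ``alpha``.
    """
    x = residual.values
    fstart, fstop = p.footprint
    pre = x[max(0, fstart - pre_win) : fstart]
    post = x[fstop : fstop + post_win]
    pre = pre[np.isfinite(pre)]
    post = post[np.isfinite(post)]
    if pre.size < max(3, int(min_fraction * pre_win)) or post.size < max(
        3, int(min_fraction * post_win)
    ):
        return replace(p, retained=False, reason="insufficient_data")

    drop_ok = bool(post.mean() < pre.mean())
    ks_p = float(stats.ks_2samp(pre, post).pvalue)
    retained = drop_ok and ks_p < alpha
    reason = None if retained else ("no_drop" if not drop_ok else "ks_not_significant")
    return replace(p, drop_ok=drop_ok, ks_p=ks_p, retained=retained, reason=reason)


def _exp_model(t, x0, r):
    return x0 * np.exp(r * t)


def fit_recovery(
    residual: ResidualSeries,
    p: Perturbation,
    fit_years: float = 5.0,
    r2_min: float = 0.5,
    min_search: int = 12,
    min_fraction: float = 0.5,
    other_peaks: list[int] | None = None,
) -> RecoveryFit:
    """Fit the exponential recovery after one validated perturbation.

    The local minimum is searched within ``min_search`` samples after
    the labelled disturbance; the following ``fit_years`` years of
    residuals are fitted with ``x0 * exp(r*t)`` by nonlinear least
    squares, seeded by a log-linear regression on sign-consistent
    points. Fits are rejected when the window has too few points,
    overlaps another detected perturbation, fails to converge, or has
    ``R^2`` below ``r2_min``.
    """
    x = residual.values
    n = x.size
    search_stop = min(n, p.peak_sample + min_search + 1)
    seg = x[p.peak_sample : search_stop]
    if seg.size == 0 or not np.isfinite(seg).any():
        return RecoveryFit(np.nan, np.nan, np.nan, (0, 0), False, "no_minimum", p)
    min_index = p.peak_sample + int(np.nanargmin(seg))
    p = replace(p, min_index=min_index)

    win_len = int(round(fit_years / residual.dt))
    start, stop = min_index, min(n, min_index + win_len)
    t = (np.arange(start, stop) - start) * residual.dt
    y = x[start:stop]
    ok = np.isfinite(y)
    if ok.sum() < max(4, int(min_fraction * win_len)):
        return RecoveryFit(np.nan, np.nan, np.nan, (start, stop), False, "insufficient_data", p)
    if other_peaks is not None and any(
        start < q < stop and q != p.peak_sample for q in other_peaks
    ):
        return RecoveryFit(np.nan, np.nan, np.nan, (start, stop), False, "overlapping_event", p)

    t, y = t[ok], y[ok]
    y_min = y[0]
    if y_min == 0 or not np.isfinite(y_min):
        return RecoveryFit(np.nan, np.nan, np.nan, (start, stop), False, "degenerate_minimum", p)

    # log-linear initialization on points sharing the minimum's sign
    sign = np.sign(y_min)
    consistent = (np.sign(y) == sign) & (np.abs(y) > 0)
    if consistent.sum() >= 3:
        coef = np.polyfit(t[consistent], np.log(np.abs(y[consistent])), 1)
        r0, x0_0 = float(coef[0]), sign * float(np.exp(coef[1]))
    else:
        r0, x0_0 = -1.0, float(y_min)

    try:
        popt, _ = optimize.curve_fit(
            _exp_model, t, y, p0=[x0_0, r0], maxfev=10000
        )
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return RecoveryFit(np.nan, np.nan, np.nan, (start, stop), False, "no_convergence", p)
    x0_fit, r_fit = float(popt[0]), float(popt[1])

    pred = _exp_model(t, x0_fit, r_fit)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return RecoveryFit(x0_fit, r_fit, np.nan, (start, stop), False, "degenerate_window", p)
    r2 = 1.0 - ss_res / ss_tot
    accepted = bool(np.isfinite(r2) and r2 >= r2_min)
    return RecoveryFit(
        x0_fit, r_fit, r2, (start, stop), accepted,
        None if accepted else "low_r2", p,
    )


def find_recovery_events(
    residual: ResidualSeries,
    slope_window: int = SLOPE_WINDOW_DEFAULT,
    percentile: float = 99.0,
    pre_win: int = 24,
    post_win: int = 24,
    alpha: float = 0.05,
    fit_years: float = 5.0,
    r2_min: float = 0.5,
    min_search: int = 12,
) -> tuple[list[RecoveryFit], dict]:
    """Run the full detect -> validate -> fit chain on one pixel.

    Returns the recovery fits for KS-validated candidates together with a
    dict of filter counts (candidates, KS/drop rejections, fit
    rejections, accepted) for pipeline auditing.
    """
    counts = {"candidates": 0, "validated": 0, "accepted": 0}
    if len(residual) < slope_window:
        return [], counts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        slopes = rolling_slopes(residual, window=slope_window)
        perts = detect_perturbations(slopes, percentile=percentile, window=slope_window)
    counts["candidates"] = len(perts)
    validated = [
        validate_perturbation(residual, p, pre_win=pre_win, post_win=post_win, alpha=alpha)
        for p in perts
    ]
    retained = [p for p in validated if p.retained]
    counts["validated"] = len(retained)
    peaks = [p.peak_sample for p in retained]
    fits = [
        fit_recovery(
            residual, p, fit_years=fit_years, r2_min=r2_min,
            min_search=min_search, other_peaks=peaks,
        )
        for p in retained
    ]
    counts["accepted"] = sum(f.accepted for f in fits)
    return fits, counts
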