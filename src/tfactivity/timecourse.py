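"""Sigmoid and impulse fits to TF-activity time series.

Activity responses after an induction or a nutrient shift are summarized
by fitting either a four-parameter saturating sigmoid

    y(t) = y0 + (A - y0) / (1 + exp(-k (t - t0))),   k > 0

or a six-parameter two-transition impulse (a product of two logistics,
one rising and one falling) that can describe a response that peaks and
returns toward a final level:

    f(t) = (1/h1) [h0 + (h1-h0) s(b(t-t1))] [h2 + (h1-h2) s(-b(t-t2))]

with s the logistic function, onset/offset times t1 < t2 and slope b > 0.
The two families are compared by BIC with the Gaussian-error profile
likelihood, n ln(SSE/n) + k ln(n).  Fits use multi-start nonlinear least
squares with data-driven starts, so they are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .containers import ValidationError

__all__ = [
    "TimeSeries",
    "CurveFit",
    "sigmoid4",
    "impulse6",
    "fit_sigmoid",
    "fit_impulse",
    "select_by_bic",
    "summarize_directions",
]

Family = Literal["sigmoid4", "impulse6"]


@dataclass(frozen=True)
class TimeSeries:
    """Time points (minutes) and log2 fold changes of activity vs time 0."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValidationError("times and values must be 1-d and equal length")
        if (np.diff(t) <= 0).any():
            raise ValidationError("times must be strictly increasing")
        if (t < 0).any():
            raise ValidationError("times must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class CurveFit:
    family: Family
    params: np.ndarray
    r_squared: float
    bic: float
    direction: Literal["increasing", "decreasing"]
    sse: float
    success: bool = True

    @property
    def n_params(self) -> int:
        return 4 if self.family == "sigmoid4" else 6


def sigmoid4(t: np.ndarray, y0: float, A: float, k: float, t0: float) -> np.ndarray:
    return y0 + (A - y0) / (1.0 + np.exp(-np.clip(k * (t - t0), -500, 500)))


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def impulse6(
    t: np.ndarray,
    h0: float,
    h1: float,
    h2: float,
    t1: float,
    t2: float,
    beta: float,
) -> np.ndarray:
    h1_safe = h1 if abs(h1) > 1e-8 else (1e-8 if h1 >= 0 else -1e-8)
    rise = h0 + (h1 - h0) * _logistic(beta * (t - t1))
    fall = h2 + (h1 - h2) * _logistic(-beta * (t - t2))
    return rise * fall / h1_safe


def _fit_stats(ts: TimeSeries, pred: np.ndarray, k: int) -> tuple[float, float, float]:
    sse = float(np.sum((ts.values - pred) ** 2))
    sst = float(np.sum((ts.values - ts.values.mean()) ** 2))
    r2 = np.nan if sst == 0 else 1.0 - sse / sst
    n = len(ts)
    bic = n * np.log(max(sse, 1e-300) / n) + k * np.log(n)
    return sse, r2, float(bic)


def _multistart(residual, starts, lb, ub):
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-12, np.where(np.isfinite(ub), ub - 1e-12, x0))
        try:
            sol = least_squares(residual, x0, bounds=(lb, ub), method="trf")
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def fit_sigmoid(ts: TimeSeries) -> CurveFit:
    """Fit the four-parameter saturating sigmoid by multi-start nonlinear
    least squares.  Direction is increasing iff the plateau A exceeds the
    initial level y0."""
    if len(ts) < 5:
        raise ValidationError("sigmoid fit needs at least 5 time points")
    t, v = ts.times, ts.values
    span = t[-1] - t[0]

    def residual(p):
        return sigmoid4(t, *p) - v

    lo, hi = float(v.min()), float(v.max())
    starts = []
    for q in (0.15, 0.35, 0.55, 0.75):
        t0 = t[0] + q * span
        for k in (1.0 / max(span, 1e-9) * 4, 1.0 / max(span, 1e-9) * 16):
            starts.append([v[0], v[-1], k, t0])
            starts.append([hi, lo, k, t0])
    lb = np.array([-np.inf, -np.inf, 1e-6, t[0] - span])
    ub = np.array([np.inf, np.inf, np.inf, t[-1] + span])
    best = _multistart(residual, starts, lb, ub)
    if best is None:
        return CurveFit(
            "sigmoid4", np.full(4, np.nan), np.nan, np.inf, "increasing", np.inf, False
        )
    y0, A, k, t0 = best.x
    sse, r2, bic = _fit_stats(ts, sigmoid4(t, *best.x), 4)
    direction = "increasing" if A > y0 else "decreasing"
    return CurveFit("sigmoid4", best.x.copy(), r2, bic, direction, sse)


def fit_impulse(ts: TimeSeries) -> CurveFit:
    """Fit the six-parameter impulse by multi-start nonlinear least squares.

    Internally the offset time is parameterized as t2 = t1 + dt with
    dt > 0 so the two transitions stay ordered; reported parameters are
    (h0, h1, h2, t1, t2, beta).  Direction compares the fitted values at
    the last and first observed times.
    """
    if len(ts) < 7:
        raise ValidationError("impulse fit needs at least 7 time points")
    t, v = ts.times, ts.values
    span = t[-1] - t[0]

    def residual(p):
        h0, h1, h2, t1, dt, beta = p
        return impulse6(t, h0, h1, h2, t1, t1 + dt, beta) - v

    peak = float(v[np.argmax(np.abs(v))])
    starts = []
    for q1, q2 in ((0.1, 0.5), (0.2, 0.7), (0.35, 0.85), (0.1, 0.9)):
        t1 = t[0] + q1 * span
        dt = max((q2 - q1) * span, 1e-3)
        for beta in (4.0 / max(span, 1e-9), 16.0 / max(span, 1e-9)):
            starts.append([v[0], peak, v[-1], t1, dt, beta])
            starts.append([v[0], v[-1], v[-1], t1, dt, beta])
    lb = np.array([-np.inf, -np.inf, -np.inf, t[0] - span, 1e-6, 1e-3 / max(span, 1e-9)])
    ub = np.array([np.inf, np.inf, np.inf, t[-1] + span, 3 * span + 1.0, np.inf])
    best = _multistart(residual, starts, lb, ub)
    if best is None:
        return CurveFit(
            "impulse6", np.full(6, np.nan), np.nan, np.inf, "increasing", np.inf, False
        )
    h0, h1, h2, t1, dt, beta = best.x
    params = np.array([h0, h1, h2, t1, t1 + dt, beta])
    pred = impulse6(t, *params)
    sse, r2, bic = _fit_stats(ts, pred, 6)
    direction = "increasing" if pred[-1] > pred[0] else "decreasing"
    return CurveFit("impulse6", params, r2, bic, direction, sse)


def select_by_bic(fits: Sequence[CurveFit], n_points: int) -> CurveFit:
    """Pick the fit with the lowest BIC; ties go to fewer parameters."""
    ok = [f for f in fits if f.success]
    if not ok:
        raise ValidationError("no successful fits to select from")
    return min(ok, key=lambda f: (f.bic, f.n_params))


def summarize_directions(
    fits: Mapping[str, CurveFit], r2_threshold: float
) -> tuple[float, int]:
    """Fraction of retained fits classified as increasing.

    Fits that failed or explain less variance than ``r2_threshold`` are
    dropped; returns (fraction_increasing, n_retained), with NaN when
    nothing is retained.
    """
    if not 0.0 <= r2_threshold <= 1.0:
        raise ValidationError("r2_threshold must lie in [0, 1]")
    kept = [
        f
        for f in fits.values()
        if f.success and np.isfinite(f.r_squared) and f.r_squared >= r2_threshold
    ]
    if not kept:
        return float("nan"), 0
    frac = sum(1 for f in kept if f.direction == "increasing") / len(kept)
    return frac, len(kept)
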