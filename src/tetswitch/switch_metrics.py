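"""Switch-off time statistic and reporter half-life estimation.

The switch-off time T_off summarises how quickly fluorescence falls after
Doxycycline addition.  Two threshold conventions are supported:

``mode="initial"``
    The time the smoothed curve first crosses ``threshold_fraction`` of the
    mean initial fluorescence F0 (the default convention).
``mode="steady_state"``
    The time the smoothed curve first covers ``threshold_fraction`` of the
    distance from F0 down to the final (OFF) steady-state level, i.e. the
    crossing of ``off_level + threshold_fraction*(F0 - off_level)``.  For a
    linear system this statistic is exactly independent of the inducer dose,
    which is the open-loop circuit's defining invariance.

The half-life estimator mirrors the cycloheximide-chase experiment: a pure
exponential is fitted to a decaying fluorescence course and the degradation
rate delta converted to a half-life log(2)/delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .timecourse import TimeCourse

__all__ = ["DecayFit", "t_off", "fit_exponential_decay", "moving_average"]


def moving_average(values, window: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return values.copy()
    half = window // 2
    out = np.empty_like(values)
    n = len(values)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def t_off(
    tc: TimeCourse,
    threshold_fraction: float = 0.5,
    smoothing_window: int = 5,
    n_initial: int = 4,
    mode: str = "initial",
    off_level: float | None = None,
) -> float | None:
    """Switch-off time [min] of one fluorescence course, or None if not reached.

    The course is smoothed by a centred moving average; F0 is the mean of
    the first ``n_initial`` smoothed samples.  The crossing time of the
    threshold level (see module docstring for the two modes) is located by
    linear interpolation between samples.  In ``steady_state`` mode the OFF
    level defaults to the mean of the last ``n_initial`` smoothed samples;
    pass the model-predicted OFF fluorescence for an exact reference.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    if len(tc.values) < smoothing_window:
        raise ValueError("course has fewer samples than the smoothing window")
    if mode not in ("initial", "steady_state"):
        raise ValueError(f"unknown mode {mode!r}")
    smoothed = moving_average(tc.values, smoothing_window)
    f0 = smoothed[:n_initial].mean()
    if mode == "initial":
        level = threshold_fraction * f0
    else:
        base = smoothed[-n_initial:].mean() if off_level is None else float(off_level)
        if base >= f0:
            return None  # no decay towards the reference level
        level = base + threshold_fraction * (f0 - base)
    below = smoothed <= level
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(tc.times[0])
    t0, t1 = tc.times[i - 1], tc.times[i]
    y0, y1 = smoothed[i - 1], smoothed[i]
    if y0 == y1:
        return float(t1)
    return float(t0 + (y0 - level) / (y0 - y1) * (t1 - t0))


@dataclass
class DecayFit:
    """Exponential-decay fit ``A*exp(-delta*t) (+ offset)`` of a course."""

    delta: float  # decay rate [1/min]
    amplitude: float  # A [a.u.]
    offset: float  # floor [a.u.] (0 unless fitted)
    half_life: float  # log(2)/delta [min]
    rss: float  # residual sum of squares

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be > 0")


def fit_exponential_decay(tc: TimeCourse, fit_offset: bool = False) -> DecayFit:
    """Fit ``A*exp(-delta*t)`` to a decaying fluorescence course.

    Nonlinear least squares seeded by a log-linear regression; raises
    ``ValueError`` on flat or rising input (no decay to fit) and
    ``RuntimeError`` with a residual report on non-convergence.
    """
    t = tc.times
    y = tc.values
    if len(y) < 5:
        raise ValueError("need at least 5 samples to fit a decay")
    if np.any(y <= 0):
        raise ValueError("values must be strictly positive for a decay fit")
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if slope >= -1e-12:
        raise ValueError("no decay detected (log-linear slope is not negative)")
    try:
        if fit_offset:
            fun = lambda t, a, d, c: a * np.exp(-d * t) + c  # noqa: E731
            p0 = [math.exp(intercept), -slope, 0.0]
            bounds = ([0.0, 1e-12, 0.0], [np.inf, np.inf, np.inf])
        else:
            fun = lambda t, a, d: a * np.exp(-d * t)  # noqa: E731
            p0 = [math.exp(intercept), -slope]
            bounds = ([0.0, 1e-12], [np.inf, np.inf])
        popt, _ = curve_fit(fun, t, y, p0=p0, bounds=bounds, maxfev=10000)
    except RuntimeError as err:
        raise RuntimeError(f"decay fit did not converge: {err}") from err
    rss = float(np.sum((fun(t, *popt) - y) ** 2))
    amplitude, delta = float(popt[0]), float(popt[1])
    offset = float(popt[2]) if fit_offset else 0.0
    return DecayFit(
        delta=delta,
        amplitude=amplitude,
        offset=offset,
        half_life=math.log(2.0) / delta,
        rss=rss,
    )
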