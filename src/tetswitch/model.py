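"""Right-hand sides and elementary response functions of the circuit models.

The positive feedback loop (PFL) is a four-state ODE system: bicistronic
tTA-IRES-d2EYFP mRNA (``x1``), tTA protein (``x2``), unfolded reporter
(``x3``) and folded, fluorescent reporter (``x4``).  The open-loop control
(NOPFL) replaces the self-activating tTA with a constant protein level
``rho_tTA`` and keeps the three remaining states ``(x1, x3, x4)``.

Modelling assumptions: Hill transcription with additive basal leakiness,
linear translation and degradation, Doxycycline acting as a decreasing Hill
factor on tTA activity before the promoter, and a two-stage
(unfolded -> folded) reporter maturation model in which both reporter forms
are degraded at the same rate ``d3``.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares

from .params import ParameterSet

__all__ = [
    "CircuitState",
    "dox_repression",
    "dox_repression_mm_approx",
    "fit_mm_approx",
    "transcription_rate",
    "pfl_rhs",
    "nopfl_rhs",
    "pfl_jacobian",
    "nopfl_jacobian",
    "observe",
]


class CircuitState(NamedTuple):
    """Species concentrations [nM] at one instant.

    ``x2`` is the tTA protein level; in the open-loop circuit it is fixed at
    ``rho_tTA`` and is not a dynamical state.
    """

    x1: float  # mRNA
    x2: float  # tTA protein
    x3: float  # unfolded d2EYFP
    x4: float  # folded d2EYFP

    def to_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)


def dox_repression(dox, k_dox: float, h: float):
    """Active fraction of tTA at Doxycycline concentration ``dox`` [nM].

    Decreasing Hill function ``k_dox**h / (k_dox**h + dox**h)``; equals 1 at
    zero Doxycycline and 0.5 at ``dox == k_dox``.
    """
    dox = np.asarray(dox, dtype=float)
    if np.any(dox < 0):
        raise ValueError("dox must be >= 0")
    if not (k_dox > 0 and h > 0):
        raise ValueError("k_dox and h must be > 0")
    kh = k_dox**h
    out = kh / (kh + dox**h)
    return float(out) if out.ndim == 0 else out


def dox_repression_mm_approx(dox, k_mm: float, leak: float):
    """Michaelis-Menten surrogate for the Doxycycline response.

    ``leak + (1 - leak) * k_mm / (k_mm + dox)``: a hyperbolic repression
    curve with a residual activity floor ``leak`` at saturating inducer.
    With the fitted Doxycycline Hill coefficient far below 1, the exact Hill
    response is nearly hyperbolic over the experimental working range but
    never shuts off completely; the leak term captures that.
    """
    dox = np.asarray(dox, dtype=float)
    if np.any(dox < 0):
        raise ValueError("dox must be >= 0")
    if not k_mm > 0:
        raise ValueError("k_mm must be > 0")
    if not (0 <= leak < 1):
        raise ValueError("leak must be in [0, 1)")
    out = leak + (1.0 - leak) * k_mm / (k_mm + dox)
    return float(out) if out.ndim == 0 else out


def fit_mm_approx(
    p: ParameterSet,
    dox_min: float = 0.1,
    dox_max: float = 100.0,
    num: int = 200,
) -> tuple[float, float, float]:
    """Least-squares (k_mm, leak) approximating the Hill Doxycycline response.

    Fits :func:`dox_repression_mm_approx` to :func:`dox_repression` on a
    log-spaced grid over the experimental working range and returns
    ``(k_mm, leak, max_abs_dev)``.
    """
    grid = np.geomspace(dox_min, dox_max, num)
    target = dox_repression(grid, p.k_dox, p.h)

    def resid(x):
        return dox_repression_mm_approx(grid, x[0], x[1]) - target

    sol = least_squares(resid, x0=[p.k_dox, 0.3], bounds=([1e-6, 0.0], [1e6, 0.999]))
    k_mm, leak = sol.x
    max_dev = float(np.max(np.abs(resid(sol.x))))
    return float(k_mm), float(leak), max_dev


def _hill_activation(u, theta: float, n: float):
    """Saturating promoter occupancy ``u^n / (theta^n + u^n)`` in [0, 1].

    Evaluated as ``1 / (1 + (theta/u)^n)`` so that extreme ``u^n`` never
    overflows; an overflowing ``(theta/u)^n`` saturates cleanly to 0 or 1.
    """
    u = np.asarray(u, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ratio_n = (theta / np.where(u > 0, u, np.nan)) ** n
        out = np.where(u > 0, 1.0 / (1.0 + ratio_n), 0.0)
    return out if out.ndim else float(out)


def _hill_activation_deriv(u: float, theta: float, n: float) -> float:
    # dH/du = (n/u) * H * (1-H); the product form never overflows for u > 0
    if u == 0.0:
        if n > 1:
            return 0.0
        if n == 1:
            return 1.0 / theta
        return np.inf
    hill = float(_hill_activation(u, theta, n))
    return n / u * hill * (1.0 - hill)


def transcription_rate(tta_active, p: ParameterSet):
    """CMV-TET transcription rate [nM/min] at active-tTA level ``tta_active``.

    ``v1 * (alpha0 + hill(tta_active))``: basal leakiness plus a Hill
    activation term; bounded in ``[v1*alpha0, v1*(alpha0 + 1)]``.
    """
    tta_active = np.asarray(tta_active, dtype=float)
    if np.any(tta_active < 0):
        raise ValueError("tta_active must be >= 0")
    out = p.v1 * (p.alpha0 + _hill_activation(tta_active, p.theta, p.n))
    return float(out) if np.ndim(out) == 0 else out


def _check_state(state, size: int) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (size,):
        raise ValueError(f"state must have shape ({size},), got {x.shape}")
    if np.any(x < 0):
        raise ValueError(f"state components must be >= 0, got {x}")
    return x


def _pfl_rhs(x: np.ndarray, w: float, p: ParameterSet) -> np.ndarray:
    """Unchecked PFL RHS; ``w`` is the precomputed Doxycycline factor."""
    x1, x2, x3, x4 = x
    tx = p.v1 * (p.alpha0 + _hill_activation(max(x2, 0.0) * w, p.theta, p.n))
    return np.array(
        [
            tx - p.d1 * x1,
            p.kp * x1 - p.d2 * x2,
            p.kp * x1 - (p.Kf + p.d3) * x3,
            p.Kf * x3 - p.d3 * x4,
        ]
    )


def _nopfl_rhs(x: np.ndarray, w: float, p: ParameterSet) -> np.ndarray:
    """Unchecked NOPFL RHS on the reduced state ``(x1, x3, x4)``."""
    x1, x3, x4 = x
    tx = p.v1 * (p.alpha0 + _hill_activation(p.rho_tTA * w, p.theta, p.n))
    return np.array(
        [
            tx - p.d1 * x1,
            p.kp * x1 - (p.Kf + p.d3) * x3,
            p.Kf * x3 - p.d3 * x4,
        ]
    )


def pfl_rhs(state, dox: float, p: ParameterSet) -> np.ndarray:
    """Time derivative of the PFL state ``(x1, x2, x3, x4)`` [nM/min]."""
    x = _check_state(state, 4)
    w = dox_repression(dox, p.k_dox, p.h)
    return _pfl_rhs(x, w, p)


def nopfl_rhs(state, dox: float, p: ParameterSet) -> np.ndarray:
    """Time derivative of the NOPFL state ``(x1, x3, x4)`` [nM/min].

    Linear time-invariant for fixed ``dox``: Doxycycline only changes the
    constant transcription input, never the dynamics.
    """
    x = _check_state(state, 3)
    w = dox_repression(dox, p.k_dox, p.h)
    return _nopfl_rhs(x, w, p)


def pfl_jacobian(state, dox: float, p: ParameterSet) -> np.ndarray:
    """Analytic Jacobian of :func:`pfl_rhs` at ``state``."""
    x = np.asarray(state, dtype=float)
    w = dox_repression(dox, p.k_dox, p.h)
    dtx_dx2 = p.v1 * w * _hill_activation_deriv(x[1] * w, p.theta, p.n)
    return np.array(
        [
            [-p.d1, dtx_dx2, 0.0, 0.0],
            [p.kp, -p.d2, 0.0, 0.0],
            [p.kp, 0.0, -(p.Kf + p.d3), 0.0],
            [0.0, 0.0, p.Kf, -p.d3],
        ]
    )


def nopfl_jacobian(p: ParameterSet) -> np.ndarray:
    """Constant Jacobian of the linear NOPFL system (state-independent)."""
    return np.array(
        [
            [-p.d1, 0.0, 0.0],
            [p.kp, -(p.Kf + p.d3), 0.0],
            [0.0, p.Kf, -p.d3],
        ]
    )


def observe(state, s_obs: float):
    """Fluorescence readout [a.u.]: ``s_obs`` times the folded reporter.

    Accepts a :class:`CircuitState`, a state vector or an array of state
    vectors (last axis = species); only the final component (folded d2EYFP)
    fluoresces.
    """
    x = np.asarray(state, dtype=float)
    out = s_obs * x[..., -1]
    return float(out) if out.ndim == 0 else out
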