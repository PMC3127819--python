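"""Stiff integration of the circuit models and the switch-off protocol.

The switch-off protocol mirrors the time-lapse experiment: cells grown
without Doxycycline sit at the model's ON steady state; at t=0 the inducer
is applied at a constant concentration and mean population fluorescence is
sampled on a uniform grid (default every 15 min for 43 h).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from . import equilibria as _eq
from .model import (
    CircuitState,
    _nopfl_rhs,
    _pfl_rhs,
    dox_repression,
    nopfl_jacobian,
    observe,
    pfl_jacobian,
)
from .params import ParameterSet
from .timecourse import TimeCourse

__all__ = ["steady_state", "integrate", "simulate_switch_off"]


def steady_state(
    network: str, dox: float, p: ParameterSet, branch: str = "ON"
) -> CircuitState:
    """Steady state of one network at a fixed Doxycycline level.

    For the feedback loop the ``branch`` selects the high- ("ON") or
    low-expression ("OFF") stable equilibrium; when the loop is monostable
    both branches return the unique equilibrium.  The open-loop system is
    linear with a single global steady state, so ``branch`` is ignored.
    Raises ``RuntimeError`` if no state meets the equilibrium residual bound.
    """
    network = network.upper()
    branch = branch.upper()
    if branch not in ("ON", "OFF"):
        raise ValueError(f"branch must be 'ON' or 'OFF', got {branch!r}")
    if network == "NOPFL":
        e = _eq.nopfl_equilibrium(dox, p)
        x1, x3, x4 = e.state
        state = CircuitState(x1=x1, x2=p.rho_tTA, x3=x3, x4=x4)
        rnorm = _eq.relative_rhs_norm(e.state, dox, p, "NOPFL")
    else:
        es = _eq.find_equilibria(dox, p)
        stable = sorted(es.stable(), key=lambda e: e.x2)
        if not stable:
            raise RuntimeError(
                f"no stable equilibrium found for PFL at dox={dox} "
                f"({len(es)} equilibria located)"
            )
        e = stable[-1] if branch == "ON" else stable[0]
        state = CircuitState(*e.state)
        rnorm = _eq.relative_rhs_norm(e.state, dox, p, "PFL")
    if rnorm > _eq.RHS_TOL:
        raise RuntimeError(
            f"steady-state residual {rnorm:.2e} exceeds {_eq.RHS_TOL} "
            f"(network={network}, dox={dox}, branch={branch})"
        )
    return state


def integrate(
    network: str,
    dox: float,
    p: ParameterSet,
    t_eval,
    x0=None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate one network at constant ``dox``; returns states (T, dim).

    ``x0`` defaults to the ON steady state of the untreated (dox=0) circuit,
    i.e. the initial condition of the switch-off protocol.  State dimension
    is 4 for the PFL and 3 (mRNA, unfolded, folded) for the NOPFL.
    """
    network = network.upper()
    t_eval = np.asarray(t_eval, dtype=float)
    w = dox_repression(dox, p.k_dox, p.h)
    if network == "PFL":
        rhs = lambda t, x: _pfl_rhs(x, w, p)  # noqa: E731
        jac = lambda t, x: pfl_jacobian(x, dox, p)  # noqa: E731
        dim = 4
    elif network == "NOPFL":
        rhs = lambda t, x: _nopfl_rhs(x, w, p)  # noqa: E731
        jac = lambda t, x: nopfl_jacobian(p)  # noqa: E731
        dim = 3
    else:
        raise ValueError(f"unknown network {network!r}")
    if x0 is None:
        ss = steady_state(network, 0.0, p, branch="ON")
        x0 = ss.to_array() if dim == 4 else np.array([ss.x1, ss.x3, ss.x4])
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (dim,):
        raise ValueError(f"x0 must have shape ({dim},), got {x0.shape}")
    sol = solve_ivp(
        rhs,
        (t_eval[0], t_eval[-1]),
        x0,
        method="LSODA",
        t_eval=t_eval,
        jac=jac,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return sol.y.T


def simulate_switch_off(
    network: str,
    dox: float,
    p: ParameterSet,
    duration: float = 2580.0,
    dt: float = 15.0,
    replicate_id: int = 0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TimeCourse:
    """Simulate the switch-off experiment and return sampled fluorescence.

    The initial state is always the ON steady state of the untreated circuit
    (the pre-treatment culture condition); ``dox`` is applied from t=0.
    """
    if not (duration > 0 and dt > 0):
        raise ValueError("duration and dt must be > 0")
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    states = integrate(network, dox, p, times, rtol=rtol, atol=atol)
    values = np.maximum(observe(states, p.s_obs), 0.0)
    return TimeCourse(
        network=network,
        dox=float(dox),
        replicate_id=replicate_id,
        times=times,
        values=values,
    )
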