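"""Equilibrium and bistability analysis of the feedback circuit.

The feedback lives entirely in the (mRNA, tTA) = (x1, x2) plane: the two
reporter states are linear, one-way readouts.  Equilibria are therefore
located on the exact scalar fixed-point reduction of that plane — the mRNA
nullcline substituted into the tTA nullcline — by dense bracketing
root-finding, then lifted back to the full four-state system.  With the
fitted parameters the loop is bistable (ON/OFF separated by a saddle-like
unstable point) at low Doxycycline and collapses to the single OFF state as
the inducer rises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import (
    _hill_activation,
    dox_repression,
    nopfl_jacobian,
    nopfl_rhs,
    pfl_jacobian,
    pfl_rhs,
    transcription_rate,
)
from .params import ParameterSet

__all__ = [
    "Equilibrium",
    "EquilibriumSet",
    "relative_rhs_norm",
    "nullclines",
    "find_equilibria",
    "classify_stability",
    "bifurcation_scan",
    "basin_of_attraction",
]

#: Relative residual bound below which a state counts as an equilibrium.
RHS_TOL = 1e-10


@dataclass
class Equilibrium:
    state: np.ndarray
    stability: str  # "stable" or "unstable"
    eigenvalues: np.ndarray = field(repr=False)

    @property
    def x2(self) -> float:
        return float(self.state[1])


@dataclass
class EquilibriumSet:
    """All equilibria of one network at one Doxycycline level."""

    network: str
    dox: float
    points: list[Equilibrium]

    @property
    def n_stable(self) -> int:
        return sum(1 for e in self.points if e.stability == "stable")

    @property
    def n_unstable(self) -> int:
        return sum(1 for e in self.points if e.stability == "unstable")

    def stable(self) -> list[Equilibrium]:
        return [e for e in self.points if e.stability == "stable"]

    def __len__(self) -> int:
        return len(self.points)


def relative_rhs_norm(state, dox: float, p: ParameterSet, network: str = "PFL") -> float:
    """Scale-free residual of the RHS: |dx_i/dt| over the term magnitudes.

    Each component's derivative is compared with the sum of the absolute
    production and loss terms feeding it, so the measure is invariant under
    rescaling of concentrations or time.
    """
    x = np.asarray(state, dtype=float)
    network = network.upper()
    if network == "PFL":
        f = pfl_rhs(x, dox, p)
        w = dox_repression(dox, p.k_dox, p.h)
        tx = transcription_rate(x[1] * w, p)
        scales = np.array(
            [
                tx + p.d1 * x[0],
                p.kp * x[0] + p.d2 * x[1],
                p.kp * x[0] + (p.Kf + p.d3) * x[2],
                p.Kf * x[2] + p.d3 * x[3],
            ]
        )
    else:
        f = nopfl_rhs(x, dox, p)
        w = dox_repression(dox, p.k_dox, p.h)
        tx = transcription_rate(p.rho_tTA * w, p)
        scales = np.array(
            [
                tx + p.d1 * x[0],
                p.kp * x[0] + (p.Kf + p.d3) * x[1],
                p.Kf * x[1] + p.d3 * x[2],
            ]
        )
    scales = np.maximum(scales, 1e-300)
    return float(np.max(np.abs(f) / scales))


def nullclines(dox: float, p: ParameterSet, x2_grid) -> pd.DataFrame:
    """The two nullclines of the reduced (tTA, mRNA) phase plane.

    Returns a frame with columns ``tta`` (the grid), ``mrna_dx1`` (mRNA level
    making dx1/dt = 0) and ``mrna_dx2`` (mRNA level making dx2/dt = 0).
    Intersections of the two curves are the equilibria of the loop.
    """
    x2 = np.asarray(x2_grid, dtype=float)
    if x2.size == 0 or np.any(x2 < 0):
        raise ValueError("x2_grid must be a nonempty array of nonnegative values")
    w = dox_repression(dox, p.k_dox, p.h)
    curve_a = transcription_rate(x2 * w, p) / p.d1
    curve_b = p.d2 * x2 / p.kp
    return pd.DataFrame({"tta": x2, "mrna_dx1": curve_a, "mrna_dx2": curve_b})


def _lift(x2: float, p: ParameterSet) -> np.ndarray:
    """Full equilibrium state implied by a tTA fixed point."""
    x1 = p.d2 * x2 / p.kp
    x3 = p.kp * x1 / (p.Kf + p.d3)
    x4 = p.Kf * x3 / p.d3
    return np.array([x1, x2, x3, x4])


def _fixed_point_residual(x2, w: float, p: ParameterSet):
    """g(x2) = K*(alpha0 + hill(w*x2)) - x2 with K = kp*v1/(d1*d2)."""
    gain = p.kp * p.v1 / (p.d1 * p.d2)
    return gain * (p.alpha0 + _hill_activation(np.asarray(x2) * w, p.theta, p.n)) - x2


def find_equilibria(dox: float, p: ParameterSet, grid_size: int = 4000) -> EquilibriumSet:
    """Locate and classify all PFL equilibria at one Doxycycline level.

    Roots of the scalar fixed-point equation are bracketed on a dense grid
    (log-spaced plus the origin) spanning the full attainable tTA range,
    refined with Brent's method, deduplicated within 1e-6 relative distance
    and lifted to the full state.
    """
    w = dox_repression(dox, p.k_dox, p.h)
    gain = p.kp * p.v1 / (p.d1 * p.d2)
    hi = gain * (p.alpha0 + 1.0) * (1.0 + 1e-9)
    lo = hi * 1e-14
    grid = np.concatenate([[0.0], np.geomspace(lo, hi, grid_size)])
    res = _fixed_point_residual(grid, w, p)

    roots: list[float] = []
    if res[0] == 0.0:  # origin equilibrium (alpha0 == 0)
        roots.append(0.0)
    for i in range(len(grid) - 1):
        a, b = res[i], res[i + 1]
        if a == 0.0 and grid[i] > 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0.0:
            root = brentq(
                _fixed_point_residual,
                grid[i],
                grid[i + 1],
                args=(w, p),
                xtol=1e-300,
                rtol=8.9e-16,
            )
            roots.append(float(root))

    # dedupe within relative distance 1e-6, keeping the smaller residual
    roots.sort()
    kept: list[float] = []
    for r in roots:
        if kept and abs(r - kept[-1]) <= 1e-6 * max(1e-30, abs(kept[-1])):
            if abs(_fixed_point_residual(r, w, p)) < abs(
                _fixed_point_residual(kept[-1], w, p)
            ):
                kept[-1] = r
        else:
            kept.append(r)

    points = []
    for x2 in kept:
        state = _lift(x2, p)
        label, eig = classify_stability(state, dox, p)
        points.append(Equilibrium(state=state, stability=label, eigenvalues=eig))
    return EquilibriumSet(network="PFL", dox=float(dox), points=points)


def nopfl_equilibrium(dox: float, p: ParameterSet) -> Equilibrium:
    """The unique (globally stable) equilibrium of the linear NOPFL system."""
    w = dox_repression(dox, p.k_dox, p.h)
    x1 = transcription_rate(p.rho_tTA * w, p) / p.d1
    x3 = p.kp * x1 / (p.Kf + p.d3)
    x4 = p.Kf * x3 / p.d3
    eig = np.array([-p.d1, -(p.Kf + p.d3), -p.d3])
    return Equilibrium(state=np.array([x1, x3, x4]), stability="stable", eigenvalues=eig)


def classify_stability(
    state, dox: float, p: ParameterSet, network: str = "PFL"
) -> tuple[str, np.ndarray]:
    """Linear stability of an equilibrium from the analytic Jacobian.

    Raises ``ValueError`` when the supplied state is not an equilibrium
    (relative RHS residual above ``RHS_TOL``).
    """
    network = network.upper()
    rnorm = relative_rhs_norm(state, dox, p, network)
    if rnorm > RHS_TOL:
        raise ValueError(
            f"state is not an equilibrium (relative RHS norm {rnorm:.2e} > {RHS_TOL})"
        )
    if network == "PFL":
        jac = pfl_jacobian(state, dox, p)
    else:
        jac = nopfl_jacobian(p)
    eig = np.linalg.eigvals(jac)
    label = "stable" if np.all(eig.real < -1e-12) else "unstable"
    return label, eig


def bifurcation_scan(dox_values, p: ParameterSet) -> pd.DataFrame:
    """Equilibrium counts per Doxycycline level (bistable -> monostable)."""
    dox_values = np.atleast_1d(np.asarray(dox_values, dtype=float))
    if dox_values.size == 0:
        raise ValueError("dox_values must be nonempty")
    rows = []
    for dox in dox_values:
        es = find_equilibria(float(dox), p)
        rows.append(
            {
                "dox_nM": float(dox),
                "n_equilibria": len(es),
                "n_stable": es.n_stable,
                "n_unstable": es.n_unstable,
            }
        )
    return pd.DataFrame(rows)


def _reduced_rhs(t, x, w, p):
    x1, x2 = x
    tx = p.v1 * (p.alpha0 + _hill_activation(max(x2, 0.0) * w, p.theta, p.n))
    return [tx - p.d1 * x1, p.kp * x1 - p.d2 * x2]


def basin_of_attraction(
    dox: float,
    p: ParameterSet,
    tta_grid,
    mrna_grid,
    capture_radius: float = 1e-3,
    max_time: float = 2e5,
    chunk: float = 2000.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Label each (mRNA, tTA) lattice point by the stable equilibrium it reaches.

    Trajectories of the reduced plane are integrated in chunks until they come
    within ``capture_radius`` (relative) of a stable equilibrium; points that
    never converge within ``max_time`` are labelled ``"undetermined"``.
    Returns the long-format lattice and the basin area fractions.
    """
    es = find_equilibria(dox, p)
    stable = es.stable()
    names = {}
    by_x2 = sorted(stable, key=lambda e: e.x2)
    if len(by_x2) == 1:
        names[0] = "OFF" if by_x2[0].x2 < p.theta else "ON"
    else:
        names = {0: "OFF", len(by_x2) - 1: "ON"}
        for i in range(1, len(by_x2) - 1):
            names[i] = f"EQ{i}"
    targets = [(names[i], np.array([e.state[0], e.state[1]])) for i, e in enumerate(by_x2)]
    w = dox_repression(dox, p.k_dox, p.h)

    def capture(xy):
        for label, tgt in targets:
            if np.linalg.norm(xy - tgt) <= capture_radius * (1.0 + np.linalg.norm(tgt)):
                return label
        return None

    rows = []
    for mrna in np.asarray(mrna_grid, dtype=float):
        for tta in np.asarray(tta_grid, dtype=float):
            xy = np.array([mrna, tta])
            label = capture(xy)
            t_done = 0.0
            while label is None and t_done < max_time:
                sol = solve_ivp(
                    _reduced_rhs,
                    (0.0, chunk),
                    xy,
                    method="LSODA",
                    args=(w, p),
                    rtol=1e-8,
                    atol=1e-12,
                )
                if not sol.success:
                    break
                xy = sol.y[:, -1]
                t_done += chunk
                label = capture(xy)
            rows.append(
                {"tta": tta, "mrna": mrna, "label": label or "undetermined"}
            )
    lattice = pd.DataFrame(rows)
    fractions = lattice["label"].value_counts(normalize=True).to_dict()
    return lattice, fractions
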