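"""Synthetic switch-off and decay experiments with replicate-level noise.

The generator reproduces the statistical structure of the time-lapse study:
43 h switch-off courses sampled every 15 min, four Doxycycline conditions
with 2/2/3/5 replicates each, for both the feedback (PFL) and open-loop
(NOPFL) circuits — 24 courses in total.  Replicate noise is multiplicative
lognormal (default 10% CV) plus a small additive floor (1% of the course
maximum), independent across time points; the noiseless mean is exactly the
output of :func:`tetswitch.simulate.simulate_switch_off`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterSet
from .simulate import simulate_switch_off
from .timecourse import TimeCourse

__all__ = ["ExperimentDesign", "generate_experiment", "generate_decay_experiment"]


@dataclass
class ExperimentDesign:
    """Layout and noise model of one synthetic switch-off campaign."""

    dox_levels: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    replicates: tuple[int, ...] = (2, 2, 3, 5)
    networks: tuple[str, ...] = ("PFL", "NOPFL")
    duration: float = 2580.0  # 43 h [min]
    dt: float = 15.0  # sampling interval [min]
    noise_cv: float = 0.10  # lognormal coefficient of variation
    noise_floor_frac: float = 0.01  # additive sd as fraction of course max
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.dox_levels) != len(self.replicates):
            raise ValueError("replicates must align one-to-one with dox_levels")
        if any(r < 1 for r in self.replicates):
            raise ValueError("each condition needs at least one replicate")
        if self.noise_cv < 0 or self.noise_floor_frac < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def n_courses(self) -> int:
        return len(self.networks) * sum(self.replicates)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_experiment(
    p: ParameterSet,
    design: ExperimentDesign | None = None,
    seed: int | None = None,
) -> tuple[list[TimeCourse], pd.DataFrame]:
    """Generate one synthetic switch-off campaign.

    Returns the list of noisy time-courses and the per-point replicate
    sample-variance table (columns ``network, dox_nM, time_min, variance``)
    that the chi-square objective weights residuals with.
    """
    design = design or ExperimentDesign()
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    courses: list[TimeCourse] = []
    var_rows = []
    for network in design.networks:
        for dox, n_rep in zip(design.dox_levels, design.replicates):
            mean_tc = simulate_switch_off(
                network, dox, p, duration=design.duration, dt=design.dt
            )
            mean = mean_tc.values
            floor_sd = design.noise_floor_frac * mean.max()
            reps = np.empty((n_rep, len(mean)))
            for r in range(n_rep):
                y = mean * _lognormal_factors(rng, design.noise_cv, len(mean))
                if floor_sd > 0 and design.noise_cv > 0:
                    y = y + rng.normal(0.0, floor_sd, size=len(mean))
                y = np.maximum(y, 0.0)
                reps[r] = y
                courses.append(
                    TimeCourse(
                        network=network,
                        dox=dox,
                        replicate_id=r,
                        times=mean_tc.times.copy(),
                        values=y,
                    )
                )
            variance = reps.var(axis=0, ddof=1) if n_rep > 1 else np.zeros(len(mean))
            for t, v in zip(mean_tc.times, variance):
                var_rows.append(
                    {
                        "network": network,
                        "dox_nM": float(dox),
                        "time_min": float(t),
                        "variance": float(v),
                    }
                )
    return courses, pd.DataFrame(var_rows)


def generate_decay_experiment(
    delta: float,
    amplitude: float = 100.0,
    duration: float = 750.0,
    dt: float = 15.0,
    n_replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int | None = None,
) -> list[TimeCourse]:
    """Synthetic cycloheximide-chase decay courses ``A*exp(-delta*t)``.

    Emulates the reporter half-life experiment: translation is blocked at
    t=0 and fluorescence decays exponentially at the protein degradation
    rate, followed for 750 min at 15-min sampling in replicate.
    """
    if not delta > 0:
        raise ValueError("delta must be > 0")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    mean = amplitude * np.exp(-delta * times)
    courses = []
    for r in range(n_replicates):
        y = mean * _lognormal_factors(rng, noise_cv, len(mean))
        courses.append(
            TimeCourse(
                network="NOPFL",
                dox=0.0,
                replicate_id=r,
                times=times.copy(),
                values=np.maximum(y, 0.0),
            )
        )
    return courses
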