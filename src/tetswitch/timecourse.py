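"""The TimeCourse container: one replicate's sampled fluorescence trajectory."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeCourse", "NETWORKS"]

NETWORKS = ("PFL", "NOPFL")


@dataclass
class TimeCourse:
    """One fluorescence time-course.

    Attributes
    ----------
    network : str
        ``"PFL"`` or ``"NOPFL"``.
    dox : float
        Doxycycline concentration applied at t=0 [nM].
    replicate_id : int
        Replicate index within the (network, dox) condition.
    times : ndarray
        Sampling times [min], strictly increasing on a uniform grid.
    values : ndarray
        Mean population fluorescence [a.u.], finite and >= 0.
    """

    network: str
    dox: float
    replicate_id: int
    times: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.network = str(self.network).upper()
        if self.network not in NETWORKS:
            raise ValueError(f"network must be one of {NETWORKS}, got {self.network!r}")
        if self.dox < 0:
            raise ValueError("dox must be >= 0")
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise ValueError("a time-course needs at least two samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ValueError("times must lie on a uniform grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values < 0):
            raise ValueError("values must be >= 0")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def key(self) -> tuple[str, float, int]:
        return (self.network, float(self.dox), int(self.replicate_id))
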