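"""Model constants for the Tet-OFF feedback circuit.

A :class:`ParameterSet` holds the twelve kinetic constants of the positive
feedback loop (PFL) and its open-loop control (NOPFL) plus the observation
scaling factor that converts folded-reporter concentration (nM) into the
arbitrary fluorescence units reported by the microscope.  Units are nM and
minutes throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["ParameterSet", "PARAM_NAMES", "load_params", "table1_params"]

#: Canonical ordering of the model constants (12 kinetic + 1 observation).
PARAM_NAMES = (
    "theta",
    "alpha0",
    "v1",
    "kp",
    "d1",
    "d2",
    "d3",
    "n",
    "k_dox",
    "h",
    "Kf",
    "rho_tTA",
    "s_obs",
)


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic constants of the PFL/NOPFL circuit models.

    Attributes
    ----------
    theta : float
        Activation coefficient of the CMV-TET promoter [nM].
    alpha0 : float
        Basal (leaky) activity of the CMV-TET promoter, as a fraction of the
        maximal transcription rate [-].
    v1 : float
        Maximal transcription rate of the CMV-TET promoter [nM/min].
    kp : float
        General translation rate, shared by both proteins translated from the
        bicistronic (IRES) transcript [1/min].
    d1, d2, d3 : float
        First-order degradation rates of the mRNA, the tTA protein and the
        d2EYFP reporter protein [1/min].
    n : float
        Hill coefficient of the CMV-TET promoter [-].
    k_dox : float
        Half-repression Doxycycline concentration [nM].
    h : float
        Hill coefficient of the Doxycycline response [-].
    Kf : float
        Folding (maturation) rate of the reporter [1/min].
    rho_tTA : float
        Constant tTA protein level in the open-loop (NOPFL) circuit [nM].
    s_obs : float
        Observation scaling factor [fluorescence a.u. per nM].
    """

    theta: float
    alpha0: float
    v1: float
    kp: float
    d1: float
    d2: float
    d3: float
    n: float
    k_dox: float
    h: float
    Kf: float
    rho_tTA: float
    s_obs: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha0 < 0:
            raise ValueError(f"alpha0 must be >= 0, got {self.alpha0}")
        for name in PARAM_NAMES:
            if name == "alpha0":
                continue
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"parameter {name} must be > 0, got {value}")

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - {"s_obs"} - set(mapping)
        if missing:
            raise ValueError(f"missing parameter(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


def load_params(path: str | Path) -> ParameterSet:
    """Load a :class:`ParameterSet` from a flat YAML/JSON key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: expected a flat key/value mapping")
    return ParameterSet.from_mapping(raw)


def table1_params() -> ParameterSet:
    """The packaged best-fit parameter set for the CHO Tet-OFF circuit."""
    ref = resources.files("tetswitch").joinpath("data/table1_params.yaml")
    raw = yaml.safe_load(ref.read_text())
    return ParameterSet.from_mapping(raw)
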