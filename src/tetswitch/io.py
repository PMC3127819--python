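"""Tabular I/O and configuration handling shared by all subcommands.

Time-courses travel as a single CSV dialect (comma separator, dot decimal,
mandatory header ``network,dox_nM,replicate,time_min,fluorescence``).
Leading ``# key: value`` comment lines carry provenance (seed, config) and
are ignored on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .timecourse import TimeCourse

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "read_variances",
    "write_variances",
    "load_config",
]

TIMECOURSE_COLUMNS = ["network", "dox_nM", "replicate", "time_min", "fluorescence"]


def _write_header(fh, metadata: Mapping[str, object] | None) -> None:
    for key, value in (metadata or {}).items():
        fh.write(f"# {key}: {value}\n")


def write_timecourses(
    path: str | Path,
    courses: Iterable[TimeCourse],
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write time-courses as CSV with optional provenance header lines."""
    frames = []
    for tc in courses:
        frames.append(
            pd.DataFrame(
                {
                    "network": tc.network,
                    "dox_nM": tc.dox,
                    "replicate": tc.replicate_id,
                    "time_min": tc.times,
                    "fluorescence": tc.values,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        _write_header(fh, metadata)
        table.to_csv(fh, index=False)


def read_timecourses(path: str | Path) -> list[TimeCourse]:
    """Read and validate time-courses from the package CSV dialect.

    Rows may appear in any order; courses are grouped on
    (network, dox, replicate).  Malformed rows, non-uniform grids and
    negative fluorescence raise descriptive errors naming the offender.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, comment="#")
    except Exception as err:
        raise ValueError(f"{path}: cannot parse CSV ({err})") from err
    missing = set(TIMECOURSE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("dox_nM", "time_min", "fluorescence"):
        bad = table[pd.to_numeric(table[col], errors="coerce").isna()]
        if len(bad):
            line = int(bad.index[0]) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric {col!r} near line {line}")
        table[col] = pd.to_numeric(table[col])
    courses = []
    for (network, dox, rep), grp in table.groupby(
        ["network", "dox_nM", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(dtype=float)
        values = grp["fluorescence"].to_numpy(dtype=float)
        label = f"course (network={network}, dox={dox}, replicate={rep})"
        steps = np.diff(times)
        if len(times) < 2:
            raise ValueError(f"{path}: {label} has fewer than two samples")
        if np.any(steps <= 0):
            raise ValueError(f"{path}: {label} has duplicate or unordered times")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ValueError(f"{path}: {label} is not on a uniform time grid")
        try:
            courses.append(
                TimeCourse(
                    network=str(network),
                    dox=float(dox),
                    replicate_id=int(rep),
                    times=times,
                    values=values,
                )
            )
        except ValueError as err:
            raise ValueError(f"{path}: {label}: {err}") from err
    return courses


def write_variances(
    path: str | Path,
    variances: pd.DataFrame,
    metadata: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, metadata)
        variances.to_csv(fh, index=False)


def read_variances(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#")
    expected = {"network", "dox_nM", "time_min", "variance"}
    missing = expected - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return table


def load_config(path: str | Path) -> dict:
    """Load a flat YAML/JSON configuration mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return raw
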