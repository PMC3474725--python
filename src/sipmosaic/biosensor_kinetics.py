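"""Whole-cell biosensor kinetics: normalization and induction-onset calls.

A biosensor-based gene transducer reports pathway function as light: if
the cloned gene cluster converts the fed substrate into the reporter's
inducer, luminescence rises within minutes.  The quantitative readout is
*relative bioluminescence* -- raw luminescence divided by cell density
(OD600) per well and time point -- compared between induced wells and
vehicle controls on the same time grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

NOT_INDUCED = "NOT_INDUCED"

CONDITIONS = ("induced", "vehicle_control")


class DataError(ValueError):
    """Unusable well (e.g. non-positive OD)."""


@dataclass(frozen=True)
class KineticSeries:
    """One well's time course: minutes, luminescence (a.u.), OD600."""

    well_id: str
    times: np.ndarray
    luminescence: np.ndarray
    od: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        lum = np.asarray(self.luminescence, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if not (len(t) == len(lum) == len(od)):
            raise ValueError(f"well {self.well_id}: vectors differ in length")
        if len(t) == 0:
            raise ValueError(f"well {self.well_id}: empty series")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"well {self.well_id}: times must strictly increase")
        if np.any(lum < 0):
            raise DataError(f"well {self.well_id}: negative luminescence")
        if np.any(od <= 0):
            raise DataError(f"well {self.well_id}: OD must be positive everywhere")
        if self.condition not in CONDITIONS:
            raise ValueError(f"well {self.well_id}: unknown condition {self.condition!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "luminescence", lum)
        object.__setattr__(self, "od", od)


def relative_bioluminescence(series: KineticSeries) -> np.ndarray:
    """Luminescence / OD, elementwise (the density-normalized readout)."""
    return series.luminescence / series.od


def average_replicates(wells: Sequence[KineticSeries]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and standard deviation of normalized replicate wells.

    Returns (times, mean, sd); all wells must share one time grid.
    """
    if not wells:
        raise ValueError("no replicate wells supplied")
    t0 = wells[0].times
    for w in wells[1:]:
        if len(w.times) != len(t0) or np.any(w.times != t0):
            raise ValueError("replicate wells are on different time grids")
    values = np.vstack([relative_bioluminescence(w) for w in wells])
    return t0, values.mean(axis=0), values.std(axis=0, ddof=0)


def call_induction(
    times: np.ndarray,
    induced: np.ndarray,
    control: np.ndarray,
    fold_threshold: float = 2.0,
) -> float | str:
    """Earliest onset time where induced >= fold_threshold * control at two
    consecutive points (two points guard against single-sample spikes).

    Returns the onset time in minutes, or NOT_INDUCED.
    """
    times = np.asarray(times, dtype=float)
    induced = np.asarray(induced, dtype=float)
    control = np.asarray(control, dtype=float)
    if not (len(times) == len(induced) == len(control)):
        raise ValueError("mismatched time grids")
    above = induced >= fold_threshold * control
    for i in range(len(times) - 1):
        if above[i] and above[i + 1]:
            return float(times[i])
    return NOT_INDUCED


# ---------------------------------------------------------------------------
# plate-reader I/O (long-format CSV: well,time_min,lum,od600,condition)

def read_plate_csv(path) -> list[KineticSeries]:
    df = pd.read_csv(path)
    required = {"well", "time_min", "lum", "od600", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    wells = []
    for well_id, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("time_min")
        cond = grp["condition"].iloc[0]
        wells.append(
            KineticSeries(
                str(well_id),
                grp["time_min"].to_numpy(),
                grp["lum"].to_numpy(),
                grp["od600"].to_numpy(),
                str(cond),
            )
        )
    return wells


def normalized_to_csv(wells: Sequence[KineticSeries]) -> str:
    rows = ["well,condition,time_min,relative_bioluminescence"]
    for w in wells:
        for t, v in zip(w.times, relative_bioluminescence(w)):
            rows.append(f"{w.well_id},{w.condition},{t:g},{v:g}")
    return "\n".join(rows) + "\n"
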