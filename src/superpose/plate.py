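"""Plate-reader tables, plate maps, and per-well time series.

The canonical on-disk dialect is a *wide* CSV with one ``time_min`` column
and two columns per well, suffixed ``.od`` and ``.fluo`` (e.g. ``A1.od``,
``A1.fluo``).  A separate plate-map CSV assigns each well a promoter, a
condition set ("+"-joined supplement labels, empty string = base medium),
a replicate day and a background-control flag.  Both readers accept
gzip-compressed files transparently (pandas dispatches on the extension).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConditionSet",
    "PlateSeries",
    "read_plate_table",
    "write_plate_table",
    "subtract_background",
]


@dataclass(frozen=True, order=True)
class ConditionSet:
    """A set of medium supplements, canonicalized to sorted unique labels.

    ``ConditionSet("B", "A") == ConditionSet("A", "B")``; the empty set
    denotes the base medium.  Hashable, so usable as a dict key.
    """

    labels: tuple[str, ...]

    def __init__(self, *labels: str | Iterable[str]):
        flat: list[str] = []
        for item in labels:
            if isinstance(item, str):
                flat.append(item)
            else:
                flat.extend(item)
        if len(set(flat)) != len(flat):
            raise ValueError(f"duplicate supplement labels in {flat!r}")
        object.__setattr__(self, "labels", tuple(sorted(flat)))

    @classmethod
    def parse(cls, text: str, sep: str = "+") -> "ConditionSet":
        """Parse a "+"-joined label string; '' or NaN gives the empty set."""
        if text is None or (isinstance(text, float) and np.isnan(text)):
            return cls()
        text = str(text).strip()
        if not text:
            return cls()
        return cls(*[p.strip() for p in text.split(sep) if p.strip()])

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __str__(self) -> str:
        return "+".join(self.labels)

    def subsets(self, size: int) -> list["ConditionSet"]:
        """All sub-cocktails of a given size, in canonical order."""
        from itertools import combinations

        return [ConditionSet(*c) for c in combinations(self.labels, size)]

    def without(self, label: str) -> "ConditionSet":
        if label not in self.labels:
            raise KeyError(label)
        return ConditionSet(*[l for l in self.labels if l != label])


@dataclass
class PlateSeries:
    """Raw OD600/fluorescence time series for one well.

    Attributes
    ----------
    well_id : str
        Plate-reader well coordinate (e.g. ``"A1"``).
    promoter : str
        Reporter-strain promoter name; promoterless controls use their own
        label (conventionally ``"control"``).
    condition_set : ConditionSet
        Supplements mixed into the base medium for this well.
    replicate_day : int
        Day label distinguishing biological replicates.
    time_min : ndarray
        Sampling times in minutes, strictly increasing.
    od : ndarray
        Optical density at 600 nm; non-negative.
    fluo : ndarray
        GFP fluorescence (535 nm), same length as ``time_min``.
    is_background_control : bool
        True for the promoterless-vector well used for background
        subtraction within its condition/day group.
    """

    well_id: str
    promoter: str
    condition_set: ConditionSet
    replicate_day: int
    time_min: np.ndarray
    od: np.ndarray
    fluo: np.ndarray
    is_background_control: bool = False

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        self.fluo = np.asarray(self.fluo, dtype=float)
        n = self.time_min.size
        if self.od.size != n or self.fluo.size != n:
            raise ValueError(
                f"well {self.well_id}: od/fluo lengths "
                f"({self.od.size}, {self.fluo.size}) != time length {n}"
            )
        if n >= 2 and not np.all(np.diff(self.time_min) > 0):
            raise ValueError(f"well {self.well_id}: time_min not strictly increasing")
        if np.any(self.od < 0):
            raise ValueError(f"well {self.well_id}: negative OD values")

    def __len__(self) -> int:
        return self.time_min.size


def read_plate_table(path, plate_map) -> list[PlateSeries]:
    """Read a wide plate CSV plus its plate-map CSV into PlateSeries.

    Parameters
    ----------
    path : path-like
        Wide CSV: ``time_min`` column plus ``<well>.od`` / ``<well>.fluo``
        column pairs.
    plate_map : path-like or DataFrame
        Columns ``well, promoter, conditions, day, is_control``.

    Raises
    ------
    ValueError
        If a mapped well is missing from the table (named in the message),
        a table well is absent from the map, or time is non-monotone.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    if "time_min" not in table.columns:
        raise ValueError(f"{path}: plate table lacks a 'time_min' column")
    pmap = plate_map if isinstance(plate_map, pd.DataFrame) else pd.read_csv(plate_map)
    required = {"well", "promoter", "conditions", "day", "is_control"}
    missing_cols = required - set(pmap.columns)
    if missing_cols:
        raise ValueError(f"plate map missing columns: {sorted(missing_cols)}")

    table_wells = {
        c.rsplit(".", 1)[0] for c in table.columns if c.endswith((".od", ".fluo"))
    }
    time = table["time_min"].to_numpy(dtype=float)
    if time.size >= 2 and not np.all(np.diff(time) > 0):
        raise ValueError(f"{path}: non-monotone time_min column")

    out: list[PlateSeries] = []
    for row in pmap.itertuples(index=False):
        well = str(row.well)
        od_col, fl_col = f"{well}.od", f"{well}.fluo"
        if od_col not in table.columns or fl_col not in table.columns:
            raise ValueError(f"well {well!r} in plate map has no columns in plate table")
        out.append(
            PlateSeries(
                well_id=well,
                promoter=str(row.promoter),
                condition_set=ConditionSet.parse(row.conditions),
                replicate_day=int(row.day),
                time_min=time,
                od=table[od_col].to_numpy(dtype=float),
                fluo=table[fl_col].to_numpy(dtype=float),
                is_background_control=bool(row.is_control),
            )
        )
    unmapped = table_wells - set(pmap["well"].astype(str))
    if unmapped:
        raise ValueError(f"plate table wells absent from map: {sorted(unmapped)}")
    return out


def write_plate_table(series: Sequence[PlateSeries], table_path, map_path) -> None:
    """Write PlateSeries sharing one time grid to the wide CSV dialect."""
    if not series:
        raise ValueError("no series to write")
    time = series[0].time_min
    for s in series:
        if s.time_min.size != time.size or not np.allclose(s.time_min, time):
            raise ValueError("write_plate_table requires a shared time grid")
    cols: dict[str, np.ndarray] = {"time_min": time}
    rows = []
    for s in series:
        cols[f"{s.well_id}.od"] = s.od
        cols[f"{s.well_id}.fluo"] = s.fluo
        rows.append(
            {
                "well": s.well_id,
                "promoter": s.promoter,
                "conditions": str(s.condition_set),
                "day": s.replicate_day,
                "is_control": s.is_background_control,
            }
        )
    # %.17g guarantees float round-trip through the text format
    pd.DataFrame(cols).to_csv(table_path, index=False, float_format="%.17g")
    pd.DataFrame(rows).to_csv(map_path, index=False)


def subtract_background(
    series: PlateSeries, control: PlateSeries, clip_negative: bool = False
) -> PlateSeries:
    """Subtract promoterless-control fluorescence from a reporter well.

    The control is linearly interpolated onto the series' time grid when
    the grids differ.  Negative values are retained by default so the
    derivative stage sees unbiased noise; ``clip_negative=True`` floors the
    result at zero.  OD is untouched.
    """
    if not control.is_background_control:
        raise ValueError(f"well {control.well_id} is not flagged as a background control")
    lo = max(series.time_min[0], control.time_min[0])
    hi = min(series.time_min[-1], control.time_min[-1])
    span = series.time_min[-1] - series.time_min[0]
    if span > 0 and (hi - lo) < 0.5 * span:
        raise ValueError(
            f"control well {control.well_id} overlaps <50% of well {series.well_id}"
        )
    if control.time_min.size == series.time_min.size and np.allclose(
        control.time_min, series.time_min
    ):
        bg = control.fluo
    else:
        bg = np.interp(series.time_min, control.time_min, control.fluo)
    fluo = series.fluo - bg
    if clip_negative:
        fluo = np.maximum(fluo, 0.0)
    return replace(series, fluo=fluo)
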