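"""Time-series container and CSV I/O.

The observational interface between the agent-based simulator and the
state-space forecasting code is a plain table: one row per time step,
integer ``time`` index, numeric columns.  Simulator output uses the fixed
schema ``time,Quiet,Active,Jailed,Legitimacy,Propaganda``; synthetic test
series may carry arbitrary numeric columns.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

#: canonical column order of simulator output
ABM_COLUMNS = ("Quiet", "Active", "Jailed", "Legitimacy", "Propaganda")


class TimeSeriesTable:
    """A time-indexed table of observations.

    Parameters
    ----------
    frame:
        DataFrame with a ``time`` column (or an integer index named
        ``time``) and one or more numeric columns.
    validate:
        ``"basic"`` checks only the time axis (strictly increasing,
        consecutive, integer).  ``"abm"`` additionally enforces the
        simulator schema: the three citizen-state counts are non-negative
        integers summing to a constant population, legitimacy lies in
        (0, 1] and propaganda in [0, 1].
    """

    def __init__(self, frame: pd.DataFrame, validate: str = "basic"):
        frame = frame.copy()
        if "time" in frame.columns:
            frame = frame.set_index("time")
        frame.index.name = "time"
        self.frame = frame
        self._check_time_axis()
        if validate == "abm":
            self._check_abm_schema()
        elif validate != "basic":
            raise ValueError(f"unknown validation mode {validate!r}")

    # -- validation ------------------------------------------------------
    def _check_time_axis(self) -> None:
        t = np.asarray(self.frame.index)
        if len(t) == 0:
            raise FormatError("table has no rows")
        if not np.issubdtype(t.dtype, np.integer):
            if not np.allclose(t, np.round(t)):
                raise FormatError("time stamps must be integers")
            t = t.astype(np.int64)
            self.frame.index = pd.Index(t, name="time")
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise FormatError(f"time not strictly increasing at row {row}")
        if np.any(dt != 1):
            row = int(np.argmax(dt != 1)) + 1
            raise FormatError(f"time axis has a gap at row {row}")

    def _check_abm_schema(self) -> None:
        for col in ABM_COLUMNS:
            if col not in self.frame.columns:
                raise FormatError(f"missing required column {col!r}")
        counts = self.frame[["Quiet", "Active", "Jailed"]].to_numpy()
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise FormatError("citizen counts must be non-negative integers")
        totals = counts.sum(axis=1)
        if not np.all(totals == totals[0]):
            raise FormatError("Quiet + Active + Jailed must be constant")
        leg = self.frame["Legitimacy"].to_numpy(float)
        if np.any((leg <= 0) | (leg > 1)):
            raise FormatError("Legitimacy must lie in (0, 1]")
        prop = self.frame["Propaganda"].to_numpy(float)
        if np.any((prop < 0) | (prop > 1)):
            raise FormatError("Propaganda must lie in [0, 1]")

    # -- accessors -------------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.frame.index, dtype=np.int64)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)

    def column(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise FormatError(f"missing required column {name!r}")
        return self.frame[name].to_numpy(dtype=float)

    def rows(self, first: int, last: int) -> "TimeSeriesTable":
        """Inclusive 1-based positional row range."""
        if not (1 <= first <= last <= len(self)):
            raise FormatError(f"row range ({first}, {last}) out of bounds")
        return TimeSeriesTable(self.frame.iloc[first - 1 : last].reset_index())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeSeriesTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    def __repr__(self) -> str:
        return (
            f"TimeSeriesTable({len(self)} steps, "
            f"columns={list(self.frame.columns)})"
        )


def table_from_columns(
    columns: dict[str, Sequence[float]], start_time: int = 1
) -> TimeSeriesTable:
    """Build a table from equal-length column vectors."""
    n = len(next(iter(columns.values())))
    frame = pd.DataFrame(columns)
    frame.insert(0, "time", np.arange(start_time, start_time + n))
    return TimeSeriesTable(frame)


def read_timeseries(path, columns: Iterable[str] | None = ABM_COLUMNS) -> TimeSeriesTable:
    """Read a CSV table.

    ``columns`` lists the columns that must be present (default: the
    simulator schema).  Pass ``columns=None`` to accept any numeric table.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if "time" not in frame.columns:
        raise FormatError(f"{path}: missing required column 'time'")
    if len(frame) == 0:
        raise FormatError(f"{path}: header only, no data rows")
    for col in columns or ():
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return TimeSeriesTable(frame)


def write_timeseries(table: TimeSeriesTable, path) -> None:
    """Write a table as CSV (inverse of :func:`read_timeseries`)."""
    frame = table.frame.reset_index()
    frame.to_csv(path, index=False)
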