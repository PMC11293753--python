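"""Generalized state-space embedding.

A state vector at time *t* collects lagged observations
``(col_1(t - lag_1), ..., col_E(t - lag_E))`` of one or more observed
variables.  Only non-negative lags are admitted: every coordinate is a
past or present observation, so a library row at time *t* can never see
data recorded after *t*.  The collection of all valid state vectors,
together with the value of the target variable ``Tp`` steps ahead of each
row, is the state-space library — the entire process model used for
forecasting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EmptyLibraryError
from .timeseries import TimeSeriesTable


@dataclass(frozen=True)
class EmbeddingSpec:
    """Which lagged observations form a state vector, and what to predict.

    Parameters
    ----------
    coordinates:
        Ordered ``(column, lag)`` pairs; lag is in steps, ``lag >= 0``.
    target:
        Column predicted ``Tp`` steps ahead of each state vector.
    Tp:
        Prediction horizon in steps, ``Tp >= 1``.
    """

    coordinates: tuple[tuple[str, int], ...]
    target: str
    Tp: int = 1

    def __post_init__(self):
        object.__setattr__(self, "coordinates", tuple(
            (str(c), int(lag)) for c, lag in self.coordinates
        ))
        if self.E < 1:
            raise ConfigurationError("embedding needs at least one coordinate")
        if any(lag < 0 for _, lag in self.coordinates):
            raise ConfigurationError("lags must be >= 0 (past observations only)")
        if self.Tp < 1:
            raise ConfigurationError("prediction horizon Tp must be >= 1")

    @property
    def E(self) -> int:
        """Embedding dimension: the number of coordinates."""
        return len(self.coordinates)

    @property
    def max_lag(self) -> int:
        return max(lag for _, lag in self.coordinates)

    @property
    def labels(self) -> list[str]:
        return [f"{col}(t-{lag})" for col, lag in self.coordinates]

    @classmethod
    def univariate(cls, column: str, E: int, Tp: int = 1) -> "EmbeddingSpec":
        """Classic delay embedding: lags ``0 .. E-1`` of one column."""
        return cls(tuple((column, lag) for lag in range(E)), column, Tp)


def default_embedding(Tp: int = 5) -> EmbeddingSpec:
    """The 6-D generalized embedding used for Active forecasts:
    Quiet and Jailed at lags 0, 2 and 4, target Active."""
    coords = tuple(
        (col, lag) for col in ("Quiet", "Jailed") for lag in (0, 2, 4)
    )
    return EmbeddingSpec(coords, target="Active", Tp=Tp)


@dataclass
class StateSpaceLibrary:
    """Matrix of embedded state vectors plus per-row target futures.

    ``target_futures[i]`` holds ``target(row_times[i] + Tp)`` and is NaN
    when that time exceeds the data.  Rows are in time order.
    """

    rows: np.ndarray            # (k_N, E)
    row_times: np.ndarray       # (k_N,) int
    target_futures: np.ndarray  # (k_N,) float, NaN when beyond the data
    spec: EmbeddingSpec = field(repr=False)

    @property
    def k_N(self) -> int:
        return self.rows.shape[0]

    @property
    def E(self) -> int:
        return self.rows.shape[1]

    @property
    def has_future(self) -> np.ndarray:
        """Boolean mask of rows whose target future is defined."""
        return np.isfinite(self.target_futures)

    @property
    def n_prediction_rows(self) -> int:
        return int(self.has_future.sum())

    def select_times(self, first: int, last: int) -> "StateSpaceLibrary":
        """Sub-library of rows with ``first <= time <= last`` (inclusive)."""
        mask = (self.row_times >= first) & (self.row_times <= last)
        return StateSpaceLibrary(
            self.rows[mask], self.row_times[mask],
            self.target_futures[mask], self.spec,
        )

    def restrict_futures(self, last_time: int) -> "StateSpaceLibrary":
        """Blank out futures that would fall after ``last_time``.

        Used to keep a training library causal: a row may only carry a
        future observed inside the training window.
        """
        futures = self.target_futures.copy()
        futures[self.row_times + self.spec.Tp > last_time] = np.nan
        return StateSpaceLibrary(self.rows, self.row_times, futures, self.spec)


def embed(table: TimeSeriesTable, spec: EmbeddingSpec) -> StateSpaceLibrary:
    """Construct the state-space library for ``spec`` from ``table``.

    A row exists at time *t* iff every coordinate ``col(t - lag)`` is
    available and finite.  ``target_futures`` holds ``target(t + Tp)``
    (NaN once ``t + Tp`` runs past the table).
    """
    for col, _ in spec.coordinates:
        if col not in table.columns:
            raise ConfigurationError(f"unknown embedding column {col!r}")
    if spec.target not in table.columns:
        raise ConfigurationError(f"unknown target column {spec.target!r}")

    times = table.times
    n = len(times)
    cols = {name: table.column(name) for name in
            {c for c, _ in spec.coordinates} | {spec.target}}

    # positional index i corresponds to time times[i]; lags are in steps,
    # which coincide with positions because the time axis is consecutive
    i0 = spec.max_lag
    if i0 >= n:
        raise EmptyLibraryError(
            f"table of length {n} too short for max lag {spec.max_lag}"
        )
    idx = np.arange(i0, n)
    rows = np.column_stack([cols[c][idx - lag] for c, lag in spec.coordinates])
    valid = np.all(np.isfinite(rows), axis=1)

    tgt = cols[spec.target]
    fut_idx = idx + spec.Tp
    futures = np.full(len(idx), np.nan)
    ok = fut_idx < n
    futures[ok] = tgt[fut_idx[ok]]

    rows, futures, row_times = rows[valid], futures[valid], times[idx[valid]]
    if rows.shape[0] == 0:
        raise EmptyLibraryError("no valid state vectors for this embedding")
    return StateSpaceLibrary(rows, row_times.astype(np.int64), futures, spec)
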