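"""Forecast-skill evaluation, hyperparameter scans and Jacobian series.

All scans follow one protocol: build the state-space library from a
training row range only (a row may also only carry a target future that
was observed inside the training window), predict each state in a
held-out test range, and score predictions against observations with the
Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edm import (PredictionResult, pearson_skill, simplex_predict,
                  smap_predict)
from .embedding import EmbeddingSpec, StateSpaceLibrary, embed
from .errors import ConfigurationError
from .timeseries import TimeSeriesTable

#: standard kernel-width grid used when selecting theta
THETA_GRID = (0.0, 0.01, 0.1, 0.3, 0.5, 0.75, 1.0, 1.5,
              2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0)

#: a dimension "saturates" once its skill reaches this fraction of the
#: per-horizon maximum
SATURATION_FRACTION = 0.95


def _rows_to_times(table: TimeSeriesTable, rows: tuple[int, int]):
    """Inclusive 1-based row range -> inclusive time-stamp range."""
    first, last = rows
    n = len(table)
    if not (1 <= first <= last <= n):
        raise ConfigurationError(f"row range {rows} outside 1..{n}")
    t0 = int(table.times[0])
    return t0 + first - 1, t0 + last - 1


def _check_split(train, test):
    if train[1] >= test[0] and test[1] >= train[0]:
        raise ConfigurationError(f"train {train} and test {test} overlap")


def out_of_sample(
    table: TimeSeriesTable,
    spec: EmbeddingSpec,
    train: tuple[int, int],
    test: tuple[int, int],
    method: str = "simplex",
    theta: float = 0.0,
    k: int | None = None,
) -> PredictionResult:
    """Library from the ``train`` row range, forecasts over ``test``.

    Row ranges are inclusive and 1-based.  Queries are test-range state
    vectors whose observed future exists; the library never contains a
    state vector, nor a target future, from outside the training range.
    """
    _check_split(train, test)
    tr0, tr1 = _rows_to_times(table, train)
    te0, te1 = _rows_to_times(table, test)
    full = embed(table, spec)
    lib = full.select_times(tr0, tr1).restrict_futures(tr1)
    if lib.n_prediction_rows == 0:
        raise ConfigurationError("training split leaves no usable library rows")
    queries = full.select_times(te0, te1)
    qmask = queries.has_future
    if not qmask.any():
        raise ConfigurationError("test split leaves no scorable queries")
    qX = queries.rows[qmask]
    qt = queries.row_times[qmask]
    qobs = queries.target_futures[qmask]
    pred = np.empty(len(qX))
    for i, row in enumerate(qX):
        if method == "simplex":
            pred[i] = simplex_predict(lib, row, k)
        elif method == "smap":
            pred[i] = smap_predict(lib, row, theta).prediction
        else:
            raise ConfigurationError(f"unknown method {method!r}")
    return PredictionResult(times=qt, observed=qobs, predicted=pred,
                            Tp=spec.Tp)


# ---------------------------------------------------------------------------
# hyperparameter scans


@dataclass
class ScanResult:
    """Grid of Pearson skills plus the per-horizon saturation dimension."""

    grid: pd.DataFrame            # index E, columns Tp
    lower_bound_E: dict[int, int | None] = field(default_factory=dict)


def _saturation_dim(skills: pd.Series) -> int | None:
    s = skills.dropna()
    if s.empty:
        return None
    best = s.max()
    cutoff = SATURATION_FRACTION * best if best > 0 else best
    ok = s[s >= cutoff]
    return int(ok.index.min()) if not ok.empty else None


def _scan_splits(n: int, split, folds: int | None):
    """Either the user's single (train, test) split or rolling-origin
    folds: the series is cut into ``folds + 1`` equal blocks and each
    block after the first is predicted from all blocks before it."""
    if folds is None:
        if split is None:
            half = n // 2
            split = ((1, half), (half + 1, n))
        return [split]
    block = n // (folds + 1)
    if block < 10:
        raise ConfigurationError("series too short for that many folds")
    return [((1, f * block), (f * block + 1, min((f + 1) * block, n)))
            for f in range(1, folds + 1)]


def scan_embedding_dimension(
    table: TimeSeriesTable,
    target: str,
    E_range=range(1, 11),
    Tp_set=(1, 2, 3, 4, 5),
    split=None,
    folds: int | None = None,
) -> ScanResult:
    """Out-of-sample simplex skill of univariate delay embeddings of
    ``target`` (lags ``0..E-1``) over a grid of (E, Tp).

    ``split`` is a pair of inclusive 1-based row ranges
    ``(train, test)``; default: first half / second half.  With
    ``folds`` set, skills are instead averaged over rolling-origin
    folds, which stabilizes the saturation statistic on noisy series.
    For each horizon the result also records the smallest E whose skill
    reaches 95% of that horizon's maximum — the useful lower bound on
    the embedding dimension.
    """
    splits = _scan_splits(len(table), split, folds)
    grid = pd.DataFrame(index=list(E_range), columns=list(Tp_set),
                        dtype=float)
    grid.index.name, grid.columns.name = "E", "Tp"
    for Tp in Tp_set:
        for E in E_range:
            spec = EmbeddingSpec.univariate(target, E, Tp)
            skills = [
                out_of_sample(table, spec, tr, te, method="simplex").skill
                for tr, te in splits
            ]
            grid.loc[E, Tp] = (np.nanmean(skills)
                               if np.isfinite(skills).any() else np.nan)
    bounds = {int(Tp): _saturation_dim(grid[Tp]) for Tp in Tp_set}
    return ScanResult(grid=grid, lower_bound_E=bounds)


def scan_prediction_horizon(
    table: TimeSeriesTable,
    target: str,
    E_set=(2, 3, 5, 7),
    Tp_range=range(1, 11),
    split=None,
) -> ScanResult:
    """As :func:`scan_embedding_dimension` with the roles of E and Tp
    exchanged: skill as a function of forecast interval at fixed E."""
    if split is None:
        half = len(table) // 2
        split = ((1, half), (half + 1, len(table)))
    train, test = split
    grid = pd.DataFrame(index=list(Tp_range), columns=list(E_set),
                        dtype=float)
    grid.index.name, grid.columns.name = "Tp", "E"
    for E in E_set:
        for Tp in Tp_range:
            spec = EmbeddingSpec.univariate(target, E, Tp)
            res = out_of_sample(table, spec, train, test, method="simplex")
            grid.loc[Tp, E] = res.skill
    return ScanResult(grid=grid)


def theta_skill_profile(
    lib: StateSpaceLibrary,
    theta_grid=THETA_GRID,
    split: float = 0.7,
) -> dict[float, float]:
    """Out-of-sample s-map skill at each kernel width.

    The library is split chronologically: the first ``split`` fraction of
    rows form the training library, the remainder are queries.
    """
    grid = sorted(float(t) for t in theta_grid)
    if not grid:
        raise ConfigurationError("empty theta grid")
    cut = int(np.floor(lib.k_N * split))
    if cut < 2 or cut >= lib.k_N:
        raise ConfigurationError("split leaves an empty train or test portion")
    t_train_end = int(lib.row_times[cut - 1])
    train = StateSpaceLibrary(
        lib.rows[:cut], lib.row_times[:cut], lib.target_futures[:cut],
        lib.spec,
    ).restrict_futures(t_train_end)
    qmask = np.isfinite(lib.target_futures[cut:])
    qX = lib.rows[cut:][qmask]
    qobs = lib.target_futures[cut:][qmask]
    if train.n_prediction_rows == 0 or len(qX) < 3:
        raise ConfigurationError("split leaves an empty train or test portion")
    profile = {}
    for theta in grid:
        pred = np.array(
            [smap_predict(train, row, theta).prediction for row in qX]
        )
        profile[theta] = pearson_skill(qobs, pred)
    return profile


def select_theta(
    lib: StateSpaceLibrary,
    theta_grid=THETA_GRID,
    split: float = 0.7,
) -> float:
    """Kernel width maximizing out-of-sample s-map skill on a
    chronological split of the library.  Ties (and an all-undefined
    profile) resolve to the smallest theta."""
    grid = sorted(float(t) for t in theta_grid)
    if not grid:
        raise ConfigurationError("empty theta grid")
    if len(grid) == 1:
        return grid[0]
    profile = theta_skill_profile(lib, grid, split)
    best_theta, best_skill = grid[0], -np.inf
    for theta in grid:
        skill = profile[theta]
        if np.isfinite(skill) and skill > best_skill:
            best_theta, best_skill = theta, skill
    return best_theta


# ---------------------------------------------------------------------------
# interaction-strength (Jacobian) series


@dataclass
class CoefficientSeries:
    """Time-indexed s-map coefficients, one column per embedding
    coordinate plus the intercept.

    A coordinate whose library column is constant is collinear with the
    intercept; its coefficient comes from the minimum-norm solution and
    is flagged in ``unreliable``.
    """

    frame: pd.DataFrame
    unreliable: dict[str, bool]

    def coordinate(self, column: str, lag: int = 0) -> pd.Series:
        label = f"{column}(t-{lag})"
        return self.frame[label]


def coefficient_series(
    table: TimeSeriesTable,
    spec: EmbeddingSpec,
    theta: float,
) -> CoefficientSeries:
    """Repeated s-map solves across the whole series, recording the local
    linear coefficients at every predictable time step.

    With a forcing variable such as Propaganda included at lag 0, the
    coefficient attached to that coordinate estimates the time-varying
    partial derivative of the target with respect to the forcing
    (e.g. dActive/dPropaganda).  Library rows within ``|dt| <= Tp`` of
    the query time are excluded from each solve.
    """
    lib = embed(table, spec)
    labels = ["intercept"] + spec.labels
    col_std = lib.rows.std(axis=0)
    col_scale = np.maximum(1.0, np.abs(lib.rows).max(axis=0))
    unreliable = {lab: bool(col_std[i] <= 1e-12 * col_scale[i])
                  for i, lab in enumerate(spec.labels)}
    out_times, out_coefs = [], []
    for i in range(lib.k_N):
        if not np.isfinite(lib.target_futures[i]):
            continue
        t = int(lib.row_times[i])
        near = np.abs(lib.row_times - t) <= spec.Tp
        excl = frozenset(int(s) for s in lib.row_times[near])
        sol = smap_predict(lib, lib.rows[i], theta, exclusion=excl)
        out_times.append(t)
        out_coefs.append(sol.coefficients)
    frame = pd.DataFrame(out_coefs, columns=labels,
                         index=pd.Index(out_times, name="time"))
    return CoefficientSeries(frame=frame, unreliable=unreliable)
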