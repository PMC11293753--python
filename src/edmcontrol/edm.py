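"""Empirical dynamic modeling: simplex projection and the s-map.

Both predictors are nearest-neighbor methods in a reconstructed state
space.  Simplex projection averages the futures of the ``E + 1`` closest
library states with weights ``exp(-d_i / d_1)``.  The s-map (sequential
locally weighted global linear map) instead solves a weighted linear
regression over *all* library states, localized by the exponential kernel
``w_i = exp(-theta * d_i / D)`` where ``D`` is the mean neighbor distance;
``theta = 0`` recovers a global linear model, larger ``theta`` an
increasingly local — hence nonlinear — map.  The fitted s-map coefficients
approximate the time-varying partial derivatives (interaction Jacobians)
of the target with respect to each state-space coordinate.

The scikit-learn-style estimators :class:`SimplexRegressor` and
:class:`SMapRegressor` are the primary interface; the module-level
functions operating on a :class:`~edmcontrol.embedding.StateSpaceLibrary`
are thin wrappers kept for pipeline-free use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .embedding import StateSpaceLibrary
from .errors import InsufficientLibraryError, ParameterError

#: relative singular-value cutoff of the minimum-norm least-squares solve
LSTSQ_RCOND = 1e-10


@dataclass
class NeighborSet:
    """Distance-ordered library neighbors of one query state."""

    indices: np.ndarray    # positions into the library arrays
    distances: np.ndarray  # non-decreasing Euclidean distances

    @property
    def mean_distance(self) -> float:
        return float(self.distances.mean())


@dataclass
class SMapSolution:
    """One s-map solve: kernel weights, local linear model, prediction.

    ``coefficients[0]`` is the intercept; ``coefficients[1:]`` attach to
    the embedding coordinates in order and estimate the local partial
    derivative of the target with respect to each coordinate.
    """

    theta: float
    weights: np.ndarray
    coefficients: np.ndarray
    prediction: float


@dataclass
class PredictionResult:
    """Aligned observed/predicted pairs and their Pearson skill."""

    times: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray
    Tp: int

    @property
    def skill(self) -> float:
        return pearson_skill(self.observed, self.predicted)


def pearson_skill(observed, predicted) -> float:
    """Sample Pearson correlation over pairs where both values are finite.

    Returns NaN (the undefined-skill sentinel, never an exception) when
    fewer than 3 valid pairs remain or either side has zero variance.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    mask = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[mask], pred[mask]
    if obs.size < 3:
        return float("nan")
    so, sp = obs.std(), pred.std()
    if so == 0.0 or sp == 0.0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


# ---------------------------------------------------------------------------
# core geometry


def _usable_mask(lib: StateSpaceLibrary, exclusion, require_future: bool):
    mask = lib.has_future if require_future else np.ones(lib.k_N, bool)
    if exclusion:
        mask = mask & ~np.isin(lib.row_times, list(exclusion))
    return mask


def _order_by_distance(distances: np.ndarray, times: np.ndarray) -> np.ndarray:
    # primary key distance, ties broken by ascending time stamp
    return np.lexsort((times, distances))


def nearest_neighbors(
    lib: StateSpaceLibrary,
    y,
    k: int,
    exclusion=frozenset(),
    require_future: bool = True,
) -> NeighborSet:
    """The ``k`` library rows closest (Euclidean) to query state ``y``.

    ``exclusion`` is a collection of row *times* to leave out (used to
    suppress trivial self-matching for in-sample queries).  Ties in
    distance are broken by ascending row time.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != lib.E:
        raise ParameterError(f"query has dimension {y.size}, library {lib.E}")
    mask = _usable_mask(lib, exclusion, require_future)
    avail = np.flatnonzero(mask)
    if not 1 <= k <= avail.size:
        raise ParameterError(
            f"k={k} outside 1..{avail.size} available library rows"
        )
    d = np.linalg.norm(lib.rows[avail] - y, axis=1)
    order = _order_by_distance(d, lib.row_times[avail])[:k]
    return NeighborSet(indices=avail[order], distances=d[order])


def simplex_predict(
    lib: StateSpaceLibrary, y, k: int | None = None, exclusion=frozenset()
) -> float:
    """Simplex projection: exponentially weighted average of the futures
    of the ``k`` nearest library states (default ``k = E + 1``).

    Weights are ``u_i = exp(-d_i / d_1)`` with the nearest distance
    ``d_1`` floored at machine epsilon, so an exact match dominates.
    The prediction always lies within [min, max] of the neighbor futures.
    """
    if k is None:
        k = lib.E + 1
    try:
        nn = nearest_neighbors(lib, y, k, exclusion, require_future=True)
    except ParameterError as exc:
        raise InsufficientLibraryError(str(exc)) from exc
    d1 = max(nn.distances[0], np.finfo(float).eps)
    u = np.exp(-nn.distances / d1)
    futures = lib.target_futures[nn.indices]
    return float(np.dot(u, futures) / u.sum())


def smap_predict(
    lib: StateSpaceLibrary,
    y,
    theta: float,
    exclusion=frozenset(),
) -> SMapSolution:
    """One s-map solve at query state ``y``.

    All usable library rows act as neighbors.  With ``D`` the mean
    query-to-row distance, each row receives weight
    ``w_i = exp(-theta * d_i / D)`` (uniform weights when ``D = 0``), and
    the local model is the minimum-norm solution of the row-weighted
    least-squares system with design ``[1 | X]``.  The prediction is the
    local model evaluated at ``y``; the slope coefficients estimate the
    local Jacobian of the target with respect to each coordinate.
    """
    if theta < 0:
        raise ParameterError("theta must be >= 0")
    y = np.asarray(y, dtype=float).ravel()
    if y.size != lib.E:
        raise ParameterError(f"query has dimension {y.size}, library {lib.E}")
    mask = _usable_mask(lib, exclusion, require_future=True)
    if not mask.any():
        raise InsufficientLibraryError("no library rows with defined futures")
    X = lib.rows[mask]
    b = lib.target_futures[mask]
    d = np.linalg.norm(X - y, axis=1)
    D = d.mean()
    w = np.exp(-theta * d / D) if D > 0 else np.ones_like(d)
    A = np.column_stack([np.ones(len(X)), X]) * w[:, None]
    coef, *_ = np.linalg.lstsq(A, b * w, rcond=LSTSQ_RCOND)
    pred = float(coef[0] + coef[1:] @ y)
    return SMapSolution(theta=float(theta), weights=w,
                        coefficients=coef, prediction=pred)


# ---------------------------------------------------------------------------
# scikit-learn estimators


class _LibraryRegressor(BaseEstimator, RegressorMixin):
    """Shared fit/validation plumbing of the two EDM estimators.

    The "model" is the training data itself: ``fit`` stores the library
    of state vectors ``X`` and their future target values ``y``.  Optional
    per-row time stamps enable the temporal exclusion window applied when
    predicting at in-sample times (``exclusion_radius`` > 0): library rows
    within ``|t_row - t_query| <= exclusion_radius`` are left out of that
    query's neighborhood, preventing trivial self-matching under serial
    correlation.
    """

    exclusion_radius: int

    def _fit(self, X, y, times):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one target per row")
        if X.shape[0] == 0:
            raise InsufficientLibraryError("empty library")
        self.X_ = X
        self.y_ = y
        self.times_ = (np.arange(len(y)) if times is None
                       else np.asarray(times, dtype=np.int64))
        self.n_features_in_ = X.shape[1]
        return self

    def _as_library(self) -> StateSpaceLibrary:
        from .embedding import EmbeddingSpec

        spec = EmbeddingSpec(
            tuple((f"x{i}", 0) for i in range(self.n_features_in_)),
            target="x0", Tp=1,
        )
        return StateSpaceLibrary(self.X_, self.times_, self.y_, spec)

    def _exclusion_for(self, t: int | None):
        if t is None or self.exclusion_radius <= 0:
            return frozenset()
        r = self.exclusion_radius
        return frozenset(
            int(s) for s in self.times_[np.abs(self.times_ - t) <= r]
        )

    def predict(self, X, times=None):
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lib = self._as_library()
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            t = None if times is None else int(times[i])
            out[i] = self._predict_one(lib, row, self._exclusion_for(t))
        return out


class SimplexRegressor(_LibraryRegressor):
    """Simplex-projection forecaster.

    Parameters
    ----------
    n_neighbors:
        Neighborhood size ``k``; ``None`` means ``E + 1`` where ``E`` is
        the number of state-space coordinates.
    exclusion_radius:
        Temporal exclusion window for in-sample queries (see above).
    """

    def __init__(self, n_neighbors: int | None = None, exclusion_radius: int = 0):
        self.n_neighbors = n_neighbors
        self.exclusion_radius = exclusion_radius

    def fit(self, X, y, times=None):
        return self._fit(X, y, times)

    def _predict_one(self, lib, row, exclusion):
        return simplex_predict(lib, row, self.n_neighbors, exclusion)


class SMapRegressor(_LibraryRegressor):
    """S-map forecaster with kernel localization ``theta``.

    ``theta = 0`` is an ordinary (global) linear regression; increasing
    ``theta`` localizes the fit around each query state.  After
    ``predict``, per-query local slope coefficients are available from
    :meth:`solve`.
    """

    def __init__(self, theta: float = 0.0, exclusion_radius: int = 0):
        self.theta = theta
        self.exclusion_radius = exclusion_radius

    def fit(self, X, y, times=None):
        return self._fit(X, y, times)

    def _predict_one(self, lib, row, exclusion):
        return smap_predict(lib, row, self.theta, exclusion).prediction

    def solve(self, x, time: int | None = None) -> SMapSolution:
        """Full s-map solution (weights, coefficients, prediction) at one
        query state."""
        check_is_fitted(self, "X_")
        lib = self._as_library()
        return smap_predict(lib, np.asarray(x, dtype=float).ravel(),
                            self.theta, self._exclusion_for(time))
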