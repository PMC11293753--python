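"""Logistic propaganda controller and the closed EDM-MPC loop.

The government regulates propaganda with a logistic response to the
*predicted* number of Active citizens,

    P = (P_max - P_min) / (1 + exp(-m (A_hat - A_0))) + P_min,

so propaganda saturates at ``P_max`` under a forecast mass rebellion and
relaxes toward ``P_min`` when quiet.  The forecast comes from an s-map
over the generalized embedding of the Quiet and Jailed observables,
re-fit online on the growing library of the run's own observations; no
future data is ever used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .abm import LegitimacySchedule, RebellionWorld
from .edm import simplex_predict, smap_predict
from .embedding import EmbeddingSpec, StateSpaceLibrary, default_embedding
from .errors import ConfigurationError, InsufficientLibraryError
from .scans import THETA_GRID, select_theta
from .timeseries import TimeSeriesTable, table_from_columns

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ControllerParams:
    """Constants of the logistic control law."""

    p_min: float = 0.06
    p_max: float = 0.6
    m: float = 0.05
    a0: float = 50.0

    def __post_init__(self):
        if not self.p_min < self.p_max:
            if self.p_min == self.p_max:
                return  # degenerate constant controller is allowed
            raise ConfigurationError("p_min must not exceed p_max")
        if self.m <= 0:
            raise ConfigurationError("logistic slope m must be > 0")


def propaganda_response(a_pred: float, params: ControllerParams) -> float:
    """Evaluate the logistic control law at predicted Active count
    ``a_pred`` (used as-is, not rounded)."""
    z = -params.m * (a_pred - params.a0)
    # guard exp overflow at extreme forecasts; the logistic saturates anyway
    if z > 700:
        return params.p_min
    value = (params.p_max - params.p_min) / (1.0 + math.exp(z)) + params.p_min
    # rounding can push the saturated sum a ulp past the bounds
    return min(max(value, params.p_min), params.p_max)


@dataclass
class ControlLoopConfig:
    """How the forecast feeds back into the simulator.

    ``warmup_obs`` observations are recorded (propaganda held at
    ``nominal_propaganda``) before the first controller estimate;
    ``theta`` is either a number or ``"grid"`` for one-off selection on
    the warm-up library; ``refit_interval`` re-selects theta every so
    many steps (``None``: never).
    """

    warmup_obs: int = 3000
    embedding: EmbeddingSpec = field(default_factory=default_embedding)
    theta: float | str = "grid"
    refit_interval: int | None = None
    predictor: str = "smap"  # or "simplex"
    nominal_propaganda: float = 0.1

    def __post_init__(self):
        spec = self.embedding
        if self.warmup_obs < spec.max_lag + spec.Tp:
            raise ConfigurationError(
                "warmup_obs must cover at least max lag + Tp observations"
            )
        if self.predictor not in ("smap", "simplex"):
            raise ConfigurationError(f"unknown predictor {self.predictor!r}")


@dataclass
class ControlLoopResult:
    """Output of a controlled run: the observation table, the kernel
    width actually used, and the per-step Active forecasts (NaN before
    the controller engaged or on prediction failure)."""

    table: TimeSeriesTable
    theta: float | None
    predictions: np.ndarray


def control_loop(
    world: RebellionWorld,
    params: ControllerParams,
    config: ControlLoopConfig,
    n_steps: int,
    schedule: LegitimacySchedule | None = None,
) -> ControlLoopResult:
    """Run the closed loop for ``n_steps`` ticks.

    Each tick: (1) the latest observation extends the library;
    (2) during warm-up propaganda stays nominal; (3) afterwards the most
    recent Quiet/Jailed lags form the query state, the s-map forecasts
    the Active count ``Tp`` steps ahead, and the logistic law converts
    the forecast into the propaganda applied to the very next tick.  A
    failed forecast (library still too thin) holds the previous level.
    """
    spec = config.embedding
    max_lag, Tp, E = spec.max_lag, spec.Tp, spec.E
    cols = {name: np.full(n_steps, np.nan) for name in
            ("Quiet", "Active", "Jailed", "Legitimacy", "Propaganda")}
    X = np.full((n_steps, E), np.nan)
    times = np.arange(n_steps, dtype=np.int64)
    predictions = np.full(n_steps, np.nan)
    theta: float | None = None
    p_current = config.nominal_propaganda

    def library(n_obs: int) -> StateSpaceLibrary | None:
        lo, hi = max_lag, n_obs - Tp  # rows with observed futures
        if hi <= lo:
            return None
        futures = cols["Active"][lo + Tp : hi + Tp]
        return StateSpaceLibrary(X[lo:hi], times[lo:hi], futures, spec)

    for t in range(n_steps):
        n_obs = t  # observations recorded so far
        if n_obs >= config.warmup_obs:
            refit = theta is None or (
                config.refit_interval is not None
                and (n_obs - config.warmup_obs) % config.refit_interval == 0
            )
            lib = library(n_obs)
            if lib is not None and refit and config.predictor == "smap":
                theta = (select_theta(lib, THETA_GRID)
                         if config.theta == "grid" else float(config.theta))
                log.info("controller theta = %s at observation %d",
                         theta, n_obs)
            query = np.array(
                [cols[c][n_obs - 1 - lag] for c, lag in spec.coordinates]
            )
            try:
                if lib is None:
                    raise InsufficientLibraryError("library still empty")
                if config.predictor == "smap":
                    a_pred = smap_predict(lib, query, theta).prediction
                else:
                    a_pred = simplex_predict(lib, query)
                predictions[t] = a_pred
                p_current = propaganda_response(a_pred, params)
            except InsufficientLibraryError as exc:
                log.warning("step %d: forecast failed (%s); holding P=%.3f",
                            t, exc, p_current)
        legit = schedule.value_at(t) if schedule is not None else None
        obs = world.step(legitimacy=legit, propaganda=p_current)
        for name in cols:
            cols[name][t] = obs[name]
        if t >= max_lag:
            X[t] = [cols[c][t - lag] for c, lag in spec.coordinates]

    table = table_from_columns(cols, start_time=1)
    return ControlLoopResult(table=table, theta=theta,
                             predictions=predictions)
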