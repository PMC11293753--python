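"""Post-hoc analyses of simulated runs.

Covers rebellion-episode statistics (punctuated equilibrium shows up as
exponentially distributed waiting times between episodes), trapped-state
detection, the train/test forecast-skill protocol, and the variance of
the dActive/dPropaganda interaction coefficient partitioned by
legitimacy regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .edm import PredictionResult
from .embedding import EmbeddingSpec, default_embedding, embed
from .errors import ConfigurationError
from .scans import THETA_GRID, CoefficientSeries, out_of_sample, select_theta
from .timeseries import TimeSeriesTable


# ---------------------------------------------------------------------------
# episodes & trapped states


@dataclass
class EpisodeTable:
    """Disjoint, time-ordered rebellion episodes and the waiting times
    between consecutive episode starts."""

    episodes: pd.DataFrame  # columns start, end, peak (times inclusive)
    waiting_times: np.ndarray

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)


def detect_episodes(table: TimeSeriesTable, active_threshold: float = 50,
                    min_gap: int = 20) -> EpisodeTable:
    """Segment the Active series into rebellion episodes.

    An episode is a maximal run of steps with ``Active > threshold``;
    runs separated by fewer than ``min_gap`` sub-threshold steps merge.
    """
    active = table.column("Active")
    times = table.times
    above = active > active_threshold
    runs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < min_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    rows = [
        {"start": int(times[a]), "end": int(times[b]),
         "peak": float(active[a : b + 1].max())}
        for a, b in merged
    ]
    frame = pd.DataFrame(rows, columns=["start", "end", "peak"])
    waits = np.diff(frame["start"].to_numpy()) if len(frame) > 1 else np.array([])
    return EpisodeTable(episodes=frame, waiting_times=waits)


def waiting_time_exponential_test(episodes: EpisodeTable):
    """Kolmogorov-Smirnov test of the inter-episode waiting times against
    an exponential distribution with the fitted (mean) scale.
    Returns the (statistic, p-value) pair."""
    waits = episodes.waiting_times
    if waits.size < 3:
        raise ConfigurationError("need at least 3 waiting times for the test")
    res = stats.kstest(waits, "expon", args=(0, waits.mean()))
    return float(res.statistic), float(res.pvalue)


def detect_trapped_state(table: TimeSeriesTable, frac_threshold: float = 0.25,
                         duration: int = 200):
    """Sustained rebellion: the Active fraction of the citizenry exceeds
    ``frac_threshold`` for at least ``duration`` consecutive steps.
    Returns ``(trapped, onset_time_or_None)``."""
    counts = table.frame[["Quiet", "Active", "Jailed"]].to_numpy()
    population = counts.sum(axis=1)
    above = table.column("Active") / population > frac_threshold
    times = table.times
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= duration:
            return True, int(times[i - run + 1])
    return False, None


# ---------------------------------------------------------------------------
# forecast-skill protocol


def skill_protocol(
    table: TimeSeriesTable,
    spec: EmbeddingSpec | None = None,
    split_train: tuple[int, int] = (1, 1500),
    split_test: tuple[int, int] = (1601, 3100),
    theta: float | str = "grid",
) -> PredictionResult:
    """Train/test forecast evaluation.

    The s-map library is built from the training row range only; the
    kernel width is grid-selected on a chronological sub-split of the
    training library (unless a number is given); predictions are scored
    over the test range with the Pearson correlation.
    """
    if spec is None:
        spec = default_embedding(Tp=5)
    if split_train[1] >= split_test[0] and split_test[1] >= split_train[0]:
        raise ConfigurationError("train and test row ranges overlap")
    if theta == "grid":
        train_table = table.rows(*split_train)
        lib = embed(train_table, spec)
        theta = select_theta(lib, THETA_GRID)
    return out_of_sample(table, spec, split_train, split_test,
                         method="smap", theta=float(theta))


# ---------------------------------------------------------------------------
# Jacobian variance by legitimacy regime


@dataclass
class RegimeVarianceResult:
    """Rolling-window variances of the dActive/dPropaganda coefficient,
    partitioned into low/high legitimacy regimes, with Gaussian kernel
    density estimates of each variance population."""

    threshold: float
    window: int
    stride: int
    low_variances: np.ndarray
    high_variances: np.ndarray
    low_density: object | None
    high_density: object | None

    def rank_test(self):
        """One-sided Mann-Whitney U: are low-regime variances
        stochastically larger than high-regime ones?  Returns
        (statistic, p-value)."""
        res = stats.mannwhitneyu(self.low_variances, self.high_variances,
                                 alternative="greater")
        return float(res.statistic), float(res.pvalue)


def _kde(sample: np.ndarray):
    if sample.size < 3 or np.std(sample) == 0:
        return None
    return stats.gaussian_kde(sample)


def jacobian_variance_by_regime(
    coeffs: CoefficientSeries,
    legitimacy,
    threshold: float = 0.7,
    window: int = 100,
    stride: int = 10,
    coordinate: str = "Propaganda(t-0)",
) -> RegimeVarianceResult:
    """Partition rolling-window variances of an interaction coefficient
    by the mean legitimacy of each window.

    ``legitimacy`` must be aligned with the coefficient series' time
    index (a pandas Series indexed by time, or an equal-length array).
    Windows whose mean legitimacy is exactly at the threshold count as
    high regime.
    """
    series = coeffs.frame[coordinate].to_numpy()
    if isinstance(legitimacy, pd.Series):
        leg = legitimacy.reindex(coeffs.frame.index).to_numpy(float)
    else:
        leg = np.asarray(legitimacy, dtype=float)
        if leg.size != series.size:
            raise ConfigurationError(
                "legitimacy must align with the coefficient series"
            )
    if window > series.size:
        raise ConfigurationError("window longer than the coefficient series")
    low, high = [], []
    for start in range(0, series.size - window + 1, stride):
        sl = slice(start, start + window)
        var = float(np.var(series[sl]))
        if float(np.mean(leg[sl])) < threshold:
            low.append(var)
        else:
            high.append(var)
    low_arr, high_arr = np.array(low), np.array(high)
    return RegimeVarianceResult(
        threshold=threshold, window=window, stride=stride,
        low_variances=low_arr, high_variances=high_arr,
        low_density=_kde(low_arr), high_density=_kde(high_arr),
    )
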