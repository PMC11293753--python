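"""Deterministic synthetic series for unit-level oracles.

These generators are first-class, tested code: the logistic map gives a
noiseless chaotic benchmark, AR(1) a linear stochastic one, constants the
degenerate zero-variance case, and ``linear_forcing`` a table whose
Active column is an exact linear function of Propaganda and Quiet plus
noise, used to check coefficient recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .timeseries import TimeSeriesTable, table_from_columns

GENERATORS = ("logistic_map", "ar1", "constant", "linear_forcing")


@dataclass(frozen=True)
class FixtureSpec:
    """Name + parameters of one synthetic series; identical specs yield
    identical series."""

    generator: str
    length: int = 100
    seed: int = 0
    params: tuple[tuple[str, float], ...] = ()

    def param_dict(self) -> dict:
        return dict(self.params)


def _logistic_map(n: int, r: float = 3.9, x0: float = 0.2) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    for i in range(1, n):
        x[i] = r * x[i - 1] * (1.0 - x[i - 1])
    return x


def _ar1(n: int, rng, phi: float = 0.5, sigma: float = 1.0,
         x0: float = 0.0) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    noise = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + noise[i]
    return x


def make_fixture(spec: FixtureSpec) -> TimeSeriesTable:
    """Generate the synthetic series described by ``spec``."""
    p = spec.param_dict()
    n = spec.length
    rng = np.random.default_rng(spec.seed)
    if spec.generator == "logistic_map":
        x = _logistic_map(n, r=p.get("r", 3.9), x0=p.get("x0", 0.2))
        return table_from_columns({"x": x})
    if spec.generator == "ar1":
        x = _ar1(n, rng, phi=p.get("phi", 0.5), sigma=p.get("sigma", 1.0),
                 x0=p.get("x0", 0.0))
        return table_from_columns({"x": x})
    if spec.generator == "constant":
        return table_from_columns({"x": np.full(n, p.get("value", 1.0))})
    if spec.generator == "linear_forcing":
        # Active(t) = a * Propaganda(t - lag) + b * Quiet(t - lag) + noise,
        # with smoothly varying forcings so the design is well conditioned;
        # the lag matches a forecast horizon, so a regression of the
        # target's future on present coordinates recovers (a, b) exactly
        a, b = p.get("a", 2.0), p.get("b", 0.0)
        sigma = p.get("sigma", 0.05)
        lag = int(p.get("lag", 5))
        prop = 0.5 + 0.4 * np.sin(np.linspace(0, 12 * np.pi, n))
        prop += 0.05 * rng.standard_normal(n)
        prop = np.clip(prop, 0.0, 1.0)
        quiet = 600 + 200 * np.cos(np.linspace(0, 5 * np.pi, n))
        lagged = lambda x: np.concatenate([np.full(lag, x[0]), x[:n - lag]])
        active = (a * lagged(prop) + b * lagged(quiet)
                  + sigma * rng.standard_normal(n))
        jailed = np.zeros(n)
        leg = np.full(n, 0.8)
        return table_from_columns({
            "Quiet": quiet, "Active": active, "Jailed": jailed,
            "Legitimacy": leg, "Propaganda": prop,
        })
    raise ConfigurationError(f"unknown generator {spec.generator!r}")
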