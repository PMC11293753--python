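"""Scenario runner: nominal, uncontrolled and controlled simulations.

* ``nominal`` — constant legitimacy and propaganda; the classic
  punctuated-equilibrium regime.
* ``uncontrolled`` — legitimacy follows a random step schedule, the
  propaganda threshold stays at its nominal constant.
* ``controlled`` — the same schedule, with propaganda set each tick by
  the logistic controller driven by s-map forecasts.

A single root seed drives everything through labelled substreams, so an
uncontrolled and a controlled run with the same seed share their world
initialization and legitimacy schedule (matched twins).
"""

from __future__ import annotations

import logging

import numpy as np

from .abm import LegitimacySchedule, RebellionWorld, sample_legitimacy_schedule
from .config import RunConfig
from .controller import ControlLoopResult, control_loop
from .errors import ConfigurationError
from .timeseries import TimeSeriesTable, table_from_columns

log = logging.getLogger(__name__)


def _substreams(seed: int):
    world_ss, sched_ss = np.random.SeedSequence(seed).spawn(2)
    return world_ss, sched_ss


def _schedule_for(config: RunConfig, sched_ss) -> LegitimacySchedule:
    sp = config.schedule
    if sp.change_points is not None and sp.values is not None:
        return LegitimacySchedule(sp.change_points, sp.values,
                                  initial=sp.initial)
    return sample_legitimacy_schedule(
        config.run_length, sched_ss, n_changes=sp.n_changes,
        low=sp.low, high=sp.high, initial=sp.initial,
    )


def _run_open_loop(world: RebellionWorld, n_steps: int,
                   schedule: LegitimacySchedule | None,
                   propaganda: float) -> TimeSeriesTable:
    cols = {name: np.empty(n_steps) for name in
            ("Quiet", "Active", "Jailed", "Legitimacy", "Propaganda")}
    for t in range(n_steps):
        legit = schedule.value_at(t) if schedule is not None else None
        obs = world.step(legitimacy=legit, propaganda=propaganda)
        for name in cols:
            cols[name][t] = obs[name]
    return table_from_columns(cols, start_time=1)


def run_scenario(config: RunConfig) -> TimeSeriesTable:
    """Run the configured scenario and return the observation table."""
    return run_scenario_full(config).table


def run_scenario_full(config: RunConfig) -> ControlLoopResult:
    """As :func:`run_scenario`, also exposing controller internals
    (selected theta and per-step forecasts) for controlled runs."""
    world_ss, sched_ss = _substreams(config.seed)
    world = RebellionWorld(config.model, world_ss,
                           legitimacy=config.nominal_legitimacy,
                           propaganda=config.nominal_propaganda)
    n = config.run_length
    log.info("scenario=%s seed=%d steps=%d", config.scenario, config.seed, n)
    if config.scenario == "nominal":
        table = _run_open_loop(world, n, None, config.nominal_propaganda)
        return ControlLoopResult(table=table, theta=None,
                                 predictions=np.full(n, np.nan))
    schedule = _schedule_for(config, sched_ss)
    if config.scenario == "uncontrolled":
        table = _run_open_loop(world, n, schedule,
                               config.nominal_propaganda)
        return ControlLoopResult(table=table, theta=None,
                                 predictions=np.full(n, np.nan))
    if config.scenario == "controlled":
        loop = config.loop
        if loop.nominal_propaganda != config.nominal_propaganda:
            loop.nominal_propaganda = config.nominal_propaganda
        return control_loop(world, config.controller, loop, n,
                            schedule=schedule)
    raise ConfigurationError(f"unknown scenario {config.scenario!r}")
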