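"""Canned experiment configurations and result-surface computations.

These functions pin down the study conditions of the package's headline
experiments — the forecast-skill benchmark, the embedding-dimension
scan, the control-robustness twins, and the Jacobian-variance-by-regime
analysis — so that tests, the CLI and reproduction scripts all run the
same protocols.

Two regimes of the simulator are used.  The *nominal* regime (constant
legitimacy 0.82, propaganda 0.1, unlimited jail capacity) exhibits
punctuated equilibrium.  The *variable-legitimacy* regime draws
legitimacy from (0.6, 0.85] at 20 random change points and bounds jail
capacity at 25% of the population; when legitimacy stays low the cops
saturate and the system falls into a trapped state of sustained
rebellion — the state the controller must avoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import (detect_trapped_state, jacobian_variance_by_regime,
                       skill_protocol)
from .config import RunConfig, ScheduleParams
from .controller import ControlLoopConfig
from .abm import ModelParams
from .embedding import EmbeddingSpec
from .scans import coefficient_series
from .scenario import run_scenario, run_scenario_full

#: jail capacity (fraction of citizens) in the variable-legitimacy
#: experiments; cops saturating at this bound is what makes sustained
#: rebellion a reachable (trapped) state
CONTROL_JAIL_CAPACITY = 300

#: embedding used for Jacobian extraction: the forecast coordinates plus
#: the propaganda forcing at lag 0
JACOBIAN_SPEC = EmbeddingSpec(
    (("Quiet", 0), ("Quiet", 2), ("Quiet", 4),
     ("Jailed", 0), ("Jailed", 2), ("Jailed", 4),
     ("Propaganda", 0)),
    target="Active", Tp=5,
)


def _post_warmup_schedule(seed_label, run_length, warmup, n_changes=20,
                          low=0.6, high=0.85, initial=0.82) -> ScheduleParams:
    """Random step schedule whose change points all fall after warm-up,
    so the library is built under nominal conditions before forcing
    starts to vary (mirroring the warm-up protocol of the control
    experiments)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed_label))
    pts = np.sort(rng.choice(np.arange(warmup, run_length),
                             size=n_changes, replace=False))
    values = high - (high - low) * rng.random(n_changes)
    return ScheduleParams(
        change_points=tuple(int(p) for p in pts),
        values=tuple(float(v) for v in values),
        initial=initial,
    )


def forecast_benchmark_config(seed: int, run_length: int = 3100) -> RunConfig:
    """Variable-legitimacy uncontrolled run providing the 3100-step
    observation table of the train/test forecast benchmark.

    Legitimacy holds at its nominal constant for the first 600 steps and
    then steps randomly through (0.6, 0.85], so the observed window shows
    punctuated equilibrium first and the transition into sustained
    rebellion afterwards — both regimes fall inside the training range.
    """
    sched = _post_warmup_schedule((seed, 0xBE), run_length, 600)
    return RunConfig(
        seed=seed, scenario="uncontrolled", run_length=run_length,
        model=ModelParams(jail_capacity=CONTROL_JAIL_CAPACITY,
                          run_length=run_length),
        schedule=sched,
    )


def forecast_benchmark(seed: int) -> float:
    """Out-of-sample Pearson skill of s-map Active forecasts (6-D
    embedding, train rows 1-1500, test rows 1601-3100, Tp=5)."""
    table = run_scenario(forecast_benchmark_config(seed))
    return skill_protocol(table).skill


def embedding_scan_config(seed: int, run_length: int = 6000) -> RunConfig:
    """Nominal punctuated-equilibrium run for the univariate
    embedding-dimension scan."""
    return RunConfig(seed=seed, scenario="nominal", run_length=run_length,
                     model=ModelParams(run_length=run_length))


def adversarial_twin_configs(
    seed: int,
    run_length: int = 1500,
    warmup_obs: int = 600,
    low: float = 0.6,
    high: float = 0.65,
) -> tuple[RunConfig, RunConfig]:
    """Matched (uncontrolled, controlled) configs under an adversarial
    legitimacy schedule.

    Legitimacy holds at its nominal level through warm-up, then steps
    through draws from the low end ``(low, high]`` of the admissible
    band — conditions that reliably trap the uncontrolled system.  Both
    configs share the seed, hence world initialization and schedule.
    """
    sched = _post_warmup_schedule((seed, 0xADF), run_length, warmup_obs,
                                  low=low, high=high)
    model = ModelParams(jail_capacity=CONTROL_JAIL_CAPACITY,
                        run_length=run_length)
    common = dict(seed=seed, run_length=run_length, model=model,
                  schedule=sched)
    return (RunConfig(scenario="uncontrolled",
                      loop=ControlLoopConfig(warmup_obs=warmup_obs),
                      **common),
            RunConfig(scenario="controlled",
                      loop=ControlLoopConfig(warmup_obs=warmup_obs),
                      **common))


@dataclass
class RobustnessResult:
    """Outcome of the paired control-robustness experiment."""

    n_pairs: int
    uncontrolled_trapped: int
    controlled_trapped: int

    @property
    def control_success_rate(self) -> float:
        return 1.0 - self.controlled_trapped / self.n_pairs


def control_robustness(n_pairs: int, seed: int,
                       run_length: int = 1500,
                       warmup_obs: int = 600) -> RobustnessResult:
    """Run ``n_pairs`` matched twins and count trapped outcomes on each
    arm.  Pair seeds are spawned from ``seed``."""
    pair_seeds = np.random.SeedSequence(seed).generate_state(n_pairs)
    un_trapped = 0
    co_trapped = 0
    for ps in pair_seeds:
        un_cfg, co_cfg = adversarial_twin_configs(
            int(ps % (2 ** 31)), run_length=run_length,
            warmup_obs=warmup_obs)
        if detect_trapped_state(run_scenario(un_cfg))[0]:
            un_trapped += 1
        if detect_trapped_state(run_scenario(co_cfg))[0]:
            co_trapped += 1
    return RobustnessResult(n_pairs=n_pairs,
                            uncontrolled_trapped=un_trapped,
                            controlled_trapped=co_trapped)


def jacobian_regime_config(seed: int, run_length: int = 3000,
                           warmup_obs: int = 600) -> RunConfig:
    """Controlled run with a post-warm-up mixed legitimacy schedule,
    providing the data for the dActive/dPropaganda variance-by-regime
    analysis."""
    sched = _post_warmup_schedule((seed, 0x7AC), run_length, warmup_obs)
    model = ModelParams(jail_capacity=CONTROL_JAIL_CAPACITY,
                        run_length=run_length)
    return RunConfig(seed=seed, scenario="controlled",
                     run_length=run_length, model=model, schedule=sched,
                     loop=ControlLoopConfig(warmup_obs=warmup_obs))


def jacobian_regime_analysis(seed: int, theta: float = 2.0,
                             run_length: int = 3000):
    """Controlled run -> coefficient series -> variance populations
    partitioned by the legitimacy regime (threshold 0.7)."""
    result = run_scenario_full(jacobian_regime_config(seed,
                                                      run_length=run_length))
    coeffs = coefficient_series(result.table, JACOBIAN_SPEC, theta)
    return jacobian_variance_by_regime(
        coeffs, result.table.frame["Legitimacy"])
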