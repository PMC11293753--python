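"""Agent-based model of civil disobedience (an Epstein rebellion variant).

1200 citizens and a force of cops share a 40x40 toroidal lattice.  Each
citizen carries fixed individual draws of risk aversion and perceived
hardship; its grievance is ``hardship * (1 - legitimacy)``.  Every tick
each citizen moves to a random empty cell within its vision and rebels
(turns Active) iff

    grievance - risk_aversion * arrest_probability > propaganda,

where the arrest probability ``1 - exp(-k * cop_ratio)`` is estimated
from the local cop-to-active ratio within vision (the citizen counting
itself as active).  Cops move the same way and jail one uniformly chosen
Active citizen in vision, subject to jail capacity; jail terms are drawn
uniformly from ``1..max_jail_term``.

Government *legitimacy* is the exogenous forcing (constant, or a random
step schedule) and *propaganda* is the rebellion threshold — the variable
the feedback controller manipulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import ConfigurationError, ParameterError

#: arrest constant calibrated so one cop facing one active citizen
#: yields a 90% arrest probability: 1 - exp(-k * 1) = 0.9
ARREST_K = math.log(10.0)


def grievance(hardship: float, legitimacy: float) -> float:
    """Citizen grievance ``H * (1 - L)``; both arguments in [0, 1]."""
    if not (0.0 <= hardship <= 1.0 and 0.0 <= legitimacy <= 1.0):
        raise ParameterError("hardship and legitimacy must lie in [0, 1]")
    return hardship * (1.0 - legitimacy)


def arrest_probability(cop_ratio: float, k: float = ARREST_K) -> float:
    """``1 - exp(-k * cop_ratio)``, increasing in the cop-to-active ratio."""
    if cop_ratio < 0 or k <= 0:
        raise ParameterError("cop_ratio must be >= 0 and k > 0")
    return 1.0 - math.exp(-k * cop_ratio)


def decides_active(grievance_: float, risk_aversion: float,
                   arrest_prob: float, propaganda: float) -> bool:
    """The rebellion rule: ``grievance - R * p > propaganda`` (strict)."""
    return grievance_ - risk_aversion * arrest_prob > propaganda


@dataclass(frozen=True)
class ModelParams:
    """Structural parameters of the simulator.

    Defaults follow the canonical rebellion-model configuration: 1200
    citizens on 1600 cells, a 4%-of-cells cop force, vision radius 7
    (Chebyshev, toroidal), jail terms up to 30 steps, and unlimited jail
    capacity (``jail_capacity=None`` means ``n_citizens``).
    """

    n_citizens: int = 1200
    n_cops: int = 64
    grid_side: int = 40
    arrest_k: float = ARREST_K
    max_jail_term: int = 30
    vision: int = 7
    jail_capacity: int | None = None
    run_length: int = 3000

    def __post_init__(self):
        for name in ("n_citizens", "n_cops", "grid_side", "max_jail_term",
                     "run_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.vision < 0 or self.arrest_k <= 0:
            raise ConfigurationError("vision must be >= 0 and arrest_k > 0")
        if self.n_citizens + self.n_cops > self.n_cells:
            raise ConfigurationError(
                f"{self.n_citizens} citizens + {self.n_cops} cops exceed "
                f"{self.n_cells} cells"
            )

    @property
    def n_cells(self) -> int:
        return self.grid_side ** 2

    @property
    def effective_jail_capacity(self) -> int:
        return self.n_citizens if self.jail_capacity is None else self.jail_capacity


@dataclass(frozen=True)
class LegitimacySchedule:
    """Piecewise-constant legitimacy: ``values[i]`` applies from
    ``change_points[i]`` until the next change point."""

    change_points: tuple[int, ...]
    values: tuple[float, ...]
    initial: float = 0.82

    def __post_init__(self):
        if len(self.change_points) != len(self.values):
            raise ConfigurationError("change_points and values differ in length")
        if any(b <= a for a, b in zip(self.change_points,
                                      self.change_points[1:])):
            raise ConfigurationError("change points must be strictly increasing")

    def value_at(self, t: int) -> float:
        v = self.initial
        for cp, val in zip(self.change_points, self.values):
            if cp <= t:
                v = val
            else:
                break
        return v


def sample_legitimacy_schedule(
    run_length: int,
    seed,
    n_changes: int = 20,
    low: float = 0.6,
    high: float = 0.85,
    initial: float = 0.82,
) -> LegitimacySchedule:
    """Random step schedule: ``n_changes`` change points drawn uniformly
    without replacement over the run, values i.i.d. uniform on
    ``(low, high]``."""
    if run_length < n_changes:
        raise ConfigurationError(
            f"run_length {run_length} < {n_changes} change points"
        )
    rng = np.random.default_rng(seed)
    points = np.sort(rng.choice(run_length, size=n_changes, replace=False))
    # high - (high-low)*U[0,1) lies in the half-open interval (low, high]
    values = high - (high - low) * rng.random(n_changes)
    return LegitimacySchedule(tuple(int(p) for p in points),
                              tuple(float(v) for v in values),
                              initial=initial)


class RebellionWorld:
    """Mutable simulator state plus the stepping interface.

    A world is a pure function of ``(params, seed)``: agent placement and
    individual draws come from a numpy generator seeded from ``seed``, and
    each tick reseeds the compiled kernel's RNG from a per-step stream, so
    trajectories are reproducible regardless of how runs interleave.
    """

    def __init__(self, params: ModelParams, seed,
                 legitimacy: float = 0.82, propaganda: float = 0.1):
        self.params = params
        self.legitimacy = float(legitimacy)
        self.propaganda = float(propaganda)
        ss = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
        init_ss, self._step_ss = ss.spawn(2)
        rng = np.random.default_rng(init_ss)
        p = params
        n_agents = p.n_citizens + p.n_cops
        self.grid = np.full(p.n_cells, -1, dtype=np.int64)
        self.pos = rng.choice(p.n_cells, size=n_agents,
                              replace=False).astype(np.int64)
        self.grid[self.pos] = np.arange(n_agents)
        self.state = np.zeros(p.n_citizens, dtype=np.int64)  # all Quiet
        self.risk_aversion = rng.random(p.n_citizens)
        self.perceived_hardship = rng.random(p.n_citizens)
        self.jail_remaining = np.zeros(p.n_citizens, dtype=np.int64)
        self._neigh = _kernels.make_neighborhoods(p.grid_side, p.vision)
        self._step_seeds = self._step_ss.generate_state(1024)
        self.t = 0

    # -- observation -----------------------------------------------------
    def counts(self) -> tuple[int, int, int]:
        """(Quiet, Active, Jailed) citizen counts."""
        return (int(np.sum(self.state == _kernels.QUIET)),
                int(np.sum(self.state == _kernels.ACTIVE)),
                int(np.sum(self.state == _kernels.JAILED)))

    def observation(self) -> dict:
        q, a, j = self.counts()
        return {"Quiet": q, "Active": a, "Jailed": j,
                "Legitimacy": self.legitimacy, "Propaganda": self.propaganda}

    # -- dynamics --------------------------------------------------------
    def _tick_seed(self) -> int:
        while self.t >= len(self._step_seeds):
            more = self._step_ss.generate_state(len(self._step_seeds) + 1024)
            self._step_seeds = more
        return int(self._step_seeds[self.t] % (2 ** 31))

    def step(self, legitimacy: float | None = None,
             propaganda: float | None = None) -> dict:
        """Advance one tick under the given forcing levels and return the
        post-tick observation record."""
        if legitimacy is not None:
            self.legitimacy = float(legitimacy)
        if propaganda is not None:
            self.propaganda = float(propaganda)
        p = self.params
        _kernels.seed_rng(self._tick_seed())
        _kernels.step_kernel(
            self.grid, self.pos, self.state, self.risk_aversion,
            self.perceived_hardship, self.jail_remaining, self._neigh,
            p.n_citizens, p.n_cops, p.arrest_k,
            self.legitimacy, self.propaganda, p.max_jail_term,
            p.effective_jail_capacity,
        )
        self.t += 1
        return self.observation()

    # -- introspection helpers (used by property tests) ------------------
    def decision_set(self, legitimacy: float | None = None,
                     propaganda: float | None = None) -> np.ndarray:
        """Would-be-Active mask over citizens at current positions.

        Evaluates the rebellion rule for every non-jailed citizen without
        moving anyone and without consuming randomness, so the effect of
        changing propaganda or legitimacy can be compared exactly.
        """
        L = self.legitimacy if legitimacy is None else legitimacy
        P = self.propaganda if propaganda is None else propaganda
        p = self.params
        side = p.grid_side
        free = np.flatnonzero(self.state != _kernels.JAILED)
        cx, cy = self.pos[free] // side, self.pos[free] % side
        cop_pos = self.pos[p.n_citizens:]
        kx, ky = cop_pos // side, cop_pos % side
        act = free[self.state[free] == _kernels.ACTIVE]
        ax, ay = self.pos[act] // side, self.pos[act] % side

        def cheb(x1, y1, x2, y2):
            dx = np.abs(x1[:, None] - x2[None, :])
            dy = np.abs(y1[:, None] - y2[None, :])
            dx = np.minimum(dx, side - dx)
            dy = np.minimum(dy, side - dy)
            return np.maximum(dx, dy)

        n_cops_vis = (cheb(cx, cy, kx, ky) <= p.vision).sum(axis=1)
        in_vis = cheb(cx, cy, ax, ay) <= p.vision
        # a citizen does not count itself via the distance matrix ...
        self_mask = (self.state[free] == _kernels.ACTIVE)
        n_act_vis = in_vis.sum(axis=1) - self_mask.astype(int)
        ratio = n_cops_vis / (n_act_vis + 1.0)
        p_arr = 1.0 - np.exp(-p.arrest_k * ratio)
        g = self.perceived_hardship[free] * (1.0 - L)
        mask = np.zeros(p.n_citizens, dtype=bool)
        mask[free] = g - self.risk_aversion[free] * p_arr > P
        return mask


def init_world(params: ModelParams, seed, legitimacy: float = 0.82,
               propaganda: float = 0.1) -> RebellionWorld:
    """Place agents uniformly at random on distinct cells, all citizens
    Quiet, with per-citizen risk/hardship draws fixed for life."""
    return RebellionWorld(params, seed, legitimacy, propaganda)
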