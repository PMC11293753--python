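"""Compiled inner loop of the rebellion agent-based model.

All functions operate on flat numpy arrays describing the toroidal grid
and the agent population; they are jitted with numba so that multi-
thousand-step simulations stay cheap.  Randomness uses numba's internal
nopython RNG; callers must seed it with :func:`seed_rng` before every
tick so trajectories are pure functions of the supplied seeds.

Conventions: cells are indexed ``x * side + y``; agent ids ``0..n_cit-1``
are citizens, the rest cops; ``grid[cell]`` holds the occupying agent id
or -1; a jailed citizen has ``pos = -1`` and occupies no cell.  Citizen
states: 0 = Quiet, 1 = Active, 2 = Jailed.  ``neigh`` is the precomputed
vision neighborhood: ``neigh[c]`` lists the cells within Chebyshev
distance ``vision`` of ``c`` on the torus, excluding ``c`` itself.
"""

import numba as nb
import numpy as np

QUIET, ACTIVE, JAILED = 0, 1, 2


@nb.njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


def make_neighborhoods(side: int, vision: int) -> np.ndarray:
    """Per-cell toroidal Chebyshev neighborhoods of radius ``vision``."""
    offs = [(dx, dy)
            for dx in range(-vision, vision + 1)
            for dy in range(-vision, vision + 1)
            if (dx, dy) != (0, 0)]
    cells = np.arange(side * side)
    cx, cy = cells // side, cells % side
    neigh = np.empty((side * side, len(offs)), dtype=np.int64)
    for i, (dx, dy) in enumerate(offs):
        neigh[:, i] = ((cx + dx) % side) * side + (cy + dy) % side
    return neigh


@nb.njit(cache=True)
def _move(a, grid, pos, neigh):
    """Relocate agent ``a`` to a uniformly chosen empty cell within its
    vision neighborhood; stay put when none is empty."""
    c = pos[a]
    cand = neigh[c]
    n_empty = 0
    for i in range(cand.shape[0]):
        if grid[cand[i]] == -1:
            n_empty += 1
    if n_empty == 0:
        return
    j = np.random.randint(n_empty)
    for i in range(cand.shape[0]):
        cell = cand[i]
        if grid[cell] == -1:
            if j == 0:
                grid[c] = -1
                grid[cell] = a
                pos[a] = cell
                return
            j -= 1


@nb.njit(cache=True)
def _behave(a, grid, pos, state, risk, hardship, neigh, n_cit,
            k, legitimacy, propaganda):
    """Re-evaluate the Quiet/Active decision of citizen ``a``.

    The citizen estimates its arrest risk from the local cop-to-active
    ratio (counting itself as active) and rebels iff
    grievance - risk_aversion * arrest_probability > propaganda.

    The ratio enters through its floor, as in Epstein's estimated arrest
    likelihood: risk only vanishes once actives locally outnumber cops,
    which is the mechanism that lets rebellion cascades nucleate.
    """
    cand = neigh[pos[a]]
    ncop = 0
    nact = 0
    for i in range(cand.shape[0]):
        occ = grid[cand[i]]
        if occ >= n_cit:
            ncop += 1
        elif occ >= 0 and state[occ] == ACTIVE:
            nact += 1
    ratio = np.floor(ncop / (nact + 1.0))
    p_arrest = 1.0 - np.exp(-k * ratio)
    g = hardship[a] * (1.0 - legitimacy)
    if g - risk[a] * p_arrest > propaganda:
        state[a] = ACTIVE
    else:
        state[a] = QUIET


@nb.njit(cache=True)
def _enforce(a, grid, pos, state, jail_rem, neigh, n_cit,
             max_jail, jail_cap, n_jailed):
    """Cop ``a`` jails one uniformly chosen Active citizen in vision,
    if any and if jail capacity allows.  Returns the updated jail count."""
    if n_jailed >= jail_cap:
        return n_jailed
    cand = neigh[pos[a]]
    nact = 0
    for i in range(cand.shape[0]):
        occ = grid[cand[i]]
        if 0 <= occ < n_cit and state[occ] == ACTIVE:
            nact += 1
    if nact == 0:
        return n_jailed
    j = np.random.randint(nact)
    for i in range(cand.shape[0]):
        cell = cand[i]
        occ = grid[cell]
        if 0 <= occ < n_cit and state[occ] == ACTIVE:
            if j == 0:
                state[occ] = JAILED
                jail_rem[occ] = 1 + np.random.randint(max_jail)
                grid[cell] = -1
                pos[occ] = -1
                return n_jailed + 1
            j -= 1
    return n_jailed


@nb.njit(cache=True)
def _random_empty_cell(grid):
    ncells = grid.shape[0]
    for _ in range(10000):
        c = np.random.randint(ncells)
        if grid[c] == -1:
            return c
    # fall back to an exhaustive scan from a random origin
    start = np.random.randint(ncells)
    for i in range(ncells):
        c = (start + i) % ncells
        if grid[c] == -1:
            return c
    return -1


@nb.njit(cache=True)
def step_kernel(grid, pos, state, risk, hardship, jail_rem, neigh,
                n_cit, n_cops, k, legitimacy, propaganda,
                max_jail, jail_cap):
    """One synchronous tick.

    All agents mobile at tick start act in uniformly shuffled order
    (citizen: move then decide; cop: move then enforce); then jail terms
    decrement, releasing finished citizens as Quiet onto random empty
    cells.  Returns the (Quiet, Active, Jailed) counts after the tick.
    """
    n_agents = n_cit + n_cops
    n_jailed = 0
    for a in range(n_cit):
        if state[a] == JAILED:
            n_jailed += 1
    mobile = np.empty(n_agents, np.int64)
    m = 0
    for a in range(n_agents):
        if a >= n_cit or state[a] != JAILED:
            mobile[m] = a
            m += 1
    order = np.random.permutation(m)
    for i in range(m):
        a = mobile[order[i]]
        if a < n_cit:
            if state[a] == JAILED:  # arrested earlier this tick
                continue
            _move(a, grid, pos, neigh)
            _behave(a, grid, pos, state, risk, hardship, neigh, n_cit,
                    k, legitimacy, propaganda)
        else:
            _move(a, grid, pos, neigh)
            n_jailed = _enforce(a, grid, pos, state, jail_rem, neigh,
                                n_cit, max_jail, jail_cap, n_jailed)
    for a in range(n_cit):
        if state[a] == JAILED:
            jail_rem[a] -= 1
            if jail_rem[a] <= 0:
                c = _random_empty_cell(grid)
                state[a] = QUIET
                pos[a] = c
                grid[c] = a
    n_quiet = 0
    n_active = 0
    n_jail = 0
    for a in range(n_cit):
        if state[a] == QUIET:
            n_quiet += 1
        elif state[a] == ACTIVE:
            n_active += 1
        else:
            n_jail += 1
    return n_quiet, n_active, n_jail
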