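"""Numba-compiled inner loops of the lattice simulation.

Everything here operates on the raw representation: an ``(L, L)`` int8 grid of
strategy codes (see :mod:`pggmob.strategy`; -1 = empty) and an ``(L, L)``
float64 payoff accumulator.  The public API in :mod:`pggmob.dynamics` and
:mod:`pggmob.driver` wraps these functions; there is no second implementation.

Randomness uses numba's internal NumPy-compatible RNG; seed it through
:func:`seed_rng` (one stream per process, re-seeded per run for
reproducibility).
"""

from __future__ import annotations

import numpy as np
from numba import njit

EMPTY = -1
COOPERATOR = 0
DEFECTOR = 1
PUNISHER_BASE = 2
NUM_CLASSES = 11

# Moore offsets in fixed scan order (row-major over the 3x3 block, focal excluded)
MOORE_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)

# punisher decision codes
PUNISH = 0
MIGRATE = 1
STAY_IDLE = 2


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def fermi(p_i, p_j, kappa):
    """Imitation probability 1/(1+exp((p_i-p_j)/kappa)), overflow-safe."""
    x = (p_i - p_j) / kappa
    if x > 0.0:
        e = np.exp(-x)
        return e / (1.0 + e)
    return 1.0 / (1.0 + np.exp(x))


@njit(cache=True)
def gather_group(grid, fi, fj, gi, gj):
    """Fill gi/gj with the occupied group of the organizer at (fi, fj).

    The focal site comes first, then occupied Moore neighbors in scan order.
    Returns (n_members, n_contributors, n_defectors).
    """
    L = grid.shape[0]
    gi[0] = fi
    gj[0] = fj
    n = 1
    n_c = 0
    n_d = 0
    s = grid[fi, fj]
    if s == DEFECTOR:
        n_d += 1
    else:
        n_c += 1
    for k in range(8):
        ii = (fi + MOORE_OFFSETS[k, 0]) % L
        jj = (fj + MOORE_OFFSETS[k, 1]) % L
        t = grid[ii, jj]
        if t != EMPTY:
            gi[n] = ii
            gj[n] = jj
            n += 1
            if t == DEFECTOR:
                n_d += 1
            else:
                n_c += 1
    return n, n_c, n_d


@njit(cache=True)
def pgg_payoffs(grid, payoff, gi, gj, n, n_c, r, c):
    """Distribute one game's payoffs to a pre-gathered group.

    Contributors (C and P) pay c into the pool; the pool r*n_c*c is split
    equally among all n group members regardless of contribution.
    """
    share = r * n_c * c / n
    for m in range(n):
        if grid[gi[m], gj[m]] == DEFECTOR:
            payoff[gi[m], gj[m]] += share
        else:
            payoff[gi[m], gj[m]] += share - c


@njit(cache=True)
def play_pgg(grid, payoff, fi, fj, r, c):
    """One public goods game organized at (fi, fj)."""
    gi = np.empty(9, np.int64)
    gj = np.empty(9, np.int64)
    n, n_c, _ = gather_group(grid, fi, fj, gi, gj)
    pgg_payoffs(grid, payoff, gi, gj, n, n_c, r, c)


@njit(cache=True)
def punish_stage(grid, payoff, gi, gj, n, n_d, beta, gamma, organizer_only, actions):
    """Punish-or-migrate decisions for a pre-gathered group.

    Every punisher in the group (or only the organizer, if ``organizer_only``)
    compares the number of defectors n_D it met in the game with its own
    threshold theta.  n_D <= theta (and n_D >= 1): it fines every defector by
    beta at a personal cost gamma per defector.  n_D > theta: it migrates to a
    uniformly random empty Moore neighbor of its own site, punishing nobody;
    with no empty neighbor it stays idle.  n_D = 0: nothing to do.

    ``actions`` is an (9, 5) int64 scratch buffer; each acting punisher writes
    a row (site_i, site_j, decision, dest_i, dest_j) with dest = (-1, -1)
    unless it migrated.  Returns (n_actions, n_migrations).
    """
    L = grid.shape[0]
    n_act = 0
    n_mig = 0
    for m in range(n):
        ii = gi[m]
        jj = gj[m]
        t = grid[ii, jj]
        if t < PUNISHER_BASE:
            continue
        if organizer_only and m != 0:
            continue
        theta = t - PUNISHER_BASE
        actions[n_act, 0] = ii
        actions[n_act, 1] = jj
        actions[n_act, 3] = -1
        actions[n_act, 4] = -1
        if n_d == 0:
            actions[n_act, 2] = STAY_IDLE
        elif n_d <= theta:
            actions[n_act, 2] = PUNISH
            payoff[ii, jj] -= gamma * n_d
            for m2 in range(n):
                if grid[gi[m2], gj[m2]] == DEFECTOR:
                    payoff[gi[m2], gj[m2]] -= beta
        else:
            # count empty Moore neighbors of the punisher's own site
            n_empty = 0
            for k in range(8):
                ni = (ii + MOORE_OFFSETS[k, 0]) % L
                nj = (jj + MOORE_OFFSETS[k, 1]) % L
                if grid[ni, nj] == EMPTY:
                    n_empty += 1
            if n_empty == 0:
                actions[n_act, 2] = STAY_IDLE
            else:
                pick = np.random.randint(n_empty)
                for k in range(8):
                    ni = (ii + MOORE_OFFSETS[k, 0]) % L
                    nj = (jj + MOORE_OFFSETS[k, 1]) % L
                    if grid[ni, nj] == EMPTY:
                        if pick == 0:
                            grid[ni, nj] = t
                            payoff[ni, nj] = payoff[ii, jj]
                            grid[ii, jj] = EMPTY
                            payoff[ii, jj] = 0.0
                            actions[n_act, 2] = MIGRATE
                            actions[n_act, 3] = ni
                            actions[n_act, 4] = nj
                            n_mig += 1
                            break
                        pick -= 1
        n_act += 1
    return n_act, n_mig


@njit(cache=True)
def punisher_response(grid, payoff, fi, fj, beta, gamma, organizer_only, actions):
    """Punish-or-migrate stage for the group organized at (fi, fj)."""
    gi = np.empty(9, np.int64)
    gj = np.empty(9, np.int64)
    n, _, n_d = gather_group(grid, fi, fj, gi, gj)
    return punish_stage(grid, payoff, gi, gj, n, n_d, beta, gamma, organizer_only, actions)


@njit(cache=True)
def run_generation(grid, payoff, n_occupied, r, c, beta, gamma, organizer_only):
    """One evolutionary generation: n_occupied elementary steps.

    Each step draws an organizer uniformly at random among currently occupied
    sites (with replacement), plays the PGG, then applies the punish-or-migrate
    stage.  Payoffs are reset at the start.  Returns the number of voluntary
    (threshold-triggered) punisher migrations.
    """
    payoff[:, :] = 0.0
    if n_occupied == 0:
        return 0
    L = grid.shape[0]
    actions = np.empty((9, 5), np.int64)
    gi = np.empty(9, np.int64)
    gj = np.empty(9, np.int64)
    steps = 0
    total_mig = 0
    while steps < n_occupied:
        fi = np.random.randint(L)
        fj = np.random.randint(L)
        if grid[fi, fj] == EMPTY:
            continue
        n, n_c, n_d = gather_group(grid, fi, fj, gi, gj)
        pgg_payoffs(grid, payoff, gi, gj, n, n_c, r, c)
        _, n_mig = punish_stage(grid, payoff, gi, gj, n, n_d, beta, gamma, organizer_only, actions)
        total_mig += n_mig
        steps += 1
    return total_mig


@njit(cache=True)
def synchronous_update(grid, payoff, kappa):
    """Synchronous Fermi imitation over the whole population.

    Every agent i picks one occupied Moore neighbor j uniformly at random and
    adopts j's full strategy (kind and theta) with probability
    fermi(P_i, P_j, kappa), all decisions based on the pre-update grid and the
    generation's accumulated payoffs.  Agents without occupied neighbors keep
    their strategy.  Mutates ``grid`` in place at the end.
    """
    L = grid.shape[0]
    new = grid.copy()
    ci = np.empty(8, np.int64)
    cj = np.empty(8, np.int64)
    for i in range(L):
        for j in range(L):
            s = grid[i, j]
            if s == EMPTY:
                continue
            n_occ = 0
            for k in range(8):
                ni = (i + MOORE_OFFSETS[k, 0]) % L
                nj = (j + MOORE_OFFSETS[k, 1]) % L
                if grid[ni, nj] != EMPTY:
                    ci[n_occ] = ni
                    cj[n_occ] = nj
                    n_occ += 1
            if n_occ == 0:
                continue
            pick = np.random.randint(n_occ)
            p = fermi(payoff[i, j], payoff[ci[pick], cj[pick]], kappa)
            if np.random.random() < p:
                new[i, j] = grid[ci[pick], cj[pick]]
    grid[:, :] = new


@njit(cache=True)
def random_diffusion(grid, payoff, epsilon):
    """Background migration: each agent moves with probability epsilon.

    Agents are visited in a uniformly random order; a moving agent relocates to
    an empty site chosen uniformly from its Moore neighborhood (staying put if
    it has none).  Keeps isolated clusters from freezing permanently.
    """
    if epsilon <= 0.0:
        return
    L = grid.shape[0]
    si = np.empty(L * L, np.int64)
    sj = np.empty(L * L, np.int64)
    n = 0
    for i in range(L):
        for j in range(L):
            if grid[i, j] != EMPTY:
                si[n] = i
                sj[n] = j
                n += 1
    # Fisher-Yates shuffle of the visit order
    for t in range(n - 1, 0, -1):
        u = np.random.randint(t + 1)
        si[t], si[u] = si[u], si[t]
        sj[t], sj[u] = sj[u], sj[t]
    for t in range(n):
        i = si[t]
        j = sj[t]
        if np.random.random() >= epsilon:
            continue
        n_empty = 0
        for k in range(8):
            ni = (i + MOORE_OFFSETS[k, 0]) % L
            nj = (j + MOORE_OFFSETS[k, 1]) % L
            if grid[ni, nj] == EMPTY:
                n_empty += 1
        if n_empty == 0:
            continue
        pick = np.random.randint(n_empty)
        for k in range(8):
            ni = (i + MOORE_OFFSETS[k, 0]) % L
            nj = (j + MOORE_OFFSETS[k, 1]) % L
            if grid[ni, nj] == EMPTY:
                if pick == 0:
                    grid[ni, nj] = grid[i, j]
                    payoff[ni, nj] = payoff[i, j]
                    grid[i, j] = EMPTY
                    payoff[i, j] = 0.0
                    break
                pick -= 1


@njit(cache=True)
def class_counts(grid, out):
    """Count agents per strategy code into ``out`` (length NUM_CLASSES)."""
    out[:] = 0
    L = grid.shape[0]
    for i in range(L):
        for j in range(L):
            s = grid[i, j]
            if s != EMPTY:
                out[s] += 1


@njit(cache=True)
def run_mcs_block(grid, payoff, r, c, beta, gamma, kappa, epsilon, organizer_only, n_mcs, counts_out):
    """Run up to ``n_mcs`` full Monte Carlo steps, recording class counts.

    One MCS = one generation (N_occupied elementary game steps) + one
    synchronous imitation sweep + one epsilon-diffusion pass.  Stops early if
    the population becomes compositionally uniform (absorbing state).

    ``counts_out`` has shape (n_mcs, NUM_CLASSES); row t gets the counts after
    MCS t.  Returns (mcs_done, absorbed, voluntary_migrations).
    """
    L = grid.shape[0]
    n_occ = 0
    for i in range(L):
        for j in range(L):
            if grid[i, j] != EMPTY:
                n_occ += 1
    done = 0
    absorbed = False
    total_mig = 0
    for t in range(n_mcs):
        total_mig += run_generation(grid, payoff, n_occ, r, c, beta, gamma, organizer_only)
        synchronous_update(grid, payoff, kappa)
        random_diffusion(grid, payoff, epsilon)
        class_counts(grid, counts_out[t])
        done = t + 1
        for k in range(NUM_CLASSES):
            if counts_out[t, k] == n_occ:
                absorbed = True
                break
        if absorbed:
            break
    return done, absorbed, total_mig
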