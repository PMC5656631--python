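"""The diluted periodic square lattice: construction, geometry, snapshots.

The population lives on an L x L toroidal lattice at density rho; empty sites
are the niches punishers can migrate into.  Coordinates are 0-based
(row, col), row-major, with wraparound by modular arithmetic.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import strategy as st
from ._kernel import MOORE_OFFSETS
from .params import InitialComposition, SimulationParams

__all__ = [
    "Population",
    "moore_neighborhood",
    "init_population",
    "group_members",
]


def moore_neighborhood(site: tuple, L: int) -> list:
    """The 8 Chebyshev-distance-1 neighbors of ``site`` with periodic wrap.

    All returned coordinates are distinct and exclude the focal site (L >= 3
    guarantees no self-wrap).
    """
    i, j = site
    if not (0 <= i < L and 0 <= j < L):
        raise ValueError(f"site {site} outside [0, {L})^2")
    return [((i + di) % L, (j + dj) % L) for di, dj in MOORE_OFFSETS]


class Population:
    """Lattice state: per-site occupancy and strategy, toroidal geometry.

    ``grid`` is an (L, L) int8 array of strategy codes, -1 for empty.  The
    number of occupied sites is constant over a simulation: imitation changes
    strategies in place and migration only relocates agents.
    """

    def __init__(self, grid: np.ndarray):
        grid = np.asarray(grid, dtype=np.int8)
        if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
            raise ValueError(f"grid must be square, got shape {grid.shape}")
        if grid.shape[0] < 3:
            raise ValueError("lattice side must be >= 3")
        lo, hi = grid.min(), grid.max()
        if lo < st.EMPTY or hi >= st.NUM_CLASSES:
            raise ValueError("grid contains invalid strategy codes")
        self.grid = grid

    @property
    def L(self) -> int:
        return self.grid.shape[0]

    @property
    def occupancy_count(self) -> int:
        return int(np.count_nonzero(self.grid != st.EMPTY))

    def class_counts(self) -> dict:
        """Agents per class label (all 11 classes, zeros included)."""
        counts = np.bincount(self.grid[self.grid != st.EMPTY].astype(np.int64), minlength=st.NUM_CLASSES)
        return {lab: int(counts[i]) for i, lab in enumerate(st.CLASS_LABELS)}

    def class_fractions(self) -> dict:
        n = self.occupancy_count
        if n == 0:
            return {lab: 0.0 for lab in st.CLASS_LABELS}
        return {lab: cnt / n for lab, cnt in self.class_counts().items()}

    def copy(self) -> "Population":
        return Population(self.grid.copy())

    # -- plain-text snapshot format ------------------------------------------
    # one character per site: '.' empty, 'C', 'D', '0'-'8' punisher with that theta

    _CODE_TO_CHAR = {st.EMPTY: ".", st.COOPERATOR: "C", st.DEFECTOR: "D"}
    _CHAR_TO_CODE = {".": st.EMPTY, "C": st.COOPERATOR, "D": st.DEFECTOR}
    for _t in range(st.THETA_MAX + 1):
        _CODE_TO_CHAR[st.PUNISHER_BASE + _t] = str(_t)
        _CHAR_TO_CODE[str(_t)] = st.PUNISHER_BASE + _t
    del _t

    def to_text(self) -> str:
        return "\n".join("".join(self._CODE_TO_CHAR[int(v)] for v in row) for row in self.grid)

    @classmethod
    def from_text(cls, text: str) -> "Population":
        rows = [line.strip() for line in text.strip().splitlines() if line.strip()]
        try:
            grid = np.array([[cls._CHAR_TO_CODE[ch] for ch in row] for row in rows], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"invalid snapshot character {exc.args[0]!r}") from None
        if len({len(r) for r in rows}) != 1:
            raise ValueError("snapshot rows have unequal lengths")
        return cls(grid)

    def __eq__(self, other) -> bool:
        return isinstance(other, Population) and np.array_equal(self.grid, other.grid)

    def __repr__(self) -> str:
        return f"Population(L={self.L}, occupied={self.occupancy_count})"


def _composition_counts(composition: InitialComposition, n_occupied: int) -> dict:
    """Integer class counts for n_occupied agents.

    Each class gets round(fraction * N) (half away from zero); any remainder is
    assigned to the largest-fraction class, ties broken by canonical class
    order (C, D, P0..P8).
    """
    labels = composition.classes
    counts = {}
    for lab in labels:
        f = composition.fractions[lab]
        cnt = int(np.floor(f * n_occupied + 0.5))
        if f > 0 and cnt == 0:
            warnings.warn(
                f"fraction {f} of class {lab} rounds to 0 agents at N={n_occupied}",
                stacklevel=3,
            )
        counts[lab] = cnt
    remainder = n_occupied - sum(counts.values())
    if remainder != 0:
        largest = max(labels, key=lambda lab: (composition.fractions[lab], -st.code_for_label(lab)))
        counts[largest] += remainder
        if counts[largest] < 0:
            raise ValueError("composition rounding produced a negative count")
    return counts


def init_population(
    params: SimulationParams,
    composition: InitialComposition,
    rng: np.random.Generator | None = None,
) -> Population:
    """Random initial population at density rho with the given composition.

    round(rho * L^2) sites are occupied, chosen uniformly at random; strategies
    are assigned in the requested proportions and placed uniformly at random
    among the occupied sites (i.i.d. placement, no initial clustering).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    L = params.L
    n_occ = int(np.floor(params.rho * L * L + 0.5))
    grid = np.full((L, L), st.EMPTY, dtype=np.int8)
    if n_occ == 0:
        return Population(grid)
    sites = rng.choice(L * L, size=n_occ, replace=False)
    codes = np.empty(n_occ, dtype=np.int8)
    pos = 0
    for lab, cnt in _composition_counts(composition, n_occ).items():
        codes[pos : pos + cnt] = st.code_for_label(lab)
        pos += cnt
    rng.shuffle(codes)
    grid.flat[sites] = codes
    return Population(grid)


def group_members(pop: Population, focal: tuple) -> list:
    """Occupied sites of the game group organized at ``focal``.

    The focal site (which must be occupied — only occupied sites organize
    games) comes first, followed by its occupied Moore neighbors; between 1
    and 9 members.
    """
    i, j = focal
    if pop.grid[i, j] == st.EMPTY:
        raise ValueError(f"focal site {focal} is empty; only occupied sites organize games")
    members = [(i, j)]
    for site in moore_neighborhood(focal, pop.L):
        if pop.grid[site] != st.EMPTY:
            members.append(site)
    return members
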