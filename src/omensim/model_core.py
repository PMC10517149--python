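"""Cells, states and the cubic lattice underlying the hybrid automaton.

The virtual culture is a cubic lattice whose nodes hold at most one cell.
z = 0 is the culture bottom; the bottom half of the grid is seeded with
fibroblasts, a thin mesothelial band sits immediately above, and cancer
cells are placed on top of the mesothelium, mimicking the layered omentum
lining colonised during transcoelomic metastasis.

Cell bookkeeping is kept as flat numpy arrays (struct-of-arrays) for speed;
:class:`Cell` objects are lightweight views materialised on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "CellState",
    "Cell",
    "LatticeState",
    "SeedingSpec",
    "build_lattice",
    "seed_layered_culture",
    "count_by_state",
]


class CellState(IntEnum):
    """The five cell states of the automaton.

    Stromal states (fibroblast, mesothelial) have no behavioural rules and
    never transition; the three cancer states carry the dynamics.
    """

    FIBROBLAST = 0
    MESOTHELIAL = 1
    CANCER_PROLIFERATING = 2
    CANCER_QUIESCENT = 3
    CANCER_DEAD = 4


#: states that occupy a node and consume nutrients
LIVING_STATES = (
    CellState.FIBROBLAST,
    CellState.MESOTHELIAL,
    CellState.CANCER_PROLIFERATING,
    CellState.CANCER_QUIESCENT,
)
STROMAL_STATES = (CellState.FIBROBLAST, CellState.MESOTHELIAL)
CANCER_STATES = (
    CellState.CANCER_PROLIFERATING,
    CellState.CANCER_QUIESCENT,
    CellState.CANCER_DEAD,
)


def is_stromal(state: int) -> bool:
    return state in (CellState.FIBROBLAST, CellState.MESOTHELIAL)


def is_cancer(state: int) -> bool:
    return state in CANCER_STATES


@dataclass(frozen=True)
class Cell:
    """Immutable view of one cell's record.

    ``death_iteration`` is ``None`` unless the cell is dead; iteration
    counters are in hours (one iteration = one hour).
    """

    id: int
    state: CellState
    position: tuple[int, int, int]
    birth_iteration: int
    last_division_iteration: int
    death_iteration: int | None


@dataclass
class SeedingSpec:
    """Layered seeding of the virtual omentum.

    Fibroblasts occupy z in [0, Z//2); the mesothelial band of
    ``mesothelial_thickness`` layers sits immediately above; cancer cells
    are seeded in the ``cancer_thickness`` layers above the mesothelium.
    """

    n_fibroblast: int = 400
    n_mesothelial: int = 200
    n_cancer: int = 100
    mesothelial_thickness: int = 1
    cancer_thickness: int = 2

    def regions(self, dims: tuple[int, int, int]) -> dict[str, tuple[int, int]]:
        """Half-open z bands (lo, hi) for each seeded population."""
        z_half = dims[2] // 2
        meso_hi = z_half + self.mesothelial_thickness
        cancer_hi = meso_hi + self.cancer_thickness
        if cancer_hi > dims[2]:
            raise ValueError(
                f"seeding bands exceed lattice depth {dims[2]}: "
                f"fibroblast [0,{z_half}), mesothelial [{z_half},{meso_hi}), "
                f"cancer [{meso_hi},{cancer_hi})"
            )
        return {
            "fibroblast": (0, z_half),
            "mesothelial": (z_half, meso_hi),
            "cancer": (meso_hi, cancer_hi),
        }


class LatticeState:
    """Cubic lattice with per-node occupancy and a growable cell table.

    ``occupancy[x, y, z]`` holds the cell index at that node or -1.
    Removed (degraded) cells keep their row but are flagged absent, so ids
    stay stable for the whole simulation.
    """

    _EMPTY = -1

    def __init__(self, dims: tuple[int, int, int]):
        dims = tuple(int(d) for d in dims)
        if len(dims) != 3 or any(d < 4 for d in dims):
            raise ValueError(f"lattice dims must be three integers >= 4, got {dims}")
        self.dims: tuple[int, int, int] = dims
        self.iteration: int = 0
        self.occupancy = np.full(dims, self._EMPTY, dtype=np.int32)
        cap = 256
        self._state = np.empty(cap, dtype=np.int8)
        self._pos = np.empty((cap, 3), dtype=np.int16)
        self._birth = np.empty(cap, dtype=np.int32)
        self._last_div = np.empty(cap, dtype=np.int32)
        self._death = np.empty(cap, dtype=np.int32)  # -1 = not dead
        self._present = np.zeros(cap, dtype=bool)
        self._n = 0  # rows used (including removed cells)

    # -- storage ---------------------------------------------------------

    def ensure_capacity(self, capacity: int) -> None:
        """Pre-allocate row storage (the engine sizes it to the node count,
        the hard ceiling on the cell population)."""
        while len(self._state) < capacity:
            self._grow()

    def _grow(self) -> None:
        cap = len(self._state) * 2
        for name in ("_state", "_birth", "_last_div", "_death", "_present"):
            arr = getattr(self, name)
            new = np.zeros(cap, dtype=arr.dtype)
            new[: self._n] = arr[: self._n]
            setattr(self, name, new)
        new_pos = np.zeros((cap, 3), dtype=np.int16)
        new_pos[: self._n] = self._pos[: self._n]
        self._pos = new_pos

    def add_cell(
        self,
        state: CellState,
        position: tuple[int, int, int],
        birth_iteration: int = 0,
    ) -> int:
        x, y, z = position
        if not self.in_bounds(position):
            raise ValueError(f"position {position} outside lattice {self.dims}")
        if self.occupancy[x, y, z] != self._EMPTY:
            raise ValueError(f"node {position} already occupied")
        if self._n == len(self._state):
            self._grow()
        i = self._n
        self._n += 1
        self._state[i] = int(state)
        self._pos[i] = position
        self._birth[i] = birth_iteration
        self._last_div[i] = birth_iteration
        self._death[i] = -1
        self._present[i] = True
        self.occupancy[x, y, z] = i
        return i

    def remove_cell(self, cell_id: int) -> None:
        if not self._present[cell_id]:
            raise ValueError(f"cell {cell_id} not on the lattice")
        x, y, z = self._pos[cell_id]
        self.occupancy[x, y, z] = self._EMPTY
        self._present[cell_id] = False

    def move_cell(self, cell_id: int, new_position: tuple[int, int, int]) -> None:
        x, y, z = new_position
        if self.occupancy[x, y, z] != self._EMPTY:
            raise ValueError(f"node {new_position} already occupied")
        ox, oy, oz = self._pos[cell_id]
        self.occupancy[ox, oy, oz] = self._EMPTY
        self.occupancy[x, y, z] = cell_id
        self._pos[cell_id] = new_position

    # -- queries ---------------------------------------------------------

    def in_bounds(self, position) -> bool:
        x, y, z = position
        return 0 <= x < self.dims[0] and 0 <= y < self.dims[1] and 0 <= z < self.dims[2]

    @property
    def n_cells(self) -> int:
        return int(self._present[: self._n].sum())

    def present_ids(self) -> np.ndarray:
        return np.nonzero(self._present[: self._n])[0]

    def states(self) -> np.ndarray:
        """States of present cells (aligned with :meth:`present_ids`)."""
        return self._state[self.present_ids()]

    def positions(self) -> np.ndarray:
        return self._pos[self.present_ids()]

    def cell(self, cell_id: int) -> Cell:
        if cell_id >= self._n:
            raise ValueError(f"no cell with id {cell_id}")
        death = int(self._death[cell_id])
        return Cell(
            id=int(cell_id),
            state=CellState(int(self._state[cell_id])),
            position=tuple(int(v) for v in self._pos[cell_id]),
            birth_iteration=int(self._birth[cell_id]),
            last_division_iteration=int(self._last_div[cell_id]),
            death_iteration=None if death < 0 else death,
        )

    def cells(self) -> Iterator[Cell]:
        for i in self.present_ids():
            yield self.cell(int(i))

    def to_dataframe(self) -> pd.DataFrame:
        """Columnar snapshot: id, state, x, y, z, birth, death, last_division."""
        ids = self.present_ids()
        return pd.DataFrame(
            {
                "id": ids,
                "state": [CellState(int(s)).name for s in self._state[ids]],
                "x": self._pos[ids, 0].astype(int),
                "y": self._pos[ids, 1].astype(int),
                "z": self._pos[ids, 2].astype(int),
                "birth": self._birth[ids].astype(int),
                "death": self._death[ids].astype(int),
                "last_division": self._last_div[ids].astype(int),
            }
        )


def build_lattice(dims: tuple[int, int, int]) -> LatticeState:
    """Create an empty lattice; every dimension must be at least 4 nodes."""
    return LatticeState(dims)


def _seed_region(
    lattice: LatticeState,
    z_band: tuple[int, int],
    n: int,
    state: CellState,
    rng: np.random.Generator,
) -> None:
    X, Y, _ = lattice.dims
    lo, hi = z_band
    band = lattice.occupancy[:, :, lo:hi]
    free = np.nonzero(band.ravel() == LatticeState._EMPTY)[0]
    if n > free.size:
        raise ValueError(
            f"cannot seed {n} {state.name} cells into {free.size} free nodes "
            f"of z-band [{lo},{hi})"
        )
    chosen = rng.choice(free, size=n, replace=False)
    xs, ys, zs = np.unravel_index(chosen, band.shape)
    for x, y, z in zip(xs, ys, zs + lo):
        lattice.add_cell(state, (int(x), int(y), int(z)))


def seed_layered_culture(
    lattice: LatticeState,
    spec: SeedingSpec,
    rng: np.random.Generator | int,
) -> LatticeState:
    """Populate an empty lattice with the layered omentum arrangement.

    Positions are drawn uniformly without replacement within each z band.
    All seeded cancer cells start proliferating. Raises ``ValueError`` if a
    band cannot hold the requested count.
    """
    if lattice.n_cells:
        raise ValueError("seed_layered_culture requires an empty lattice")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    regions = spec.regions(lattice.dims)
    _seed_region(lattice, regions["fibroblast"], spec.n_fibroblast, CellState.FIBROBLAST, rng)
    _seed_region(lattice, regions["mesothelial"], spec.n_mesothelial, CellState.MESOTHELIAL, rng)
    _seed_region(lattice, regions["cancer"], spec.n_cancer, CellState.CANCER_PROLIFERATING, rng)
    return lattice


def count_by_state(lattice: LatticeState) -> dict[CellState, int]:
    """Number of cells currently on the lattice, per state."""
    counts = dict.fromkeys(CellState, 0)
    states = lattice.states()
    for s, c in zip(*np.unique(states, return_counts=True)):
        counts[CellState(int(s))] = int(c)
    return counts
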