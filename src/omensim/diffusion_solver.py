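"""Continuous component of the hybrid model.

Normalised glucose, oxygen and drug concentrations live on the same cubic
lattice as the cells. Each hourly iteration performs one forward-Euler
diffusion update (internally sub-stepped to satisfy the explicit-scheme
stability bound), linear consumption by living cells, first-order drug
decay, and optional top-face reservoir boundary (the media above the
culture). All concentrations are dimensionless: nutrients are normalised
to their media concentration, drug to the administered amount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model_core import LatticeState, CellState

__all__ = [
    "ContinuousField",
    "DiffusionParams",
    "Environment",
    "make_environment",
    "step_environment",
    "sample_local",
]

FIELD_NAMES = ("glucose", "oxygen", "drug")

#: forward-Euler stability requires D*dt_sub <= 1/6 on a 3D unit grid;
#: substeps are chosen so D*dt_sub <= this safety value.
_ALPHA_MAX = 0.15


@dataclass
class ContinuousField:
    """One scalar field on the lattice, in normalised units."""

    name: str
    values: np.ndarray
    diffusivity: float  # nodes^2 / hour

    def __post_init__(self):
        if self.name not in FIELD_NAMES:
            raise ValueError(f"unknown field {self.name!r}")
        if np.any(self.values < 0):
            raise ValueError("field values must be non-negative")


@dataclass
class DiffusionParams:
    """Transport and reaction rates of the continuous environment.

    ``consumption`` is removed per living cell per hour from the cell's
    node, floored at zero. ``drug_decay_rate`` is the first-order decay
    constant (default half-life 24 h). ``boundary_mode`` is either
    ``"top_reservoir"`` (top face clamped to the media value: 1.0 for
    nutrients, the administered normalised dose for drug while treatment
    is active) or ``"closed"`` (zero-flux on all faces).
    """

    diffusivity: dict[str, float] = field(
        default_factory=lambda: {"glucose": 1.0, "oxygen": 1.0, "drug": 1.0}
    )
    consumption: dict[str, float] = field(
        default_factory=lambda: {"glucose": 0.005, "oxygen": 0.005, "drug": 0.0}
    )
    drug_decay_rate: float = math.log(2.0) / 24.0  # 1/h
    boundary_mode: str = "top_reservoir"

    def __post_init__(self):
        if self.boundary_mode not in ("top_reservoir", "closed"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        for d in (self.diffusivity, self.consumption):
            if any(v < 0 for v in d.values()):
                raise ValueError("rates must be non-negative")
        if self.drug_decay_rate < 0:
            raise ValueError("drug_decay_rate must be non-negative")


@dataclass
class Environment:
    """The three continuous fields plus the treatment switch."""

    fields: dict[str, ContinuousField]
    treatment_active: bool = False
    dose_norm: float = 1.0  # reservoir value of the normalised drug field

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.fields["glucose"].values.shape


def make_environment(
    dims: tuple[int, int, int], params: DiffusionParams | None = None
) -> Environment:
    """Fresh environment: nutrients at 1.0 everywhere, no drug."""
    params = params or DiffusionParams()
    fields = {}
    for name in FIELD_NAMES:
        init = 0.0 if name == "drug" else 1.0
        fields[name] = ContinuousField(
            name=name,
            values=np.full(dims, init, dtype=np.float64),
            diffusivity=params.diffusivity[name],
        )
    return Environment(fields=fields)


def administer_drug(env: Environment, dose_norm: float = 1.0) -> None:
    """Activate treatment: the top face acts as a drug reservoir at
    ``dose_norm`` (the field is normalised to the administered amount,
    so 1.0 by convention)."""
    env.treatment_active = True
    env.dose_norm = float(dose_norm)
    env.fields["drug"].values[:, :, -1] = dose_norm


@njit(cache=True)
def _evolve(u, alpha, n_sub, cell_counts, rate, dt_sub, decay_sub, top_value):
    """Sub-stepped forward-Euler diffusion with zero-flux walls.

    ``top_value`` is NaN for a closed box, otherwise the Dirichlet value
    reimposed on the z = Z-1 face after every substep. Consumption is
    ``cell_counts * rate`` per hour per node; values are clamped at 0.
    """
    X, Y, Z = u.shape
    src = u
    dst = np.empty_like(u)
    for _ in range(n_sub):
        for x in range(X):
            for y in range(Y):
                for z in range(Z):
                    c = src[x, y, z]
                    acc = 0.0
                    if x > 0:
                        acc += src[x - 1, y, z] - c
                    if x < X - 1:
                        acc += src[x + 1, y, z] - c
                    if y > 0:
                        acc += src[x, y - 1, z] - c
                    if y < Y - 1:
                        acc += src[x, y + 1, z] - c
                    if z > 0:
                        acc += src[x, y, z - 1] - c
                    if z < Z - 1:
                        acc += src[x, y, z + 1] - c
                    v = c + alpha * acc - cell_counts[x, y, z] * rate * dt_sub
                    v *= decay_sub
                    if v < 0.0:
                        v = 0.0
                    dst[x, y, z] = v
        if not math.isnan(top_value):
            for x in range(X):
                for y in range(Y):
                    dst[x, y, Z - 1] = top_value
        swap = src
        src = dst
        dst = swap
    if src is not u:
        u[:, :, :] = src


def _living_cell_grid(lattice: LatticeState) -> np.ndarray:
    """Per-node count of living cells (all states except dead)."""
    X, Y, Z = lattice.dims
    ids = lattice.present_ids()
    if not ids.size:
        return np.zeros(lattice.dims, dtype=np.float64)
    states = lattice._state[ids]
    pos = lattice._pos[ids[states != int(CellState.CANCER_DEAD)]].astype(np.int64)
    flat = (pos[:, 0] * Y + pos[:, 1]) * Z + pos[:, 2]
    return np.bincount(flat, minlength=X * Y * Z).reshape(lattice.dims).astype(np.float64)


def step_environment(
    env: Environment,
    lattice: LatticeState,
    params: DiffusionParams,
    dt: float = 1.0,
    cell_grid: np.ndarray | None = None,
) -> Environment:
    """Advance all fields by ``dt`` hours (diffusion, consumption, decay).

    ``cell_grid`` optionally supplies the per-node living-cell counts (the
    engine maintains one incrementally); otherwise it is derived from the
    lattice.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if env.dims != lattice.dims:
        raise ValueError(f"environment dims {env.dims} != lattice dims {lattice.dims}")

    counts = _living_cell_grid(lattice) if cell_grid is None else cell_grid
    any_cells = bool(counts.any())

    for name in FIELD_NAMES:
        f = env.fields[name]
        D = params.diffusivity[name]
        rate = params.consumption[name]
        decay = params.drug_decay_rate if name == "drug" else 0.0

        if name == "drug" and not env.treatment_active and not f.values.any():
            continue  # untreated run: field identically zero

        if params.boundary_mode == "top_reservoir":
            if name == "drug":
                top = env.dose_norm if env.treatment_active else math.nan
            else:
                top = 1.0
        else:
            top = math.nan

        n_sub = max(1, math.ceil(D * dt / _ALPHA_MAX)) if D > 0 else 1
        dt_sub = dt / n_sub
        alpha = D * dt_sub
        decay_sub = math.exp(-decay * dt_sub) if decay > 0 else 1.0
        if D == 0 and (rate == 0 or not any_cells) and decay == 0 and math.isnan(top):
            continue  # nothing to do
        _evolve(f.values, alpha, n_sub, counts, rate, dt_sub, decay_sub, top)
    return env


def sample_local(env: Environment, position: tuple[int, int, int]):
    """Normalised (Glu, O2, D) at a node, plus the depth fraction D0.

    Returns an :class:`~omensim.behaviour_rules.EnvLocal`; D0 = z/(Z-1)
    so that 0 is the culture bottom and 1 the top face.
    """
    from .behaviour_rules import EnvLocal

    x, y, z = position
    X, Y, Z = env.dims
    if not (0 <= x < X and 0 <= y < Y and 0 <= z < Z):
        raise ValueError(f"position {position} outside lattice {env.dims}")
    return EnvLocal(
        glu=float(env.fields["glucose"].values[x, y, z]),
        o2=float(env.fields["oxygen"].values[x, y, z]),
        drug=float(env.fields["drug"].values[x, y, z]),
        depth_frac=z / (Z - 1),
    )
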