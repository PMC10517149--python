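"""Hourly iteration loop of the hybrid automaton.

Each iteration (one hour) first advances the continuous environment, then
visits every cancer cell in a freshly shuffled order and executes exactly
one sampled rule per cell. Division places a daughter in a uniformly
random free Moore neighbour (silently failing when the neighbourhood is
full); migration moves a cell one node toward the culture bottom,
displacing a stromal occupant to a random free neighbour when needed;
degradation removes dead cells. The per-cell update is JIT-compiled
(numba) and operates directly on the lattice's flat arrays; its RNG is
seeded from the run seed, so trajectories are bitwise reproducible.

The arc probabilities computed in the kernel are the same expressions as
:mod:`omensim.behaviour_rules`; the scalar functions there remain the
readable reference and are cross-checked against the kernel's aggregate
behaviour in the test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .behaviour_rules import DrugParameters, RuleParameters, NUTRIENT_FLOOR
from .diffusion_solver import (
    DiffusionParams,
    Environment,
    administer_drug,
    make_environment,
    step_environment,
)
from .model_core import (
    CellState,
    LatticeState,
    SeedingSpec,
    build_lattice,
    seed_layered_culture,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "ReplicateSet",
    "run_simulation",
    "run_replicates",
    "simulate_dose_response",
]

_N_STATES = 5
_PROLIF = int(CellState.CANCER_PROLIFERATING)
_QUIESC = int(CellState.CANCER_QUIESCENT)
_DEAD = int(CellState.CANCER_DEAD)


@dataclass
class SimulationConfig:
    """One simulated culture. ``n_iterations`` hours at dt = 1 h."""

    rule_params: RuleParameters
    dims: tuple[int, int, int] = (20, 20, 20)
    seeding: SeedingSpec = field(
        default_factory=lambda: SeedingSpec(n_fibroblast=120, n_mesothelial=60, n_cancer=30)
    )
    drug_params: DrugParameters | None = None
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    n_iterations: int = 72
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class SimulationResult:
    """Per-iteration observables of one run (row 0 = initial state).

    ``counts`` is (n_iterations+1, 5) cells per state; ``z_counts`` is
    (n_iterations+1, 5, Z); the event arrays are cumulative tallies.
    """

    counts: np.ndarray
    z_counts: np.ndarray
    migration_cum: np.ndarray
    division_cum: np.ndarray
    degradation_cum: np.ndarray
    final_lattice: LatticeState
    rng_seed: int | None = None

    @property
    def migration_events(self) -> int:
        return int(self.migration_cum[-1])

    @property
    def division_events(self) -> int:
        return int(self.division_cum[-1])

    def cancer_counts(self, include_dead: bool = True) -> np.ndarray:
        """Cancer cells on the lattice over time.

        By default dead-but-not-yet-degraded cells are included: this is
        the count the calibration scores use (the reference assays count
        nuclei / stained cells). Pass ``include_dead=False`` for the live
        count used in viability readouts.
        """
        live = self.counts[:, _PROLIF] + self.counts[:, _QUIESC]
        return live + self.counts[:, _DEAD] if include_dead else live

    @property
    def c0(self) -> int:
        return int(self.cancer_counts()[0])


@njit(cache=True)
def _step_cells(
    state,
    pos,
    birth,
    last_div,
    death,
    present,
    occ,
    n_rows,
    t,
    inv_T,
    a,
    b,
    c,
    d,
    e,
    use_drug,
    f,
    g,
    dose,
    ic50,
    hill,
    glu,
    o2,
    drugf,
):
    """One iteration of shuffled per-cell rule sampling and execution.

    Mutates the lattice arrays in place; returns the new row count and
    the numbers of divisions, migrations and degradations executed.
    numba's global RNG must have been seeded by the caller.
    """
    X, Y, Z = occ.shape
    zden = float(Z - 1)

    ids = np.empty(n_rows, dtype=np.int64)
    m = 0
    for i in range(n_rows):
        if present[i] and state[i] >= 2:
            ids[m] = i
            m += 1
    # Fisher-Yates shuffle
    for i in range(m - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = ids[i]
        ids[i] = ids[j]
        ids[j] = tmp

    n = n_rows
    divisions = 0
    migrations = 0
    degradations = 0
    # scratch buffers for free-neighbour gathering, reused across cells
    fx = np.empty(26, dtype=np.int64)
    fy = np.empty(26, dtype=np.int64)
    fz = np.empty(26, dtype=np.int64)

    for k in range(m):
        cid = ids[k]
        s = state[cid]
        x = pos[cid, 0]
        y = pos[cid, 1]
        z = pos[cid, 2]
        u = np.random.random()

        if s == 4:  # dead: degrade with d*(Tc - Td)
            p_deg = d * (t - death[cid]) * inv_T
            if p_deg > 1.0:
                p_deg = 1.0
            if u < p_deg:
                occ[x, y, z] = -1
                present[cid] = False
                degradations += 1
            continue

        nutrients = glu[x, y, z] + o2[x, y, z]
        s_drug = 0.0
        if use_drug:
            conc = drugf[x, y, z] * dose
            if conc > 0.0:
                ch = conc**hill
                s_drug = ch / (ch + ic50**hill)

        denom = nutrients if nutrients > NUTRIENT_FLOOR else NUTRIENT_FLOOR
        age = (t - birth[cid]) * inv_T

        if s == 2:  # proliferating: divide / migrate / go quiescent
            tld = (t - last_div[cid]) * inv_T
            p_div = a * tld + c * nutrients - f * s_drug
            if p_div < 0.0:
                p_div = 0.0
            elif p_div > 1.0:
                p_div = 1.0
            p_mig = e * (z / zden)
            if p_mig > 1.0:
                p_mig = 1.0
            p_q = b * age / denom
            if p_q > 1.0:
                p_q = 1.0
            total = p_div + p_mig + p_q
            if total > 1.0:
                p_div /= total
                p_mig /= total
                p_q /= total
                total = 1.0

            if u < p_div:
                # divide into a uniformly random free Moore neighbour
                nfree = 0
                for dx in range(-1, 2):
                    for dy in range(-1, 2):
                        for dz in range(-1, 2):
                            if dx == 0 and dy == 0 and dz == 0:
                                continue
                            nx = x + dx
                            ny = y + dy
                            nz = z + dz
                            if (
                                0 <= nx < X
                                and 0 <= ny < Y
                                and 0 <= nz < Z
                                and occ[nx, ny, nz] < 0
                            ):
                                fx[nfree] = nx
                                fy[nfree] = ny
                                fz[nfree] = nz
                                nfree += 1
                if nfree > 0:
                    pick = np.random.randint(0, nfree)
                    row = n
                    n += 1
                    state[row] = 2
                    pos[row, 0] = fx[pick]
                    pos[row, 1] = fy[pick]
                    pos[row, 2] = fz[pick]
                    birth[row] = t
                    last_div[row] = t
                    death[row] = -1
                    present[row] = True
                    occ[fx[pick], fy[pick], fz[pick]] = row
                    last_div[cid] = t
                    divisions += 1
            elif u < p_div + p_mig:
                if _try_migrate(state, pos, present, occ, cid, x, y, z, X, Y, Z):
                    migrations += 1
            elif u < total:
                state[cid] = 3

        else:  # quiescent: die / resume proliferating
            p_die = b * age / denom - g * s_drug
            if p_die < 0.0:
                p_die = 0.0
            elif p_die > 1.0:
                p_die = 1.0
            p_pro = c * nutrients
            if p_pro > 1.0:
                p_pro = 1.0
            total = p_die + p_pro
            if total > 1.0:
                p_die /= total
                p_pro /= total
            if u < p_die:
                state[cid] = 4
                death[cid] = t
            elif u < p_die + p_pro:
                state[cid] = 2

    return n, divisions, migrations, degradations


@njit(cache=True)
def _try_migrate(state, pos, present, occ, cid, x, y, z, X, Y, Z):
    """Downward migration attempt; True iff the move was executed.

    The node directly below is preferred; if blocked, one of the in-bounds
    lower-diagonal neighbours is drawn at random and tried. A stromal
    occupant of the target is displaced to a random free Moore neighbour
    of its node; cancer occupants block, and an undisplaceable stromal
    cell cancels the migration.
    """
    if z == 0:
        return False
    if _move_or_displace(state, pos, occ, cid, x, y, z - 1, X, Y, Z):
        return True
    cx = np.empty(8, dtype=np.int64)
    cy = np.empty(8, dtype=np.int64)
    ncand = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            if dx == 0 and dy == 0:
                continue
            nx = x + dx
            ny = y + dy
            if 0 <= nx < X and 0 <= ny < Y:
                cx[ncand] = nx
                cy[ncand] = ny
                ncand += 1
    if ncand == 0:
        return False
    pick = np.random.randint(0, ncand)
    return _move_or_displace(state, pos, occ, cid, cx[pick], cy[pick], z - 1, X, Y, Z)


@njit(cache=True)
def _move_or_displace(state, pos, occ, cid, tx, ty, tz, X, Y, Z):
    holder = occ[tx, ty, tz]
    if holder >= 0:
        if state[holder] > 1:
            return False  # cancer cells are never displaced
        # displace the stromal occupant to a random free Moore neighbour
        fx = np.empty(26, dtype=np.int64)
        fy = np.empty(26, dtype=np.int64)
        fz = np.empty(26, dtype=np.int64)
        nfree = 0
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                for dz in range(-1, 2):
                    if dx == 0 and dy == 0 and dz == 0:
                        continue
                    nx = tx + dx
                    ny = ty + dy
                    nz = tz + dz
                    if 0 <= nx < X and 0 <= ny < Y and 0 <= nz < Z and occ[nx, ny, nz] < 0:
                        fx[nfree] = nx
                        fy[nfree] = ny
                        fz[nfree] = nz
                        nfree += 1
        if nfree == 0:
            return False
        pick = np.random.randint(0, nfree)
        occ[fx[pick], fy[pick], fz[pick]] = holder
        pos[holder, 0] = fx[pick]
        pos[holder, 1] = fy[pick]
        pos[holder, 2] = fz[pick]
        occ[tx, ty, tz] = -1
    # move the migrating cell
    occ[pos[cid, 0], pos[cid, 1], pos[cid, 2]] = -1
    occ[tx, ty, tz] = cid
    pos[cid, 0] = tx
    pos[cid, 1] = ty
    pos[cid, 2] = tz
    return True


@njit(cache=True)
def _seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _census(state, pos, present, n, counts_row, z_row, living_grid):
    """One pass over the cell table: per-state counts, per-depth counts,
    and the living-cell grid used for nutrient consumption."""
    counts_row[:] = 0
    z_row[:, :] = 0
    living_grid[:, :, :] = 0.0
    n_prolif = 0
    for i in range(n):
        if not present[i]:
            continue
        s = state[i]
        counts_row[s] += 1
        z_row[s, pos[i, 2]] += 1
        if s != 4:
            living_grid[pos[i, 0], pos[i, 1], pos[i, 2]] += 1.0
        if s == 2:
            n_prolif += 1
    return n_prolif


def run_simulation(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    observer: Callable[[LatticeState, Environment, int], None] | None = None,
) -> SimulationResult:
    """Run one culture for ``config.n_iterations`` hours.

    ``observer(lattice, env, t)`` is called after every iteration
    (including t = 0); it is intended for tests and detailed tracing.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    T = config.n_iterations
    X, Y, Z = config.dims
    inv_T = 1.0 / T

    lattice = build_lattice(config.dims)
    seed_layered_culture(lattice, config.seeding, rng)
    lattice.ensure_capacity(X * Y * Z)
    env = make_environment(config.dims, config.diffusion)
    drug = config.drug_params
    if drug is not None and drug.administered_dose > 0:
        administer_drug(env, 1.0)  # drug field normalised to administered amount
    _seed_kernel_rng(int(rng.integers(2**31)))

    p = config.rule_params
    counts = np.zeros((T + 1, _N_STATES), dtype=np.int64)
    z_counts = np.zeros((T + 1, _N_STATES, Z), dtype=np.int32)
    mig_cum = np.zeros(T + 1, dtype=np.int64)
    div_cum = np.zeros(T + 1, dtype=np.int64)
    deg_cum = np.zeros(T + 1, dtype=np.int64)
    living_grid = np.zeros(config.dims, dtype=np.float64)
    n_prolif = _census(
        lattice._state, lattice._pos, lattice._present, lattice._n,
        counts[0], z_counts[0], living_grid,
    )
    if observer is not None:
        observer(lattice, env, 0)

    migrations = divisions = degradations = 0

    for t in range(1, T + 1):
        step_environment(env, lattice, config.diffusion, dt=1.0, cell_grid=living_grid)
        lattice.iteration = t
        # rows are append-only (degraded rows are not reused), so make room
        # for the worst case of one daughter per proliferating cell
        lattice.ensure_capacity(lattice._n + n_prolif)
        glu_f = env.fields["glucose"].values
        o2_f = env.fields["oxygen"].values
        drug_f = env.fields["drug"].values
        n, n_div, n_mig, n_deg = _step_cells(
            lattice._state,
            lattice._pos,
            lattice._birth,
            lattice._last_div,
            lattice._death,
            lattice._present,
            lattice.occupancy,
            lattice._n,
            t,
            inv_T,
            p.a,
            p.b,
            p.c,
            p.d,
            p.e,
            drug is not None,
            drug.f if drug is not None else 0.0,
            drug.g if drug is not None else 0.0,
            drug.administered_dose if drug is not None else 0.0,
            drug.ic50 if drug is not None else 1.0,
            drug.hill_coefficient if drug is not None else 1.0,
            glu_f,
            o2_f,
            drug_f,
        )
        lattice._n = int(n)
        divisions += n_div
        migrations += n_mig
        degradations += n_deg

        n_prolif = _census(
            lattice._state, lattice._pos, lattice._present, lattice._n,
            counts[t], z_counts[t], living_grid,
        )
        mig_cum[t] = migrations
        div_cum[t] = divisions
        deg_cum[t] = degradations
        if observer is not None:
            observer(lattice, env, t)

    return SimulationResult(
        counts=counts,
        z_counts=z_counts,
        migration_cum=mig_cum,
        division_cum=div_cum,
        degradation_cum=deg_cum,
        final_lattice=lattice,
        rng_seed=config.rng_seed,
    )


@dataclass
class ReplicateSet:
    """Replicate runs of one configuration plus averaged observables."""

    results: list[SimulationResult]
    mean_counts: np.ndarray  # (n_iterations+1, 5), float
    sd_counts: np.ndarray
    mean_migration: float
    sd_migration: float

    @property
    def n_replicates(self) -> int:
        return len(self.results)

    def mean_cancer(self, include_dead: bool = True) -> np.ndarray:
        """Replicate-averaged cancer trajectory (dead cells included by
        default, matching the calibration's count convention)."""
        live = self.mean_counts[:, _PROLIF] + self.mean_counts[:, _QUIESC]
        return live + self.mean_counts[:, _DEAD] if include_dead else live


def run_replicates(
    config: SimulationConfig,
    n_replicates: int,
    master_seed: int | None = None,
) -> ReplicateSet:
    """Run ``n_replicates`` independent simulations and average them.

    Replicate seeds are spawned deterministically from ``master_seed``
    (default: the config seed).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    root = np.random.SeedSequence(config.rng_seed if master_seed is None else master_seed)
    results = [
        run_simulation(config, rng=np.random.default_rng(child))
        for child in root.spawn(n_replicates)
    ]
    counts = np.stack([r.counts for r in results]).astype(float)
    migs = np.array([r.migration_events for r in results], dtype=float)
    return ReplicateSet(
        results=results,
        mean_counts=counts.mean(axis=0),
        sd_counts=counts.std(axis=0, ddof=0),
        mean_migration=float(migs.mean()),
        sd_migration=float(migs.std(ddof=0)),
    )


def simulate_dose_response(
    config: SimulationConfig,
    concentrations: Sequence[float],
    drug_template: DrugParameters,
    n_replicates: int = 10,
    master_seed: int | None = None,
    drug_name: str = "drug",
):
    """Viability (live cancer cells at the end, untreated-normalised) per dose.

    ``concentrations`` are absolute doses in the units of the template's
    IC50 and must include 0 (the self-normalising untreated reference).
    The same replicate seed set is reused at every dose, so with f = g = 0
    the curve is exactly flat at 1.
    """
    conc = np.asarray(sorted(float(c) for c in concentrations))
    if conc.size == 0 or conc[0] != 0.0:
        raise ValueError("concentrations must include the untreated dose 0")
    root = np.random.SeedSequence(config.rng_seed if master_seed is None else master_seed)
    children = root.spawn(n_replicates)

    finals = np.empty((conc.size, n_replicates))
    for i, dose in enumerate(conc):
        if dose == 0.0:
            cfg = dataclasses.replace(config, drug_params=None)
        else:
            cfg = dataclasses.replace(
                config,
                drug_params=dataclasses.replace(drug_template, administered_dose=float(dose)),
            )
        for j, child in enumerate(children):
            r = run_simulation(cfg, rng=np.random.default_rng(child))
            finals[i, j] = r.cancer_counts(include_dead=False)[-1]

    untreated = finals[0].mean()
    if untreated == 0:
        raise ValueError("untreated cultures died out; cannot normalise viability")
    norm = finals / untreated
    from .validation_analysis import DoseResponseCurve

    return DoseResponseCurve(
        drug=drug_name,
        concentrations=conc,
        viability=norm.mean(axis=1),
        sd=norm.std(axis=1, ddof=0),
        replicates=norm,
    )
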