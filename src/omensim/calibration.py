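"""Scoring of simulations against assay data and exhaustive grid search.

The calibration score is S = S_p + S_i + S_a (equal weights):

    S_p = |(C_72/C_0 - EG) / EG|                       (proliferation)
    S_i = |(I_silico - I_vitro) / I_vitro|             (invasion)
    S_a = sum_{t=2..4} |(C_t/C_4 - A_t/A_4)/(A_t/A_4)| (adhesion)

C_t counts every cancer cell on the lattice at iteration t (the cell-count
and staining assays the references come from do not distinguish live from
freshly dead cells); I_silico is the tally of executed migration events;
EG is the expected population growth (2 for 2D monolayers, 0.87 for 3D
multi-spheroids). Scores are deviation magnitudes: each component takes
an absolute value so that the lowest score is the best fit; a signed mode
is kept for auditing. The search enumerates the full regular grid (the
reference grid is {0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1} for every
parameter), averages replicates before scoring, and breaks score ties by
the lexicographically smallest parameter tuple.

Drug parameters (f, g) are fitted the same way at a simulated IC50 dose,
scored by S_p alone with EG = 0.5 (the definition of the IC50) on the
live-cell count, mirroring the viability assays.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .behaviour_rules import DrugParameters, RuleParameters
from .simulation_engine import ReplicateSet, SimulationConfig, run_replicates
from .validation_analysis import DoseResponseCurve

__all__ = [
    "PAPER_GRID",
    "ExperimentalDataset",
    "ModelCombination",
    "ScoreBreakdown",
    "CalibrationResult",
    "score_proliferation",
    "score_invasion",
    "score_adhesion",
    "total_score",
    "config_distance",
    "score_replicates",
    "grid_search_growth",
    "grid_search_drug",
    "assemble_model_combinations",
    "evaluate_score_distribution",
]

#: the regular grid used for every behavioural parameter
PAPER_GRID: tuple[float, ...] = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0)

ADHESION_TIMES = (2, 3, 4)
ASSAYS = ("proliferation", "invasion", "adhesion")


@dataclass
class ExperimentalDataset:
    """Reference readouts of one (possibly mixed 2D/3D) data combination.

    ``adhesion`` maps hour (2, 3, 4) to absorbance; ``dose_response`` maps
    drug name to its experimental viability curve; ``tags`` records, per
    assay, whether the readout came from a 2D or 3D experimental model.
    ``assay_replicates`` optionally retains replicate-level values for
    distribution-level (KS) comparisons.
    """

    eg: float
    invasion_count: float
    adhesion: Mapping[int, float]
    tags: dict[str, str] = field(
        default_factory=lambda: {a: "2D" for a in ASSAYS}
    )
    dose_response: dict[str, DoseResponseCurve] | None = None
    assay_replicates: dict[str, np.ndarray] | None = None
    combination_id: int | None = None

    def __post_init__(self):
        if self.eg <= 0:
            raise ValueError("expected population growth must be positive")
        if any(self.adhesion.get(t, 0) <= 0 for t in ADHESION_TIMES):
            raise ValueError(f"adhesion absorbances at hours {ADHESION_TIMES} must be positive")
        unknown = set(self.tags) - set(ASSAYS)
        if unknown or any(v not in ("2D", "3D") for v in self.tags.values()):
            raise ValueError(f"tags must map {ASSAYS} to '2D'/'3D', got {self.tags}")


@dataclass(frozen=True)
class ModelCombination:
    """One of the 8 per-assay 2D/3D mixtures."""

    id: int
    assays: Mapping[str, str]  # assay -> "2D" | "3D"


@dataclass(frozen=True)
class ScoreBreakdown:
    s_p: float
    s_i: float
    s_a: float

    @property
    def s_total(self) -> float:
        return self.s_p + self.s_i + self.s_a


def _magnitude(value: float, signed: bool) -> float:
    return value if signed else abs(value)


def score_proliferation(c0: float, c72: float, eg: float, signed: bool = False) -> float:
    """S_p = |(C_72/C_0 - EG)/EG|; undefined for empty initial populations."""
    if c0 <= 0:
        raise ValueError("initial cancer count must be positive")
    if eg <= 0:
        raise ValueError("expected population growth must be positive")
    return _magnitude((c72 / c0 - eg) / eg, signed)


def score_invasion(i_silico: float, i_vitro: float, signed: bool = False) -> float:
    """S_i = |(I_silico - I_vitro)/I_vitro|."""
    if i_vitro <= 0:
        raise ValueError("in-vitro invasion count must be positive")
    return _magnitude((i_silico - i_vitro) / i_vitro, signed)


def score_adhesion(
    c: Sequence[float], a: Mapping[int, float], signed: bool = False
) -> float:
    """S_a over hours 2..4; both series are normalised by their hour-4 value,
    so the t = 4 term is identically zero and any common scale factor on
    the simulated counts cancels."""
    c2, c3, c4 = (float(v) for v in c)
    if c4 <= 0:
        raise ValueError("simulated count at hour 4 must be positive")
    if any(a.get(t, 0) <= 0 for t in ADHESION_TIMES):
        raise ValueError("adhesion absorbances must be positive")
    a4 = a[4]
    total = 0.0
    for t, ct in zip(ADHESION_TIMES, (c2, c3, c4)):
        ratio_a = a[t] / a4
        total += _magnitude((ct / c4 - ratio_a) / ratio_a, signed)
    return total


def total_score(s_p: float, s_i: float, s_a: float) -> float:
    """Unweighted sum of the three components."""
    return s_p + s_i + s_a


def config_distance(p_c: RuleParameters, p_o: RuleParameters) -> float:
    """L1 distance between two parameter sets over a..e."""
    return float(
        sum(abs(x - y) for x, y in zip(p_c.as_tuple(), p_o.as_tuple()))
    )


def score_replicates(
    reps: ReplicateSet, dataset: ExperimentalDataset, signed: bool = False
) -> ScoreBreakdown:
    """Score replicate-averaged observables against a dataset."""
    cancer = reps.mean_cancer()
    if len(cancer) < 5:
        raise ValueError("scoring needs at least 4 iterations (adhesion hours 2-4)")
    s_p = score_proliferation(cancer[0], cancer[-1], dataset.eg, signed)
    s_i = score_invasion(reps.mean_migration, dataset.invasion_count, signed)
    s_a = score_adhesion(cancer[2:5], dataset.adhesion, signed)
    return ScoreBreakdown(s_p=s_p, s_i=s_i, s_a=s_a)


@dataclass
class CalibrationResult:
    best_params: RuleParameters | DrugParameters | None
    best_score: ScoreBreakdown | None
    table: pd.DataFrame
    n_replicates: int
    n_configurations: int


def _grid_axes(
    grid_values, names: Sequence[str]
) -> list[tuple[float, ...]]:
    if isinstance(grid_values, Mapping):
        axes = [tuple(sorted(grid_values[n])) for n in names]
    else:
        axis = tuple(sorted(grid_values))
        axes = [axis for _ in names]
    if any(len(ax) == 0 for ax in axes):
        raise ValueError("grid must be non-empty for every parameter")
    return axes


def grid_search_growth(
    dataset: ExperimentalDataset,
    base_config: SimulationConfig,
    grid_values: Sequence[float] | Mapping[str, Sequence[float]] = PAPER_GRID,
    n_replicates: int = 3,
    master_seed: int | None = None,
    scorer: Callable[[RuleParameters], float] | None = None,
    dry_run: bool = False,
) -> CalibrationResult:
    """Exhaustive regular-grid search over the growth parameters a..e.

    Every grid point is simulated ``n_replicates`` times (same spawned
    replicate seeds for every configuration), replicates are averaged
    before scoring, and the lowest-score configuration is returned with
    deterministic lexicographic tie-breaking. ``scorer`` injects an
    alternative objective (used for testing the enumerator); ``dry_run``
    only enumerates the grid.
    """
    names = ("a", "b", "c", "d", "e")
    axes = _grid_axes(grid_values, names)
    combos = list(itertools.product(*axes))

    if dry_run:
        table = pd.DataFrame(combos, columns=names)
        return CalibrationResult(None, None, table, 0, len(combos))

    rows = []
    best: tuple[float, tuple[float, ...]] | None = None
    best_entry = None
    for combo in combos:
        params = RuleParameters(*combo)
        if scorer is not None:
            s_val = scorer(params)
            score = s_val if isinstance(s_val, ScoreBreakdown) else ScoreBreakdown(float(s_val), 0.0, 0.0)
        else:
            reps = run_replicates(
                dataclasses.replace(base_config, rule_params=params),
                n_replicates,
                master_seed=master_seed,
            )
            score = score_replicates(reps, dataset)
        rows.append(combo + (score.s_p, score.s_i, score.s_a, score.s_total))
        key = (score.s_total, combo)
        if best is None or key < best:
            best = key
            best_entry = (params, score)
    table = pd.DataFrame(rows, columns=list(names) + ["s_p", "s_i", "s_a", "s_total"])
    return CalibrationResult(
        best_params=best_entry[0],
        best_score=best_entry[1],
        table=table,
        n_replicates=0 if scorer else n_replicates,
        n_configurations=len(combos),
    )


def grid_search_drug(
    base_config: SimulationConfig,
    ic50: float,
    grid_values: Sequence[float] | Mapping[str, Sequence[float]] = PAPER_GRID,
    hill_coefficient: float = 1.0,
    eg: float = 0.5,
    n_replicates: int = 3,
    master_seed: int | None = None,
    scorer: Callable[[DrugParameters], float] | None = None,
) -> CalibrationResult:
    """Grid search over the drug parameters (f, g) at a simulated IC50 dose.

    ``base_config`` carries the already-fixed growth parameters. Each
    (f, g) pair is scored by S_p with EG = 0.5 on the live cancer count
    (the viability readout), per the definition of the IC50.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    names = ("f", "g")
    axes = _grid_axes(grid_values, names)
    combos = list(itertools.product(*axes))

    rows = []
    best = None
    best_entry = None
    for combo in combos:
        drug = DrugParameters(
            f=combo[0],
            g=combo[1],
            ic50=ic50,
            hill_coefficient=hill_coefficient,
            administered_dose=ic50,
        )
        if scorer is not None:
            s_p = float(scorer(drug))
        else:
            reps = run_replicates(
                dataclasses.replace(base_config, drug_params=drug),
                n_replicates,
                master_seed=master_seed,
            )
            live = reps.mean_cancer(include_dead=False)
            s_p = score_proliferation(live[0], live[-1], eg)
        rows.append(combo + (s_p,))
        key = (s_p, combo)
        if best is None or key < best:
            best = key
            best_entry = (drug, ScoreBreakdown(s_p, 0.0, 0.0))
    table = pd.DataFrame(rows, columns=list(names) + ["s_p"])
    return CalibrationResult(
        best_params=best_entry[0],
        best_score=best_entry[1],
        table=table,
        n_replicates=0 if scorer else n_replicates,
        n_configurations=len(combos),
    )


def assemble_model_combinations(
    data_2d: ExperimentalDataset, data_3d: ExperimentalDataset
) -> list[ExperimentalDataset]:
    """The 8 per-assay 2D/3D mixtures of two complete source datasets.

    Numbering follows the convention that adhesion toggles fastest and
    proliferation slowest: id = 1 + 4*(prolif 3D) + 2*(invasion 3D) +
    (adhesion 3D); so 1 is all-2D and 8 all-3D. The dose-response curves
    travel with the proliferation setting (they are measured in the same
    experimental model).
    """
    for name, d in (("2D", data_2d), ("3D", data_3d)):
        if d.dose_response is None:
            raise ValueError(f"{name} dataset is missing dose-response curves")
    out = []
    source = {"2D": data_2d, "3D": data_3d}
    for p_tag, i_tag, a_tag in itertools.product(("2D", "3D"), repeat=3):
        cid = 1 + 4 * (p_tag == "3D") + 2 * (i_tag == "3D") + (a_tag == "3D")
        out.append(
            ExperimentalDataset(
                eg=source[p_tag].eg,
                invasion_count=source[i_tag].invasion_count,
                adhesion=dict(source[a_tag].adhesion),
                tags={"proliferation": p_tag, "invasion": i_tag, "adhesion": a_tag},
                dose_response=source[p_tag].dose_response,
                combination_id=cid,
            )
        )
    out.sort(key=lambda d: d.combination_id)
    return out


def evaluate_score_distribution(
    params: RuleParameters,
    base_config: SimulationConfig,
    dataset: ExperimentalDataset,
    n_simulations: int = 50,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Score each simulation independently, then summarise mean and sd.

    This is the reporting convention for the best configuration (as
    opposed to the replicate-averaged scoring used inside the search).
    """
    root = np.random.SeedSequence(
        base_config.rng_seed if master_seed is None else master_seed
    )
    from .simulation_engine import run_simulation

    rows = []
    cfg = dataclasses.replace(base_config, rule_params=params)
    for child in root.spawn(n_simulations):
        r = run_simulation(cfg, rng=np.random.default_rng(child))
        cancer = r.cancer_counts()
        s_p = score_proliferation(cancer[0], cancer[-1], dataset.eg)
        s_i = score_invasion(r.migration_events, dataset.invasion_count)
        s_a = score_adhesion(cancer[2:5], dataset.adhesion)
        rows.append((s_p, s_i, s_a, s_p + s_i + s_a))
    return pd.DataFrame(rows, columns=["s_p", "s_i", "s_a", "s_total"])
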