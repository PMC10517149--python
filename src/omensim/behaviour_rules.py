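"""Discrete component: per-arc probability functions of the cell state graph.

Proliferating cancer cells may divide, migrate toward the culture bottom,
or become quiescent; quiescent cells may die or resume proliferation; dead
cells degrade and leave the lattice. Stromal cells (fibroblasts,
mesothelial) have no behavioural rules. The printed probability functions
are

    PD  = a*TLD + c*(Glu + O2) - f*S(D)      (division)
    CDR = b*AGE / (Glu + O2)   - g*S(D)      (death of quiescent cells)

with S(D) a Hill-form sigmoid anchored at the drug's IC50. The remaining
arcs use the same dimensionless variables (see ``docs/methods.md`` for the
rationale behind each form):

    P(proliferating -> quiescent)  = b*AGE / (Glu + O2)
    P(quiescent -> proliferating)  = c*(Glu + O2)
    P(migrate)                     = e*D0
    P(degrade)                     = d*(Tc - Td)

All variables are normalised: AGE, TLD, Tc, Td by the simulation length,
D0 (depth) to [0, 1], nutrient and drug levels to their media /
administered concentrations. Raw values are clipped to [0, 1]; when the
applicable arcs of a cell sum to more than 1 they are jointly rescaled,
otherwise the residual mass is "no action".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .model_core import Cell, CellState, is_stromal

__all__ = [
    "Action",
    "RuleParameters",
    "DrugParameters",
    "EnvLocal",
    "RuleDistribution",
    "drug_effect",
    "division_probability",
    "death_probability",
    "rule_distribution",
    "sample_rule",
]

#: floor on Glu+O2 in rate denominators; below it the starvation terms
#: saturate at their clipped maximum
NUTRIENT_FLOOR = 1e-6


class Action(Enum):
    DIVIDE = "divide"
    MIGRATE = "migrate"
    TO_QUIESCENT = "to_quiescent"
    TO_PROLIFERATING = "to_proliferating"
    DIE = "die"
    DEGRADE = "degrade"
    NONE = "none"


@dataclass(frozen=True)
class RuleParameters:
    """Dimensionless scale factors of the untreated behavioural rules."""

    a: float  # division drive per unit time-since-last-division
    b: float  # starvation/age drive of quiescence and death
    c: float  # nutrient drive of division and of quiescence exit
    d: float  # degradation drive of dead cells
    e: float  # depth drive of downward migration

    def __post_init__(self):
        for name in "abcde":
            if getattr(self, name) < 0:
                raise ValueError(f"rule parameter {name} must be >= 0")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.e)


@dataclass(frozen=True)
class DrugParameters:
    """Drug-effect scale factors and the sigmoid response curve.

    ``f`` scales the inhibition of division, ``g`` the promotion of death.
    ``ic50`` and ``administered_dose`` are in the same concentration units
    (e.g. uM); the simulated drug field is normalised to the administered
    amount, so the absolute local concentration is D * administered_dose.
    """

    f: float
    g: float
    ic50: float
    hill_coefficient: float = 1.0
    administered_dose: float = 1.0

    def __post_init__(self):
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.f < 0 or self.g < 0:
            raise ValueError("f and g must be >= 0")
        if self.hill_coefficient <= 0:
            raise ValueError("hill_coefficient must be positive")
        if self.administered_dose < 0:
            raise ValueError("administered_dose must be >= 0")


@dataclass(frozen=True)
class EnvLocal:
    """Local environment sampled at one lattice node."""

    glu: float
    o2: float
    drug: float
    depth_frac: float  # D0 = z/(Z-1), 0 at the culture bottom

    def __post_init__(self):
        if min(self.glu, self.o2, self.drug) < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0.0 <= self.depth_frac <= 1.0:
            raise ValueError("depth_frac must lie in [0, 1]")


@dataclass
class RuleDistribution:
    """Probabilities of the applicable arcs plus the no-action residual."""

    probabilities: dict[Action, float]
    residual: float

    def total(self) -> float:
        return sum(self.probabilities.values()) + self.residual


def _clip01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def drug_effect(d_norm: float, drug: DrugParameters | None) -> float:
    """Hill sigmoid S of the absolute drug concentration.

    S(0) = 0 (no effect without drug) and S(IC50) = 0.5 by construction;
    S is strictly increasing and bounded below 1.
    """
    if d_norm < 0:
        raise ValueError("drug concentration must be non-negative")
    if drug is None:
        return 0.0
    conc = d_norm * drug.administered_dose
    if conc == 0.0:
        return 0.0
    h = drug.hill_coefficient
    ch = conc**h
    return ch / (ch + drug.ic50**h)


# -- scalar arc helpers (shared with the simulation engine) ---------------

def proliferating_arcs(
    tld: float,
    age: float,
    glu: float,
    o2: float,
    depth: float,
    p: RuleParameters,
    s_drug: float,
    f: float,
) -> tuple[float, float, float]:
    """(divide, migrate, to_quiescent) raw clipped probabilities."""
    nutrients = glu + o2
    p_div = _clip01(p.a * tld + p.c * nutrients - f * s_drug)
    p_mig = _clip01(p.e * depth)
    p_q = _clip01(p.b * age / max(nutrients, NUTRIENT_FLOOR))
    return p_div, p_mig, p_q


def quiescent_arcs(
    age: float,
    glu: float,
    o2: float,
    p: RuleParameters,
    s_drug: float,
    g: float,
) -> tuple[float, float]:
    """(die, to_proliferating) raw clipped probabilities."""
    nutrients = glu + o2
    p_die = _clip01(p.b * age / max(nutrients, NUTRIENT_FLOOR) - g * s_drug)
    p_pro = _clip01(p.c * nutrients)
    return p_die, p_pro


def dead_arc(t_c: float, t_d: float, p: RuleParameters) -> float:
    """Degradation probability of a dead cell; zero at the death instant."""
    return _clip01(p.d * (t_c - t_d))


# -- public per-cell interface -------------------------------------------

def _cell_clock(cell: Cell, iteration: int, total_iterations: int):
    age = (iteration - cell.birth_iteration) / total_iterations
    tld = (iteration - cell.last_division_iteration) / total_iterations
    t_c = iteration / total_iterations
    t_d = (cell.death_iteration / total_iterations) if cell.death_iteration is not None else None
    return age, tld, t_c, t_d


def division_probability(
    cell: Cell,
    env: EnvLocal,
    p: RuleParameters,
    drug: DrugParameters | None = None,
    *,
    iteration: int,
    total_iterations: int = 72,
) -> float:
    """PD = a*TLD + c*(Glu+O2) - f*S(D), clipped to [0, 1]."""
    if cell.state is not CellState.CANCER_PROLIFERATING:
        raise ValueError("division applies to proliferating cancer cells only")
    age, tld, _, _ = _cell_clock(cell, iteration, total_iterations)
    s = drug_effect(env.drug, drug)
    f = drug.f if drug is not None else 0.0
    return proliferating_arcs(tld, age, env.glu, env.o2, env.depth_frac, p, s, f)[0]


def death_probability(
    cell: Cell,
    env: EnvLocal,
    p: RuleParameters,
    drug: DrugParameters | None = None,
    *,
    iteration: int,
    total_iterations: int = 72,
) -> float:
    """CDR = b*AGE/(Glu+O2) - g*S(D), clipped to [0, 1].

    Below the nutrient floor the starvation term saturates at its clipped
    maximum instead of dividing by zero.
    """
    if cell.state is not CellState.CANCER_QUIESCENT:
        raise ValueError("death applies to quiescent cancer cells only")
    age, _, _, _ = _cell_clock(cell, iteration, total_iterations)
    s = drug_effect(env.drug, drug)
    g = drug.g if drug is not None else 0.0
    return quiescent_arcs(age, env.glu, env.o2, p, s, g)[0]


def rule_distribution(
    cell: Cell,
    env: EnvLocal,
    p: RuleParameters,
    drug: DrugParameters | None,
    iteration: int,
    total_iterations: int,
) -> RuleDistribution:
    """Arc probabilities applicable to ``cell`` in its current state.

    Each arc is clipped to [0, 1] individually; if the clipped arcs sum to
    more than 1 they are jointly rescaled to sum to 1 (one rule per cell
    per iteration), otherwise the residual is the no-action mass.
    """
    if is_stromal(cell.state):
        raise ValueError("stromal cells have no behavioural rules")
    age, tld, t_c, t_d = _cell_clock(cell, iteration, total_iterations)
    s = drug_effect(env.drug, drug)
    if cell.state is CellState.CANCER_PROLIFERATING:
        f = drug.f if drug is not None else 0.0
        p_div, p_mig, p_q = proliferating_arcs(
            tld, age, env.glu, env.o2, env.depth_frac, p, s, f
        )
        probs = {Action.DIVIDE: p_div, Action.MIGRATE: p_mig, Action.TO_QUIESCENT: p_q}
    elif cell.state is CellState.CANCER_QUIESCENT:
        g = drug.g if drug is not None else 0.0
        p_die, p_pro = quiescent_arcs(age, env.glu, env.o2, p, s, g)
        probs = {Action.DIE: p_die, Action.TO_PROLIFERATING: p_pro}
    else:  # dead
        if t_d is None:
            raise ValueError("dead cell without death_iteration")
        probs = {Action.DEGRADE: dead_arc(t_c, t_d, p)}
    total = sum(probs.values())
    if total > 1.0:
        probs = {k: v / total for k, v in probs.items()}
        residual = 0.0
    else:
        residual = 1.0 - total
    return RuleDistribution(probabilities=probs, residual=residual)


def sample_rule(dist: RuleDistribution, rng: np.random.Generator) -> Action:
    """Draw exactly one action (possibly NONE) from the distribution."""
    u = rng.random()
    acc = 0.0
    for action, prob in dist.probabilities.items():
        acc += prob
        if u < acc:
            return action
    return Action.NONE
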