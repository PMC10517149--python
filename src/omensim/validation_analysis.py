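"""Validation of calibrated models against held-out dose-response data,
plus depth-resolved density profiles of the simulated culture.

The per-dose relative error |S - E| / E (summed over the concentration
ladder) quantifies how well a simulated dose-response curve matches the
experimental one; two-sample Kolmogorov-Smirnov tests (threshold p < 0.05)
compare replicate-level distributions. Density maps give, per cell state,
the average number of cells at each depth z and iteration, normalised by
the total initial cell number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .simulation_engine import SimulationResult

from .model_core import CellState

__all__ = [
    "DoseResponseCurve",
    "DensityMap",
    "KSResult",
    "dose_response_error",
    "ks_two_sample",
    "z_profile_density",
]

KS_ALPHA = 0.05


@dataclass
class DoseResponseCurve:
    """Untreated-normalised viability along an ascending dose ladder.

    ``replicates`` (optional) holds the per-replicate normalised values,
    shape (n_doses, n_replicates), for distribution-level comparisons.
    """

    drug: str
    concentrations: np.ndarray
    viability: np.ndarray
    sd: np.ndarray | None = None
    replicates: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.ndim != 1 or len(self.concentrations) != len(self.viability):
            raise ValueError("concentrations and viability must be 1D and aligned")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"drug": self.drug, "concentration": self.concentrations, "viability": self.viability}
        )
        if self.sd is not None:
            df["sd"] = self.sd
        return df


@dataclass
class KSResult:
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < KS_ALPHA


def dose_response_error(sim: DoseResponseCurve, exp: DoseResponseCurve) -> float:
    """Sum over doses of |S([D]) - E([D])| / E([D]).

    Requires matching concentration ladders and strictly positive
    experimental viabilities.
    """
    if sim.concentrations.shape != exp.concentrations.shape or not np.allclose(
        sim.concentrations, exp.concentrations
    ):
        raise ValueError("dose ladders of the two curves do not match")
    if np.any(exp.viability <= 0):
        raise ValueError("experimental viabilities must be positive")
    return float(np.sum(np.abs(sim.viability - exp.viability) / exp.viability))


def per_dose_errors(sim: DoseResponseCurve, exp: DoseResponseCurve) -> pd.DataFrame:
    """Per-concentration relative errors (the summed total is
    :func:`dose_response_error`)."""
    total = dose_response_error(sim, exp)  # validates inputs
    err = np.abs(sim.viability - exp.viability) / exp.viability
    df = pd.DataFrame({"concentration": sim.concentrations, "rel_error": err})
    df.attrs["total"] = total
    return df


def ks_two_sample(sample_a: Sequence[float], sample_b: Sequence[float]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test (max ECDF gap)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ks_2samp(a, b)
    return KSResult(statistic=float(res.statistic), p_value=float(res.pvalue))


@dataclass
class DensityMap:
    """Average cell density over (iteration, depth) for one cell state.

    ``values[t, z]`` is the mean (over simulations) number of cells of
    the state at depth z and iteration t, divided by the total number of
    initially seeded cells, so summing iteration 0 over states and depths
    gives 1.
    """

    state: CellState
    values: np.ndarray  # (n_iterations+1, Z)
    n_simulations: int

    def to_frame(self) -> pd.DataFrame:
        T1, Z = self.values.shape
        return pd.DataFrame(
            self.values,
            index=pd.Index(range(T1), name="iteration"),
            columns=pd.Index(range(Z), name="z"),
        )


def z_profile_density(results: Sequence["SimulationResult"]) -> dict[CellState, DensityMap]:
    """Depth-by-time density maps averaged over simulations.

    All results must share lattice dims and length; normalisation is by
    each run's total initial cell count.
    """
    if not results:
        raise ValueError("need at least one simulation result")
    shape = results[0].z_counts.shape
    if any(r.z_counts.shape != shape for r in results):
        raise ValueError("simulation results have inconsistent dims or lengths")
    stacks = np.stack(
        [r.z_counts / r.counts[0].sum() for r in results]
    )  # (n_sims, T+1, 5, Z)
    mean = stacks.mean(axis=0)
    return {
        state: DensityMap(state=state, values=mean[:, int(state), :], n_simulations=len(results))
        for state in CellState
    }
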