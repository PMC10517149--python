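"""Synthetic stand-ins for the wet-lab reference measurements.

Two generators are provided. :func:`generate_dataset` draws datasets with
the statistical structure of the study's readouts: 2D monolayer data
(expected population growth EG = 2, tighter replicates) versus 3D
organotypic/multi-spheroid data (EG = 0.87, roughly twice the invasion
count, larger replicate scatter, flatter dose-response with a higher
residual-viability floor). :func:`generate_from_simulator` instead runs
the simulator at a known parameter configuration and converts its
observables into a dataset, giving a ground-truth target for
parameter-recovery experiments.

Replicate noise is multiplicative log-normal (assay readouts are positive
and heteroscedastic), mean-preserving, with the coefficient of variation
set per assay. Defaults are structural stand-ins, not fits to the real
deposited data; real measurements in the documented CSV schema can be
loaded through :func:`read_dataset_csv`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviour_rules import DrugParameters, RuleParameters
from .calibration import ADHESION_TIMES, ExperimentalDataset
from .simulation_engine import SimulationConfig, run_replicates, simulate_dose_response
from .validation_analysis import DoseResponseCurve

__all__ = [
    "SyntheticSpec",
    "default_spec",
    "generate_dataset",
    "generate_from_simulator",
    "generate_drug_inputs",
    "dataset_to_csv",
    "read_dataset_csv",
    "CONCENTRATION_LADDER",
    "IC50",
]

#: assay concentration ladder (uM for cisplatin, nM for paclitaxel)
CONCENTRATION_LADDER: tuple[float, ...] = (50, 25, 12.5, 6.2, 3.1, 1.6, 0.8, 0.4, 0)
#: literature IC50 values used as inputs: cisplatin in uM, paclitaxel in nM
IC50: dict[str, float] = {"cisplatin": 10.4, "paclitaxel": 3.04}
_UNITS: dict[str, str] = {"cisplatin": "uM", "paclitaxel": "nM"}


@dataclass
class SyntheticSpec:
    """Statistical description of one experimental setting (2D or 3D)."""

    setting: str = "2D"
    eg_mean: float = 2.0
    invasion_mean: float = 100.0
    adhesion_level: float = 1.0  # absorbance, approximately constant over 2-4 h
    noise_cv: dict[str, float] = field(
        default_factory=lambda: {
            "proliferation": 0.08,
            "invasion": 0.08,
            "adhesion": 0.08,
            "dose_response": 0.08,
        }
    )
    ic50: dict[str, float] = field(default_factory=lambda: dict(IC50))
    hill_coefficient: float = 1.0
    response_floor: float = 0.15  # residual viability at saturating dose
    n_replicates: int = 3
    rng_seed: int = 0

    def __post_init__(self):
        if self.setting not in ("2D", "3D"):
            raise ValueError("setting must be '2D' or '3D'")
        if any(cv < 0 for cv in self.noise_cv.values()):
            raise ValueError("noise coefficients of variation must be >= 0")
        if not 0 <= self.response_floor < 1:
            raise ValueError("response_floor must lie in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def default_spec(setting: str, rng_seed: int = 0) -> SyntheticSpec:
    """Study defaults: 2D (EG 2, cv 0.08, floor 0.15) or 3D (EG 0.87,
    invasion ~2x the 2D mean, cv 0.20, floor 0.35)."""
    if setting == "2D":
        return SyntheticSpec(setting="2D", rng_seed=rng_seed)
    if setting == "3D":
        return SyntheticSpec(
            setting="3D",
            eg_mean=0.87,
            invasion_mean=190.0,
            noise_cv={k: 0.20 for k in ("proliferation", "invasion", "adhesion", "dose_response")},
            response_floor=0.35,
            rng_seed=rng_seed,
        )
    raise ValueError("setting must be '2D' or '3D'")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-preserving multiplicative noise with the given cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size) - 0.5 * sigma * sigma)


def generate_dataset(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> ExperimentalDataset:
    """Draw one dataset with the spec's means, noise and dose-response shape.

    Replicate-level values are retained in ``assay_replicates`` and in the
    dose-response curves so distribution-level (KS) comparisons remain
    possible downstream.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_replicates

    eg_reps = spec.eg_mean * _lognormal_factors(rng, spec.noise_cv["proliferation"], n)
    inv_reps = spec.invasion_mean * _lognormal_factors(rng, spec.noise_cv["invasion"], n)
    adhesion_reps = {
        t: spec.adhesion_level * _lognormal_factors(rng, spec.noise_cv["adhesion"], n)
        for t in ADHESION_TIMES
    }

    curves: dict[str, DoseResponseCurve] = {}
    for drug, ic50 in spec.ic50.items():
        doses = np.array(sorted(CONCENTRATION_LADDER), dtype=float)
        h = spec.hill_coefficient
        hill = spec.response_floor + (1 - spec.response_floor) / (1 + (doses / ic50) ** h)
        raw = hill[:, None] * _lognormal_factors(
            rng, spec.noise_cv["dose_response"], (doses.size, n)
        )
        norm = raw / raw[0].mean()  # normalise to the untreated condition
        curves[drug] = DoseResponseCurve(
            drug=drug,
            concentrations=doses,
            viability=norm.mean(axis=1),
            sd=norm.std(axis=1, ddof=0),
            replicates=norm,
        )

    return ExperimentalDataset(
        eg=float(eg_reps.mean()),
        invasion_count=float(inv_reps.mean()),
        adhesion={t: float(v.mean()) for t, v in adhesion_reps.items()},
        tags={a: spec.setting for a in ("proliferation", "invasion", "adhesion")},
        dose_response=curves,
        assay_replicates={
            "proliferation": eg_reps,
            "invasion": inv_reps,
            **{f"adhesion_{t}": v for t, v in adhesion_reps.items()},
        },
    )


def generate_from_simulator(
    true_params: RuleParameters,
    sim_config: SimulationConfig,
    drug_params: DrugParameters | None = None,
    n_replicates: int = 3,
    master_seed: int | None = None,
    concentrations=None,
    adhesion_scale: float = 0.01,
) -> ExperimentalDataset:
    """Pseudo-experimental dataset produced by the simulator at a known
    ground-truth configuration.

    EG is the replicate-averaged fold change C_end/C_0, the invasion count
    the averaged migration tally, and the adhesion series is proportional
    to the early cancer counts (the proportionality constant cancels in
    the adhesion score). If ``drug_params`` and ``concentrations`` are
    given, dose-response curves are simulated as well.
    """
    cfg = dataclasses.replace(sim_config, rule_params=true_params)
    reps = run_replicates(cfg, n_replicates, master_seed=master_seed)
    cancer = reps.mean_cancer()
    curves = None
    if drug_params is not None and concentrations is not None:
        curve = simulate_dose_response(
            cfg,
            concentrations,
            drug_params,
            n_replicates=n_replicates,
            master_seed=master_seed,
        )
        curves = {curve.drug: curve}
    return ExperimentalDataset(
        eg=float(cancer[-1] / cancer[0]),
        invasion_count=float(reps.mean_migration),
        adhesion={t: float(adhesion_scale * cancer[t]) for t in ADHESION_TIMES},
        dose_response=curves,
    )


def generate_drug_inputs() -> pd.DataFrame:
    """Drug configuration table: IC50 and assay concentration ladder per
    drug (cisplatin in uM, paclitaxel in nM)."""
    rows = [
        {"drug": drug, "unit": _UNITS[drug], "ic50": ic50, "concentration": float(c)}
        for drug, ic50 in IC50.items()
        for c in CONCENTRATION_LADDER
    ]
    return pd.DataFrame(rows)


# -- CSV schema -----------------------------------------------------------
# columns: assay, setting, replicate, time_or_dose, value
#   proliferation: value = per-replicate EG, time_or_dose empty
#   invasion:      value = per-replicate invaded-cell count
#   adhesion:      value = absorbance, time_or_dose = hour (2, 3, 4)
#   dose_response:<drug>: value = normalised viability, time_or_dose = dose


def dataset_to_csv(dataset: ExperimentalDataset, path) -> None:
    """Write a dataset (replicate-level where available) in the documented
    long-format schema, so real measurements can use the same reader."""
    rows = []

    def assay_rows(assay, values, time_or_dose=np.nan):
        tag = dataset.tags.get(assay.split(":")[0].replace("dose_response", "proliferation"), "2D")
        for i, v in enumerate(np.atleast_1d(values)):
            rows.append(
                {
                    "assay": assay,
                    "setting": tag,
                    "replicate": i,
                    "time_or_dose": time_or_dose,
                    "value": float(v),
                }
            )

    rep = dataset.assay_replicates or {}
    assay_rows("proliferation", rep.get("proliferation", dataset.eg))
    assay_rows("invasion", rep.get("invasion", dataset.invasion_count))
    for t in ADHESION_TIMES:
        assay_rows("adhesion", rep.get(f"adhesion_{t}", dataset.adhesion[t]), time_or_dose=t)
    if dataset.dose_response:
        for drug, curve in dataset.dose_response.items():
            for i, dose in enumerate(curve.concentrations):
                vals = curve.replicates[i] if curve.replicates is not None else curve.viability[i]
                assay_rows(f"dose_response:{drug}", vals, time_or_dose=float(dose))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dataset_csv(path) -> ExperimentalDataset:
    """Read a dataset written by :func:`dataset_to_csv` (or real data in
    the same schema); replicates are averaged into the point estimates."""
    df = pd.read_csv(path)
    tags = {}
    for assay in ("proliferation", "invasion", "adhesion"):
        sub = df[df["assay"] == assay]
        if not sub.empty:
            tags[assay] = str(sub["setting"].iloc[0])

    eg = float(df.loc[df["assay"] == "proliferation", "value"].mean())
    invasion = float(df.loc[df["assay"] == "invasion", "value"].mean())
    adh = df[df["assay"] == "adhesion"]
    adhesion = {
        int(t): float(g["value"].mean()) for t, g in adh.groupby("time_or_dose")
    }

    curves = {}
    for assay, g in df[df["assay"].str.startswith("dose_response:")].groupby("assay"):
        drug = assay.split(":", 1)[1]
        by_dose = g.groupby("time_or_dose")["value"]
        doses = np.array(sorted(by_dose.groups))
        means = np.array([by_dose.get_group(d).mean() for d in doses])
        reps = None
        sizes = {len(by_dose.get_group(d)) for d in doses}
        if len(sizes) == 1:
            reps = np.stack([by_dose.get_group(d).to_numpy() for d in doses])
        curves[drug] = DoseResponseCurve(
            drug=drug, concentrations=doses, viability=means, replicates=reps
        )

    return ExperimentalDataset(
        eg=eg,
        invasion_count=invasion,
        adhesion=adhesion,
        tags=tags or None or {a: "2D" for a in ("proliferation", "invasion", "adhesion")},
        dose_response=curves or None,
    )
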