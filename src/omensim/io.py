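"""Configuration files and whole-grid checkpoints.

Run configurations round-trip through YAML; lattice + field snapshots go
to HDF5 (cell table plus the three continuous fields), and lattice
snapshots alone to CSV via :meth:`LatticeState.to_dataframe`.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np
import yaml

from .behaviour_rules import DrugParameters, RuleParameters
from .diffusion_solver import DiffusionParams, Environment, make_environment
from .model_core import LatticeState, SeedingSpec
from .simulation_engine import SimulationConfig

__all__ = ["save_config", "load_config", "save_checkpoint", "load_checkpoint"]


def save_config(config: SimulationConfig, path) -> None:
    doc = {
        "dims": list(config.dims),
        "n_iterations": config.n_iterations,
        "rng_seed": config.rng_seed,
        "seeding": dataclasses.asdict(config.seeding),
        "rule_params": dataclasses.asdict(config.rule_params),
        "drug_params": (
            dataclasses.asdict(config.drug_params) if config.drug_params else None
        ),
        "diffusion": dataclasses.asdict(config.diffusion),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SimulationConfig(
        rule_params=RuleParameters(**doc["rule_params"]),
        dims=tuple(doc["dims"]),
        seeding=SeedingSpec(**doc["seeding"]),
        drug_params=DrugParameters(**doc["drug_params"]) if doc.get("drug_params") else None,
        diffusion=DiffusionParams(**doc["diffusion"]),
        n_iterations=doc["n_iterations"],
        rng_seed=doc["rng_seed"],
    )


def save_checkpoint(lattice: LatticeState, env: Environment, path) -> None:
    ids = lattice.present_ids()
    with h5py.File(path, "w") as fh:
        fh.attrs["dims"] = lattice.dims
        fh.attrs["iteration"] = lattice.iteration
        grp = fh.create_group("cells")
        grp.create_dataset("state", data=lattice._state[ids])
        grp.create_dataset("pos", data=lattice._pos[ids])
        grp.create_dataset("birth", data=lattice._birth[ids])
        grp.create_dataset("last_division", data=lattice._last_div[ids])
        grp.create_dataset("death", data=lattice._death[ids])
        fgrp = fh.create_group("fields")
        for name, f in env.fields.items():
            fgrp.create_dataset(name, data=f.values)
        fgrp.attrs["treatment_active"] = env.treatment_active
        fgrp.attrs["dose_norm"] = env.dose_norm


def load_checkpoint(path) -> tuple[LatticeState, Environment]:
    with h5py.File(path, "r") as fh:
        dims = tuple(int(d) for d in fh.attrs["dims"])
        lattice = LatticeState(dims)
        lattice.iteration = int(fh.attrs["iteration"])
        grp = fh["cells"]
        states = grp["state"][:]
        pos = grp["pos"][:]
        for i in range(len(states)):
            cid = lattice.add_cell(int(states[i]), tuple(int(v) for v in pos[i]))
            lattice._birth[cid] = grp["birth"][i]
            lattice._last_div[cid] = grp["last_division"][i]
            lattice._death[cid] = grp["death"][i]
        env = make_environment(dims)
        for name in env.fields:
            env.fields[name].values[:] = fh["fields"][name][:]
        env.treatment_active = bool(fh["fields"].attrs["treatment_active"])
        env.dose_norm = float(fh["fields"].attrs["dose_norm"])
    return lattice, env
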