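#!/usr/bin/env python
"""Depth-by-time density maps of every cell type, per calibrated model.

Averages 20 simulations per model (untreated and cisplatin at IC50) and
writes, for each cell state, the mean cell density as a function of
iteration and depth z, normalised by the total initial cell number. The
raw matrices go to CSV (one file per model/state/condition) and a heatmap
figure per condition to PNG.
"""

import dataclasses
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from omensim.behaviour_rules import DrugParameters, RuleParameters
from omensim.model_core import CellState
from omensim.simulation_engine import run_simulation
from omensim.synthetic_data import IC50
from omensim.validation_analysis import z_profile_density

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location("calib", Path(__file__).parent / "02_calibrate_models.py")
_calib = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_calib)

OUT = Path("results/depth_profiles")
N_SIMS = 20
MASTER_SEED = 31


def run_maps(cfg, n_sims, master_seed):
    root = np.random.SeedSequence(master_seed)
    results = [run_simulation(cfg, rng=np.random.default_rng(c)) for c in root.spawn(n_sims)]
    return z_profile_density(results)


def main() -> None:
    best_path = Path("results/calibration/best_params.json")
    if not best_path.exists():
        raise SystemExit("run analysis/02_calibrate_models.py first")
    best = {int(k): RuleParameters(*v) for k, v in json.loads(best_path.read_text()).items()}
    OUT.mkdir(parents=True, exist_ok=True)

    conditions = {
        "untreated": None,
        "cisplatin_ic50": DrugParameters(
            f=0.5, g=0.05, ic50=IC50["cisplatin"], administered_dose=IC50["cisplatin"]
        ),
    }
    for model, params in sorted(best.items()):
        for cond, drug in conditions.items():
            cfg = dataclasses.replace(
                _calib.base_config(), rule_params=params, drug_params=drug
            )
            maps = run_maps(cfg, N_SIMS, MASTER_SEED)
            fig, axes = plt.subplots(1, 5, figsize=(18, 3), sharey=True)
            for ax, state in zip(axes, CellState):
                m = maps[state]
                m.to_frame().to_csv(OUT / f"model{model}_{cond}_{state.name.lower()}.csv")
                ax.imshow(
                    m.values.T, origin="lower", aspect="auto", cmap="jet",
                    extent=[0, m.values.shape[0] - 1, 0, m.values.shape[1] - 1],
                )
                ax.set_title(state.name, fontsize=8)
                ax.set_xlabel("iteration (h)")
            axes[0].set_ylabel("depth z")
            fig.suptitle(f"model {model}, {cond}")
            fig.tight_layout()
            fig.savefig(OUT / f"model{model}_{cond}.png", dpi=120)
            plt.close(fig)
        live = maps[CellState.CANCER_PROLIFERATING].values[-1]
        depth = np.average(np.arange(live.size), weights=live) if live.sum() else float("nan")
        print(f"model {model}: treated final mean infiltration depth z = {depth:.2f}")
    print(f"wrote density matrices and heatmaps to {OUT}")


if __name__ == "__main__":
    main()
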