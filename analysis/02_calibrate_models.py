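#!/usr/bin/env python
"""Calibrate all eight 2D/3D data combinations.

Assembles the 8 per-assay mixtures of the 2D and 3D datasets written by
01_generate_datasets.py and runs the exhaustive grid search (3 replicates
per configuration, replicates averaged before scoring) for each. Writes
the best parameter set and score breakdown per combination, plus the full
score table of the all-2D and all-3D searches.

The default grid is a reduced subset of the reference 7-value grid so the
step runs in a few minutes; pass --paper-grid for the full 7^5 search
(hours of CPU time).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from omensim.behaviour_rules import RuleParameters
from omensim.calibration import PAPER_GRID, assemble_model_combinations, grid_search_growth
from omensim.model_core import SeedingSpec
from omensim.simulation_engine import SimulationConfig
from omensim.synthetic_data import read_dataset_csv

DATA = Path("results/datasets")
OUT = Path("results/calibration")
SEARCH_GRID = {
    "a": (0.01, 0.1, 1.0),
    "b": (0.01, 0.1),
    "c": (0.001, 0.01, 0.1),
    "d": (0.1,),
    "e": (0.01, 0.05, 0.1, 0.5),
}
MASTER_SEED = 42


def base_config() -> SimulationConfig:
    return SimulationConfig(
        rule_params=RuleParameters(0, 0, 0, 0, 0),
        dims=(20, 20, 20),
        seeding=SeedingSpec(n_fibroblast=120, n_mesothelial=60, n_cancer=30),
        n_iterations=72,
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--paper-grid", action="store_true", help="full 7^5 grid")
    args = ap.parse_args()
    grid = PAPER_GRID if args.paper_grid else SEARCH_GRID

    OUT.mkdir(parents=True, exist_ok=True)
    d2 = read_dataset_csv(DATA / "dataset_2d.csv")
    d3 = read_dataset_csv(DATA / "dataset_3d.csv")
    combos = assemble_model_combinations(d2, d3)

    rows, best_params = [], {}
    cfg = base_config()
    for ds in combos:
        res = grid_search_growth(ds, cfg, grid, n_replicates=3, master_seed=MASTER_SEED)
        p = res.best_params
        best_params[ds.combination_id] = p.as_tuple()
        rows.append(
            {
                "model": ds.combination_id,
                **{f"{k}_tag": v for k, v in ds.tags.items()},
                **dict(zip("abcde", p.as_tuple())),
                "s_p": res.best_score.s_p,
                "s_i": res.best_score.s_i,
                "s_a": res.best_score.s_a,
                "score": res.best_score.s_total,
            }
        )
        if ds.combination_id in (1, 8):
            res.table.to_csv(OUT / f"score_table_model{ds.combination_id}.csv", index=False)
        print(
            f"model {ds.combination_id} "
            f"({ds.tags['proliferation']}/{ds.tags['invasion']}/{ds.tags['adhesion']}): "
            f"a-e={p.as_tuple()}  S={res.best_score.s_total:.3f}"
        )

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "best_configurations.csv", index=False)
    (OUT / "best_params.json").write_text(json.dumps(best_params, indent=2))
    s28 = table.set_index("model")["score"]
    print(f"\noverall score, all-2D model: {s28[1]:.2f}; all-3D model: {s28[8]:.2f}")
    print(f"wrote {OUT/'best_configurations.csv'} and {OUT/'best_params.json'}")


if __name__ == "__main__":
    main()
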