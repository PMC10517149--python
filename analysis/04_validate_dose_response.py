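#!/usr/bin/env python
"""Validate the calibrated models against held-out dose-response data.

Simulates cisplatin and paclitaxel dose-response curves for every
calibrated model (with its fitted f, g) and compares them with the 2D and
3D experimental stand-in curves: summed per-dose relative error plus a
replicate-level Kolmogorov-Smirnov test at each dose (threshold p<0.05).
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from omensim.behaviour_rules import DrugParameters, RuleParameters
from omensim.simulation_engine import simulate_dose_response
from omensim.synthetic_data import IC50, read_dataset_csv
from omensim.validation_analysis import DoseResponseCurve, dose_response_error, ks_two_sample

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location("calib", Path(__file__).parent / "02_calibrate_models.py")
_calib = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_calib)

OUT = Path("results/validation")
DOSES = [0.0, 0.8, 3.1, 12.5, 50.0]
MASTER_SEED = 55
N_REPLICATES = 10


def main() -> None:
    best_path = Path("results/calibration/best_params.json")
    drug_path = Path("results/drug_fit/drug_parameters.csv")
    if not (best_path.exists() and drug_path.exists()):
        raise SystemExit("run analysis/02 and analysis/03 first")
    best = {int(k): RuleParameters(*v) for k, v in json.loads(best_path.read_text()).items()}
    fits = pd.read_csv(drug_path).set_index(["model", "drug"])
    data = {
        "2D": read_dataset_csv(Path("results/datasets/dataset_2d.csv")),
        "3D": read_dataset_csv(Path("results/datasets/dataset_3d.csv")),
    }

    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for model, params in sorted(best.items()):
        cfg = dataclasses.replace(_calib.base_config(), rule_params=params)
        for drug, ic50 in IC50.items():
            fit = fits.loc[(model, drug)]
            tmpl = DrugParameters(f=fit["f"], g=fit["g"], ic50=ic50)
            sim = simulate_dose_response(
                cfg, DOSES, tmpl, n_replicates=N_REPLICATES,
                master_seed=MASTER_SEED, drug_name=drug,
            )
            for setting, ds in data.items():
                exp = ds.dose_response[drug]
                keep = np.isin(exp.concentrations, DOSES)
                exp_sub = DoseResponseCurve(
                    drug, exp.concentrations[keep], exp.viability[keep],
                    replicates=exp.replicates[keep] if exp.replicates is not None else None,
                )
                err = dose_response_error(sim, exp_sub)
                n_sig = 0
                if exp_sub.replicates is not None:
                    for i in range(len(DOSES)):
                        ks = ks_two_sample(sim.replicates[i], exp_sub.replicates[i])
                        n_sig += ks.significant
                rows.append(
                    {
                        "model": model, "drug": drug, "setting": setting,
                        "total_rel_error": err, "n_significant_ks": n_sig,
                        "pct_error": 100 * err / len(DOSES),
                    }
                )
        print(f"model {model}: validated against 2D and 3D curves for both drugs")

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "dose_response_errors.csv", index=False)
    summary = table.pivot_table(
        index="model", columns=["drug", "setting"], values="pct_error"
    ).round(1)
    print("\nmean per-dose percentage error (|S-E|/E, %):")
    print(summary.to_string())
    best_model = table.groupby("model")["total_rel_error"].sum().idxmin()
    print(f"\nlowest overall validation error: model {best_model}")
    print(f"wrote {OUT/'dose_response_errors.csv'}")


if __name__ == "__main__":
    main()
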